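"""Synthetic forest-plot generator.

Produces a full input set — stem census, ultrametric phylogeny, species
trait table, elevation surface and soil point samples — with the
statistical structure the downstream analysis assumes, under three named
assembly scenarios:

* ``neutral``   — stems placed by a Thomas cluster process only
  (dispersal limitation and demographic stochasticity; no interaction
  with the environment);
* ``filtered``  — the same cluster process thinned by a Gaussian niche
  acceptance probability exp(-(E(x) - mu_s)^2 / (2 sigma_f^2)), where
  E is a designated soil field and mu_s the species' environmental
  optimum (strong environmental filtering);
* ``mixed``     — intermediate niche breadth.

Each species' optimum mu_s is a linear map of its first trait onto the
observed range of the designated soil field, so filtering induces both
functional and, when traits carry phylogenetic signal (w > 0),
phylogenetic turnover.  Regional abundances are log-series, mimicking a
tropical-forest rank-abundance curve.  Soil and elevation surfaces are
Gaussian random fields with exponential covariance (circulant-embedding
FFT simulation); "range" is the e-folding correlation length, matching
the variogram convention in :mod:`forestbeta.soilenv`.

The soil sampling design emulates a standard forest-dynamics-plot
campaign: base points on a regular grid, plus satellites at paired radii
(2 & 5, 2 & 15 or 5 & 15 m) along a random compass bearing from each
base.  The published totals for this design are internally inconsistent,
so satellites-per-base is configuration, default 2 (the two radii of one
randomly chosen pair along one bearing).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field

import dendropy
import numpy as np
import pandas as pd

from .io import (DEFAULT_SOIL_VARIABLES, Phylogeny, SoilSampleTable,
                 StemCensus, TraitTable, ValidationError, logger)

SCENARIOS = ("neutral", "filtered", "mixed")

#: plausible field means for the default soil variables (units as labelled)
_SOIL_MEANS = {
    "pH": 4.8, "total_N": 1.6, "total_P": 0.35, "total_K": 8.0,
    "available_N": 120.0, "extractable_P": 4.5, "extractable_K": 95.0,
    "total_C": 22.0, "bulk_density": 1.1, "water_content": 28.0,
}
_SATELLITE_RADIUS_PAIRS = ((2.0, 5.0), (2.0, 15.0), (5.0, 15.0))


#: loading of each soil variable on the shared latent fertility/moisture
#: field; soil variables in stem-mapped plots are strongly cross-correlated
_SOIL_LOADINGS = {
    "pH": 0.7, "total_N": 0.9, "total_P": 0.8, "total_K": 0.5,
    "available_N": 0.85, "extractable_P": 0.6, "extractable_K": 0.55,
    "total_C": 0.85, "bulk_density": -0.6, "water_content": 0.8,
}


@dataclass
class FieldParams:
    mean: float
    sill: float
    range_: float   # correlation length, m
    nugget: float = 0.0
    latent_loading: float = 0.0  # correlation with the shared latent field

    def __post_init__(self) -> None:
        if self.range_ <= 0 or self.sill < 0 or self.nugget < 0:
            raise ValidationError("field parameters out of range")
        if not -1.0 <= self.latent_loading <= 1.0:
            raise ValidationError("latent loading must be in [-1, 1]")


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic plot.

    Defaults describe the full-size study system: a 20-ha (400 x 500 m)
    stem-mapped plot with ~10^5 stems of 450 species.  The scaled-down
    conditions used throughout the test suite (1 ha, 2,000 stems, 50
    species) are available via :meth:`scaled`.
    """

    n_species: int = 450
    n_stems: int = 100_000
    width: float = 400.0
    height: float = 500.0
    scenario: str = "filtered"
    sigma_f: float = 0.3          # niche breadth in field units (field sd = 1)
    parent_mean_offspring: float = 25.0  # stems per dispersal cluster
    offspring_sd: float = 15.0    # dispersal kernel sd, m
    trait_signal_w: float = 0.7   # 1 = pure Brownian traits
    n_traits: int = 8
    logseries_p: float = 0.995    # log-series shape for regional abundances
    resolution: float = 5.0       # landscape grid, m
    soil_params: dict = dc_field(default_factory=dict)
    elevation_params: FieldParams | None = None
    relief: tuple[float, float] = (708.2, 869.1)   # elevation extremes, m
    filter_variable: str = "total_N"
    env_elevation_corr: float = 0.0   # couples soil filter field to topography
    soil_grid_spacing: float = 30.0
    satellites_per_base: int = 2
    soil_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if min(self.n_species, self.n_stems, self.n_traits) < 1:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.trait_signal_w <= 1.0:
            raise ValidationError("trait signal weight w must be in [0, 1]")
        if self.sigma_f <= 0:
            raise ValidationError("sigma_f must be positive")
        if not self.soil_params:
            self.soil_params = {
                v: FieldParams(mean=_SOIL_MEANS[v], sill=1.0, range_=60.0,
                               nugget=0.1, latent_loading=_SOIL_LOADINGS[v])
                for v in DEFAULT_SOIL_VARIABLES
            }
        if self.elevation_params is None:
            self.elevation_params = FieldParams(mean=0.0, sill=1.0,
                                                range_=120.0, nugget=0.0)

    @classmethod
    def scaled(cls, scenario: str, seed: int = 0, **kw) -> "ScenarioConfig":
        """1-ha scaled-down conditions (2,000 stems, 50 species).

        Correlation lengths shrink with the plot so spatial structure is
        preserved at the smaller extent; the filtered preset couples the
        soil filter field to topography so habitats carry the filter.
        """
        sigma = {"neutral": 1.0, "filtered": 0.25, "mixed": 1.0}[scenario]
        defaults = dict(
            n_species=50, n_stems=2000, width=100.0, height=100.0,
            scenario=scenario, sigma_f=sigma,
            parent_mean_offspring=20.0, offspring_sd=10.0,
            soil_params={
                v: FieldParams(mean=_SOIL_MEANS[v], sill=1.0, range_=30.0,
                               nugget=0.1, latent_loading=_SOIL_LOADINGS[v])
                for v in DEFAULT_SOIL_VARIABLES
            },
            elevation_params=FieldParams(mean=0.0, sill=1.0, range_=60.0),
            env_elevation_corr=0.95 if scenario == "filtered" else 0.0,
            soil_grid_spacing=10.0,
            seed=seed,
        )
        defaults.update(kw)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Tree and traits
# ---------------------------------------------------------------------------


def species_labels(n: int) -> list[str]:
    return [f"sp{i:04d}" for i in range(n)]


def simulate_tree(n_tips: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree, root-to-tip depth 1."""
    if n_tips < 2:
        raise ValidationError("need at least 2 tips")
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(species_labels(n_tips))
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=rng,
    )
    tree.is_rooted = True
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return Phylogeny(tree)


def _brownian_plus_noise(phylo: Phylogeny, k: int, w: float,
                         rng: np.random.Generator) -> np.ndarray:
    """k columns of w * (BM along the tree, rate 1) + (1-w) * iid noise,
    rows ordered by sorted tip label."""
    tree = phylo.tree
    tips = sorted(phylo.tip_labels)
    bm = {t: np.zeros(k) for t in tips}
    state: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        parent = state.get(id(node.parent_node), np.zeros(k))
        bl = node.edge.length or 0.0
        val = parent + rng.standard_normal(k) * np.sqrt(bl)
        state[id(node)] = val
        if node.is_leaf():
            bm[node.taxon.label] = val
    bm_mat = np.array([bm[t] for t in tips])
    return w * bm_mat + (1.0 - w) * rng.standard_normal((len(tips), k))


def trait_loadings(k_traits: int) -> np.ndarray:
    """Default loadings of each trait on the shared latent axis (the
    leaf-economics-spectrum-like dominant axis of covariation)."""
    return np.geomspace(0.85, 0.3, k_traits)


def simulate_traits(phylo: Phylogeny, k_traits: int, w: float, seed: int,
                    loadings: np.ndarray | None = None) -> TraitTable:
    """Correlated traits mixing Brownian tree signal with tip noise.

    Traits covary along one latent axis, as measured functional traits
    do (a few principal components carry most trait variation): trait t
    is lam_t * L + sqrt(1 - lam_t^2) * own_t, where the latent axis L and
    each trait's own component are independent draws of
    w * (Brownian motion along the tree, rate 1) + (1 - w) * iid normal.
    Columns are standardized to mean 0 / sd 1 across species.  w = 1
    gives pure phylogenetic signal, w = 0 none; intermediate w emulates
    the weak-but-significant signal typical of field trait data.
    """
    if k_traits < 1:
        raise ValidationError("need at least 1 trait")
    if not 0.0 <= w <= 1.0:
        raise ValidationError("w must be in [0, 1]")
    lam = trait_loadings(k_traits) if loadings is None \
        else np.asarray(loadings, float)
    if lam.shape != (k_traits,) or np.any(np.abs(lam) > 1):
        raise ValidationError("need one loading in [-1, 1] per trait")
    rng = np.random.default_rng(seed)
    tips = sorted(phylo.tip_labels)
    latent = _brownian_plus_noise(phylo, 1, w, rng)[:, 0]
    latent = (latent - latent.mean()) / latent.std(ddof=1)
    own = _brownian_plus_noise(phylo, k_traits, w, rng)
    own = (own - own.mean(axis=0)) / own.std(axis=0, ddof=1)
    raw = lam[None, :] * latent[:, None] + np.sqrt(1 - lam ** 2)[None, :] * own
    z = (raw - raw.mean(axis=0)) / raw.std(axis=0, ddof=1)
    cols = [f"trait{i + 1}" for i in range(k_traits)]
    return TraitTable(pd.DataFrame(z, index=pd.Index(tips, name="species"),
                                   columns=cols))


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """Gridded elevation and soil fields over the plot."""

    width: float
    height: float
    resolution: float
    elevation: np.ndarray           # (n_rows, n_cols), value at cell centers
    fields: dict[str, np.ndarray]

    def _node_index(self, x, y):
        j = np.clip((np.asarray(x) / self.resolution).astype(int), 0,
                    self.elevation.shape[1] - 1)
        i = np.clip((np.asarray(y) / self.resolution).astype(int), 0,
                    self.elevation.shape[0] - 1)
        return i, j

    def value_at(self, name: str, x, y) -> np.ndarray:
        """Field value at the nearest grid node."""
        i, j = self._node_index(x, y)
        arr = self.elevation if name == "elevation" else self.fields[name]
        return arr[i, j]


def _gaussian_random_field(n_rows: int, n_cols: int, res: float,
                           sill: float, range_: float, nugget: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Stationary GRF with exponential covariance, by circulant embedding.

    C(h) = sill * exp(-h / range); a nugget adds iid noise on top.  Small
    negative embedding eigenvalues are clipped — the standard, slightly
    approximate variant, ample for generating test landscapes.
    """
    if sill <= 0:
        base = np.zeros((n_rows, n_cols))
    else:
        m, n = 2 * n_rows, 2 * n_cols
        iy = np.minimum(np.arange(m), m - np.arange(m)) * res
        ix = np.minimum(np.arange(n), n - np.arange(n)) * res
        h = np.sqrt(iy[:, None] ** 2 + ix[None, :] ** 2)
        cov = sill * np.exp(-h / range_)
        lam = np.fft.fft2(cov).real
        lam = np.clip(lam, 0.0, None)
        noise = rng.standard_normal((m, n)) + 1j * rng.standard_normal((m, n))
        f = np.fft.fft2(np.sqrt(lam / (m * n)) * noise)
        base = f.real[:n_rows, :n_cols]
    if nugget > 0:
        base = base + rng.standard_normal((n_rows, n_cols)) * np.sqrt(nugget)
    return base


def simulate_landscape(config: ScenarioConfig) -> Landscape:
    """Draw elevation and every soil field for one plot."""
    res = config.resolution
    for dim in (config.width, config.height):
        if abs(dim / res - round(dim / res)) > 1e-9:
            raise ValidationError(
                f"resolution {res} does not divide plot dimension {dim}"
            )
    n_cols = int(round(config.width / res))
    n_rows = int(round(config.height / res))
    rng = np.random.default_rng(config.seed)

    ep = config.elevation_params
    elev_raw = _gaussian_random_field(n_rows, n_cols, res, ep.sill, ep.range_,
                                      ep.nugget, rng)
    lo, hi = config.relief
    span = elev_raw.max() - elev_raw.min()
    if span > 0:
        elevation = lo + (elev_raw - elev_raw.min()) / span * (hi - lo)
    else:
        elevation = np.full_like(elev_raw, (lo + hi) / 2.0)
    elev_std = ((elev_raw - elev_raw.mean()) / elev_raw.std()
                if elev_raw.std() > 0 else np.zeros_like(elev_raw))

    # shared latent fertility/moisture field, optionally tied to topography
    rho = config.env_elevation_corr
    ranges = [p.range_ for p in config.soil_params.values()]
    latent_range = float(np.median(ranges)) if ranges else 30.0
    latent_raw = _gaussian_random_field(n_rows, n_cols, res, 1.0,
                                        latent_range, 0.0, rng)
    latent = ((latent_raw - latent_raw.mean()) / latent_raw.std()
              if latent_raw.std() > 0 else np.zeros_like(latent_raw))
    if rho != 0.0:
        latent = rho * elev_std + np.sqrt(1 - rho ** 2) * latent

    fields = {}
    for var, p in config.soil_params.items():
        own = _gaussian_random_field(n_rows, n_cols, res, 1.0, p.range_,
                                     0.0, rng)
        if own.std() > 0:
            own = (own - own.mean()) / own.std()
        lam = p.latent_loading
        z = lam * latent + np.sqrt(1 - lam ** 2) * own
        raw = np.sqrt(p.sill) * z
        if p.nugget > 0:
            raw = raw + rng.standard_normal(raw.shape) * np.sqrt(p.nugget)
        fields[var] = p.mean + raw
    return Landscape(width=config.width, height=config.height, resolution=res,
                     elevation=elevation, fields=fields)


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


def _regional_abundances(n_species: int, p: float,
                         rng: np.random.Generator) -> np.ndarray:
    from scipy.stats import logser
    weights = logser.rvs(p, size=n_species, random_state=rng).astype(float)
    return weights / weights.sum()


def species_optima(traits: TraitTable, landscape: Landscape,
                   filter_variable: str) -> pd.Series:
    """Environmental optimum mu_s: trait 1 mapped onto the field's range."""
    t = traits.table.iloc[:, 0]
    field = landscape.fields[filter_variable]
    t_lo, t_hi = float(t.min()), float(t.max())
    span = (t_hi - t_lo) or 1.0
    frac = (t - t_lo) / span
    return field.min() + frac * (field.max() - field.min())


def simulate_census(phylo: Phylogeny, traits: TraitTable,
                    landscape: Landscape, config: ScenarioConfig
                    ) -> StemCensus:
    """Place stems by a Thomas cluster process with optional niche thinning.

    Regional species abundances are log-series; each species' stems
    descend from uniformly placed cluster parents with Gaussian offspring
    displacement (dispersal limitation).  Under ``filtered``/``mixed``
    a stem at x survives with probability
    exp(-(E(x) - mu_s)^2 / (2 sigma_f^2)); under ``neutral`` every stem
    survives.  Rejected positions are resampled until the configured stem
    count is reached (retry cap 500 x target per species).
    """
    species = sorted(traits.species)
    if set(species) != set(phylo.tip_labels):
        raise ValidationError("tree and trait table species sets differ")
    rng = np.random.default_rng(config.seed + 1)
    p = _regional_abundances(len(species), config.logseries_p, rng)
    targets = rng.multinomial(config.n_stems, p)
    mu = species_optima(traits, landscape, config.filter_variable)
    use_filter = config.scenario in ("filtered", "mixed")
    sig2 = 2.0 * config.sigma_f ** 2
    w, h = config.width, config.height

    def _acceptance(xs: np.ndarray, ys: np.ndarray, mu_s: float) -> np.ndarray:
        e = landscape.value_at(config.filter_variable, xs, ys)
        return np.exp(-(np.asarray(e, float) - mu_s) ** 2 / sig2)

    def _place_parents(n_parents: int, mu_s: float) -> tuple[np.ndarray, np.ndarray]:
        # parents establish under the same filter as their offspring, so
        # dispersal clusters sit inside suitable habitat
        px = np.empty(n_parents)
        py = np.empty(n_parents)
        got = 0
        best_xy, best_p = [], []
        for _ in range(200):
            cx = rng.uniform(0, w, 64)
            cy = rng.uniform(0, h, 64)
            if use_filter:
                acc = _acceptance(cx, cy, mu_s)
                keep = rng.random(64) < acc
                best_xy.append(np.column_stack([cx, cy]))
                best_p.append(acc)
            else:
                keep = np.ones(64, bool)
            take = min(int(keep.sum()), n_parents - got)
            px[got:got + take] = cx[keep][:take]
            py[got:got + take] = cy[keep][:take]
            got += take
            if got == n_parents:
                return px, py
        # near-degenerate niche (sigma_f -> 0): put the remaining parents
        # at the most suitable candidate sites seen
        cand = np.concatenate(best_xy)
        acc = np.concatenate(best_p)
        order = np.argsort(acc)[::-1]
        need = n_parents - got
        if acc[order[need - 1]] < 1e-12:
            raise ValidationError(
                "could not place cluster parents; acceptance probability "
                "too low everywhere (sigma_f too small for this field)"
            )
        px[got:] = cand[order[:need], 0]
        py[got:] = cand[order[:need], 1]
        return px, py

    rows_sp, rows_x, rows_y = [], [], []
    for s, n_s in zip(species, targets):
        if n_s == 0:
            continue
        n_parents = max(1, int(round(n_s / config.parent_mean_offspring)))
        px, py = _place_parents(n_parents, float(mu[s]))
        xs = np.empty(n_s)
        ys = np.empty(n_s)
        accepted = 0
        batches = 0
        cap = 200 + 500 * int(np.ceil(n_s / 64))
        cand_xy, cand_p = [], []
        while accepted < n_s:
            batches += 1
            if batches > cap:
                # sigma_f -> 0 limit: fill with the most suitable in-plot
                # candidates seen; give up only if acceptance is ~0
                # everywhere around the parents
                cand = np.concatenate(cand_xy) if cand_xy else np.empty((0, 2))
                acc = np.concatenate(cand_p) if cand_p else np.empty(0)
                need = n_s - accepted
                order = np.argsort(acc)[::-1]
                if len(acc) < need or acc[order[need - 1]] < 1e-12:
                    raise ValidationError(
                        f"could not place {n_s} stems of {s} within retry "
                        "cap; acceptance probability too low everywhere"
                    )
                xs[accepted:] = cand[order[:need], 0]
                ys[accepted:] = cand[order[:need], 1]
                accepted = n_s
                break
            k = rng.integers(n_parents, size=64)
            cx = px[k] + rng.normal(0, config.offspring_sd, 64)
            cy = py[k] + rng.normal(0, config.offspring_sd, 64)
            keep = (cx >= 0) & (cx < w) & (cy >= 0) & (cy < h)
            if use_filter:
                acc = np.zeros(64)
                acc[keep] = _acceptance(cx[keep], cy[keep], float(mu[s]))
                cand_xy.append(np.column_stack([cx[keep], cy[keep]]))
                cand_p.append(acc[keep])
                keep = rng.random(64) < acc
            take = min(int(keep.sum()), n_s - accepted)
            xs[accepted:accepted + take] = cx[keep][:take]
            ys[accepted:accepted + take] = cy[keep][:take]
            accepted += take
        rows_sp.extend([s] * n_s)
        rows_x.append(xs)
        rows_y.append(ys)

    df = pd.DataFrame({
        "stem_id": [f"stem{i:06d}" for i in range(len(rows_sp))],
        "species": rows_sp,
        "x": np.concatenate(rows_x) if rows_x else np.array([]),
        "y": np.concatenate(rows_y) if rows_y else np.array([]),
    })
    census = StemCensus(df, width=w, height=h)
    assert census.n_stems == config.n_stems
    return census


# ---------------------------------------------------------------------------
# Soil sampling
# ---------------------------------------------------------------------------


def simulate_soil_sampling(landscape: Landscape, config: ScenarioConfig
                           ) -> SoilSampleTable:
    """Grid-plus-satellite soil sampling read off the landscape fields.

    Base points at every grid intersection in the half-open plot extent;
    per base, one radius pair and one bearing are drawn, and satellites
    are placed at the pair's radii (cycled) along that bearing.  A
    satellite falling outside the plot gets a fresh bearing (up to 200
    tries).  Observation noise (sd ``soil_noise_sd``) is added on top of
    the nearest-node field value.
    """
    spacing = config.soil_grid_spacing
    if spacing >= min(config.width, config.height):
        raise ValidationError("plot smaller than soil grid spacing")
    rng = np.random.default_rng(config.seed + 2)
    bx = np.arange(0.0, config.width, spacing)
    by = np.arange(0.0, config.height, spacing)
    bases = [(x, y) for y in by for x in bx]
    logger.info("soil design: %d base points on a %g m grid, %d satellites "
                "each", len(bases), spacing, config.satellites_per_base)

    pts = []
    for (x0, y0) in bases:
        pts.append((x0, y0))
        pair = _SATELLITE_RADIUS_PAIRS[int(rng.integers(3))]
        radii = [pair[k % 2] for k in range(config.satellites_per_base)]
        for _ in range(200):  # one shared bearing; redraw until all inside
            theta = rng.uniform(0, 2 * np.pi)
            cand = [(x0 + r * np.cos(theta), y0 + r * np.sin(theta))
                    for r in radii]
            if all(0 <= x < config.width and 0 <= y < config.height
                   for x, y in cand):
                pts.extend(cand)
                break
        else:
            logger.warning("no in-plot bearing for satellites of base "
                           "(%g, %g); skipped", x0, y0)

    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    data = {"x": xs, "y": ys}
    for var in landscape.fields:
        vals = landscape.value_at(var, xs, ys).astype(float)
        if config.soil_noise_sd > 0:
            vals = vals + rng.normal(0, config.soil_noise_sd, len(vals))
        data[var] = vals
    return SoilSampleTable(pd.DataFrame(data), list(landscape.fields))


def simulate_all(config: ScenarioConfig):
    """One full synthetic input set: tree, traits, landscape, census, soil."""
    phylo = simulate_tree(config.n_species, config.seed)
    traits = simulate_traits(phylo, config.n_traits, config.trait_signal_w,
                             config.seed + 3)
    landscape = simulate_landscape(config)
    census = simulate_census(phylo, traits, landscape, config)
    soil = simulate_soil_sampling(landscape, config)
    return phylo, traits, landscape, census, soil
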