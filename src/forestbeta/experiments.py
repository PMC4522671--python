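"""Canned experiments over the synthetic study conditions.

These are the replicable computations behind the pipeline's headline
properties, shared by the analysis drivers, the test suite and the
acceptance script:

* :func:`scenario_partition` — one scaled replicate (1 ha, 2,000 stems,
  50 species) of the full simulate → grid → krige → beta → MRM chain at
  the 20 m scale, returning the pure-geographic and pure-environmental
  fractions per distance source and metric;
* :func:`habitat_direction` — the same replicate extended with SES and
  the within- vs across-habitat contrast;
* :func:`ses_calibration` — SES of randomly assembled communities with
  no trait or tree structure, which should be centred on zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import beta as beta_mod
from . import grid as grid_mod
from . import habitat as habitat_mod
from . import io as io_mod
from . import mrm as mrm_mod
from . import nullses as nullses_mod
from . import simulate as sim_mod
from . import soilenv as soilenv_mod
from . import traitspace as traitspace_mod


@dataclass
class ScenarioReplicate:
    """Everything one scaled replicate produces up to the beta matrices."""

    scenario: str
    seed: int
    landscape: sim_mod.Landscape
    grid: grid_mod.SubplotGrid
    community: grid_mod.CommunityMatrix
    deltas: dict[str, io_mod.DistanceMatrix]
    geo: io_mod.DistanceMatrix
    env: io_mod.DistanceMatrix
    occupied_labels: list[str]


def build_replicate(scenario: str, seed: int, scale: float = 20.0,
                    n_trait_axes: int = 3, n_env_axes: int = 3
                    ) -> ScenarioReplicate:
    """Simulate one scaled plot and assemble all distance matrices."""
    cfg = sim_mod.ScenarioConfig.scaled(scenario, seed=seed)
    phylo, traits, landscape, census, soil = sim_mod.simulate_all(cfg)

    grd = grid_mod.subdivide_plot(cfg.width, cfg.height, scale)
    cm = grid_mod.build_community_matrix(census, grd)
    geo = grid_mod.geographic_distances(grd)

    env_table = soilenv_mod.krige_all(soil, grd)
    env, _ = soilenv_mod.environment_distance(env_table, n_axes=n_env_axes)

    phylo_delta = io_mod.cophenetic_distance(phylo)
    pca = traitspace_mod.trait_pca(traits, n_axes=n_trait_axes)
    dend = traitspace_mod.upgma(traitspace_mod.trait_distance(pca.scores))
    func_delta = traitspace_mod.dendrogram_cophenetic(dend)

    present = sorted(census.species)
    deltas = {
        "phylo": phylo_delta.submatrix(present),
        "func": func_delta.submatrix(present),
    }
    occupied = cm.abundance[present].to_numpy(float).sum(axis=1) > 0
    occ_labels = [cid for cid, keep in zip(grd.cell_ids, occupied) if keep]
    return ScenarioReplicate(
        scenario=scenario, seed=seed, landscape=landscape, grid=grd,
        community=cm.restrict_species(present), deltas=deltas,
        geo=geo, env=env, occupied_labels=occ_labels,
    )


def beta_matrix(rep: ScenarioReplicate, source: str, metric: str,
                weighted: bool = True) -> io_mod.DistanceMatrix:
    """One beta-diversity distance matrix over non-empty subplots."""
    delta = rep.deltas[source]
    counts = rep.community.abundance[delta.labels].to_numpy(float)
    mats = beta_mod.pair_beta_matrices(counts, delta.values,
                                       weighted=weighted)
    ids = rep.community.abundance.index.to_list()
    idx = [ids.index(l) for l in rep.occupied_labels]
    vals = mats[metric][np.ix_(idx, idx)].copy()
    np.fill_diagonal(vals, 0.0)
    return io_mod.DistanceMatrix(rep.occupied_labels, vals)


def scenario_partition(scenario: str, seed: int, scale: float = 20.0,
                       n_perm: int = 99, weighted: bool = True
                       ) -> pd.DataFrame:
    """Variation partition of every source x metric at one scale.

    Returns a row per (source, metric) with the full, marginal and pure
    R2 fractions for the given scenario replicate.
    """
    rep = build_replicate(scenario, seed, scale=scale)
    geo = rep.geo.submatrix(rep.occupied_labels)
    env = rep.env.submatrix(rep.occupied_labels)
    rows = []
    for source in rep.deltas:
        for metric in beta_mod.METRICS:
            d = beta_matrix(rep, source, metric, weighted=weighted)
            part = mrm_mod.variation_partition(d, geo, env, n_perm=n_perm,
                                               seed=seed)
            part.scale = scale
            part.metric = f"{source}_{metric}"
            rows.append(part.to_row())
    out = pd.DataFrame(rows)
    out.insert(0, "scenario", scenario)
    out.insert(1, "seed", seed)
    return out


def habitat_direction(seed: int, scenario: str = "filtered",
                      scale: float = 10.0, n_null: int = 199,
                      source: str = "func", metric: str = "dpw",
                      weighted: bool = False, method: str = "threshold",
                      welch: bool = False) -> habitat_mod.HabitatContrast:
    """Within- vs across-habitat SES contrast for one scaled replicate.

    Scaled defaults: on a 1-ha plot the 10 m subplots (100 cells) are the
    proportionate analogue of 20 m subplots on 20 ha (500 cells), and the
    elevation-tercile classifier is the robust habitat delineation at this
    extent; occurrence-based (unweighted) SES avoids the dominance noise a
    50-species log-series pool puts into the abundance-weighted forms.
    """
    rep = build_replicate(scenario, seed, scale=scale)
    ses_table = nullses_mod.ses(rep.community, rep.deltas[source],
                                weighted=weighted, n_null=n_null, seed=seed)
    metrics = habitat_mod.topo_metrics(rep.landscape, rep.grid)
    hmap = habitat_mod.classify_habitats(metrics, method=method, seed=seed)
    return habitat_mod.within_across_test(ses_table, hmap, metric=metric,
                                          welch=welch)


def random_communities(n_species: int, n_subplots: int, richness: int,
                       seed: int) -> grid_mod.CommunityMatrix:
    """Communities drawn at random from the pool: no spatial, trait or
    phylogenetic structure, the null-calibration reference."""
    rng = np.random.default_rng(seed)
    species = sim_mod.species_labels(n_species)
    side = int(np.ceil(np.sqrt(n_subplots)))
    grd = grid_mod.subdivide_plot(side * 10.0, side * 10.0, 10.0)
    counts = np.zeros((grd.n_cells, n_species), dtype=int)
    for i in range(n_subplots):
        chosen = rng.choice(n_species, size=richness, replace=False)
        counts[i, chosen] = rng.integers(1, 10, size=richness)
    return grid_mod.CommunityMatrix(
        grd, pd.DataFrame(counts, index=grd.cell_ids, columns=species))


def ses_calibration(seed: int, n_species: int = 20, n_subplots: int = 16,
                    richness: int = 8, n_null: int = 199) -> pd.DataFrame:
    """SES table for structureless random communities on a random tree."""
    phylo = sim_mod.simulate_tree(n_species, seed)
    delta = io_mod.cophenetic_distance(phylo)
    cm = random_communities(n_species, n_subplots, richness, seed + 1)
    return nullses_mod.ses(cm, delta, weighted=True, n_null=n_null,
                           seed=seed + 2)
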