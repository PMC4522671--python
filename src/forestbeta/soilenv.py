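"""Soil geostatistics and environmental distances.

Point soil samples are interpolated to subplot block means by ordinary
block kriging under a fitted variogram model, the kriged per-subplot
soil profiles are summarized by PCA, and the environmental distance
between two subplots is the Euclidean distance between their scores on
the first three principal components.

Conventions.  The variogram model is parameterized as

    gamma(h) = nugget + psill * g(h / range)

with g the unit exponential 1 - exp(-h/L) (default) or spherical form;
``range`` is therefore the e-folding correlation length L for the
exponential family, not the 95% practical range (~3L).  The same
convention is used by the synthetic landscape generator, so simulation
recovery tests compare like with like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.decomposition import PCA

from .grid import SubplotGrid
from .io import DistanceMatrix, SoilSampleTable, ValidationError, logger

FAMILIES = ("exponential", "spherical")


@dataclass
class VariogramModel:
    family: str
    nugget: float
    psill: float      # partial sill (sill - nugget)
    range_: float     # correlation length L, m

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.psill < 0 or self.range_ <= 0:
            raise ValidationError("variogram parameters out of range")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.family == "exponential":
            g = 1.0 - np.exp(-h / self.range_)
        else:  # spherical, with "range" the full spherical range
            r = np.clip(h / self.range_, 0.0, 1.0)
            g = 1.5 * r - 0.5 * r ** 3
        out = self.nugget + self.psill * g
        return np.where(h == 0, 0.0, out)  # gamma(0) = 0 by definition


@dataclass
class EmpiricalVariogram:
    lags: np.ndarray        # bin-center lag distances, m
    semivariance: np.ndarray
    counts: np.ndarray      # pair counts per bin


def empirical_variogram(samples: SoilSampleTable, variable: str,
                        n_bins: int = 15, max_lag: float | None = None
                        ) -> EmpiricalVariogram:
    """Binned Matheron semivariance estimator.

    gamma_hat(h) = (1 / 2 N(h)) * sum over pairs in the bin of (z_i - z_j)^2.
    Empty bins are flagged (count 0, NaN semivariance) and excluded from
    fitting.  Default max lag is one third of the maximum pairwise
    distance — long lags carry few, strongly dependent pairs and
    destabilize the model fit.
    """
    if variable not in samples.variables:
        raise ValidationError(f"soil variable {variable!r} absent from table")
    if samples.n_points < 30:
        logger.warning("only %d sample points for variogram of %s",
                       samples.n_points, variable)
    xy = samples.coords()
    z = samples.samples[variable].to_numpy(float)
    diff = xy[:, None, :] - xy[None, :, :]
    h = np.sqrt((diff ** 2).sum(axis=-1))
    iu = np.triu_indices(len(z), k=1)
    h = h[iu]
    sq = (z[:, None] - z[None, :])[iu] ** 2
    if max_lag is None:
        max_lag = float(h.max()) / 3.0
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    keep = h <= max_lag
    which = np.clip(np.digitize(h[keep], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sq[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * counts), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_empty = int((counts == 0).sum())
    if n_empty:
        logger.info("%d empty variogram lag bins excluded", n_empty)
    return EmpiricalVariogram(lags=centers, semivariance=gamma, counts=counts)


def fit_variogram(emp: EmpiricalVariogram, family: str = "exponential"
                  ) -> VariogramModel:
    """Weighted least-squares fit (weights = pair counts per bin).

    Parameters are bounded — partial sill by a multiple of the largest
    binned semivariance and range by twice the largest lag — to exclude
    the degenerate near-linear limit (range and sill growing without
    bound in lockstep) that unconstrained WLS drifts into on noisy
    empirical variograms.
    """
    ok = (emp.counts > 0) & np.isfinite(emp.semivariance)
    if ok.sum() < 4:
        raise ValidationError(
            f"variogram fit needs >= 4 non-empty bins, have {int(ok.sum())}"
        )
    h = emp.lags[ok]
    g = emp.semivariance[ok]
    w = np.sqrt(emp.counts[ok].astype(float))
    sill0 = max(float(g.mean()), 1e-12)
    range0 = max(float(h.mean()) / 2.0, 1e-6)
    sill_cap = max(5.0 * float(g.max()), 1e-9)
    range_cap = 2.0 * float(h.max())

    def resid(theta):
        nugget, psill, rng = theta
        model = VariogramModel(family, max(nugget, 0.0), max(psill, 0.0),
                               max(rng, 1e-9))
        return w * (model(h) - g)

    fit = least_squares(
        resid, x0=[0.1 * sill0, 0.9 * sill0, range0],
        bounds=([0.0, 0.0, 1e-9], [sill_cap, sill_cap, range_cap]),
    )
    if not fit.success:
        raise ValidationError(f"variogram fit did not converge: {fit.message}")
    nugget, psill, rng = fit.x
    model = VariogramModel(family, float(nugget), float(psill), float(rng))
    logger.info("variogram fit (%s): nugget=%.4g psill=%.4g range=%.4g, "
                "cost=%.4g", family, nugget, psill, rng, fit.cost)
    return model


def _dedupe(xy: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    _, idx = np.unique(np.round(xy, 9), axis=0, return_index=True)
    if len(idx) < len(xy):
        logger.warning("deduplicated %d coincident soil sample points",
                       len(xy) - len(idx))
    idx = np.sort(idx)
    return xy[idx], z[idx]


def block_krige(samples: SoilSampleTable, model: VariogramModel,
                grid: SubplotGrid, variable: str,
                discretization: int = 4,
                return_weights: bool = False):
    """Ordinary block kriging of each subplot's mean soil value.

    The block integral is approximated by a ``discretization`` x
    ``discretization`` point grid inside each subplot.  One ordinary-
    kriging system (semivariance form, Lagrange multiplier for the
    unbiasedness constraint) is factorized once and solved against all
    block right-hand sides; the weights of every prediction sum to 1.
    """
    if variable not in samples.variables:
        raise ValidationError(f"soil variable {variable!r} absent from table")
    xy = samples.coords()
    z = samples.samples[variable].to_numpy(float)
    xy, z = _dedupe(xy, z)
    n = len(z)
    if n < 2:
        raise ValidationError("block kriging needs at least 2 samples")

    # LHS: [[Gamma, 1], [1', 0]]
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    lhs = np.empty((n + 1, n + 1))
    lhs[:n, :n] = model(d)
    lhs[n, :n] = lhs[:n, n] = 1.0
    lhs[n, n] = 0.0

    # block discretization points per cell
    k = discretization
    offs = (np.arange(k) + 0.5) / k * grid.scale
    ox, oy = np.meshgrid(offs, offs)
    offsets = np.column_stack([ox.ravel(), oy.ravel()])  # (k*k, 2)
    centers = grid.centers() - grid.scale / 2.0           # cell origins

    rhs = np.empty((n + 1, grid.n_cells))
    for c in range(grid.n_cells):
        pts = centers[c][None, :] + offsets
        dd = np.sqrt(((xy[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1))
        rhs[:n, c] = model(dd).mean(axis=1)  # mean sample-to-block semivariance
    rhs[n, :] = 1.0

    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular kriging system: {exc}") from exc
    weights = sol[:n, :]
    wsum = weights.sum(axis=0)
    if not np.allclose(wsum, 1.0, atol=1e-8):
        raise ValidationError("kriging weights do not sum to 1")
    pred = weights.T @ z
    out = pd.Series(pred, index=grid.cell_ids, name=variable)
    if return_weights:
        return out, weights
    return out


def krige_all(samples: SoilSampleTable, grid: SubplotGrid,
              family: str = "exponential", n_bins: int = 12,
              discretization: int = 4) -> pd.DataFrame:
    """Variogram fit + block kriging for every soil variable."""
    cols = {}
    for var in samples.variables:
        emp = empirical_variogram(samples, var, n_bins=n_bins)
        model = fit_variogram(emp, family=family)
        cols[var] = block_krige(samples, model, grid, var,
                                discretization=discretization)
    return pd.DataFrame(cols)


def environment_distance(env: pd.DataFrame, n_axes: int = 3
                         ) -> tuple[DistanceMatrix, np.ndarray]:
    """Euclidean distance between subplots on the first soil PCA axes.

    Soil variables are z-scored before the PCA (their units differ
    wildly), and the distance uses the first ``n_axes`` component scores.
    Returns the distance matrix and the variance-explained fractions.
    """
    if env.isna().any().any():
        raise ValidationError("environment table has missing values")
    sd = env.std(ddof=1)
    keep = list(sd.index[sd > 0])
    dropped = [c for c in env.columns if c not in keep]
    if dropped:
        logger.warning("dropping zero-variance soil variables: %s", dropped)
    z = (env[keep] - env[keep].mean()) / env[keep].std(ddof=1)
    n_avail = min(n_axes, z.shape[1], z.shape[0] - 1)
    if n_avail < n_axes:
        logger.warning("only %d positive-variance components available "
                       "(requested %d)", n_avail, n_axes)
    pca = PCA(n_components=n_avail)
    scores = pca.fit_transform(z.to_numpy())
    diff = scores[:, None, :] - scores[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return (DistanceMatrix([str(i) for i in env.index], d),
            pca.explained_variance_ratio_.copy())
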