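"""Multiple regression on distance matrices and variation partitioning.

MRM regresses the vectorized lower triangle of a dependent distance
matrix (here: D_pw' or D_nn' between subplots) on the lower triangles of
explanatory distance matrices (geographic and environmental distance).
Significance comes from permuting the rows and columns of the dependent
matrix jointly and refitting — the Lichstein-style scheme, which
preserves the dependence structure among pairwise distances that plain
residual permutation would destroy.

Variation partitioning fits three models (geo + env, geo alone, env
alone) and decomposes the full R² by differencing:

    pure_geo = R²_full - R²_env_only
    pure_env = R²_full - R²_geo_only
    shared   = R²_geo_only + R²_env_only - R²_full

The shared fraction can be negative (suppression) and is reported
as-is.  The marginal single-matrix R² values are reported alongside the
differenced pure fractions, since published tables are not always
explicit about which rendering they print.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DistanceMatrix, ValidationError


def lower_triangle(dm: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Strictly-below-diagonal entries, row-major order."""
    values = dm.values if isinstance(dm, DistanceMatrix) else np.asarray(dm)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("lower_triangle needs a square matrix")
    if not np.allclose(values, values.T, atol=1e-10, equal_nan=True):
        raise ValidationError("matrix is not symmetric")
    n = values.shape[0]
    rows, cols = np.tril_indices(n, k=-1)
    return values[rows, cols]


@dataclass
class MrmFit:
    r2: float
    coefficients: np.ndarray    # intercept first
    coef_pvalues: np.ndarray    # permutation p per slope (two-sided)
    model_pvalue: float         # permutation p for R² (upper tail)
    n_permutations: int
    names: list[str] = field(default_factory=list)


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else 0.0
    return r2, beta


def mrm_fit(d: DistanceMatrix, xs: list[DistanceMatrix],
            n_perm: int = 999, seed: int | np.random.Generator = 0,
            names: list[str] | None = None) -> MrmFit:
    """OLS on vectorized lower triangles with matrix-permutation tests."""
    if not xs:
        raise ValidationError("need at least one explanatory matrix")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    for x in xs:
        if x.labels != d.labels:
            raise ValidationError("matrices have different labels/order")
    y = lower_triangle(d)
    x_cols = np.column_stack([lower_triangle(x) for x in xs])

    # collinearity guard: refuse perfectly correlated explanatory vectors
    if x_cols.shape[1] > 1:
        cc = np.corrcoef(x_cols, rowvar=False)
        for i in range(len(xs)):
            for j in range(i + 1, len(xs)):
                if abs(cc[i, j]) > 1.0 - 1e-10:
                    raise ValidationError(
                        f"explanatory matrices {i} and {j} are collinear"
                    )

    r2_obs, beta_obs = _ols(y, x_cols)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed

    n = len(d.labels)
    values = d.values
    ge_r2 = 0
    ge_coef = np.zeros(x_cols.shape[1])
    rows, cols = np.tril_indices(n, k=-1)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = values[np.ix_(perm, perm)][rows, cols]
        r2_p, beta_p = _ols(y_perm, x_cols)
        ge_r2 += r2_p >= r2_obs
        ge_coef += np.abs(beta_p[1:]) >= np.abs(beta_obs[1:])
    model_p = (1.0 + ge_r2) / (1.0 + n_perm)
    coef_p = (1.0 + ge_coef) / (1.0 + n_perm)
    return MrmFit(r2=r2_obs, coefficients=beta_obs, coef_pvalues=coef_p,
                  model_pvalue=model_p, n_permutations=n_perm,
                  names=names or [f"x{i}" for i in range(len(xs))])


@dataclass
class MrmResult:
    """Two-block variation partition of one beta-diversity matrix."""

    r2_full: float
    r2_geo_only: float
    r2_env_only: float
    p_full: float
    p_geo_only: float
    p_env_only: float
    coefficients: np.ndarray
    n_permutations: int
    scale: float | None = None
    metric: str | None = None

    @property
    def pure_geo(self) -> float:
        return self.r2_full - self.r2_env_only

    @property
    def pure_env(self) -> float:
        return self.r2_full - self.r2_geo_only

    @property
    def shared(self) -> float:
        return self.r2_geo_only + self.r2_env_only - self.r2_full

    def to_row(self) -> dict:
        return {
            "scale": self.scale, "metric": self.metric,
            "r2_full": self.r2_full, "p_full": self.p_full,
            "r2_geo_only": self.r2_geo_only, "p_geo_only": self.p_geo_only,
            "r2_env_only": self.r2_env_only, "p_env_only": self.p_env_only,
            "pure_geo": self.pure_geo, "pure_env": self.pure_env,
            "shared": self.shared,
        }


def variation_partition(d: DistanceMatrix, geo: DistanceMatrix,
                        env: DistanceMatrix, n_perm: int = 999,
                        seed: int = 0) -> MrmResult:
    """Partition beta diversity between geographic and environmental blocks."""
    full = mrm_fit(d, [geo, env], n_perm=n_perm, seed=seed,
                   names=["geo", "env"])
    g = mrm_fit(d, [geo], n_perm=n_perm, seed=seed + 1, names=["geo"])
    e = mrm_fit(d, [env], n_perm=n_perm, seed=seed + 2, names=["env"])
    return MrmResult(
        r2_full=full.r2, r2_geo_only=g.r2, r2_env_only=e.r2,
        p_full=full.model_pvalue, p_geo_only=g.model_pvalue,
        p_env_only=e.model_pvalue, coefficients=full.coefficients,
        n_permutations=n_perm,
    )


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def partition_table(results: list[MrmResult]) -> pd.DataFrame:
    """Render partitions in the conventional published layout.

    One row per scale x metric with the combined R² and both the
    differenced pure fractions and the marginal single-matrix R² values,
    significance-starred from the permutation tests.
    """
    rows = []
    for r in results:
        rows.append({
            "scale": r.scale,
            "metric": r.metric,
            "combined": f"{r.r2_full:.3f}{_stars(r.p_full)}",
            "pure_geographic": f"{r.pure_geo:.3f}{_stars(r.p_geo_only)}",
            "pure_environmental": f"{r.pure_env:.3f}{_stars(r.p_env_only)}",
            "marginal_geographic": f"{r.r2_geo_only:.3f}{_stars(r.p_geo_only)}",
            "marginal_environmental": f"{r.r2_env_only:.3f}{_stars(r.p_env_only)}",
            "shared": f"{r.shared:.3f}",
        })
    return pd.DataFrame(rows)
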