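"""Topographic habitat classification and within- vs across-habitat SES.

Each 20 m subplot is summarized by three topographic metrics — mean
elevation, mean slope (gradient magnitude of the elevation surface) and
convexity (subplot mean elevation minus the mean of its edge-adjacent
neighbours) — and classified into three habitat types (valley, slope,
ridge).  The default classifier is k-means (k = 3) on z-scored metrics
with cluster labels mapped to habitat names by ascending mean elevation;
a quantile threshold rule is available as an alternative, since the
exact published delineation rules for such plots vary.

The habitat contrast partitions subplot-pair SES values into
within-habitat pairs (V-V, S-S, R-R) and across-habitat pairs (V-S,
V-R, S-R) and compares group means with a two-sample t test (pooled
Student's by default, Welch behind a flag).  Pairwise SES values are not
independent; the test inherits that limitation from the study design and
is reported as a descriptive contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .grid import SubplotGrid
from .io import ValidationError, logger
from .simulate import Landscape

HABITATS = ("valley", "slope", "ridge")


def topo_metrics(landscape: Landscape, grid: SubplotGrid) -> pd.DataFrame:
    """Per-subplot elevation, slope and convexity from the elevation field."""
    res = landscape.resolution
    if res > grid.scale:
        raise ValidationError("elevation field coarser than subplot scale")
    elev = landscape.elevation
    gy, gx = np.gradient(elev, res)
    slope_field = np.sqrt(gx ** 2 + gy ** 2)

    n_rows, n_cols = grid.n_rows, grid.n_cols
    k = int(round(grid.scale / res))
    mean_elev = np.zeros((n_rows, n_cols))
    mean_slope = np.zeros((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            block = np.s_[r * k:(r + 1) * k, c * k:(c + 1) * k]
            mean_elev[r, c] = elev[block].mean()
            mean_slope[r, c] = slope_field[block].mean()

    convexity = np.zeros((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            neigh = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    neigh.append(mean_elev[rr, cc])
            convexity[r, c] = mean_elev[r, c] - float(np.mean(neigh))

    return pd.DataFrame({
        "elevation": mean_elev.ravel(),
        "slope": mean_slope.ravel(),
        "convexity": convexity.ravel(),
    }, index=grid.cell_ids)


@dataclass
class HabitatMap:
    labels: pd.Series          # subplot id -> habitat name
    metrics: pd.DataFrame

    def __post_init__(self) -> None:
        used = set(self.labels.unique())
        if used != set(HABITATS):
            logger.warning("habitat map uses %d labels, expected 3: %s",
                           len(used), sorted(used))

    def write_csv(self, path) -> None:
        out = self.labels.rename("habitat").to_frame()
        out.index.name = "subplot_id"
        out.to_csv(path)


def classify_habitats(metrics: pd.DataFrame, method: str = "kmeans3",
                      seed: int = 0) -> HabitatMap:
    """Assign valley / slope / ridge to each subplot.

    ``kmeans3``: k-means on z-scored (elevation, slope, convexity),
    clusters renamed by ascending mean elevation.  ``threshold``:
    elevation terciles.  Degenerate (all-identical) metrics are rejected
    for k-means with advice to use the threshold rule.
    """
    cols = ["elevation", "slope", "convexity"]
    x = metrics[cols].to_numpy(float)
    if method == "kmeans3":
        sd = x.std(axis=0, ddof=1)
        if np.all(sd == 0):
            raise ValidationError(
                "all topographic metrics identical; use method='threshold'"
            )
        z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        km = KMeans(n_clusters=3, n_init=10, random_state=seed)
        cluster = km.fit_predict(z)
        order = np.argsort([metrics["elevation"].to_numpy()[cluster == c].mean()
                            for c in range(3)])
        name = {c: HABITATS[rank] for rank, c in enumerate(order)}
        labels = pd.Series([name[c] for c in cluster], index=metrics.index)
    elif method == "threshold":
        terciles = np.quantile(metrics["elevation"], [1 / 3, 2 / 3])
        bins = np.digitize(metrics["elevation"], terciles)
        labels = pd.Series([HABITATS[b] for b in bins], index=metrics.index)
    else:
        raise ValidationError(f"unknown habitat method {method!r}")
    return HabitatMap(labels=labels, metrics=metrics)


@dataclass
class HabitatContrast:
    metric: str
    mean_within: float
    mean_across: float
    n_within: int
    n_across: int
    t: float
    df: float
    p: float
    category_means: pd.Series   # V-V, S-S, R-R, V-S, V-R, S-R means


def _pair_category(h1: str, h2: str) -> str:
    code = {"valley": "V", "slope": "S", "ridge": "R"}
    a, b = sorted((code[h1], code[h2]), key="VSR".index)
    return f"{a}-{b}"


def within_across_test(ses_table: pd.DataFrame, habitat_map: HabitatMap,
                       metric: str = "dpw", welch: bool = False
                       ) -> HabitatContrast:
    """Compare mean SES of within- vs across-habitat subplot pairs."""
    sub = ses_table[ses_table["metric"] == metric].dropna(subset=["ses"])
    labels = habitat_map.labels
    missing = (set(sub["k1"]) | set(sub["k2"])) - set(labels.index)
    if missing:
        raise ValidationError(f"subplots without habitat label: "
                              f"{sorted(missing)[:5]}")
    h1 = sub["k1"].map(labels)
    h2 = sub["k2"].map(labels)
    within_mask = (h1 == h2).to_numpy()
    ses = sub["ses"].to_numpy(float)
    within = ses[within_mask]
    across = ses[~within_mask]
    if len(within) < 2 or len(across) < 2:
        raise ValidationError("need >= 2 SES values in each habitat group")
    if within.var(ddof=1) == 0 and across.var(ddof=1) == 0 \
            and within.mean() == across.mean():
        t, p = 0.0, 1.0  # identical constant groups: no evidence either way
    else:
        t, p = stats.ttest_ind(within, across, equal_var=not welch)
    if welch:
        v1, v2 = within.var(ddof=1), across.var(ddof=1)
        n1, n2 = len(within), len(across)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = len(within) + len(across) - 2
    cats = pd.Series(
        [_pair_category(a, b) for a, b in zip(h1, h2)], index=sub.index
    )
    cat_means = sub.groupby(cats)["ses"].mean()
    return HabitatContrast(
        metric=metric,
        mean_within=float(within.mean()), mean_across=float(across.mean()),
        n_within=len(within), n_across=len(across),
        t=float(t), df=float(df), p=float(p),
        category_means=cat_means,
    )
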