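"""Tip-shuffle null model and standardized effect sizes.

The null model randomizes phylogenetic relatedness (or trait similarity)
while holding the community data matrix fixed: species names are
shuffled across the tips of the tree or dendrogram, which is equivalent
to permuting the rows and columns of the species distance matrix by one
random permutation.  Species occupancy frequencies, abundances and
spatial distributions are untouched.

For each subplot pair and metric the standardized effect size is

    S.E.S. = -(observed - mean_null) / sd_null

(sample sd over the null replicates).  The sign convention makes
*negative* S.E.S. mean observed dissimilarity *above* the null mean —
turnover faster than expected given the observed species turnover — and
positive S.E.S. mean slower-than-expected turnover.

One permutation stream is drawn per run and reused across all subplot
pairs; each shuffle is a single relabeling of the whole species pool, so
per-pair null values remain exchangeable with the observed values while
the all-pairs engine runs once per replicate instead of once per pair.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .beta import METRICS, pair_beta_matrices
from .grid import CommunityMatrix
from .io import DistanceMatrix, ValidationError, logger


def shuffle_labels(delta: DistanceMatrix, seed: int | np.random.Generator
                   ) -> DistanceMatrix:
    """One tip-shuffle: permute rows and columns of delta jointly."""
    if len(delta) < 2:
        raise ValidationError("need at least two species to shuffle")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    perm = rng.permutation(len(delta))
    return DistanceMatrix(delta.labels, delta.values[np.ix_(perm, perm)])


def standardized_effect_size(observed: float, null_mean: float,
                             null_sd: float) -> float:
    """SES from null moments: -(observed - mean) / sd, NaN when sd = 0."""
    if null_sd <= 0:
        return float("nan")
    return -(observed - null_mean) / null_sd


def ses(cm: CommunityMatrix, delta: DistanceMatrix,
        weighted: bool = True, n_null: int = 999,
        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """SES of D_pw and D_nn for every pair of non-empty subplots.

    Returns one row per (pair, metric) with observed value, null mean,
    null sample sd, SES and the replicate count.  Pairs whose null sd is
    zero get SES = NaN and are excluded downstream with a logged count.
    """
    if n_null < 2:
        raise ValidationError("need at least 2 null replicates")
    species = [s for s in cm.species if s in delta._index]
    if len(species) < len(cm.species):
        raise ValidationError("community species absent from distance matrix")
    sub = delta.submatrix(species)
    counts = cm.abundance[species].to_numpy(float)
    occupied = counts.sum(axis=1) > 0
    if occupied.sum() < 2:
        raise ValidationError("fewer than 2 non-empty subplots")

    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    obs = pair_beta_matrices(counts, sub.values, weighted=weighted)

    occ_idx = np.flatnonzero(occupied)
    pairs = list(combinations(occ_idx, 2))
    a_idx = np.array([p[0] for p in pairs])
    b_idx = np.array([p[1] for p in pairs])

    # streaming mean / sd over null replicates (Welford)
    mean = {m: np.zeros(len(pairs)) for m in METRICS}
    m2 = {m: np.zeros(len(pairs)) for m in METRICS}
    n_sp = len(species)
    for r in range(1, n_null + 1):
        perm = rng.permutation(n_sp)
        null = pair_beta_matrices(counts, sub.values[np.ix_(perm, perm)],
                                  weighted=weighted)
        for m in METRICS:
            x = null[m][a_idx, b_idx]
            d = x - mean[m]
            mean[m] += d / r
            m2[m] += d * (x - mean[m])

    ids = cm.abundance.index.to_list()
    frames = []
    for m in METRICS:
        null_sd = np.sqrt(m2[m] / (n_null - 1))
        observed = obs[m][a_idx, b_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            s = -(observed - mean[m]) / null_sd
        s = np.where(null_sd > 0, s, np.nan)
        frames.append(pd.DataFrame({
            "k1": [ids[a] for a in a_idx],
            "k2": [ids[b] for b in b_idx],
            "metric": m,
            "observed": observed,
            "null_mean": mean[m],
            "null_sd": null_sd,
            "ses": s,
            "n_null": n_null,
        }))
    out = pd.concat(frames, ignore_index=True)
    n_undef = int(out["ses"].isna().sum())
    if n_undef:
        logger.info("%d pair-metric SES values undefined (null sd = 0)",
                    n_undef)
    return out


def negative_proportion(ses_table: pd.DataFrame) -> pd.Series:
    """Per-metric proportion of defined SES values below zero.

    These are the headline histogram quantities: the fraction of subplot
    pairs whose turnover is faster than the null expectation.
    """
    ok = ses_table.dropna(subset=["ses"])
    return ok.groupby("metric")["ses"].apply(lambda s: float((s < 0).mean()))
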