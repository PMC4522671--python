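"""Phylogenetic and functional beta-diversity metrics between subplots.

Two mathematically independent classes of inter-community distance are
computed on a species distance matrix delta (cophenetic distance on the
phylogeny or on the trait dendrogram):

* ``D_pw`` — the "basal" metric: mean pairwise distance between the
  species of community k1 and the species of community k2,

      D_pw = [ sum_{i in k1} dbar_{i,k2} + sum_{j in k2} dbar_{j,k1} ]
             / (n_k1 + n_k2)

  where dbar_{i,k} is the mean of delta(i, s) over all species s of k
  (the conspecific term delta(i, i) = 0 is included when i occurs in k).

* ``D_nn`` — the "terminal" metric: the same construction with the mean
  replaced by the nearest-neighbour distance min_{s in k} delta(i, s).

The primed, abundance-weighted forms weight each species term by its
relative abundance f_i within its own community and divide by 2 (the
f's already sum to one per community):

      D_pw' = [ sum_i f_i dbar_{i,k2} + sum_j f_j dbar_{j,k1} ] / 2

and analogously for D_nn'.  Shared species contribute zero nearest-
neighbour distance, so D_nn of identical communities is 0, while D_pw of
a community with itself equals its mean intra-community pairwise
distance (not 0) — both are deliberate properties of the metrics.

``pair_beta_matrices`` is the vectorized engine used by the null model;
the scalar functions mirror it one pair at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import CommunityMatrix
from .io import DistanceMatrix, ValidationError, logger

METRICS = ("dpw", "dnn")


def _community_indices(community: Iterable[str], delta: DistanceMatrix
                       ) -> list[int]:
    idx = []
    for s in community:
        if s not in delta._index:
            raise ValidationError(f"species {s!r} absent from distance matrix")
        idx.append(delta._index[s])
    return idx


def mean_cross_distance(species: str, target: Iterable[str],
                        delta: DistanceMatrix) -> float:
    """Mean delta from one species to every species of a target community.

    The self term delta(i, i) = 0 is included when the species occurs in
    the target (the comdist convention).
    """
    target = list(target)
    if not target:
        raise ValidationError("target community is empty")
    i = _community_indices([species], delta)[0]
    cols = _community_indices(target, delta)
    return float(delta.values[i, cols].mean())


def _check_pair(k1, k2):
    if not k1 or not k2:
        raise ValidationError("empty community in beta-diversity pair")


def d_pw(k1: Iterable[str], k2: Iterable[str], delta: DistanceMatrix) -> float:
    """Unweighted mean pairwise distance between two communities."""
    k1, k2 = list(k1), list(k2)
    _check_pair(k1, k2)
    terms = [mean_cross_distance(i, k2, delta) for i in k1]
    terms += [mean_cross_distance(j, k1, delta) for j in k2]
    return float(np.sum(terms) / (len(k1) + len(k2)))


def d_nn(k1: Iterable[str], k2: Iterable[str], delta: DistanceMatrix) -> float:
    """Unweighted mean nearest-neighbour distance between two communities."""
    k1, k2 = list(k1), list(k2)
    _check_pair(k1, k2)
    i1 = _community_indices(k1, delta)
    i2 = _community_indices(k2, delta)
    sub = delta.values[np.ix_(i1, i2)]
    total = sub.min(axis=1).sum() + sub.min(axis=0).sum()
    return float(total / (len(k1) + len(k2)))


def _relative_abundances(community: list[str],
                         abundances: Mapping[str, float]) -> np.ndarray:
    f = np.array([abundances[s] for s in community], dtype=float)
    if np.any(f <= 0):
        raise ValidationError("non-positive abundance for a member species")
    tot = f.sum()
    if tot <= 0:
        raise ValidationError("zero total abundance")
    return f / tot


def d_pw_weighted(k1: Iterable[str], k2: Iterable[str],
                  ab1: Mapping[str, float], ab2: Mapping[str, float],
                  delta: DistanceMatrix) -> float:
    """Abundance-weighted mean pairwise distance (D_pw')."""
    k1, k2 = list(k1), list(k2)
    _check_pair(k1, k2)
    f1 = _relative_abundances(k1, ab1)
    f2 = _relative_abundances(k2, ab2)
    t1 = sum(f * mean_cross_distance(i, k2, delta) for f, i in zip(f1, k1))
    t2 = sum(f * mean_cross_distance(j, k1, delta) for f, j in zip(f2, k2))
    return float((t1 + t2) / 2.0)


def d_nn_weighted(k1: Iterable[str], k2: Iterable[str],
                  ab1: Mapping[str, float], ab2: Mapping[str, float],
                  delta: DistanceMatrix) -> float:
    """Abundance-weighted mean nearest-neighbour distance (D_nn')."""
    k1, k2 = list(k1), list(k2)
    _check_pair(k1, k2)
    f1 = _relative_abundances(k1, ab1)
    f2 = _relative_abundances(k2, ab2)
    i1 = _community_indices(k1, delta)
    i2 = _community_indices(k2, delta)
    sub = delta.values[np.ix_(i1, i2)]
    t1 = float(f1 @ sub.min(axis=1))
    t2 = float(f2 @ sub.min(axis=0))
    return (t1 + t2) / 2.0


# ---------------------------------------------------------------------------
# Vectorized all-pairs engine
# ---------------------------------------------------------------------------


def pair_beta_matrices(counts: np.ndarray, delta: np.ndarray,
                       weighted: bool = True) -> dict[str, np.ndarray]:
    """All-pairs D_pw and D_nn as K x K matrices.

    ``counts`` is the subplot x species abundance matrix (species columns
    ordered as ``delta`` rows); empty subplots yield NaN rows/columns.
    This is the engine the null model re-runs per tip shuffle, so it is
    fully vectorized: one delta @ presence product for the pairwise part
    and one masked minimum for the nearest-neighbour part.
    """
    counts = np.asarray(counts, dtype=float)
    n_cells, n_sp = counts.shape
    if delta.shape != (n_sp, n_sp):
        raise ValidationError("delta shape does not match species count")
    pres = counts > 0
    n_k = pres.sum(axis=1).astype(float)          # species richness per cell
    occupied = n_k > 0

    # weights: relative abundance (primed) or 1/richness (unweighted)
    if weighted:
        tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(tot > 0, counts / tot, 0.0)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(pres, 1.0, 0.0) / np.where(n_k > 0, n_k, 1.0)[:, None]

    # dbar[i, k] = mean delta from species i to the species of cell k
    sums = delta @ pres.T.astype(float)           # (n_sp, n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        dbar = sums / np.where(n_k > 0, n_k, np.nan)[None, :]
    m = w @ dbar                                  # m[k1, k2] = sum_i w_i dbar_{i,k2}

    # nnd[i, k] = min delta from species i to the species of cell k
    masked = np.where(pres[None, :, :], delta[:, None, :], np.inf)
    nnd = masked.min(axis=2)                      # (n_sp, n_cells)
    nnd = np.where(np.isfinite(nnd), nnd, np.nan)
    mn = w @ nnd

    if weighted:
        dpw = (m + m.T) / 2.0
        dnn = (mn + mn.T) / 2.0
    else:
        # unweighted normalizer is (n_k1 + n_k2), not 2
        num_pw = m * n_k[:, None] + (m * n_k[:, None]).T
        num_nn = mn * n_k[:, None] + (mn * n_k[:, None]).T
        denom = n_k[:, None] + n_k[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            dpw = num_pw / denom
            dnn = num_nn / denom

    for mat in (dpw, dnn):
        mat[~occupied, :] = np.nan
        mat[:, ~occupied] = np.nan
    return {"dpw": dpw, "dnn": dnn}


@dataclass
class PairBeta:
    k1: str
    k2: str
    n_k1: int
    n_k2: int
    dpw: float
    dnn: float


def all_pairs(cm: CommunityMatrix, delta: DistanceMatrix,
              weighted: bool = True) -> pd.DataFrame:
    """D_pw and D_nn for every unordered pair of non-empty subplots.

    Species absent from ``delta`` must be dropped upstream (reconciliation);
    empty subplots are excluded with a logged count.
    """
    species = [s for s in cm.species if s in delta._index]
    if len(species) < len(cm.species):
        raise ValidationError(
            f"{len(cm.species) - len(species)} community species absent from "
            "distance matrix; reconcile first"
        )
    sub = delta.submatrix(species)
    counts = cm.abundance[species].to_numpy(float)
    occupied = counts.sum(axis=1) > 0
    n_empty = int((~occupied).sum())
    if n_empty:
        logger.info("excluding %d empty subplots from beta analysis", n_empty)
    if occupied.sum() < 2:
        raise ValidationError("fewer than 2 non-empty subplots")

    mats = pair_beta_matrices(counts, sub.values, weighted=weighted)
    ids = cm.abundance.index.to_list()
    richness = (counts > 0).sum(axis=1)
    rows = []
    occ_idx = np.flatnonzero(occupied)
    for a, b in combinations(occ_idx, 2):
        rows.append(
            PairBeta(k1=ids[a], k2=ids[b],
                     n_k1=int(richness[a]), n_k2=int(richness[b]),
                     dpw=float(mats["dpw"][a, b]),
                     dnn=float(mats["dnn"][a, b]))
        )
    return pd.DataFrame([r.__dict__ for r in rows])
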