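"""Functional trait space: PCA, UPGMA dendrogram and trait distances.

The functional species-distance matrix is built in three steps that
remove trait redundancy before clustering: (1) PCA on z-scored traits,
keeping the first axes; (2) Euclidean distance on the retained scores;
(3) UPGMA clustering of that distance into an ultrametric dendrogram
whose cophenetic distance is the functional delta used by the beta
metrics.

UPGMA here is the classical *unweighted* average-linkage algorithm with
a deterministic lexicographic tie-break: when two candidate merges are
equally close, the pair whose smallest member labels sort first is
merged, so identical inputs always give identical newick output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import DistanceMatrix, TraitTable, ValidationError, logger


@dataclass
class TraitPcaResult:
    scores: pd.DataFrame          # species x retained axes
    variance_explained: np.ndarray  # fraction per retained axis
    loadings: pd.DataFrame        # trait x axis

    @property
    def species(self) -> list[str]:
        return list(self.scores.index)


def trait_pca(traits: TraitTable, n_axes: int = 3) -> TraitPcaResult:
    """PCA of z-scored species trait means; returns the first axes.

    Traits are standardized first because they are measured on wildly
    different unit scales (mm, g, m, unitless), making the correlation
    matrix the defensible basis.  Constant trait columns carry no
    information and are dropped with a warning.
    """
    table = traits.table.sort_index()
    if table.isna().any().any():
        raise ValidationError("trait table has missing values; reconcile first")
    sd = table.std(ddof=1)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        logger.warning("dropping constant trait columns: %s", constant)
        table = table.drop(columns=constant)
    if table.shape[1] < n_axes:
        raise ValidationError(
            f"need at least {n_axes} informative traits, have {table.shape[1]}"
        )
    z = (table - table.mean()) / table.std(ddof=1)
    pca = PCA(n_components=n_axes)
    scores = pca.fit_transform(z.to_numpy())
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return TraitPcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=axes),
        variance_explained=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(pca.components_.T, index=table.columns,
                              columns=axes),
    )


def trait_distance(scores: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distance between species in PCA score space."""
    if len(scores) < 2:
        raise ValidationError("trait distance needs at least two species")
    scores = scores.sort_index()
    x = scores.to_numpy(float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(scores.index), d)


@dataclass
class TraitDendrogram:
    """Ultrametric UPGMA dendrogram over the analysis species set.

    ``merges`` records each agglomeration as (members_a, members_b, height)
    in merge order; the cophenetic distance between two species is twice
    the height of the smallest cluster containing both.
    """

    labels: list[str]
    merges: list[tuple[frozenset, frozenset, float]]
    newick: str

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def upgma(dist: DistanceMatrix) -> TraitDendrogram:
    """Classical UPGMA with lexicographic tie-breaking.

    Cluster-to-cluster distance is the unweighted mean of all member
    pairwise distances; the closest pair merges at height d/2.  On ties,
    the pair whose sorted smallest member labels compare lowest merges
    first, making the output deterministic.
    """
    labels = dist.labels
    n = len(labels)
    if n < 2:
        raise ValidationError("UPGMA needs at least two species")
    if not np.all(np.isfinite(dist.values)):
        raise ValidationError("non-finite distances")

    # active clusters: id -> (member index set, representative label, newick)
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    rep: dict[int, str] = {i: labels[i] for i in range(n)}
    nwk: dict[int, str] = {i: labels[i] for i in range(n)}
    depth: dict[int, float] = {i: 0.0 for i in range(n)}
    d = {frozenset((i, j)): dist.values[i, j]
         for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = n
    active = set(range(n))

    while len(active) > 1:
        # closest pair, ties broken by sorted representative labels
        best = min(
            (pair for pair in d if pair <= active),
            key=lambda p: (d[p], tuple(sorted(rep[c] for c in p))),
        )
        a, b = sorted(best, key=lambda c: rep[c])
        h = d[best] / 2.0
        merges.append((frozenset(labels[i] for i in members[a]),
                       frozenset(labels[i] for i in members[b]),
                       h))
        new = next_id
        next_id += 1
        na, nb = len(members[a]), len(members[b])
        members[new] = members[a] | members[b]
        rep[new] = min(rep[a], rep[b])
        nwk[new] = (f"({nwk[a]}:{h - depth[a]:.10g},"
                    f"{nwk[b]}:{h - depth[b]:.10g})")
        depth[new] = h
        active -= {a, b}
        # unweighted average linkage over all member pairs
        for c in active:
            dc = (na * d[frozenset((a, c))] + nb * d[frozenset((b, c))]) / (na + nb)
            d[frozenset((new, c))] = dc
        active.add(new)

    root = active.pop()
    return TraitDendrogram(labels=list(labels), merges=merges,
                           newick=nwk[root] + ";")


def dendrogram_cophenetic(dend: TraitDendrogram) -> DistanceMatrix:
    """Cophenetic distance: twice the merge height joining each pair."""
    labels = sorted(dend.labels)
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for left, right, h in dend.merges:
        for a in left:
            for b in right:
                out[idx[a], idx[b]] = out[idx[b], idx[a]] = 2.0 * h
    return DistanceMatrix(labels, out)
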