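"""Beta-diversity structure: Bray-Curtis, PCoA, group tests, core taxa.

PERMANOVA and ANOSIM delegate to scikit-bio; MRPP is computed here (no
established Python implementation). All three share the same label
permutation null and the valid-p convention p = (1 + exceed) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.distance import permanova as _skbio_permanova

from .io import CountTable, DegenerateSampleError
from .diversity import DesignError


def bray_curtis(table: CountTable, relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    Computed on raw counts by default; set ``relative`` to row-normalize
    first. d(x, y) = 1 - 2 * sum(min(x, y)) / (sum(x) + sum(y)).
    """
    arr = table.matrix.astype(float)
    if (arr.sum(axis=1) == 0).any():
        bad = [s for s, t in zip(table.sample_ids, arr.sum(axis=1)) if t == 0]
        raise DegenerateSampleError(f"zero-total samples: {bad}")
    if relative:
        arr = arr / arr.sum(axis=1, keepdims=True)
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix) -> dict:
    """Principal coordinates analysis (classical MDS on the Gower matrix).

    Negative eigenvalues are retained and reported; coordinates are returned
    only for positive axes, and proportion explained is relative to the sum
    of positive eigenvalues.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise DesignError("PCoA needs at least 3 samples")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return {
        "coordinates": pd.DataFrame(coords, index=list(dm.ids), columns=axes),
        "eigenvalues": eigvals,
        "proportion_explained": eigvals[pos] / eigvals[pos].sum(),
    }


def _check_groups(groups) -> np.ndarray:
    groups = np.asarray(groups)
    if len(set(groups.tolist())) < 2:
        raise DesignError("need at least 2 groups")
    return groups


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> dict:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix."""
    groups = _check_groups(groups)
    if n_perm < 99:
        raise DesignError("n_perm must be >= 99")
    res = _skbio_permanova(dm, groups, permutations=n_perm, seed=seed)
    return {"pseudo_F": float(res["test statistic"]), "p": float(res["p-value"])}


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> dict:
    """Analysis of similarities (rank-based R statistic)."""
    groups = _check_groups(groups)
    if n_perm < 99:
        raise DesignError("n_perm must be >= 99")
    res = _skbio_anosim(dm, groups, permutations=n_perm, seed=seed)
    return {"R": float(res["test statistic"]), "p": float(res["p-value"])}


def _mrpp_delta(d: np.ndarray, groups: np.ndarray, labels, weights) -> float:
    delta = 0.0
    for g, w in zip(labels, weights):
        idx = np.flatnonzero(groups == g)
        sub = d[np.ix_(idx, idx)]
        m = len(idx)
        delta += w * sub[np.triu_indices(m, k=1)].mean()
    return delta


def mrpp(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> dict:
    """Multiple-response permutation procedure.

    delta is the group-size-weighted mean within-group distance; the chance-
    corrected effect size is A = 1 - delta / E[delta] under label
    permutation, and p is the fraction of permutations with delta at most
    the observed value.
    """
    groups = _check_groups(groups)
    if n_perm < 99:
        raise DesignError("n_perm must be >= 99")
    d = np.asarray(dm.data, dtype=float)
    labels = list(dict.fromkeys(groups.tolist()))
    sizes = np.array([(groups == g).sum() for g in labels], dtype=float)
    if (sizes < 2).any():
        raise DesignError("every group needs at least 2 samples")
    weights = sizes / sizes.sum()
    obs = _mrpp_delta(d, groups, labels, weights)
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(groups)
        perm_deltas[k] = _mrpp_delta(d, perm, labels, weights)
    exceed = int((perm_deltas <= obs).sum())
    p = (1 + exceed) / (1 + n_perm)
    a = 1.0 - obs / perm_deltas.mean()
    return {"delta": float(obs), "A": float(a), "p": float(p)}


@dataclass
class CoreSet:
    """Core taxa of one group: high-occupancy, non-negligible abundance."""

    group: object
    taxa: frozenset
    occupancy_threshold: float
    abundance_threshold: float


def core_taxa(
    table: CountTable,
    group=None,
    occupancy_threshold: float = 0.8,
    abundance_threshold: float = 0.001,
) -> CoreSet:
    """Screen a (group-restricted) table for core taxa.

    A taxon is core iff it occurs in strictly more than
    ``occupancy_threshold`` of the samples AND its summed counts make up at
    least ``abundance_threshold`` of the group's grand total.
    """
    if len(table.sample_ids) < 2:
        raise DesignError("need at least 2 samples")
    arr = table.matrix
    occupancy = (arr > 0).mean(axis=0)
    rel_total = arr.sum(axis=0) / arr.sum()
    keep = (occupancy > occupancy_threshold) & (rel_total >= abundance_threshold)
    taxa = frozenset(t for t, k in zip(table.taxon_ids, keep) if k)
    return CoreSet(group, taxa, occupancy_threshold, abundance_threshold)
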