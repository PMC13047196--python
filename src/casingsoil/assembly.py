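"""Phylogenetic null-model partitioning of community assembly.

For every within-group sample pair the pipeline computes

* the abundance-weighted between-community mean nearest taxon distance
  (betaMNTD) on patristic distances,
* its standardized effect size betaNTI against a taxa-shuffle null
  (taxon labels permuted across the tips of the phylogenetic distance
  matrix, preserving abundances and occupancy), and
* the Raup-Crick metric on Bray-Curtis (RC_bray) against a pool-based
  null that preserves each sample's richness and total abundance, drawing
  membership with probability proportional to pool occupancy and filling
  abundance proportionally to pool relative abundance.

Pairs are then classified into five ecological processes:

========================  =======================================
betaNTI > +2              variable selection
betaNTI < -2              homogeneous selection
|betaNTI| <= 2, RC > +.95 dispersal limitation
|betaNTI| <= 2, RC < -.95 homogenizing dispersal
otherwise                 undominated
========================  =======================================

Boundary values fall to the stochastic/undominated side (strict
inequalities throughout).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import CountTable, SampleFrame

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


class DegenerateCommunityError(ValueError):
    pass


def patristic_distances(tree: TreeNode, taxa) -> np.ndarray:
    """Tip-to-tip patristic distance matrix in the given taxon order."""
    dm = tree.tip_tip_distances(endpoints=list(taxa))
    return dm.filter(list(taxa)).data.copy()


def bmntd(x, y, pd_matrix) -> float:
    """Abundance-weighted between-community mean nearest taxon distance.

    0.5 * [ sum_i fx_i * min_{j: y_j>0} d(i,j)
          + sum_j fy_j * min_{i: x_i>0} d(i,j) ]
    with fx, fy relative abundances among each community's present taxa.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = np.asarray(pd_matrix, dtype=float)
    ix, iy = x > 0, y > 0
    if not ix.any() or not iy.any():
        raise DegenerateCommunityError("community with no taxa")
    fx = x[ix] / x[ix].sum()
    fy = y[iy] / y[iy].sum()
    sub = d[np.ix_(ix, iy)]
    return 0.5 * float(fx @ sub.min(axis=1) + fy @ sub.min(axis=0))


def _bmntd_all_pairs(f: np.ndarray, present: np.ndarray, d: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs at once.

    ``m[b, i] = min_{j present in b} d(i, j)`` depends only on the target
    sample b, so the pair matrix is a single matrix product.
    """
    s = f.shape[0]
    m = np.empty_like(f)
    for b in range(s):
        m[b] = d[:, present[b]].min(axis=1)
    t = f @ m.T
    return 0.5 * (t + t.T)


def bnti_matrix(
    counts: np.ndarray, d: np.ndarray, n_null: int = 999, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Observed betaMNTD and betaNTI for every sample pair of one group.

    The null shuffles taxon labels across the tips of ``d`` (``n_null``
    independent permutations shared by all pairs). Pairs whose null standard
    deviation collapses below 1e-12 get betaNTI = 0 with a warning.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = np.asarray(counts, dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise DegenerateCommunityError("sample with no taxa")
    f = counts / counts.sum(axis=1, keepdims=True)
    present = counts > 0
    obs = _bmntd_all_pairs(f, present, d)
    rng = np.random.default_rng(seed)
    t = d.shape[0]
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(t)
        dp = d[np.ix_(perm, perm)]
        nb = _bmntd_all_pairs(f, present, dp)
        acc += nb
        acc2 += nb**2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var)
    degenerate = sd < 1e-12
    if degenerate.any():
        warnings.warn(
            "degenerate betaMNTD null (zero variance); betaNTI set to 0",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        bnti = np.where(degenerate, 0.0, (obs - mean) / np.where(degenerate, 1.0, sd))
    np.fill_diagonal(bnti, 0.0)
    return obs, bnti


def bnti(x, y, pd_matrix, n_null: int = 999, seed: int = 0) -> float:
    """betaNTI for a single sample pair (taxa-shuffle null on ``pd_matrix``)."""
    counts = np.vstack([np.asarray(x, float), np.asarray(y, float)])
    _, mat = bnti_matrix(counts, np.asarray(pd_matrix, float), n_null, seed)
    return float(mat[0, 1])


def _null_communities(
    counts: np.ndarray, occupancy: np.ndarray, pool_p: np.ndarray,
    n_null: int, rng,
) -> list[np.ndarray]:
    """Per-sample null assemblies preserving richness and total abundance.

    Membership is drawn without replacement by Gumbel top-k with
    log-odds(occupancy) keys — approximately a conditional Poisson draw
    whose inclusion probabilities reproduce pool occupancy, so taxa seen in
    every sample are (almost) always included and the null is consistent
    with data assembled from the pool itself. Each member taxon is seeded
    with one read and the remaining reads are filled multinomially
    proportional to pool relative abundance within the drawn membership.
    """
    s, t = counts.shape
    occ = np.clip(occupancy, 0.005, 0.995)
    log_odds = np.log(occ / (1.0 - occ))
    nulls = []
    for a in range(s):
        r = int((counts[a] > 0).sum())
        total = int(counts[a].sum())
        keys = log_odds + rng.gumbel(size=(n_null, t))
        chosen = np.argpartition(-keys, r - 1, axis=1)[:, :r]
        mask = np.zeros((n_null, t), dtype=np.int64)
        np.put_along_axis(mask, chosen, 1, axis=1)
        pmat = mask * pool_p
        pmat = pmat / pmat.sum(axis=1, keepdims=True)
        fill = rng.multinomial(total - r, pmat)
        nulls.append(mask + fill)
    return nulls


def rc_matrix(
    counts: np.ndarray, n_null: int = 999, seed: int = 0
) -> np.ndarray:
    """RC_bray for every sample pair of one group.

    RC = 2 * (#{null BC < obs BC} + 0.5 * #{null BC = obs BC}) / n_null - 1,
    clamped to [-1, 1]. The species pool (occupancy and relative abundance)
    is built from the group's own samples.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = np.asarray(counts, dtype=np.int64)
    pool = counts.sum(axis=0)
    keep = pool > 0
    if not keep.any():
        raise DegenerateCommunityError("empty species pool")
    c = counts[:, keep]
    occupancy = (c > 0).mean(axis=0)
    pool_p = pool[keep] / pool[keep].sum()
    rng = np.random.default_rng(seed)
    nulls = _null_communities(c, occupancy, pool_p, n_null, rng)
    s = c.shape[0]
    totals = c.sum(axis=1)
    rc = np.zeros((s, s))
    for a in range(s):
        for b in range(a + 1, s):
            obs = np.abs(c[a] - c[b]).sum() / (totals[a] + totals[b])
            diff = np.abs(nulls[a] - nulls[b]).sum(axis=1)
            null_bc = diff / (totals[a] + totals[b])
            below = int((null_bc < obs).sum())
            ties = int((null_bc == obs).sum())
            val = 2.0 * (below + 0.5 * ties) / n_null - 1.0
            rc[a, b] = rc[b, a] = float(np.clip(val, -1.0, 1.0))
    return rc


def rc_bray(x, y, species_pool, n_null: int = 999, seed: int = 0) -> float:
    """RC_bray for one sample pair against a pool of group samples.

    ``species_pool`` is the samples x taxa count matrix the pool statistics
    are built from; ``x`` and ``y`` must be aligned to its columns.
    """
    pool_counts = np.asarray(species_pool, dtype=np.int64)
    if pool_counts.sum() == 0:
        raise DegenerateCommunityError("empty species pool")
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    pool = pool_counts.sum(axis=0)
    keep = pool > 0
    occupancy = (pool_counts[:, keep] > 0).mean(axis=0)
    pool_p = pool[keep] / pool[keep].sum()
    c = np.vstack([x[keep], y[keep]])
    rng = np.random.default_rng(seed)
    nulls = _null_communities(c, occupancy, pool_p, n_null, rng)
    totals = c.sum(axis=1)
    obs = np.abs(c[0] - c[1]).sum() / totals.sum()
    null_bc = np.abs(nulls[0] - nulls[1]).sum(axis=1) / totals.sum()
    below = int((null_bc < obs).sum())
    ties = int((null_bc == obs).sum())
    return float(np.clip(2.0 * (below + 0.5 * ties) / n_null - 1.0, -1.0, 1.0))


def classify(bnti_value: float, rc_value: float) -> str:
    """Assign one sample pair to its dominant assembly process."""
    if not np.isfinite(bnti_value):
        raise ValueError("betaNTI must be finite")
    if bnti_value > BNTI_THRESHOLD:
        return "variable_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def summarize(processes) -> dict:
    """Fraction of pairs assigned to each of the five processes."""
    processes = list(processes)
    n = len(processes)
    if n == 0:
        raise ValueError("no pairs to summarize")
    return {p: processes.count(p) / n for p in PROCESSES}


def assembly_profile(
    table: CountTable,
    tree: TreeNode,
    metadata: SampleFrame,
    n_null: int = 999,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair assembly metrics and per-group process fractions.

    betaNTI and RC_bray are computed within groups only. The taxa shuffle
    randomizes labels across the regional pool (every taxon observed
    anywhere in the table), so that selection-driven clade confinement
    within a group registers against the null; the RC_bray species pool is
    the group's own samples.
    """
    pool_keep = table.matrix.sum(axis=0) > 0
    pool_taxa = [t for t, k in zip(table.taxon_ids, pool_keep) if k]
    d = patristic_distances(tree, pool_taxa)
    rows = []
    fracs = {}
    for gi, group in enumerate(metadata.groups()):
        sids = metadata.samples_in_group(group)
        sub = table.restrict_samples(sids)
        c = sub.matrix[:, pool_keep]
        obs, bnti_m = bnti_matrix(c, d, n_null=n_null, seed=seed + 2 * gi)
        rc_m = rc_matrix(c, n_null=n_null, seed=seed + 2 * gi + 1)
        procs = []
        for a in range(len(sids)):
            for b in range(a + 1, len(sids)):
                proc = classify(bnti_m[a, b], rc_m[a, b])
                procs.append(proc)
                rows.append(
                    {
                        "group": group,
                        "sample_a": sids[a],
                        "sample_b": sids[b],
                        "bmntd": obs[a, b],
                        "bnti": bnti_m[a, b],
                        "rc_bray": rc_m[a, b],
                        "process": proc,
                    }
                )
        fracs[group] = summarize(procs)
    pairs = pd.DataFrame(rows)
    fractions = pd.DataFrame(fracs).T
    fractions.index.name = "group"
    return pairs, fractions
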