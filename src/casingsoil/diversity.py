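"""Alpha-diversity indices and group comparisons.

Indices per sample: observed richness, bias-corrected Chao1, Shannon
diversity (natural log), Pielou evenness and inverse Simpson. Group
comparisons use one-way ANOVA with Tukey HSD post-hoc pairwise tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import CountTable, DegenerateSampleError


class DesignError(ValueError):
    pass


def _alpha_one(counts: np.ndarray) -> dict:
    counts = counts[counts > 0]
    if counts.size == 0:
        raise DegenerateSampleError("sample with zero total counts")
    s = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    # bias-corrected Chao1: well-defined even when no doubletons exist
    chao1 = s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    evenness = 1.0 if s == 1 else shannon / np.log(s)
    inv_simpson = float(1.0 / (p**2).sum())
    return {
        "richness": s,
        "chao1": chao1,
        "shannon": shannon,
        "evenness": evenness,
        "inv_simpson": inv_simpson,
    }


def alpha_indices(table: CountTable) -> pd.DataFrame:
    """Per-sample alpha-diversity indices, one row per sample."""
    records = {
        sid: _alpha_one(row)
        for sid, row in zip(table.sample_ids, table.matrix)
    }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


def group_anova(values, groups, alpha: float = 0.05) -> dict:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons.

    Returns ``{"F", "p", "tukey_pairs"}`` where ``tukey_pairs`` maps each
    unordered group pair to its adjusted p-value. Groups with identically
    zero within-group variance but different means yield ``p = 0.0`` with a
    warning (the F statistic diverges).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) < 2:
        raise DesignError("need at least 2 groups")
    split = [values[groups == g] for g in labels]
    if any(len(v) < 2 for v in split):
        raise DesignError("every group needs at least 2 observations")
    sse = sum(((v - v.mean()) ** 2).sum() for v in split)
    if sse == 0 and len({round(float(v.mean()), 12) for v in split}) > 1:
        warnings.warn("zero within-group variance; p set to 0", RuntimeWarning)
        return {"F": np.inf, "p": 0.0, "tukey_pairs": {}}
    f_stat, p = stats.f_oneway(*split)
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = {}
    res = tukey.summary().data[1:]
    for row in res:
        pairs[(row[0], row[1])] = float(row[3])
    return {"F": float(f_stat), "p": float(p), "tukey_pairs": pairs}
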