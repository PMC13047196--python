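"""Environmental drivers: partial Mantel tests and variance partitioning.

The partial Mantel test correlates community dissimilarity with the
Euclidean distance of one standardized environmental variable after
residualizing both on the distance of a covariate block (first-order
partial correlation of the three distance vectors). Significance comes
from permuting sample labels of the community matrix.

Variance partitioning (VPA) is distance-based: principal coordinates of
the community distance matrix (positive axes) are regressed on each
predictor set and their union; adjusted R-squared values are combined by
inclusion-exclusion into pure, shared and residual fractions. Negative
adjusted fractions are reported as-is, following the usual convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .beta import pcoa
from .diversity import DesignError

#: grouping of the measured casing-soil variables used throughout: physical
#: structure of the substrate vs nutrient (chemical) status
PHYSICAL_VARS = ("pH", "TS", "moisture", "unit_weight", "density")
CHEMICAL_VARS = ("TN", "AK", "AP", "NH4", "NO3")


class UndefinedDistanceError(ValueError):
    pass


@dataclass
class MantelResult:
    variable: str
    r: float
    p: float
    n_perm: int
    covariates: tuple


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise UndefinedDistanceError("constant variable has no distance signal")
    return (x - x.mean(axis=0)) / sd


def _residualize(y: np.ndarray, z: np.ndarray) -> np.ndarray:
    z1 = np.column_stack([np.ones(len(z)), z])
    coef, *_ = np.linalg.lstsq(z1, y, rcond=None)
    return y - z1 @ coef


def partial_mantel(
    d_comm: DistanceMatrix,
    env_focal,
    env_covariates=None,
    n_perm: int = 999,
    seed: int = 0,
    variable: str = "",
) -> MantelResult:
    """Partial Mantel correlation between community and focal distances.

    With no covariates this is the simple Mantel test. The p-value is
    one-sided (large positive r), p = (1 + exceed) / (1 + n_perm).
    """
    if n_perm < 99:
        raise DesignError("n_perm must be >= 99")
    dc_full = np.asarray(d_comm.data, dtype=float)
    n = dc_full.shape[0]
    focal = _standardize(np.asarray(env_focal, dtype=float).reshape(n, -1))
    df = pdist(focal, metric="euclidean")
    has_cov = env_covariates is not None and np.size(env_covariates) > 0
    if has_cov:
        cov = _standardize(np.asarray(env_covariates, dtype=float).reshape(n, -1))
        dz = pdist(cov, metric="euclidean")
        df_res = _residualize(df, dz)
        # focal fully explained by the covariate block: partial r is 0
        if np.linalg.norm(df_res) < 1e-8 * np.linalg.norm(df):
            df_res = np.zeros_like(df_res)
    else:
        dz = None
        df_res = df - df.mean()
    rng = np.random.default_rng(seed)

    def corr_with(dc_mat: np.ndarray) -> float:
        dc = squareform(dc_mat, checks=False)
        dc_res = _residualize(dc, dz) if has_cov else dc - dc.mean()
        denom = np.linalg.norm(dc_res) * np.linalg.norm(df_res)
        if denom == 0:
            return 0.0
        return float(dc_res @ df_res / denom)

    r_obs = corr_with(dc_full)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(dc_full[np.ix_(perm, perm)]) >= r_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    cov_names = tuple(
        env_covariates.columns
    ) if isinstance(env_covariates, pd.DataFrame) else ()
    return MantelResult(variable, r_obs, p, n_perm, cov_names)


@dataclass
class VpaResult:
    fraction_physical_pure: float
    fraction_chemical_pure: float
    fraction_shared: float
    residual: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _adjusted_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Adjusted R^2 of the multivariate regression of Y on X (db-RDA)."""
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        warnings.warn(
            "collinear predictors; effective rank used for adjustment",
            RuntimeWarning,
        )
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    ss_tot = (yc**2).sum()
    r2 = (fitted**2).sum() / ss_tot
    if n - rank - 1 <= 0:
        raise DesignError("too few samples for the number of predictors")
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - rank - 1))


def vpa(d_comm: DistanceMatrix, physical_vars, chemical_vars) -> VpaResult:
    """Two-set variance partitioning of community variation.

    ``physical_vars`` and ``chemical_vars`` are samples x variables arrays
    (or DataFrames) aligned with ``d_comm``. Fractions are derived from
    adjusted R^2 of each set and their union by inclusion-exclusion;
    pure + shared + residual sums to 1 exactly.
    """
    phys = np.asarray(physical_vars, dtype=float)
    chem = np.asarray(chemical_vars, dtype=float)
    if phys.size == 0 or chem.size == 0:
        raise DesignError("both predictor sets must be non-empty")
    phys = phys.reshape(len(d_comm.ids), -1)
    chem = chem.reshape(len(d_comm.ids), -1)
    n = phys.shape[0]
    if n < phys.shape[1] + chem.shape[1] + 2:
        raise DesignError("need n >= total predictors + 2")
    ord_res = pcoa(d_comm)
    y = ord_res["coordinates"].to_numpy()
    r2_p = _adjusted_r2(y, phys)
    r2_c = _adjusted_r2(y, chem)
    r2_pc = _adjusted_r2(y, np.column_stack([phys, chem]))
    pure_p = r2_pc - r2_c
    pure_c = r2_pc - r2_p
    shared = r2_p + r2_c - r2_pc
    return VpaResult(
        fraction_physical_pure=float(pure_p),
        fraction_chemical_pure=float(pure_c),
        fraction_shared=float(shared),
        residual=float(1.0 - r2_pc),
    )


def mantel_screen(
    d_comm: DistanceMatrix,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Partial Mantel of each variable, controlling for all the others."""
    rows = []
    for i, var in enumerate(env.columns):
        others = env.drop(columns=[var])
        res = partial_mantel(
            d_comm,
            env[var].to_numpy(),
            others,
            n_perm=n_perm,
            seed=seed + i,
            variable=var,
        )
        rows.append(
            {"variable": var, "r": res.r, "p": res.p, "n_perm": res.n_perm}
        )
    return pd.DataFrame(rows).set_index("variable")
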