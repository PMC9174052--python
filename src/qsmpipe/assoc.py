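"""Cross-participant association statistics.

The phenome scan treats each imaging-derived phenotype (IDP) and each
non-imaging phenotype as a participant-long vector: outliers beyond six
median absolute deviations from the median are removed, the remainder is
quantile normalized onto standard normal quantiles (rank-based, hence
invariant to any monotone rescaling of the raw data), imaging confounds
are regressed out, and pairwise Pearson correlations with two-sided
t-based p-values are computed on pairwise-complete observations.
Family-wise error is controlled by Bonferroni over the full grid of
tests (reported as a -log10 p threshold) with a Benjamini-Hochberg FDR
alternative; a separate utility reproduces the genome-wide threshold
arithmetic (7.5 plus log10 of the number of scans).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AssociationResult, ParameterError, logger

__all__ = [
    "preprocess_idp_vector",
    "regress_confounds",
    "pearson_assoc",
    "SignificanceThresholds",
    "significance_thresholds",
    "phenome_scan",
    "voxelwise_assoc",
    "group_difference_map",
    "manhattan_plot",
]

_TINY_P = np.nextafter(0.0, 1.0)


def preprocess_idp_vector(
    x: Sequence[float],
    mad_factor: float = 6.0,
    mad_scale: float = 1.0,
    rescale_sd: bool = True,
) -> np.ndarray:
    """Outlier removal (6 x MAD rule) followed by quantile normalization.

    Values more than ``mad_factor`` median absolute deviations from the
    median become missing (the MAD is used unscaled by default — the rule
    is stated directly in MAD units; set ``mad_scale=1.4826`` for the
    normal-consistent convention). Remaining values are mapped through the
    standard normal quantile function at plotting positions
    ``(rank - 0.5)/m`` with average ranks for ties, then centered and
    rescaled to unit sample standard deviation, yielding a Gaussian
    vector with mean 0 and s.d. 1. Missing values propagate.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("expected a 1D vector")
    ok = np.isfinite(x)
    if ok.sum() < 10:
        raise ParameterError("need at least 10 non-missing values")
    med = np.median(x[ok])
    mad = np.median(np.abs(x[ok] - med)) * mad_scale
    keep = ok.copy()
    if mad == 0:
        warnings.warn("MAD is zero; outlier step skipped")
    else:
        keep &= np.abs(x - med) <= mad_factor * mad
    m = int(keep.sum())
    out = np.full_like(x, np.nan)
    ranks = stats.rankdata(x[keep], method="average")
    q = stats.norm.ppf((ranks - 0.5) / m)
    q = q - q.mean()
    if rescale_sd:
        sd = q.std()
        if sd > 0:
            q = q / sd
    out[keep] = q
    return out


def _design(C: np.ndarray) -> np.ndarray:
    """Prepend an intercept and drop collinear columns (with a warning)."""
    n = C.shape[0]
    X = np.column_stack([np.ones(n), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient confound matrix; collinear columns dropped")
        # QR with column pivoting via successive inclusion
        keep: List[int] = []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        X = X[:, keep]
    return X


def regress_confounds(
    Y: Union[np.ndarray, pd.DataFrame],
    C: Union[np.ndarray, pd.DataFrame],
) -> Union[np.ndarray, pd.DataFrame]:
    """Project each column of ``Y`` off the confound column space.

    An intercept is always included. Each column is fit on its own
    complete rows (rows where the column and every confound are
    non-missing), so columns with different missingness get different
    degrees of freedom — matching how associations are later computed.
    Residuals are orthogonal to the confounds on those rows; missing
    values propagate.
    """
    was_df = isinstance(Y, pd.DataFrame)
    Yv = np.asarray(Y, dtype=float)
    squeeze = Yv.ndim == 1
    if squeeze:
        Yv = Yv[:, None]
    Cv = np.asarray(C, dtype=float)
    if Cv.ndim == 1:
        Cv = Cv[:, None]
    if Yv.shape[0] != Cv.shape[0]:
        raise ParameterError("Y and C must have aligned rows")
    c_ok = np.all(np.isfinite(Cv), axis=1)
    out = np.full_like(Yv, np.nan)
    for j in range(Yv.shape[1]):
        ok = np.isfinite(Yv[:, j]) & c_ok
        if ok.sum() <= Cv.shape[1] + 1:
            continue
        X = _design(Cv[ok])
        beta, *_ = np.linalg.lstsq(X, Yv[ok, j], rcond=None)
        out[ok, j] = Yv[ok, j] - X @ beta
    if squeeze:
        out = out[:, 0]
    if was_df:
        return pd.DataFrame(out, index=Y.index, columns=Y.columns)
    return out


def pearson_assoc(
    x: Sequence[float],
    y: Sequence[float],
    idp_name: str = "x",
    phenotype_name: str = "y",
    min_n: int = 3,
) -> Optional[AssociationResult]:
    """Pearson correlation with a two-sided t-based p on complete pairs.

    ``t = r sqrt((n-2)/(1-r^2))`` on ``n-2`` degrees of freedom; a p of
    exactly zero is reported at the smallest positive float so the
    -log10 p is finite. Degenerate input (too few pairs or zero variance)
    returns ``None`` and logs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < max(min_n, 3):
        logger.debug("%s~%s: only %d complete pairs", idp_name, phenotype_name, n)
        return None
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        logger.debug("%s~%s: zero variance", idp_name, phenotype_name)
        return None
    r, p = stats.pearsonr(xs, ys)
    p = max(float(p), _TINY_P)
    return AssociationResult(
        idp_name=idp_name,
        phenotype_name=phenotype_name,
        r=float(r),
        p=p,
        n=n,
        neglog10p=float(-np.log10(p)),
    )


@dataclass
class SignificanceThresholds:
    """Multiple-comparison thresholds on the -log10 p scale."""

    bonferroni_neglog10: float
    gwas_neglog10: Optional[float] = None
    fdr_neglog10: Optional[float] = None
    fdr_reject: Optional[np.ndarray] = None


def significance_thresholds(
    alpha: float = 0.05,
    m_tests: int = 1,
    n_gwas: Optional[int] = None,
    p_values: Optional[Sequence[float]] = None,
    fdr_q: float = 0.05,
    gwas_base_neglog10: float = 7.5,
) -> SignificanceThresholds:
    """Bonferroni, genome-wide and Benjamini-Hochberg thresholds.

    * Bonferroni: ``-log10(alpha / m_tests)`` — e.g. 7.10 for the full
      phenome grid of 629,460 tests at alpha 0.05.
    * Genome-wide (when ``n_gwas`` given): the standard single-scan
      threshold 7.5 plus ``log10(n_gwas)`` — 9.06 for 36 scans.
    * FDR (when ``p_values`` given): Benjamini-Hochberg step-up at
      ``fdr_q``; the reported threshold is the -log10 of the largest
      rejected p (None if nothing is rejected).
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ParameterError("m_tests must be >= 1")
    out = SignificanceThresholds(
        bonferroni_neglog10=float(-np.log10(alpha / m_tests))
    )
    if n_gwas is not None:
        if n_gwas < 1:
            raise ParameterError("n_gwas must be >= 1")
        out.gwas_neglog10 = float(gwas_base_neglog10 + np.log10(n_gwas))
    if p_values is not None:
        p = np.asarray(p_values, dtype=float)
        reject, *_ = multipletests(p, alpha=fdr_q, method="fdr_bh")
        out.fdr_reject = reject
        if reject.any():
            out.fdr_neglog10 = float(-np.log10(p[reject].max()))
    return out


def phenome_scan(
    idps: pd.DataFrame,
    phenotypes: pd.DataFrame,
    confounds: Optional[pd.DataFrame] = None,
    min_n: int = 40,
    preprocess: bool = True,
) -> pd.DataFrame:
    """All-pairs Pearson scan of IDP columns against phenotype columns.

    Each column is preprocessed (outlier removal + quantile normalization)
    and deconfounded; the confound fit is redone on the rows available for
    each column, so associations carry their own degrees of freedom.
    Pairs with fewer than ``min_n`` complete observations are dropped,
    mirroring the phenotype inclusion rule (data from at least 40
    individuals). Returns a tidy frame (idp, phenotype, r, p, n,
    neglog10p).
    """
    idx = idps.index
    if not idx.equals(phenotypes.index):
        raise ParameterError("IDP and phenotype tables must share participants")
    if confounds is not None and not idx.equals(confounds.index):
        raise ParameterError("confound table must share participants")

    def prep(df: pd.DataFrame) -> pd.DataFrame:
        out = df.astype(float)
        if preprocess:
            out = out.apply(lambda c: preprocess_idp_vector(c.to_numpy()), axis=0)
        if confounds is not None:
            out = regress_confounds(out, confounds.to_numpy())
        return out

    idps_c = prep(idps)
    phen_c = prep(phenotypes)
    records = []
    for pcol in phen_c.columns:
        pv = phen_c[pcol].to_numpy()
        for icol in idps_c.columns:
            res = pearson_assoc(
                idps_c[icol].to_numpy(), pv, idp_name=icol,
                phenotype_name=pcol, min_n=min_n,
            )
            if res is not None:
                records.append(
                    (res.idp_name, res.phenotype_name, res.r, res.p, res.n,
                     res.neglog10p)
                )
    return pd.DataFrame(
        records, columns=["idp", "phenotype", "r", "p", "n", "neglog10p"]
    )


def voxelwise_assoc(
    chi_4d: np.ndarray,
    pheno_vector: Sequence[float],
    confounds: Optional[np.ndarray] = None,
    mask: Optional[np.ndarray] = None,
    return_p: bool = False,
    min_n: int = 10,
):
    """Per-voxel Pearson correlation maps against one phenotype vector.

    ``chi_4d`` is (x, y, z, participant). Every voxel vector is taken
    through the same preprocessing as an IDP — outlier removal, quantile
    normalization, confound regression (recomputed per voxel) — before
    correlation with the (already preprocessed) phenotype. Constant or
    too-sparse voxels yield NaN.
    """
    chi_4d = np.asarray(chi_4d, dtype=float)
    if chi_4d.ndim != 4:
        raise ParameterError("chi_4d must be (x, y, z, participant)")
    ph = np.asarray(pheno_vector, dtype=float)
    if ph.shape[0] != chi_4d.shape[3]:
        raise ParameterError("participant axes must align")
    if mask is None:
        mask = np.ones(chi_4d.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    rmap = np.full(chi_4d.shape[:3], np.nan)
    pmap = np.full(chi_4d.shape[:3], np.nan) if return_p else None
    for ijk in np.argwhere(mask):
        v = chi_4d[tuple(ijk)]
        try:
            v = preprocess_idp_vector(v)
        except (ParameterError, ValueError):
            continue
        if confounds is not None:
            v = regress_confounds(v, confounds)
        res = pearson_assoc(v, ph, min_n=min_n)
        if res is None:
            continue
        rmap[tuple(ijk)] = res.r
        if pmap is not None:
            pmap[tuple(ijk)] = res.p
    return (rmap, pmap) if return_p else rmap


def group_difference_map(
    chi_4d: np.ndarray,
    group_a_idx: Sequence[int],
    group_b_idx: Sequence[int],
) -> np.ndarray:
    """Voxelwise mean over group A minus mean over group B.

    Used e.g. for an aging contrast between the youngest and oldest
    participants. Groups must be disjoint and nonempty.
    """
    chi_4d = np.asarray(chi_4d, dtype=float)
    a = np.asarray(group_a_idx, dtype=int)
    b = np.asarray(group_b_idx, dtype=int)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    if np.intersect1d(a, b).size:
        raise ParameterError("groups must be disjoint")
    return chi_4d[..., a].mean(axis=-1) - chi_4d[..., b].mean(axis=-1)


def manhattan_plot(results: pd.DataFrame, threshold_neglog10: float, ax=None):
    """Phenome-scan Manhattan-style plot (phenotype index vs -log10 p).

    Requires matplotlib (optional dependency). Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = np.arange(len(results))
    ax.scatter(x, results["neglog10p"], s=6, alpha=0.6)
    ax.axhline(threshold_neglog10, ls="--", color="k", lw=1)
    ax.set_xlabel("association index")
    ax.set_ylabel(r"$-\log_{10} P$")
    return ax
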