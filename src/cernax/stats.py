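"""Statistical primitives shared by every screening stage.

Pearson correlation with the two-sided t-transform p-value, Benjamini-
Hochberg step-up FDR adjustment, one-way ANOVA for the severity
contrasts, and the paired / unpaired Student t-tests used by the qPCR
stage.  Missing values are handled by pairwise deletion before any
correlation is computed.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InsufficientDataError


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson(x, y) -> PearsonResult:
    """Sample Pearson correlation with its two-sided p-value.

    Pairwise deletion: entries where either vector is NaN are dropped.
    The p-value comes from t = r*sqrt((n-2)/(1-r^2)) referred to a
    t-distribution with n-2 degrees of freedom.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 jointly non-missing observations.
    DegenerateInputError
        Either vector is constant after deletion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 jointly non-missing observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in one of the vectors")
    res = sps.pearsonr(x, y)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return PearsonResult(r=r, p=float(res.pvalue), n=n)


def pearson_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs Pearson r, p and n between rows of A and rows of B.

    NaNs are removed pairwise per (row_a, row_b) combination.  Rows that
    are constant or share < 3 samples yield NaN r and p.  Returns
    (r, p, n) arrays of shape (A rows, B rows).  Vectorised over the
    complete-data case; pairs with missing data fall back to the scalar
    path.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na, nb = A.shape[0], B.shape[0]
    R = np.full((na, nb), np.nan)
    P = np.full((na, nb), np.nan)
    N = np.zeros((na, nb), dtype=int)
    a_ok = ~np.isnan(A).any(axis=1)
    b_ok = ~np.isnan(B).any(axis=1)
    if a_ok.any() and b_ok.any():
        Ac = A[a_ok]
        Bc = B[b_ok]
        m = Ac.shape[1]
        az = Ac - Ac.mean(axis=1, keepdims=True)
        bz = Bc - Bc.mean(axis=1, keepdims=True)
        asd = np.sqrt((az**2).sum(axis=1))
        bsd = np.sqrt((bz**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (az @ bz.T) / np.outer(asd, bsd)
        r = np.clip(r, -1.0, 1.0)
        r[asd == 0, :] = np.nan
        r[:, bsd == 0] = np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((m - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(np.abs(t), df=m - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        ia = np.where(a_ok)[0]
        ib = np.where(b_ok)[0]
        R[np.ix_(ia, ib)] = r
        P[np.ix_(ia, ib)] = np.where(np.isnan(r), np.nan, p)
        N[np.ix_(ia, ib)] = m
    # pairs involving a row with missing entries: scalar fallback
    for i in range(na):
        for j in range(nb):
            if a_ok[i] and b_ok[j]:
                continue
            try:
                res = pearson(A[i], B[j])
            except (InsufficientDataError, DegenerateInputError):
                continue
            R[i, j], P[i, j], N[i, j] = res.r, res.p, res.n
    return R, P, N


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_i = min_{j >= i} (m * p_(j) / j) over the ascending sort, capped
    at 1; every q >= its p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class AnovaResult(NamedTuple):
    F: float
    p: float


def anova_two_group(severe, mild) -> AnovaResult:
    """One-way ANOVA between two sample groups (F = t^2 for two groups)."""
    severe = np.asarray(severe, dtype=float)
    mild = np.asarray(mild, dtype=float)
    if severe.size < 2 or mild.size < 2:
        raise InsufficientDataError(
            f"need >= 2 samples per group, got {severe.size} and {mild.size}"
        )
    if np.ptp(np.concatenate([severe, mild])) == 0:
        # identical constant everywhere: no evidence of difference
        return AnovaResult(F=0.0, p=1.0)
    res = sps.f_oneway(severe, mild)
    F = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(F):  # between-group variance with zero within-group variance
        return AnovaResult(F=np.inf, p=0.0)
    return AnovaResult(F=F, p=p)


class TTestResult(NamedTuple):
    t: float
    p: float
    significant: bool


def compare_groups(group_a, group_b, paired: bool = False,
                   welch: bool = False, alpha: float = 0.05) -> TTestResult:
    """Two-group Student t-test on ΔCt values (paired or unpaired).

    Unpaired uses the pooled-variance Student test by default; Welch's
    unequal-variance variant is available via ``welch=True``.  Paired
    tests operate on within-pair differences and require the caller to
    pass the groups already aligned pair-by-pair.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length, aligned groups")
        if a.size < 2:
            raise InsufficientDataError("paired test needs >= 2 pairs")
        d = a - b
        if np.ptp(d) == 0 and a.size > 1:
            if np.all(d == 0):
                return TTestResult(t=0.0, p=1.0, significant=False)
            raise DegenerateInputError("zero variance of paired differences")
        res = sps.ttest_rel(a, b)
    else:
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError("unpaired test needs >= 2 per group")
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            if a.mean() == b.mean():
                return TTestResult(t=0.0, p=1.0, significant=False)
            raise DegenerateInputError("zero variance in both groups")
        res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    return TTestResult(t=t, p=p, significant=bool(p <= alpha))
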