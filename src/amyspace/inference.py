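"""Permutation inference, FDR and profile-similarity statistics.

The statistical layer mirrors a permutation-based analysis plan:

* a one-sided one-sample sign-flip permutation t-test of whether the mean
  |Fisher z| of subject-level voxel-wise correlations exceeds a medium
  effect size (r0 = 0.3, placed on the z scale as atanh(r0));
* two-sided permutation p-values for subject-level Pearson correlations
  of amyloid load with clinical variables;
* Storey q-values (pi0 estimated from the p-value distribution) batched
  per analysis aim;
* pooled-variance Student t / chi-squared group-difference screening;
* a similarity statistic correlating the vectorised clinical-association
  profile of each MRI metric with that of amyloid load, with a
  subject-relabelling permutation null.

Sign-flip exchangeability assumes the centered effects d_i = |z_i| -
atanh(r0) are symmetrically distributed under the null; permutation
p-values use the add-one convention p = (1 + #{T* >= T}) / (1 + n_perm)
except where the null is enumerated exhaustively, in which case p is the
exact tail fraction (the identity assignment is part of the enumeration).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSizeTestResult",
    "SimilarityResult",
    "signflip_effect_size_test",
    "permutation_corr_test",
    "storey_fdr",
    "group_difference",
    "similarity_of_profiles",
]

log = logging.getLogger(__name__)

EXHAUSTIVE_SIGNFLIP_MAX_N = 20
EXHAUSTIVE_PERM_MAX_N = 7


@dataclass
class EffectSizeTestResult:
    roi_id: str
    modality_id: str
    n: int
    mean_abs_r: float
    t_stat: float
    p: float
    n_perm: int
    seed: int | None
    q: float = field(default=float("nan"))


@dataclass
class SimilarityResult:
    modality_id: str
    r_sim: float
    p: float
    n_cells: int
    q: float = field(default=float("nan"))


# --------------------------------------------------------------------------
# sign-flip one-sample test


def _t_from_means(m: np.ndarray, ss: float, n: int) -> np.ndarray:
    """t statistics from per-draw means, given the (flip-invariant) sum of
    squares ss = sum(d^2).  Zero-variance draws map to +/-inf by the sign
    of the mean (0 if the mean is 0); variance below the rounding floor of
    ss counts as zero so that identical draws yield identical statistics
    whichever code path computed them."""
    raw = ss - n * m**2
    raw = np.where(raw <= 1e-12 * ss, 0.0, raw)
    var = np.maximum(raw, 0.0) / (n - 1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / np.where(sd > 0, sd, 1.0) * math.sqrt(n),
                     np.sign(m) * np.inf)
    return np.where(np.isnan(t), 0.0, t)


def signflip_effect_size_test(z_values: np.ndarray, roi_id: str = "",
                              modality_id: str = "", r0: float = 0.3,
                              n_perm: int = 10000,
                              seed: int | None = 0) -> EffectSizeTestResult:
    """One-sided sign-flip test of mean(|z|) > atanh(r0).

    d_i = |z_i| - atanh(r0); T = mean(d) / (sd(d)/sqrt(n)).  The null is
    generated by independent random sign flips of the d_i (``n_perm``
    draws), or by exhaustive enumeration of all 2^n sign patterns when
    n <= 20, and p is the upper-tail fraction #{T* >= T}.  If every d_i
    is exactly 0 the test is degenerate and p = 1.
    """
    z = np.asarray(z_values, dtype=np.float64).ravel()
    z = z[np.isfinite(z)]
    n = z.size
    if n < 3:
        raise ValueError("sign-flip test needs at least 3 finite z values")
    d = np.abs(z) - math.atanh(r0)
    ss = float(d @ d)
    t_obs = float(_t_from_means(np.array([d.mean()]), ss, n)[0])
    mean_abs_r = float(np.tanh(np.abs(z)).mean())

    if np.all(d == 0):
        return EffectSizeTestResult(roi_id, modality_id, n, mean_abs_r,
                                    0.0, 1.0, 0, seed)

    # tie tolerance: patterns algebraically equal to the observed statistic
    # (the identity above all) must count as >= despite rounding
    t_thresh = t_obs - 1e-9 * max(1.0, abs(t_obs)) if np.isfinite(t_obs) else t_obs

    if n <= EXHAUSTIVE_SIGNFLIP_MAX_N:
        total = 1 << n
        count = 0
        chunk = 1 << 16
        bits = 1 << np.arange(n)
        for start in range(0, total, chunk):
            idx = np.arange(start, min(start + chunk, total), dtype=np.uint64)
            signs = np.where((idx[:, None] & bits.astype(np.uint64)) > 0, -1.0, 1.0)
            m = signs @ d / n
            count += int(np.count_nonzero(_t_from_means(m, ss, n) >= t_thresh))
        p = count / total
        return EffectSizeTestResult(roi_id, modality_id, n, mean_abs_r,
                                    t_obs, p, total, seed)

    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(int(n_perm), n)) * 2.0 - 1.0
    m = signs @ d / n
    t_null = _t_from_means(m, ss, n)
    count = int(np.count_nonzero(t_null >= t_thresh))
    p = (1 + count) / (1 + int(n_perm))
    return EffectSizeTestResult(roi_id, modality_id, n, mean_abs_r,
                                t_obs, p, int(n_perm), seed)


# --------------------------------------------------------------------------
# permutation correlation test


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def permutation_corr_test(x: np.ndarray, y: np.ndarray, n_perm: int = 10000,
                          seed: int | None = 0) -> tuple[float, float]:
    """Pearson r with a two-sided permutation p-value on |r|.

    Pairwise-complete on finite values; the null permutes y.  Exhaustive
    over all n! orderings when n <= 7, otherwise ``n_perm`` random
    permutations with add-one smoothing.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("permutation correlation needs >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    xs, ys = _standardize(x), _standardize(y)
    r_obs = float(xs @ ys / n)

    if n <= EXHAUSTIVE_PERM_MAX_N:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = float(xs @ ys[list(perm)] / n)
            total += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                count += 1
        return r_obs, count / total

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (int(n_perm), 1)), axis=1)
    r_null = ys[perms] @ xs / n
    count = int(np.count_nonzero(np.abs(r_null) >= abs(r_obs) - 1e-12))
    return r_obs, (1 + count) / (1 + int(n_perm))


# --------------------------------------------------------------------------
# Storey false discovery rate


def storey_fdr(p_values, pi0: float | None = None,
               lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values for a batch of p-values.

    pi0 (the null proportion) is estimated on a lambda grid 0.05..0.95
    (step 0.05) by fitting a cubic polynomial smoother to
    pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) and evaluating it
    at the largest lambda, capped into [1/m, 1].  With fewer than 8
    p-values the estimate is unstable and pi0 falls back to 1, which
    reduces the q-values exactly to step-up (Benjamini-Hochberg-style)
    adjusted values; ``pi0=1`` forces that behaviour.
    """
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 8:
            pi0 = 1.0
        else:
            lam = np.arange(0.05, 0.951, 0.05) if lambdas is None else np.asarray(lambdas)
            pi0_hat = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
            coef = np.polynomial.polynomial.polyfit(lam, pi0_hat, deg=3)
            pi0 = float(np.polynomial.polynomial.polyval(lam.max(), coef))
            pi0 = min(max(pi0, 1.0 / m), 1.0)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# group differences


def group_difference(table: pd.DataFrame, group: str,
                     variables: list[str] | None = None,
                     pi0: float | None = None) -> pd.DataFrame:
    """Screen variables for differences between two groups.

    Continuous variables get a pooled-variance two-tailed Student t test;
    categorical variables (non-numeric, boolean, or <= 2 distinct values)
    get a Pearson chi-squared test without continuity correction.  FDR
    q-values are computed across all variables in the call.
    """
    if group not in table.columns:
        raise ValueError(f"group column '{group}' not in table")
    g = table[group]
    levels = pd.unique(g.dropna())
    if len(levels) != 2:
        raise ValueError("group label must be binary")
    if variables is None:
        variables = [c for c in table.columns if c != group]
    rows = []
    for var in variables:
        col = table[var]
        numeric = (pd.api.types.is_numeric_dtype(col)
                   and not pd.api.types.is_bool_dtype(col)
                   and col.nunique() > 2)
        if numeric:
            a = col[g == levels[0]].dropna().to_numpy(dtype=np.float64)
            b = col[g == levels[1]].dropna().to_numpy(dtype=np.float64)
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"both groups need >= 2 values for '{var}'")
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append((var, "t", float(stat), float(p)))
        else:
            tab = pd.crosstab(col, g)
            if tab.empty or (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
                raise ValueError(f"empty group or category for '{var}'")
            chi2, p, _, expected = stats.chi2_contingency(tab.to_numpy(),
                                                          correction=False)
            if np.any(expected <= 0):
                raise ValueError(f"zero expected count for '{var}'")
            rows.append((var, "chi2", float(chi2), float(p)))
    out = pd.DataFrame(rows, columns=["variable", "test", "statistic", "p"])
    out["q"] = storey_fdr(out["p"].to_numpy(), pi0=pi0)
    return out.set_index("variable")


# --------------------------------------------------------------------------
# clinical-profile similarity


def similarity_of_profiles(metric_matrix, amyloid_matrix, n_perm: int = 10000,
                           seed: int | None = 0,
                           amyloid_roi_means: pd.DataFrame | None = None,
                           clinical: pd.DataFrame | None = None,
                           ) -> SimilarityResult:
    """Correlate two vectorised (ROI x clinical-variable) association matrices.

    ``r_sim`` is the Pearson r over cells present in both matrices.  The
    permutation p-value relabels subjects: amyloid ROI-mean rows are
    permuted against the clinical table, the amyloid association matrix is
    recomputed per permutation, and |r_sim*| is compared with the observed
    value (two-sided).  The null is computed complete-case over subjects
    with no missing value in any used column; without subject-level data
    (``amyloid_roi_means``/``clinical``), p is NaN.
    """
    rm, ra = metric_matrix.r, amyloid_matrix.r
    if not (rm.index.equals(ra.index) and rm.columns.equals(ra.columns)):
        raise ValueError("association matrices must share row/column labels")
    a = rm.to_numpy(dtype=np.float64).ravel()
    b = ra.to_numpy(dtype=np.float64).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    n_cells = int(ok.sum())
    if n_cells < 3:
        raise ValueError("need >= 3 shared non-missing cells")
    av, bv = a[ok], b[ok]
    r_sim = float(_standardize(av) @ _standardize(bv) / n_cells)

    p = float("nan")
    if amyloid_roi_means is not None and clinical is not None:
        variables = list(ra.columns)
        rois = list(ra.index)
        common = amyloid_roi_means.index.intersection(clinical.index)
        A = amyloid_roi_means.loc[common, rois].to_numpy(dtype=np.float64)
        C = clinical.loc[common, variables].to_numpy(dtype=np.float64)
        complete = np.isfinite(A).all(axis=1) & np.isfinite(C).all(axis=1)
        A, C = A[complete], C[complete]
        n_sub = A.shape[0]
        if n_sub < 4:
            raise ValueError("too few complete subjects for the permutation null")
        As = (A - A.mean(0)) / A.std(0)
        Cs = (C - C.mean(0)) / C.std(0)
        mv = _standardize(av)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(int(n_perm)):
            perm = rng.permutation(n_sub)
            ra_null = (As[perm].T @ Cs / n_sub).ravel()[ok]
            if ra_null.std() == 0:
                continue
            r_null = float(mv @ _standardize(ra_null) / n_cells)
            if abs(r_null) >= abs(r_sim) - 1e-12:
                count += 1
        p = (1 + count) / (1 + int(n_perm))
    return SimilarityResult(modality_id=metric_matrix.modality_id,
                            r_sim=r_sim, p=p, n_cells=n_cells)
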