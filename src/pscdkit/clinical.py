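"""Decliner classification, control matching and association statistics.

The decliner rule mirrors the nested case-control design: a patient is a
delayed-onset decliner when the MMSE falls at a rate of >= 3 points per
year or by >= 5 points in total between the baseline and last
evaluations; a non-decliner loses at most 1 point per year and fewer than
3 points in total; everything else is indeterminate.  Controls are
matched 1:1 on age (+/-3 years) and initial NIHSS (+/-2 points).

Group comparisons use t-tests or Wilcoxon rank-sum for continuous
variables (policy-driven) and chi-square with a Fisher's-exact fallback
for categorical ones.  Brain-cognition associations default to Spearman's
rho, with Pearson's r available; differential WMH effects are tested by
OLS with a group x WMH interaction, and voxel-wise amyloid patterns by a
logistic model of group on age, sex, education and voxel SUVR at an
uncorrected p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .imaging import LabeledVolume

__all__ = [
    "SubjectRecord",
    "AssociationResult",
    "StatMap",
    "classify_decliner",
    "match_controls",
    "group_compare",
    "cohen_d",
    "rank_correlation",
    "interaction_regression",
    "voxelwise_logistic",
    "records_to_frame",
]


@dataclass
class SubjectRecord:
    id: str
    group: str  # decliner | non_decliner | control | indeterminate
    age_years: float
    sex: str  # "F" | "M"
    education_years: float
    nihss_baseline: float
    mmse_baseline: float
    mmse_final: float | None = None
    interval_months: float | None = None
    wmh_fraction_pct: float | None = None
    global_suvr: float | None = None
    apoe_e4: bool | None = None
    attribute_profile: object | None = None
    sysseg: object | None = None

    def __post_init__(self) -> None:
        if self.mmse_final is not None:
            if self.interval_months is None or self.interval_months <= 0:
                raise ValueError("interval_months must be positive when mmse_final is present")
        for v in (self.mmse_baseline, self.mmse_final):
            if v is not None and not (0 <= v <= 30):
                raise ValueError("MMSE scores must lie in [0, 30]")

    @property
    def mmse_change(self) -> float | None:
        if self.mmse_final is None:
            return None
        return self.mmse_final - self.mmse_baseline


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "group": r.group,
                "age_years": r.age_years,
                "sex": r.sex,
                "education_years": r.education_years,
                "nihss_baseline": r.nihss_baseline,
                "mmse_baseline": r.mmse_baseline,
                "mmse_final": r.mmse_final,
                "mmse_change": r.mmse_change,
                "interval_months": r.interval_months,
                "wmh_fraction_pct": r.wmh_fraction_pct,
                "global_suvr": r.global_suvr,
                "apoe_e4": r.apoe_e4,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AssociationResult:
    statistic_name: str
    estimate: float
    p_value: float
    n: int
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")


def classify_decliner(
    mmse_baseline: float, mmse_final: float, interval_months: float
) -> str:
    """Apply the delayed-decline MMSE rule; annual rate = 12 x change / months."""
    if mmse_baseline is None or mmse_final is None:
        raise ValueError("missing MMSE score")
    if interval_months is None or interval_months <= 0:
        raise ValueError("interval_months must be positive")
    change = mmse_final - mmse_baseline
    rate = 12.0 * change / interval_months
    if rate <= -3.0 or change <= -5.0:
        return "decliner"
    if rate >= -1.0 and (mmse_baseline - mmse_final) < 3.0:
        return "non_decliner"
    return "indeterminate"


def match_controls(
    decliners: Sequence[SubjectRecord],
    pool: Sequence[SubjectRecord],
    age_tol: float = 3.0,
    nihss_tol: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Greedy 1:1 matching on age and NIHSS, in seeded random decliner order.

    Each decliner is paired with the nearest unused pool member (by
    |d age| + |d NIHSS|, ties by pool index) within both tolerances;
    decliners with no admissible partner are listed unmatched.
    """
    if not pool:
        raise ValueError("matching pool is empty")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(decliners))
    used: set[int] = set()
    rows = []
    for di in order:
        d = decliners[di]
        best, best_key = None, None
        for pi, c in enumerate(pool):
            if pi in used:
                continue
            da, dn = abs(d.age_years - c.age_years), abs(d.nihss_baseline - c.nihss_baseline)
            if da <= age_tol and dn <= nihss_tol:
                key = (da + dn, pi)
                if best_key is None or key < best_key:
                    best, best_key = pi, key
        if best is None:
            rows.append({"decliner": d.id, "control": None, "distance": np.nan})
        else:
            used.add(best)
            rows.append({"decliner": d.id, "control": pool[best].id, "distance": best_key[0]})
    return pd.DataFrame(rows).sort_values("decliner").reset_index(drop=True)


def group_compare(
    values_a,
    values_b=None,
    variable_kind: str = "continuous",
    small_n: int = 15,
    force: str | None = None,
) -> AssociationResult:
    """Two-group comparison with the configured test-selection policy.

    Continuous: Wilcoxon rank-sum when either group has n < ``small_n``,
    Student's t otherwise (override with ``force`` in {"t", "wilcoxon"}).
    Categorical: ``values_a`` is a 2 x k contingency table; chi-square,
    falling back to Fisher's exact on 2 x 2 tables with any expected cell
    below 5.
    """
    if variable_kind == "continuous":
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("degenerate comparison: zero variance in both groups")
        use = force or ("wilcoxon" if min(len(a), len(b)) < small_n else "t")
        if use == "wilcoxon":
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            return AssociationResult("rank_sum_U", float(res.statistic), float(res.pvalue), len(a) + len(b), "wilcoxon")
        res = stats.ttest_ind(a, b)
        return AssociationResult("t", float(res.statistic), float(res.pvalue), len(a) + len(b), "t_test")
    if variable_kind == "categorical":
        table = np.asarray(values_a, dtype=int)
        if table.ndim != 2 or table.shape[0] != 2:
            raise ValueError("categorical comparison expects a 2 x k contingency table")
        n = int(table.sum())
        expected = stats.contingency.expected_freq(table)
        if table.shape == (2, 2) and (expected < 5).any():
            odds, p = stats.fisher_exact(table)
            return AssociationResult("odds_ratio", float(odds), float(p), n, "fisher_exact")
        chi2, p, _, _ = stats.chi2_contingency(table)
        return AssociationResult("chi2", float(chi2), float(p), n, "chi_square")
    raise ValueError(f"unknown variable_kind {variable_kind!r}")


def cohen_d(values_a, values_b) -> float:
    """(mean_a - mean_b) / pooled sd, pooled with n-1 weights."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("Cohen's d undefined: pooled standard deviation is zero")
    return float((a.mean() - b.mean()) / pooled)


def rank_correlation(x, y, method: str = "spearman") -> AssociationResult:
    """Spearman's rho (default) or Pearson's r with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return AssociationResult("rho", float(rho), float(p), len(x), "spearman")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return AssociationResult("r", float(r), float(p), len(x), "pearson")
    raise ValueError(f"unknown method {method!r}")


def interaction_regression(y, x, group) -> pd.DataFrame:
    """OLS of y on {1, x, group, x*group}; the interaction row is the headline.

    ``group`` is coded 0/1 (decliner = 1).  A rank-deficient design raises
    with the name of the offending column.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(group, dtype=float)
    if len(set(g)) < 2:
        raise ValueError("both groups must be represented")
    if len(y) < 6:
        raise ValueError("need n >= 6 observations")
    X = np.column_stack([np.ones_like(x), x, g, x * g])
    names = ["intercept", "x", "group", "x:group"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"collinear design: column {names[j]!r}")
        raise ValueError("collinear design")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).set_index("term")


@dataclass
class StatMap:
    """Voxelwise Wald statistics for the SUVR term of the logistic model."""

    t_values: np.ndarray
    p_values: np.ndarray
    threshold_mask: np.ndarray
    non_converged: np.ndarray


def voxelwise_logistic(
    suvr_volumes: Sequence[LabeledVolume],
    groups,
    age,
    sex,
    education,
    brain_mask: LabeledVolume,
    alpha: float = 0.05,
    maxiter: int = 50,
) -> StatMap:
    """Per-voxel logistic fit: group ~ age + sex + education + SUVR(voxel).

    Group is coded decliner = 1, control = 0; sex as 0/1.  The Wald
    statistic and two-sided p for the SUVR coefficient are mapped; voxels
    with separation or non-convergence are flagged and excluded from the
    uncorrected p < ``alpha`` mask.
    """
    groups = np.asarray(groups, dtype=float)
    n = len(groups)
    if len(suvr_volumes) != n:
        raise ValueError("one SUVR volume per subject is required")
    if min((groups == 1).sum(), (groups == 0).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    base = np.column_stack(
        [np.ones(n), np.asarray(age, float), np.asarray(sex, float), np.asarray(education, float)]
    )
    if n <= base.shape[1] + 1:
        raise ValueError("fewer subjects than model parameters")
    shape = brain_mask.grid_shape
    for v in suvr_volumes:
        if v.grid_shape != shape:
            raise ValueError("all volumes must share the brain-mask grid")
    mask = np.asarray(brain_mask.data) > 0
    vox_idx = np.flatnonzero(mask.ravel())
    data = np.stack([np.asarray(v.data, float).ravel()[vox_idx] for v in suvr_volumes])
    t_map = np.full(shape, np.nan).ravel()
    p_map = np.full(shape, np.nan).ravel()
    bad = np.zeros(shape, dtype=np.int8).ravel()
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    for col, vi in enumerate(vox_idx):
        X = np.column_stack([base, data[:, col]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(groups, X).fit(disp=0, method="newton", maxiter=maxiter)
            if not fit.mle_retvals.get("converged", False) or not np.isfinite(fit.bse).all() or np.abs(fit.params).max() > 50:
                raise PerfectSeparationError("non-converged")
            z = fit.params[-1] / fit.bse[-1]
            t_map[vi] = z
            p_map[vi] = 2 * stats.norm.sf(abs(z))
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            bad[vi] = 1
    thresh = ((p_map < alpha) & (bad == 0) & np.isfinite(p_map)).astype(np.int8)
    return StatMap(
        t_map.reshape(shape), p_map.reshape(shape), thresh.reshape(shape), bad.reshape(shape)
    )
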