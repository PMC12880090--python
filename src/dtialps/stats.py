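"""Longitudinal group statistics for ALPS cohorts.

Implements the analysis chain of a two-arm longitudinal design: baseline
demographic contrasts (Student t / Mann-Whitney U / Pearson chi-square,
with a Shapiro-Wilk normality gate), per-region group contrasts of the
ALPS index with covariate-adjusted linear regression, within-group paired
t-tests of BL vs FU, between-group contrasts of the per-day ALPS change
rate with Benjamini-Hochberg FDR, and Spearman correlations between ALPS
(changes) and clinical-scale (changes).

Orientation conventions (fixed so statistic signs are reproducible):
paired tests report mean(BL - FU); group contrasts report HF - LF.

Standard tests delegate to scipy.stats / statsmodels; the Wilcoxon
signed-rank test is implemented here so that the exact tie-aware null
distribution (via its generating function) is used up to n = 25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "RegressionResult",
    "StatReport",
    "change_rate",
    "paired_t",
    "two_sample_t",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "chi_square_2x2",
    "shapiro_wilk_gate",
    "spearman",
    "adjusted_regression",
    "bh_fdr",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)


class DegenerateStatisticError(ValueError):
    """Raised when a test statistic is undefined for the given input."""


@dataclass
class TestResult:
    name: str
    statistic: float
    p_raw: float
    df: float | None = None
    p_fdr: float | None = None
    estimate: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError(f"p_raw={self.p_raw} outside [0, 1]")


@dataclass
class RegressionResult:
    name: str
    beta: float
    ci_low: float
    ci_high: float
    p_raw: float
    n: int
    covariates: tuple[str, ...]


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def change_rate(bl, fu, days):
    """ALPS change rate in % per day: ((FU - BL) / BL) / days * 100."""
    bl = np.asarray(bl, dtype=float)
    fu = np.asarray(fu, dtype=float)
    days = np.asarray(days, dtype=float)
    if np.any(bl <= 0):
        raise ValueError("baseline index must be positive")
    if np.any(days <= 0):
        raise ValueError("follow-up interval must be positive")
    out = ((fu - bl) / bl) / days * 100.0
    return float(out) if out.ndim == 0 else out


def paired_t(before, after, name: str = "paired_t") -> TestResult:
    """Paired Student t on (before - after); positive statistic = decline."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1D samples")
    n = before.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = before - after
    if np.all(d == 0) or d.std(ddof=1) == 0:
        raise DegenerateStatisticError("all paired differences identical")
    res = sps.ttest_rel(before, after)
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      df=float(n - 1), estimate=float(d.mean()), n=n)


def two_sample_t(a, b, pooled: bool = True, name: str = "two_sample_t") -> TestResult:
    """Two-sample t on mean(a) - mean(b); Student (pooled variance) by
    default, Welch with ``pooled=False``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateStatisticError("zero variance in both samples")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    df = float(a.size + b.size - 2) if pooled else float(res.df)
    return TestResult(name, float(res.statistic), float(res.pvalue), df=df,
                      estimate=float(a.mean() - b.mean()), n=a.size + b.size)


def _signed_rank_exact_sf(ranks2: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact signed-rank null.

    ``ranks2`` are the (tied-averaged) ranks doubled so they are integers;
    the null distribution of 2*W+ is built from its generating function
    prod_i (1 + x^{r_i}) / 2^n by direct polynomial convolution, which
    handles tied ranks exactly.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= 2.0 ** len(ranks2)
    lower = float(counts[: w2 + 1].sum())
    upper = float(counts[w2:].sum())
    return lower, upper


def wilcoxon_signed_rank(before, after, name: str = "wilcoxon") -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences get averaged
    ranks.  The exact null distribution is used for effective n <= 25
    (tie-aware), the tie-corrected normal approximation beyond.  The
    reported statistic is W+ = sum of ranks of positive (before - after)
    differences.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1D samples")
    d = before - after
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateStatisticError("all paired differences zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        lower, upper = _signed_rank_exact_sf(ranks2, int(round(2 * w_plus)))
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        if var == 0:
            raise DegenerateStatisticError("zero variance (all ranks tied away)")
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(name, w_plus, p, n=n)


def mann_whitney(a, b, name: str = "mann_whitney") -> TestResult:
    """Mann-Whitney U; exact for small untied samples, tie-corrected normal
    approximation otherwise.  Statistic is the standardized Z (signed so
    that a tending larger than b gives positive Z); U of sample a is in
    ``estimate``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("samples must be nonempty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (not has_ties and max(n1, n2) <= 12) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=False)
    u = float(res.statistic)
    mu = n1 * n2 / 2.0
    nn = n1 + n2
    _, t = np.unique(combined, return_counts=True)
    var = n1 * n2 / 12.0 * (nn + 1 - (t**3 - t).sum() / (nn * (nn - 1)))
    z = 0.0 if var == 0 else (u - mu) / np.sqrt(var)
    return TestResult(name, float(z), float(res.pvalue), estimate=u, n=nn)


def chi_square_2x2(counts, name: str = "chi_square") -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df=1."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateStatisticError("zero margin in the 2x2 table")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(name, float(chi2), float(p), df=float(df),
                      n=int(table.sum()))


def shapiro_wilk_gate(sample, alpha: float = 0.05) -> str:
    """Shapiro-Wilk normality gate: 'normal' or 'non-normal' at ``alpha``."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateStatisticError("constant sample: normality undefined")
    _, p = sps.shapiro(x)
    return "normal" if p >= alpha else "non-normal"


def spearman(x, y, name: str = "spearman") -> TestResult:
    """Spearman rank correlation; two-sided p via the t approximation with
    df = n - 2 (ties get averaged ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x/y must be equal-length 1D samples")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise DegenerateStatisticError("zero rank variance")
    rho, p = sps.spearmanr(x, y)
    return TestResult(name, float(rho), float(p), df=float(x.size - 2),
                      estimate=float(rho), n=x.size)


def adjusted_regression(
    outcome, group, age, sex_male, bmi, onset_days, name: str = "adjusted_ols"
) -> RegressionResult:
    """OLS of outcome on a group indicator (HF = 1, LF = 0) adjusted for
    age, sex (male = 1), BMI and days since stroke onset; reports the group
    coefficient with its 95% CI and two-sided p."""
    cols = {
        "group": np.asarray(group, dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex_male": np.asarray(sex_male, dtype=float),
        "bmi": np.asarray(bmi, dtype=float),
        "onset_days": np.asarray(onset_days, dtype=float),
    }
    y = np.asarray(outcome, dtype=float)
    X = np.column_stack([np.ones_like(y)] + list(cols.values()))
    names = ("const",) + tuple(cols)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [nm for i, nm in enumerate(names)
               if np.linalg.matrix_rank(np.delete(X, i, axis=1)) ==
               np.linalg.matrix_rank(X)]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        name=name,
        beta=float(fit.params[1]),
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        p_raw=float(fit.pvalues[1]),
        n=int(y.size),
        covariates=names[2:],
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, idempotent)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# full cohort analysis
# --------------------------------------------------------------------------

_REGION_COLS = {"total": "total", "stimulated": "stim", "non_stimulated": "nonstim"}

#: Table-1-style rows: (column, kind); 'auto' = Shapiro-gated t vs MWU
_TABLE1_ROWS = [
    ("age", "auto"), ("sex", "chi2"), ("bmi", "auto"), ("lymphocytes", "auto"),
    ("nihss_bl", "auto"), ("onset_days", "auto"), ("brunnstrom_bl", "auto"),
    ("fma_bl", "auto"), ("mas_bl", "auto"), ("ashworth_bl", "auto"),
    ("swmt_bl", "auto"), ("wmft_bl", "auto"), ("adl_bl", "auto"),
    ("qol_bl", "auto"),
]

_CORR_SCALES = ("nihss", "brunnstrom", "fma", "mas", "ashworth", "swmt",
                "wmft", "adl", "qol")


@dataclass
class StatReport:
    table1: dict
    table2: dict
    longitudinal: dict
    table3: dict
    correlations: dict
    fdr_families: dict
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, (TestResult, RegressionResult)):
                return {k: conv(v) for k, v in asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj
        return conv({
            "table1": self.table1,
            "table2": self.table2,
            "longitudinal": self.longitudinal,
            "table3": self.table3,
            "correlations": self.correlations,
            "fdr_families": self.fdr_families,
            "meta": self.meta,
        })


def _require_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")


def _complete(df: pd.DataFrame, cols, block: str) -> pd.DataFrame:
    sub = df.dropna(subset=list(cols))
    if len(sub) < len(df):
        logger.warning("%s: dropped %d incomplete rows", block, len(df) - len(sub))
    return sub


def cohort_change_rates(df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject ALPS change rates (% per day) for the three regions."""
    out = pd.DataFrame(index=df.index)
    for region, col in _REGION_COLS.items():
        out[region] = change_rate(
            df[f"alps_{col}_bl"], df[f"alps_{col}_fu"], df["fu_days"]
        )
    return out


def run_full_analysis(
    df: pd.DataFrame, correlation_scope: str = "pooled"
) -> StatReport:
    """Full statistical report on a cohort table.

    ``correlation_scope`` chooses whether the ALPS-vs-clinical Spearman
    correlations pool both treatment groups ('pooled', n = all subjects) or
    use the HF group only ('hf-only').
    """
    if correlation_scope not in ("pooled", "hf-only"):
        raise ValueError("correlation_scope must be 'pooled' or 'hf-only'")
    from .cohort import COHORT_COLUMNS
    _require_columns(df, COHORT_COLUMNS)
    if not {"HF", "LF"} <= set(df["group"]):
        raise ValueError("both HF and LF groups must be nonempty")
    fdr_families: dict[str, int] = {}

    hf = df[df["group"] == "HF"]
    lf = df[df["group"] == "LF"]

    # ---- Table 1: baseline demographics / clinical contrasts ----
    table1: dict[str, TestResult] = {}
    for col, kind in _TABLE1_ROWS:
        if kind == "chi2":
            counts = np.array([
                [(hf["sex"] == "M").sum(), (lf["sex"] == "M").sum()],
                [(hf["sex"] == "F").sum(), (lf["sex"] == "F").sum()],
            ])
            table1[col] = chi_square_2x2(counts, name="chi_square")
            continue
        sub = _complete(df, [col, "group"], f"table1:{col}")
        a = sub.loc[sub["group"] == "HF", col].to_numpy(float)
        b = sub.loc[sub["group"] == "LF", col].to_numpy(float)
        try:
            gate = "normal" if (
                shapiro_wilk_gate(a) == "normal"
                and shapiro_wilk_gate(b) == "normal"
            ) else "non-normal"
        except DegenerateStatisticError:
            gate = "non-normal"
        table1[col] = (
            two_sample_t(a, b, name="student_t") if gate == "normal"
            else mann_whitney(a, b, name="mann_whitney_z")
        )

    # ---- Table 2: group contrasts of the ALPS index + adjusted regression ----
    sex_male = (df["sex"] == "M").astype(float)
    group_ind = (df["group"] == "HF").astype(float)
    table2: dict[str, dict] = {}
    for region, col in _REGION_COLS.items():
        table2[region] = {}
        for tp in ("bl", "fu"):
            c = f"alps_{col}_{tp}"
            t = two_sample_t(hf[c], lf[c], name="student_t")
            reg = adjusted_regression(
                df[c], group_ind, df["age"], sex_male, df["bmi"],
                df["onset_days"],
            )
            table2[region][tp] = {"t": t, "regression": reg}

    # ---- longitudinal paired tests, per group and region ----
    longitudinal: dict[str, dict] = {}
    for grp, sub in (("HF", hf), ("LF", lf)):
        longitudinal[grp] = {}
        for region, col in _REGION_COLS.items():
            longitudinal[grp][region] = paired_t(
                sub[f"alps_{col}_bl"], sub[f"alps_{col}_fu"], name="paired_t"
            )

    # ---- Table 3: change-rate contrasts with BH-FDR over the 3 regions ----
    rates = cohort_change_rates(df)
    table3: dict[str, TestResult] = {}
    for region in _REGION_COLS:
        table3[region] = two_sample_t(
            rates.loc[hf.index, region], rates.loc[lf.index, region],
            name="student_t",
        )
    adj = bh_fdr([table3[r].p_raw for r in _REGION_COLS])
    for region, p in zip(_REGION_COLS, adj):
        table3[region].p_fdr = float(p)
    fdr_families["table3_change_rate"] = len(_REGION_COLS)

    # ---- Spearman correlations: baseline levels and longitudinal deltas ----
    scope_df = df if correlation_scope == "pooled" else hf
    scope_rates = rates.loc[scope_df.index]
    correlations: dict[str, dict] = {"baseline": {}, "delta": {}}
    for region, col in _REGION_COLS.items():
        base_row: dict[str, TestResult] = {}
        delta_row: dict[str, TestResult] = {}
        for scale in _CORR_SCALES:
            base_row[scale] = spearman(
                scope_df[f"alps_{col}_bl"], scope_df[f"{scale}_bl"]
            )
            delta_row[scale] = spearman(
                scope_rates[region],
                scope_df[f"{scale}_fu"] - scope_df[f"{scale}_bl"],
            )
        for row, label in ((base_row, "baseline"), (delta_row, "delta")):
            adj = bh_fdr([row[s].p_raw for s in _CORR_SCALES])
            for scale, p in zip(_CORR_SCALES, adj):
                row[scale].p_fdr = float(p)
            fdr_families[f"corr_{label}_{region}"] = len(_CORR_SCALES)
        correlations["baseline"][region] = base_row
        correlations["delta"][region] = delta_row

    meta = {
        "n_hf": int(len(hf)),
        "n_lf": int(len(lf)),
        "correlation_scope": correlation_scope,
    }
    return StatReport(table1, table2, longitudinal, table3, correlations,
                      fdr_families, meta)
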