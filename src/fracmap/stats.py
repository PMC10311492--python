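"""Cohort statistics: the normality/variance-driven decision tree.

Quantitative group comparisons follow the clinical convention: Shapiro-Wilk on
each group (both p > alpha means normal), then Levene's test (mean-centered) to
choose pooled versus Welch t; non-normal data go to Mann-Whitney U. Categorical
tables use Pearson chi-square without continuity correction unless more than
20% of cells have expected frequency below 5, in which case Fisher's exact test
(full conditional enumeration, two-sided as the sum of table probabilities not
exceeding the observed one) is applied. Every branch decision is recorded in a
selection trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("fracmap")

ALPHA = 0.05


@dataclass
class StatResult:
    variable: str
    groups: tuple
    test_name: str   # pooled-t | welch-t | mann-whitney | chi-square | fisher-exact
    statistic: float
    p_value: float
    df: float | None = None
    selection_trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isnan(self.p_value) and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if not self.selection_trace:
            raise ValueError("selection_trace must be nonempty")


@dataclass
class SummaryCell:
    mode: str        # mean_sd | median_iqr | freq_pct
    values: tuple

    def __str__(self) -> str:
        if self.mode == "mean_sd":
            return f"{self.values[0]:.2f} ± {self.values[1]:.2f}"
        if self.mode == "median_iqr":
            return f"{self.values[0]:.2f} ({self.values[1]:.2f})"
        return ", ".join(f"{k}: {n} ({p:.1f})" for k, n, p in self.values)


# ---------------------------------------------------------------------------
# quantitative comparisons
# ---------------------------------------------------------------------------

def compare_quantitative(x, y, alpha: float = ALPHA,
                         variable: str = "", groups=("x", "y")) -> StatResult:
    """Two-group comparison through the normality/variance decision tree."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs n >= 3")
    trace = []

    def shapiro_p(s, name):
        if np.ptp(s) == 0:
            trace.append((f"shapiro_{name}", None,
                          "constant sample: undefined, treated as non-normal"))
            return 0.0
        p = float(sps.shapiro(s).pvalue)
        trace.append((f"shapiro_{name}", p,
                      "normal" if p > alpha else "non-normal"))
        return p

    px, py = shapiro_p(x, groups[0]), shapiro_p(y, groups[1])
    if px > alpha and py > alpha:
        lev = float(sps.levene(x, y, center="mean").pvalue)
        equal = lev > alpha
        trace.append(("levene", lev,
                      "equal variances" if equal else "unequal variances"))
        res = sps.ttest_ind(x, y, equal_var=equal)
        name = "pooled-t" if equal else "welch-t"
        trace.append(("test", name, "normal branch"))
        return StatResult(variable, tuple(groups), name,
                          float(res.statistic), float(res.pvalue),
                          df=float(res.df), selection_trace=trace)
    # Mann-Whitney: exact when both small and tie-free, else normal
    # approximation with tie and continuity correction
    if np.ptp(np.concatenate([x, y])) == 0:
        trace.append(("test", "mann-whitney",
                      "all observations identical: p = 1 by convention"))
        return StatResult(variable, tuple(groups), "mann-whitney",
                          float(len(x) * len(y) / 2), 1.0, selection_trace=trace)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    trace.append(("test", "mann-whitney", f"{method} method"))
    return StatResult(variable, tuple(groups), "mann-whitney",
                      float(res.statistic), float(res.pvalue),
                      selection_trace=trace)


def t_from_summary(m1, s1, n1, m2, s2, n2, variant: str = "pooled",
                   variable: str = "", groups=("x", "y")) -> StatResult:
    """Closed-form two-sided two-sample t-test from printed summaries."""
    if s1 < 0 or s2 < 0 or n1 < 2 or n2 < 2:
        raise ValueError("need s >= 0 and n >= 2 in both groups")
    trace = [("variant", variant, "from summary statistics")]
    if s1 == 0 and s2 == 0:
        if m1 == m2:
            trace.append(("degenerate", None, "identical constants: p = 1"))
            return StatResult(variable, tuple(groups), f"{variant}-t", 0.0, 1.0,
                              df=float(n1 + n2 - 2), selection_trace=trace)
        raise ValueError("zero variance in both groups with differing means")
    equal_var = variant == "pooled"
    t, p = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatResult(variable, tuple(groups), f"{variant}-t",
                      float(t), float(p), df=df, selection_trace=trace)


# ---------------------------------------------------------------------------
# categorical comparisons
# ---------------------------------------------------------------------------

def fisher_exact_rc(table: np.ndarray) -> float:
    """Two-sided Fisher's exact test for an r x c table by full enumeration of
    the conditional (fixed-margin) distribution: p = sum of probabilities of
    tables no more probable than the observed."""
    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = int(table.sum())
    const = (sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
             - lgamma(N + 1))

    def logp(cells):
        return const - sum(lgamma(v + 1) for v in cells)

    lp_obs = logp(table.ravel())
    r, c = table.shape
    total = 0.0

    def fill_row(i, col_rem, acc_cells):
        nonlocal total
        if i == r - 1:
            last = col_rem
            if all(v >= 0 for v in last) and sum(last) == rows[i]:
                lp = logp(acc_cells + list(last))
                if lp <= lp_obs + 1e-9:
                    total += np.exp(lp)
            return

        def fill_cell(j, left, row_cells):
            if j == c - 1:
                if 0 <= left <= col_rem[j]:
                    fill_row(i + 1,
                             tuple(col_rem[k] - (row_cells + [left])[k]
                                   for k in range(c)),
                             acc_cells + row_cells + [left])
                return
            for v in range(min(left, col_rem[j]) + 1):
                fill_cell(j + 1, left - v, row_cells + [v])

        fill_cell(0, int(rows[i]), [])

    fill_row(0, tuple(int(v) for v in cols), [])
    return min(total, 1.0)


def compare_categorical(table, variable: str = "", groups=("33A", "33C"),
                        expected_rule: float = 0.20) -> StatResult:
    """Chi-square (no continuity correction) or Fisher's exact, chosen by the
    20% expected-frequency rule."""
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (table < 0).any():
        raise ValueError("counts must be >= 0")
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    if (rows == 0).any():
        raise ValueError(f"zero margin in row {int(np.argmax(rows == 0))}")
    if (cols == 0).any():
        raise ValueError(f"zero margin in column {int(np.argmax(cols == 0))}")
    expected = sps.contingency.expected_freq(table)
    frac_small = float((expected < 5).mean())
    trace = [("expected<5 fraction", frac_small,
              "fisher" if frac_small > expected_rule else "chi-square")]
    if frac_small > expected_rule:
        p = fisher_exact_rc(table)
        return StatResult(variable, tuple(groups), "fisher-exact",
                          float("nan"), p, selection_trace=trace)
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return StatResult(variable, tuple(groups), "chi-square",
                      float(chi2), float(p), df=float(dof),
                      selection_trace=trace)


# ---------------------------------------------------------------------------
# summaries and the cohort report
# ---------------------------------------------------------------------------

def summarize(x, alpha: float = ALPHA) -> SummaryCell:
    """Mean ± SD when the sample passes the Shapiro-Wilk gate, else
    median (IQR) with linear-interpolation quantiles."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    if len(x) >= 3 and np.ptp(x) > 0:
        p = float(sps.shapiro(x).pvalue)
        if p > alpha:
            return SummaryCell("mean_sd", (float(np.mean(x)), float(np.std(x, ddof=1))))
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return SummaryCell("median_iqr", (float(med), float(q3 - q1)))


QUANT_VARS = ["age", "height", "weight", "bmi", "n_fragments",
              "n_comminuted", "mean_comminuted_volume"]
CAT_VARS = ["sex", "side", "mechanism", "has_comminution"]


def cohort_report(df: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """Per-variable summaries and group comparisons between the two fracture
    classes, with significance flagged at p < alpha."""
    if df.empty:
        raise ValueError("empty cohort")
    classes = sorted(df["ao_class"].unique())
    if len(classes) != 2:
        raise ValueError(f"need both fracture classes present, got {classes}")
    g1 = df[df["ao_class"] == classes[0]]
    g2 = df[df["ao_class"] == classes[1]]
    rows = []
    for var in QUANT_VARS:
        if var not in df.columns:
            continue
        x, y = g1[var].to_numpy(float), g2[var].to_numpy(float)
        res = compare_quantitative(x, y, alpha=alpha, variable=var,
                                   groups=tuple(classes))
        rows.append({
            "variable": var,
            f"summary_{classes[0]}": str(summarize(x, alpha)),
            f"summary_{classes[1]}": str(summarize(y, alpha)),
            "test": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "significant": res.p_value < alpha,
        })
    for var in CAT_VARS:
        if var not in df.columns:
            continue
        levels = sorted(df[var].astype(str).unique())
        if len(levels) < 2:
            logger.info("skipping constant categorical %s", var)
            continue
        table = np.array([
            [int((g[var].astype(str) == lev).sum()) for g in (g1, g2)]
            for lev in levels])
        res = compare_categorical(table, variable=var, groups=tuple(classes))
        cells = {}
        for gi, g in enumerate((g1, g2)):
            vals = tuple((lev, int((g[var].astype(str) == lev).sum()),
                          100.0 * (g[var].astype(str) == lev).mean())
                         for lev in levels)
            cells[f"summary_{classes[gi]}"] = str(SummaryCell("freq_pct", vals))
        rows.append({
            "variable": var, **cells,
            "test": res.test_name,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "significant": res.p_value < alpha,
        })
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Aligned plain-text rendering of the cohort report."""
    out = report.copy()
    out["p_value"] = out["p_value"].map(
        lambda p: "<0.001" if p < 0.001 else f"{p:.3f}")
    return out.to_string(index=False)
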