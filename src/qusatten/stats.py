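"""Study statistics: errors, effect sizes, Bonferroni tiers, correlation.

Cohen's d uses the unweighted root-mean-square of the two group standard
deviations, ``d = (Xa - Xb) / sqrt((sa^2 + sb^2)/2)``, with |d| of 0.2 /
0.5 / 0.8 read as small / medium / large.  Multiple-comparison control
divides the 5%, 1% and 0.1% significance levels by the number of tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupSummary:
    """(mean, std, n) triple in native units."""

    mean: float
    std: float
    n: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class ComparisonResult:
    p_value: float
    cohens_d: float
    significance_tier: str  # "ns" or the threshold met, e.g. "0.0125"
    effect_label: str  # small / medium / large


@dataclass
class CorrelationResult:
    r_squared: float
    p_value: float
    slope: float
    intercept: float
    n: int


def absolute_error(measured: float, reference: float) -> float:
    """|measured - reference| (same units)."""
    return abs(measured - reference)


def relative_error(measured: float, reference: float) -> float:
    """100 * |measured - reference| / |reference|, in percent."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * absolute_error(measured, reference) / abs(reference)


def effect_label(d: float) -> str:
    m = abs(d)
    if m <= 0.2:
        return "small"
    if m < 0.8:
        return "medium"
    return "large"


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Standardized mean difference with the unweighted RMS-of-stds denominator."""
    denom2 = (a.std**2 + b.std**2) / 2.0
    if denom2 == 0:
        raise ValueError("both group stds are zero: effect size undefined")
    return (a.mean - b.mean) / np.sqrt(denom2)


def bonferroni_thresholds(n_tests: int) -> tuple[float, float, float]:
    """Adjusted (5%, 1%, 0.1%) significance tiers: (0.05, 0.01, 0.001)/n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return (0.05 / n_tests, 0.01 / n_tests, 0.001 / n_tests)


def _tier(p: float, thresholds: tuple[float, float, float]) -> str:
    t5, t1, t01 = thresholds
    if p < t01:
        return f"{t01:g}"
    if p < t1:
        return f"{t1:g}"
    if p < t5:
        return f"{t5:g}"
    return "ns"


def unpaired_ttest(a, b, n_tests: int = 4) -> ComparisonResult:
    """Two-sided unpaired two-sample t-test with Bonferroni-adjusted tiers."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("degenerate samples: zero variance in both groups")
    t, p = sps.ttest_ind(a, b)
    d = cohens_d(
        GroupSummary(float(a.mean()), float(a.std(ddof=1)), a.size),
        GroupSummary(float(b.mean()), float(b.std(ddof=1)), b.size),
    )
    thr = bonferroni_thresholds(n_tests)
    return ComparisonResult(float(p), float(d), _tier(float(p), thr), effect_label(d))


def correlate_log_pdff_ac(pdff_percent, alpha0, n_tests: int = 1) -> CorrelationResult:
    """Pearson correlation of log(PDFF) against the attenuation slope.

    The p-value is the standard t-test on Pearson's r with n-2 degrees of
    freedom; the fitted log-linear relation log(PDFF) = slope * alpha0 +
    intercept is returned alongside R^2 = r^2.
    """
    pdff = np.asarray(pdff_percent, dtype=float)
    alpha = np.asarray(alpha0, dtype=float)
    if pdff.shape != alpha.shape or pdff.ndim != 1:
        raise ValueError("pdff and alpha0 must be matching 1-D sequences")
    if pdff.size < 3:
        raise ValueError("need at least 3 pairs")
    bad = np.nonzero(pdff <= 0)[0]
    if bad.size:
        raise ValueError(f"nonpositive PDFF at indices {bad.tolist()}: log undefined")
    y = np.log(pdff)
    if np.ptp(y) == 0 or np.ptp(alpha) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.linregress(alpha, y)
    return CorrelationResult(
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(pdff.size),
    )


# ---------------------------------------------------------------------------
# Printed-table regeneration
# ---------------------------------------------------------------------------


def _printed_tol(printed: str) -> float:
    """+-1 unit in the last printed digit."""
    printed = printed.strip()
    if "." in printed:
        return 10.0 ** -(len(printed.split(".")[1]))
    return 1.0


def load_printed_table(name: str) -> pd.DataFrame:
    """Load one of the shipped printed-value fixtures (table1..table4)."""
    with resources.files("qusatten.data").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh, dtype=str).apply(lambda c: c.str.strip())


def rebuild_validation_tables(fixtures: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Recompute every printed error / effect-size cell from printed inputs.

    Returns a long-format report with one row per recomputed cell:
    (table, row, quantity, printed, recomputed, tol, match, reproducible).
    Cells the source computed from unrounded data carry
    ``reproducible=False`` and are reported with their discrepancy rather
    than forced to match.
    """
    if fixtures is None:
        fixtures = {n: load_printed_table(n) for n in ("table1", "table2", "table3", "table4")}
    for name in ("table1", "table2", "table3", "table4"):
        if name not in fixtures or len(fixtures[name]) == 0:
            raise ValueError(f"missing or empty fixture: {name}")
    rows = []

    def add(table, row, quantity, printed, value, reproducible=True):
        tol = _printed_tol(printed)
        rows.append(
            {
                "table": table,
                "row": row,
                "quantity": quantity,
                "printed": float(printed),
                "recomputed": float(value),
                "tol": tol,
                "match": bool(abs(float(value) - float(printed)) <= tol + 1e-12),
                "reproducible": reproducible,
            }
        )

    t1 = fixtures["table1"]
    for _, r in t1.iterrows():
        m, s_m = float(r["measured_mean"]), float(r["measured_std"])
        ref, s_r = float(r["reference_mean"]), float(r["reference_std"])
        add("table1", r["region"], "abs_error", r["printed_abs_error"], absolute_error(m, ref))
        add("table1", r["region"], "rel_error", r["printed_rel_error"], relative_error(m, ref))
        d = abs(cohens_d(GroupSummary(m, s_m), GroupSummary(ref, s_r)))
        add("table1", r["region"], "cohens_d", r["printed_cohens_d"], d)

    t2 = fixtures["table2"]
    groups = {
        r["method"]: GroupSummary(float(r["mean"]), float(r["std"]), label=r["method"])
        for _, r in t2.iterrows()
        if r["method"] in ("pwi", "sdm", "sldm")
    }
    for _, r in t2.iterrows():
        if "_vs_" not in r["method"]:
            continue
        a, b = r["method"].split("_vs_")
        d = abs(cohens_d(groups[a], groups[b]))
        add("table2", r["method"], "cohens_d", r["printed_cohens_d"], d,
            reproducible=r.get("reproducible", "true") == "true")

    for name in ("table3", "table4"):
        t = fixtures[name]
        for _, r in t.iterrows():
            m = float(r["measured_mean"])
            lit = float(r["literature_mean"])
            add(name, r["organ"], "rel_error", r["printed_rel_error"], relative_error(m, lit),
                reproducible=r.get("reproducible", "true") == "true")

    report = pd.DataFrame(rows)
    return report
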