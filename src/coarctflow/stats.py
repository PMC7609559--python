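"""Cohort statistics: normality-routed paired tests and summary tables.

Rest-vs-exercise differences are tested per variable with a paired design:
the Shapiro-Wilk test on the paired differences decides between the paired
t-test (normal) and the Wilcoxon signed-rank test (non-normal), mirroring
common practice in clinical hemodynamics studies. Percent change is the
mean of the per-patient relative changes (the ratio-of-means variant is
reported alongside for transparency). Pressure gradients are additionally
classified against the 20 mmHg interventional threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import stats as sps

from .metrics import cardiac_index, stroke_volume_index
from .records import CohortTable


@dataclass
class PairedComparison:
    variable: str
    rest: np.ndarray
    exercise: np.ndarray
    mean_rest: float = 0.0
    sd_rest: float = 0.0
    mean_ex: float = 0.0
    sd_ex: float = 0.0
    normality_p: float = float("nan")
    test: str = ""              # "paired t" | "wilcoxon" | "degenerate"
    p_value: float = float("nan")
    pct_change: float = float("nan")        # mean of per-patient changes, %
    pct_change_of_means: float = float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rest"] = list(map(float, self.rest))
        d["exercise"] = list(map(float, self.exercise))
        return d


def wilcoxon_signed_rank(diff: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 (when free of rank ties), otherwise the normal approximation
    with continuity correction.
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    ties = len(np.unique(ranks)) != len(ranks)
    if d.size <= 25 and not ties:
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method="exact")
    else:
        res = sps.wilcoxon(d, zero_method="wilcox", correction=True,
                           alternative="two-sided", method="approx")
    return float(res.pvalue)


def paired_compare(rest, exercise, variable: str = "", alpha: float = 0.05
                   ) -> PairedComparison:
    """Compare paired rest/exercise values.

    Shapiro-Wilk on the paired differences routes to the paired t-test
    (p >= alpha) or the Wilcoxon signed-rank test (p < alpha). All-zero
    differences yield a degenerate comparison with p = 1.
    """
    rest = np.asarray(rest, dtype=float)
    exercise = np.asarray(exercise, dtype=float)
    if rest.shape != exercise.shape:
        raise ValueError(f"length mismatch: {rest.shape} vs {exercise.shape}")
    if rest.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = exercise - rest
    out = PairedComparison(
        variable=variable, rest=rest, exercise=exercise,
        mean_rest=float(rest.mean()), sd_rest=float(rest.std(ddof=1)),
        mean_ex=float(exercise.mean()), sd_ex=float(exercise.std(ddof=1)),
    )
    if np.all(rest != 0.0):
        out.pct_change = float((100.0 * diff / rest).mean())
    if rest.mean() != 0.0:
        out.pct_change_of_means = float(100.0 * diff.mean() / rest.mean())
    if np.all(diff == 0.0):
        out.test = "degenerate"
        out.p_value = 1.0
        out.pct_change = 0.0
        return out
    if rest.size < 3:
        raise ValueError("need at least 3 pairs for testing")
    # Shapiro-Wilk degenerates if the differences are all equal
    if np.ptp(diff) == 0.0:
        out.normality_p = 0.0
    else:
        out.normality_p = float(sps.shapiro(diff).pvalue)
    if out.normality_p >= alpha:
        out.test = "paired t"
        out.p_value = float(sps.ttest_rel(exercise, rest).pvalue)
    else:
        out.test = "wilcoxon"
        out.p_value = wilcoxon_signed_rank(diff)
    return out


def percent_change(rest, exercise) -> float:
    """Mean of per-patient relative changes, %."""
    rest = np.asarray(rest, dtype=float)
    exercise = np.asarray(exercise, dtype=float)
    zero = np.flatnonzero(rest == 0.0)
    if zero.size:
        raise ValueError(f"rest value is zero at index {zero[0]}; relative change undefined")
    return float((100.0 * (exercise - rest) / rest).mean())


def classify_threshold(pg_rest, pg_ex, threshold: float = 20.0) -> dict[str, int]:
    """Classify paired pressure gradients against an intervention threshold.

    "above" is strict (> threshold). ``crossed`` counts rest <= t < exercise;
    reverse crossings (above at rest, below during exercise) are counted
    separately.
    """
    pg_rest = np.asarray(pg_rest, dtype=float)
    pg_ex = np.asarray(pg_ex, dtype=float)
    if pg_rest.shape != pg_ex.shape:
        raise ValueError("paired arrays required")
    above_r = pg_rest > threshold
    above_e = pg_ex > threshold
    return {
        "both_above": int(np.sum(above_r & above_e)),
        "both_below": int(np.sum(~above_r & ~above_e)),
        "crossed": int(np.sum(~above_r & above_e)),
        "reverse_crossed": int(np.sum(above_r & ~above_e)),
    }


#: variables summarized for a full cohort; (name, rest column, exercise column)
SUMMARY_VARIABLES = [
    ("heart_rate", "hr_rest", "hr_ex"),
    ("stroke_volume_index", None, None),     # computed via indices
    ("cardiac_index", None, None),
    ("q_ascending", "q_asc_rest", "q_asc_ex"),
    ("q_descending", "q_desc_rest", "q_desc_ex"),
    ("sbp", "sbp_rest", "sbp_ex"),
    ("dbp", "dbp_rest", "dbp_ex"),
    ("pressure_gradient", "pg_rest", "pg_ex"),
    ("wss", "wss_rest", "wss_ex"),
    ("sfd_ascending", "sfd_asc_rest", "sfd_asc_ex"),
    ("sfd_descending", "sfd_desc_rest", "sfd_desc_ex"),
    ("nfd_ascending", "nfd_asc_rest", "nfd_asc_ex"),
    ("nfd_descending", "nfd_desc_rest", "nfd_desc_ex"),
]


@dataclass
class CohortSummary:
    n: int
    comparisons: dict[str, PairedComparison] = field(default_factory=dict)
    threshold_counts: dict[str, int] = field(default_factory=dict)
    threshold: float = 20.0

    def to_report(self) -> dict:
        rep = {
            "n": self.n,
            "threshold_mmHg": self.threshold,
            "threshold_counts": self.threshold_counts,
            "variables": {},
        }
        for name, c in self.comparisons.items():
            rep["variables"][name] = {
                "mean_rest": c.mean_rest, "sd_rest": c.sd_rest,
                "mean_ex": c.mean_ex, "sd_ex": c.sd_ex,
                "test": c.test, "p": c.p_value,
                "pct_change": c.pct_change,
                "pct_change_of_means": c.pct_change_of_means,
            }
        return rep


def summarize_cohort(cohort: CohortTable, alpha: float = 0.05,
                     threshold: float = 20.0) -> CohortSummary:
    """Cohort-level rest-vs-exercise summary over all study variables.

    Computes mean +/- SD at rest and exercise, the normality-routed paired
    test, percent changes, and the pressure-gradient threshold counts. The
    clinical indices (SVI, CI) are derived per patient before averaging.
    Raises if a needed column is entirely missing.
    """
    patients = cohort.patients
    n = len(patients)
    if n < 3:
        raise ValueError("need at least 3 patients")
    missing_metrics = [p.id for p in patients if p.id not in cohort.metrics]
    if missing_metrics:
        raise ValueError(f"patients without metric records: {missing_metrics}")
    summary = CohortSummary(n=n, threshold=threshold)
    for name, rcol, ecol in SUMMARY_VARIABLES:
        if name == "stroke_volume_index":
            rest = [stroke_volume_index(p.sv_rest, p.bsa) for p in patients]
            ex = [stroke_volume_index(p.sv_ex, p.bsa) for p in patients]
        elif name == "cardiac_index":
            rest = [cardiac_index(p.hr_rest, p.sv_rest, p.bsa) for p in patients]
            ex = [cardiac_index(p.hr_ex, p.sv_ex, p.bsa) for p in patients]
        elif rcol.startswith(("pg", "wss", "sfd", "nfd")):
            rest = [getattr(cohort.metrics[p.id], rcol) for p in patients]
            ex = [getattr(cohort.metrics[p.id], ecol) for p in patients]
        else:
            rest = [getattr(p, rcol) for p in patients]
            ex = [getattr(p, ecol) for p in patients]
        rest = np.asarray(rest, dtype=float)
        ex = np.asarray(ex, dtype=float)
        if np.isnan(rest).any() or np.isnan(ex).any():
            raise ValueError(f"variable {name!r} has missing values")
        summary.comparisons[name] = paired_compare(rest, ex, variable=name, alpha=alpha)
    pgr = np.array([cohort.metrics[p.id].pg_rest for p in patients])
    pge = np.array([cohort.metrics[p.id].pg_ex for p in patients])
    summary.threshold_counts = classify_threshold(pgr, pge, threshold)
    return summary
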