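"""Method-comparison statistics: Bland-Altman agreement and repeatability.

Two instruments measure the same quantity (RMS sway, mm) on the same trials;
the question is not correlation but *agreement*: how big is the systematic
difference (bias) and how far apart can single paired readings be expected
to lie (limits of agreement)?

Per condition, for paired differences d = A - B over n records:

    bias      = mean(d)
    sd_diff   = sample SD of d            (1/(n-1))
    LOA       = bias +/- 1.96 * sd_diff
    CI(bias)  = bias +/- t_{0.975,n-1} * sd_diff / sqrt(n)
    CI(LOA)   = LOA  +/- t_{0.975,n-1} * sd_diff * sqrt(3/n)

The LOA confidence intervals use the classical variance approximation
var(LOA) ~= 3 * sd^2 / n with a t quantile.  Within-method precision is the
repeatability coefficient CR = 1.96 * sqrt(2) * SD_w, where the
within-subject SD comes from paired repeats:

    SD_w = sqrt( sum_j (x_j1 - x_j2)^2 / (2 m) )    over m subjects.

CR bounds the absolute difference between two repeated measurements of the
same subject with 95% coverage, assuming normal within-subject error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .skeleton_io import ExclusionReason, ValidationVerdict

__all__ = [
    "PairedSwaySet",
    "AgreementEntry",
    "AgreementReport",
    "RepeatabilityEntry",
    "TestResult",
    "bland_altman",
    "loa_from_stats",
    "repeatability",
    "cr_from_sd",
    "one_sample_test",
    "normality_screen",
    "wilcoxon_test",
    "filter_counts",
    "agreement_report",
    "round_half_away",
]

LOA_MULTIPLIER = 1.96
#: CR / within-subject SD, i.e. 1.96 * sqrt(2).
CR_FACTOR = LOA_MULTIPLIER * math.sqrt(2.0)

CONDITIONS = tuple("abcdef")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention of the report tables)."""
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(abs(float(x))).quantize(q, rounding=ROUND_HALF_UP)) * (1 if x >= 0 else -1)


@dataclass
class PairedSwaySet:
    """Aligned per-trial sway from two methods, in wide form.

    ``records`` columns: trial_id, subject, condition, repeat, sway_a_mm,
    sway_b_mm.  Method A is conventionally the force-plate comparator and
    method B the camera pipeline, so bias = A - B matches the report tables.
    """

    records: pd.DataFrame
    method_a: str = "pendulum"
    method_b: str = "three_joint"

    REQUIRED = ("trial_id", "subject", "condition", "repeat", "sway_a_mm", "sway_b_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"paired records missing columns {missing}")
        bad = set(self.records["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"conditions outside a..f: {sorted(bad)}")
        if self.records[["sway_a_mm", "sway_b_mm"]].isna().any().any():
            raise ValueError("both sway values must be present for every record")

    @classmethod
    def from_long(
        cls, long: pd.DataFrame, method_a: str = "pendulum", method_b: str = "three_joint"
    ) -> "PairedSwaySet":
        """Pivot a long table (trial_id, subject, condition, repeat, method,
        sway_rms_mm) into paired wide form; unmatched trials are an error."""
        need = {"trial_id", "subject", "condition", "repeat", "method", "sway_rms_mm"}
        missing = need - set(long.columns)
        if missing:
            raise ValueError(f"long table missing columns {sorted(missing)}")
        sub = long[long["method"].isin([method_a, method_b])]
        wide = sub.pivot_table(
            index=["trial_id", "subject", "condition", "repeat"],
            columns="method",
            values="sway_rms_mm",
            aggfunc="first",
        )
        orphans = wide.index[wide.isna().any(axis=1)].get_level_values("trial_id").tolist()
        if orphans:
            raise ValueError(f"unpaired trials (one method missing): {orphans[:10]}")
        wide = wide.reset_index()
        return cls(
            records=pd.DataFrame({
                "trial_id": wide["trial_id"],
                "subject": wide["subject"],
                "condition": wide["condition"],
                "repeat": wide["repeat"],
                "sway_a_mm": wide[method_a],
                "sway_b_mm": wide[method_b],
            }),
            method_a=method_a,
            method_b=method_b,
        )

    def select(self, condition: str, average_repeats: bool = False) -> pd.DataFrame:
        sub = self.records[self.records["condition"] == condition]
        if average_repeats:
            sub = (
                sub.groupby("subject", as_index=False)[["sway_a_mm", "sway_b_mm"]]
                .mean()
                .assign(condition=condition)
            )
        return sub

    def swapped(self) -> "PairedSwaySet":
        rec = self.records.rename(
            columns={"sway_a_mm": "sway_b_mm", "sway_b_mm": "sway_a_mm"}
        )
        return PairedSwaySet(rec, method_a=self.method_b, method_b=self.method_a)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class AgreementEntry:
    """One condition's row of the agreement analysis (all lengths in mm)."""

    condition: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    t: float
    p_t: float
    p_wilcoxon: float | None = None
    dagostino_p: float | None = None
    shapiro_p: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("agreement needs n >= 2")
        if not (self.loa_lower - 1e-12 <= self.bias <= self.loa_upper + 1e-12):
            raise ValueError("LOA must contain the bias")

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form: 2 dp, half away from zero, like the report tables."""
        r = lambda v: round_half_away(v, ndigits) if v is not None else None
        return {
            "condition": self.condition,
            "n": self.n,
            "mean_a": r(self.mean_a),
            "sd_a": r(self.sd_a),
            "mean_b": r(self.mean_b),
            "sd_b": r(self.sd_b),
            "bias": r(self.bias),
            "sd_diff": r(self.sd_diff),
            "loa_lower": r(self.loa_lower),
            "loa_upper": r(self.loa_upper),
            "ci_bias": [r(self.ci_bias[0]), r(self.ci_bias[1])],
            "t": r(self.t),
            "p_t": float(self.p_t) if np.isfinite(self.p_t) else None,
            "p_wilcoxon": self.p_wilcoxon,
        }


@dataclass
class RepeatabilityEntry:
    """Within-method precision for one condition x method."""

    condition: str
    method: str
    n_subjects: int
    sd_within: float
    cr: float

    def __post_init__(self) -> None:
        if abs(self.cr - CR_FACTOR * self.sd_within) > 1e-9:
            raise ValueError("CR must equal 1.96*sqrt(2)*SD")


@dataclass
class AgreementReport:
    entries: list[AgreementEntry] = field(default_factory=list)
    repeatability: list[RepeatabilityEntry] = field(default_factory=list)
    method_a: str = "pendulum"
    method_b: str = "three_joint"

    def entry(self, condition: str) -> AgreementEntry:
        for e in self.entries:
            if e.condition == condition:
                return e
        raise KeyError(condition)

    def to_dict(self, ndigits: int = 2) -> dict:
        return {
            "method_a": self.method_a,
            "method_b": self.method_b,
            "conditions": [e.rounded(ndigits) for e in self.entries],
            "repeatability": [
                {
                    "condition": r.condition,
                    "method": r.method,
                    "n_subjects": r.n_subjects,
                    "sd_mm": round_half_away(r.sd_within, ndigits),
                    "cr_mm": round_half_away(r.cr, ndigits),
                }
                for r in self.repeatability
            ],
        }


# ---------------------------------------------------------------------------
# Core statistics
# ---------------------------------------------------------------------------

def loa_from_stats(bias: float, sd_diff: float) -> tuple[float, float]:
    """Limits of agreement from a bias and SD of differences."""
    half = LOA_MULTIPLIER * sd_diff
    return bias - half, bias + half


def bland_altman(
    pairs: PairedSwaySet, condition: str, average_repeats: bool = False
) -> AgreementEntry:
    """Agreement entry (bias, LOA, CIs, tests) for one condition.

    Uses every record by default — repeated measures enter individually, as
    in a straightforward single-level Bland-Altman analysis; set
    ``average_repeats`` to collapse repeats per subject first.
    """
    sub = pairs.select(condition, average_repeats)
    n = len(sub)
    if n < 2:
        raise ValueError(f"condition {condition!r}: need n >= 2 paired records, got {n}")
    a = sub["sway_a_mm"].to_numpy(dtype=float)
    b = sub["sway_b_mm"].to_numpy(dtype=float)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    degenerate = sd == 0.0
    lo, hi = loa_from_stats(bias, sd)
    tq = float(stats.t.ppf(0.975, n - 1))
    half_bias = tq * sd / math.sqrt(n)
    half_loa = tq * sd * math.sqrt(3.0 / n)
    ttest = one_sample_test(d)
    norm = normality_screen(d)
    wil = wilcoxon_test(d)
    return AgreementEntry(
        condition=condition,
        n=n,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        bias=bias,
        sd_diff=sd,
        loa_lower=lo,
        loa_upper=hi,
        ci_bias=(bias - half_bias, bias + half_bias),
        ci_loa_lower=(lo - half_loa, lo + half_loa),
        ci_loa_upper=(hi - half_loa, hi + half_loa),
        t=ttest.statistic,
        p_t=ttest.p,
        p_wilcoxon=None if wil is None else wil.p,
        dagostino_p=norm.get("dagostino_p"),
        shapiro_p=norm.get("shapiro_p"),
        degenerate=degenerate,
    )


def cr_from_sd(sd_within: float) -> float:
    """95% repeatability coefficient from a within-subject SD."""
    return CR_FACTOR * sd_within


def repeatability(pairs: PairedSwaySet, condition: str, method: str) -> RepeatabilityEntry:
    """Within-subject SD and repeatability coefficient from paired repeats.

    ``method`` selects which column ('a' side or 'b' side, by method name)
    to assess.  Subjects contribute their first two repeats; subjects with a
    single repeat are skipped.
    """
    if method == pairs.method_a:
        col = "sway_a_mm"
    elif method == pairs.method_b:
        col = "sway_b_mm"
    else:
        raise ValueError(f"unknown method {method!r} (have {pairs.method_a}, {pairs.method_b})")
    sub = pairs.records[pairs.records["condition"] == condition]
    sub = sub.sort_values("repeat")
    diffs = []
    for _, grp in sub.groupby("subject"):
        if len(grp) >= 2:
            x = grp[col].to_numpy(dtype=float)
            diffs.append(x[0] - x[1])
    if not diffs:
        raise ValueError(f"condition {condition!r}: no subject has repeated measures")
    diffs = np.asarray(diffs)
    sd = float(np.sqrt(np.sum(diffs**2) / (2 * len(diffs))))
    return RepeatabilityEntry(
        condition=condition,
        method=method,
        n_subjects=len(diffs),
        sd_within=sd,
        cr=cr_from_sd(sd),
    )


def one_sample_test(diffs: np.ndarray, mu: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test of mean(diffs) = mu.

    A zero-variance sample has no defined t statistic; the result is flagged
    degenerate with NaN statistic and p.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValueError("one-sample test needs n >= 2")
    if diffs.std(ddof=1) == 0.0:
        return TestResult(float("nan"), float("nan"), n, degenerate=True)
    res = stats.ttest_1samp(diffs, popmean=mu)
    return TestResult(float(res.statistic), float(res.pvalue), n)


def wilcoxon_test(diffs: np.ndarray) -> TestResult | None:
    """Wilcoxon signed-rank on the paired differences (nonparametric check).

    Returns None when the test is undefined (all differences zero).
    """
    diffs = np.asarray(diffs, dtype=float)
    if np.all(diffs == 0):
        return None
    res = stats.wilcoxon(diffs)
    return TestResult(float(res.statistic), float(res.pvalue), len(diffs))


def normality_screen(diffs: np.ndarray, min_n: int = 8) -> dict:
    """Omnibus (D'Agostino-Pearson) and Shapiro-Wilk normality p-values.

    Below ``min_n`` samples the omnibus test is invalid; both tests are then
    skipped and the result flagged.
    """
    diffs = np.asarray(diffs, dtype=float)
    if len(diffs) < min_n or np.std(diffs) == 0.0:
        return {"dagostino_p": None, "shapiro_p": None, "skipped": True}
    return {
        "dagostino_p": float(stats.normaltest(diffs).pvalue),
        "shapiro_p": float(stats.shapiro(diffs).pvalue),
        "skipped": False,
    }


def filter_counts(
    verdicts: Iterable[ValidationVerdict], initial_count: int | None = None
) -> dict:
    """Exclusion bookkeeping: how many records survive screening.

    Returns the remaining count plus a per-reason breakdown.  When
    ``initial_count`` is omitted it defaults to the number of verdicts.
    """
    verdicts = list(verdicts)
    if initial_count is None:
        initial_count = len(verdicts)
    by_reason: dict[str, int] = {}
    excluded = 0
    for v in verdicts:
        if not v.ok:
            excluded += 1
            by_reason[v.reason.value] = by_reason.get(v.reason.value, 0) + 1
    return {
        "initial": initial_count,
        "excluded": excluded,
        "remaining": initial_count - excluded,
        "by_reason": by_reason,
    }


def agreement_report(
    pairs: PairedSwaySet,
    conditions: Sequence[str] = CONDITIONS,
    average_repeats: bool = False,
) -> AgreementReport:
    """Full analysis: per-condition agreement and per-method repeatability."""
    report = AgreementReport(method_a=pairs.method_a, method_b=pairs.method_b)
    for c in conditions:
        if (pairs.records["condition"] == c).sum() >= 2:
            report.entries.append(bland_altman(pairs, c, average_repeats))
            for method in (pairs.method_a, pairs.method_b):
                try:
                    report.repeatability.append(repeatability(pairs, c, method))
                except ValueError:
                    pass  # no repeated measures for this condition
    return report
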