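"""Chart-review endpoint statistics.

RECIST response classification from lesion-sum measurements, objective
response / disease control rates per arm, the test-selection rule (Fisher's
exact when any cell is below 5, otherwise Pearson chi-square without
continuity correction), Mann-Whitney U comparisons, CTCAE-style hypertension
event flagging from systolic blood-pressure series, and the before/after SBP
change summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from pvscreen.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "CohortPatient",
    "ResponseSummary",
    "ResponseComparison",
    "SbpSummary",
    "classify_recist",
    "compare_categorical",
    "flag_hypertension_event",
    "mann_whitney_u",
    "read_patient_table",
    "response_rates",
    "sbp_change_summary",
    "write_patient_table",
]

RESPONSES = ("CR", "PR", "SD", "PD")

#: On-treatment SBP rise (mmHg) that counts as a hypertension event.
SBP_DELTA_THRESHOLD = 20.0
#: Absolute on-treatment SBP (mmHg) that counts as a hypertension event.
SBP_ABSOLUTE_THRESHOLD = 150.0


@dataclass(frozen=True)
class CohortPatient:
    """One chart-review record.

    ``sbp_series`` holds (cycle index, systolic mmHg) pairs; cycle 0 is the
    pre-treatment baseline measurement and cycles >= 1 are on-treatment.
    """

    patient_id: str
    age_years: float
    sex: Literal["M", "F"]
    stage: Literal["I", "II", "IIIa", "IV"]
    ps: int
    regimen: Literal["XELOX", "mFOLFOX6"]
    ppi_user: bool
    antihypertensive_baseline: bool
    response: Literal["CR", "PR", "SD", "PD"]
    sbp_series: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise DataError(f"unknown response {self.response!r}")
        for _, sbp in self.sbp_series:
            if not 60.0 <= sbp <= 260.0:
                raise DataError(f"non-physiologic SBP {sbp} for {self.patient_id}")

    def baseline_sbp(self) -> float | None:
        pre = [s for cycle, s in self.sbp_series if cycle <= 0]
        return pre[-1] if pre else None

    def on_treatment_sbp(self) -> list[float]:
        return [s for cycle, s in self.sbp_series if cycle >= 1]


@dataclass(frozen=True)
class ResponseSummary:
    """Per-arm response counts and rates."""

    arm: str
    n: int
    counts: dict[str, int]  # CR/PR/SD/PD
    orr: float  # (CR+PR)/n
    dcr: float  # (CR+PR+SD)/n


@dataclass(frozen=True)
class ResponseComparison:
    """Response summaries for two arms plus between-arm tests."""

    arms: tuple[ResponseSummary, ResponseSummary]
    overall: ResponseSummary
    orr_test: str
    orr_p: float
    dcr_test: str
    dcr_p: float


def classify_recist(
    baseline_sum_mm: float, nadir_sum_mm: float, current_sum_mm: float
) -> Literal["CR", "PR", "SD", "PD"]:
    """RECIST 1.0 class from sums of lesion longest diameters.

    CR: current sum 0.  PD: >= 20% increase over the nadir (inclusive),
    taking precedence over PR.  PR: >= 30% decrease from baseline
    (inclusive).  Otherwise SD.
    """
    if baseline_sum_mm <= 0:
        raise DataError("baseline lesion sum must be > 0")
    if nadir_sum_mm < 0 or current_sum_mm < 0:
        raise DataError("lesion sums must be >= 0")
    if current_sum_mm == 0.0:
        return "CR"
    if nadir_sum_mm == 0.0 or current_sum_mm >= 1.2 * nadir_sum_mm:
        return "PD"
    if current_sum_mm <= 0.7 * baseline_sum_mm:
        return "PR"
    return "SD"


def response_rates(
    patients: Sequence[CohortPatient], arm_field: str = "ppi_user"
) -> ResponseComparison:
    """ORR/DCR per arm and overall, with between-arm tests.

    Arms are the two values of ``arm_field`` (default: PPI users versus
    non-users).  The ORR test compares responders (CR+PR) against
    non-responders across arms; the DCR test does the same for disease
    control (CR+PR+SD); both go through :func:`compare_categorical`.
    """
    if not patients:
        raise DataError("empty cohort")
    values = sorted({getattr(p, arm_field) for p in patients})
    if len(values) != 2:
        raise DataError(f"arm field {arm_field!r} must take exactly 2 values, got {values}")

    def summarize(arm_label: str, members: Sequence[CohortPatient]) -> ResponseSummary:
        if not members:
            raise DataError(f"empty arm {arm_label!r}")
        counts = {r: sum(1 for p in members if p.response == r) for r in RESPONSES}
        n = len(members)
        orr = (counts["CR"] + counts["PR"]) / n
        dcr = (counts["CR"] + counts["PR"] + counts["SD"]) / n
        return ResponseSummary(arm=arm_label, n=n, counts=counts, orr=orr, dcr=dcr)

    groups = [(str(v), [p for p in patients if getattr(p, arm_field) == v]) for v in values]
    summaries = tuple(summarize(label, members) for label, members in groups)
    overall = summarize("overall", list(patients))

    def test(rate_counts: list[list[int]]) -> tuple[str, float]:
        return compare_categorical(rate_counts)

    s0, s1 = summaries
    responders = [
        [s0.counts["CR"] + s0.counts["PR"], s0.n - s0.counts["CR"] - s0.counts["PR"]],
        [s1.counts["CR"] + s1.counts["PR"], s1.n - s1.counts["CR"] - s1.counts["PR"]],
    ]
    controlled = [
        [s0.n - s0.counts["PD"], s0.counts["PD"]],
        [s1.n - s1.counts["PD"], s1.counts["PD"]],
    ]
    orr_test, orr_p = test(responders)
    dcr_test, dcr_p = test(controlled)
    return ResponseComparison(
        arms=summaries,
        overall=overall,
        orr_test=orr_test,
        orr_p=orr_p,
        dcr_test=dcr_test,
        dcr_p=dcr_p,
    )


def _fisher_rx2(counts: np.ndarray) -> float:
    # Freeman-Halton exact test for an r x 2 table, exact integer
    # arithmetic: with row margins R_i and first-column margin C1, each
    # achievable table has probability prod_i C(R_i, k_i) / C(N, C1); all
    # numerators share the denominator, so "as or more extreme" reduces to
    # integer comparison.
    rows = counts.shape[0]
    row_sums = counts.sum(axis=1)
    c1 = int(counts[:, 0].sum())
    obs = 1
    for i in range(rows):
        obs *= math.comb(int(row_sums[i]), int(counts[i, 0]))

    total = 0
    kept = 0

    def recurse(i: int, remaining: int, weight: int) -> None:
        nonlocal total, kept
        if i == rows - 1:
            if remaining <= row_sums[i]:
                w = weight * math.comb(int(row_sums[i]), remaining)
                total += w
                if w <= obs:
                    kept += w
            return
        tail_capacity = int(row_sums[i + 1 :].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(row_sums[i]), remaining)
        for k in range(lo, hi + 1):
            recurse(i + 1, remaining - k, weight * math.comb(int(row_sums[i]), k))

    recurse(0, c1, 1)
    return kept / total


def compare_categorical(
    x_counts: Sequence[Sequence[int]], rule: Literal["auto", "fisher", "chi2"] = "auto"
) -> tuple[str, float]:
    """Compare an r x 2 count table between arms, choosing the test by rule.

    ``auto`` uses Fisher's exact test when any cell is below 5, otherwise
    Pearson's chi-square without continuity correction.  Fisher's exact test
    generalizes to r x 2 via the Freeman-Halton extension.  Returns
    ``(test_name, p_value)``.
    """
    counts = np.asarray(x_counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != 2 or counts.shape[0] < 2:
        raise DataError(f"expected an r x 2 table with r >= 2, got shape {counts.shape}")
    if (counts < 0).any():
        raise DataError("negative cell count")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise DataError("degenerate table: all-zero row or column")

    if rule == "auto":
        rule = "fisher" if counts.min() < 5 else "chi2"
    if rule == "fisher":
        return "fisher", _fisher_rx2(counts)
    if rule == "chi2":
        stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
        return "chi2", float(p)
    raise ConfigError(f"unknown rule {rule!r}")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with midrank ties; two-sided p.

    The p-value is exact (full enumeration of rank assignments) when
    ``len(x) + len(y) <= 20`` and there are no ties across the pooled
    sample; otherwise the normal approximation with tie correction and
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def flag_hypertension_event(patient: CohortPatient, med_change: bool = False) -> bool:
    """CTCAE-style hypertension event flag for one patient.

    True iff the maximum on-treatment SBP rose at least 20 mmHg over the
    baseline, or any on-treatment SBP reached 150 mmHg, or antihypertensive
    therapy was started/escalated (``med_change``).
    """
    baseline = patient.baseline_sbp()
    if baseline is None:
        raise DataError(f"patient {patient.patient_id} has no baseline SBP")
    on_treatment = patient.on_treatment_sbp()
    if not on_treatment:
        raise DataError(f"patient {patient.patient_id} has no on-treatment SBP")
    peak = max(on_treatment)
    return (
        peak - baseline >= SBP_DELTA_THRESHOLD
        or peak >= SBP_ABSOLUTE_THRESHOLD
        or med_change
    )


@dataclass(frozen=True)
class SbpSummary:
    """Per-arm before/after SBP means and the between-arm delta comparison."""

    arms: dict[str, dict[str, float]]  # arm -> before/after/delta mean & sd
    p_between: float
    n_excluded: int


def sbp_change_summary(
    patients: Iterable[CohortPatient], arm_field: str = "ppi_user"
) -> SbpSummary:
    """Mean (SD) SBP before and after treatment per arm, delta comparison.

    "Before" is the baseline measurement; "after" is the mean of a patient's
    on-treatment measurements.  Patients lacking either side are excluded
    with a warning.  Arm deltas are compared with :func:`mann_whitney_u`.
    """
    per_arm: dict[str, dict[str, list[float]]] = {}
    n_excluded = 0
    for p in patients:
        baseline = p.baseline_sbp()
        on_treatment = p.on_treatment_sbp()
        if baseline is None or not on_treatment:
            logger.warning("patient %s lacks paired SBP; excluded", p.patient_id)
            n_excluded += 1
            continue
        after = float(np.mean(on_treatment))
        arm = str(getattr(p, arm_field))
        bucket = per_arm.setdefault(arm, {"before": [], "after": [], "delta": []})
        bucket["before"].append(baseline)
        bucket["after"].append(after)
        bucket["delta"].append(after - baseline)

    if len(per_arm) != 2:
        raise DataError(f"expected 2 arms, got {sorted(per_arm)}")

    def msd(vals: list[float]) -> tuple[float, float]:
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
        return float(arr.mean()), sd

    arms_out = {}
    for arm, bucket in sorted(per_arm.items()):
        stats_out = {}
        for key in ("before", "after", "delta"):
            mean, sd = msd(bucket[key])
            stats_out[f"{key}_mean"] = mean
            stats_out[f"{key}_sd"] = sd
        stats_out["n"] = float(len(bucket["delta"]))
        arms_out[arm] = stats_out

    deltas = [per_arm[a]["delta"] for a in sorted(per_arm)]
    if all(len(d) > 0 for d in deltas):
        _, p = mann_whitney_u(deltas[0], deltas[1])
    else:  # pragma: no cover - guarded by the 2-arm check
        p = math.nan
    return SbpSummary(arms=arms_out, p_between=p, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# patient table I/O

_PATIENT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "stage",
    "ps",
    "regimen",
    "ppi_user",
    "antihypertensive_baseline",
    "response",
    "sbp_series",
]


def write_patient_table(patients: Iterable[CohortPatient], path: str | Path) -> None:
    """Write patients as TSV; SBP series encoded ``cycle:value|cycle:value``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PATIENT_COLUMNS) + "\n")
        for p in patients:
            series = "|".join(f"{cycle}:{sbp!r}" for cycle, sbp in p.sbp_series)
            fh.write(
                f"{p.patient_id}\t{p.age_years!r}\t{p.sex}\t{p.stage}\t{p.ps}\t"
                f"{p.regimen}\t{int(p.ppi_user)}\t{int(p.antihypertensive_baseline)}\t"
                f"{p.response}\t{series}\n"
            )


def read_patient_table(path: str | Path) -> list[CohortPatient]:
    """Read a patient TSV written by :func:`write_patient_table`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"patient table not found: {path}")
    patients = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PATIENT_COLUMNS:
            raise DataError(f"unexpected patient-table header in {path}")
        for lineno, line in enumerate(fh, 2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_PATIENT_COLUMNS):
                raise DataError(f"{path}:{lineno}: expected {len(_PATIENT_COLUMNS)} fields")
            series = tuple(
                (int(part.split(":")[0]), float(part.split(":")[1]))
                for part in f[9].split("|")
                if part
            )
            patients.append(
                CohortPatient(
                    patient_id=f[0],
                    age_years=float(f[1]),
                    sex=f[2],
                    stage=f[3],
                    ps=int(f[4]),
                    regimen=f[5],
                    ppi_user=bool(int(f[6])),
                    antihypertensive_baseline=bool(int(f[7])),
                    response=f[8],
                    sbp_series=series,
                )
            )
    return patients
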