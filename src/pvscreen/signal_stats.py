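"""Reporting-odds-ratio disproportionality statistics.

Every analysis reduces to a 2x2 contingency table over deduplicated reports:

=============  ==========  ============
               event       no event
=============  ==========  ============
exposed        a           b
not exposed    c           d
=============  ==========  ============

ROR = (a/b)/(c/d) with a log-scale Wald confidence interval
exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)); a pair is a positive signal
when the lower CI limit exceeds 1 and an inverse signal when the upper limit
is below 1.  For the conventional 95% interval z is exactly 1.96; other
levels use the precise normal quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from scipy import stats

from pvscreen.errors import DataError
from pvscreen.faers_io import CaseReport, EventTermSet, has_event

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "StratumSpec",
    "AgeBin",
    "build_contingency",
    "classify_signal",
    "fisher_exact",
    "format_signal_table",
    "ror",
    "round_half_up",
    "stratified_ror",
]

#: n = a+b+c+d at or below which Fisher's test runs in exact integer
#: arithmetic; larger tables use scipy's floating-point implementation.
_EXACT_FISHER_N = 1000


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts behind every ROR and test."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise DataError(f"cell {name} must be an integer, got {v!r}")
            if v < 0:
                raise DataError(f"cell {name} must be >= 0, got {v}")
        if self.n == 0:
            raise DataError("contingency table is empty (a+b+c+d == 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate, CI, p-value and signal class for one pair."""

    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    alpha: float
    p_value: float
    corrected: bool
    signal_class: Literal["positive", "inverse", "none"]
    label: str | None = None


@dataclass(frozen=True)
class AgeBin:
    """One age stratum: ``low <= age < high`` except the last bin of a spec,
    which is closed on both sides (``low <= age <= high``)."""

    label: str
    low: float
    high: float


def _default_age_bins() -> tuple[AgeBin, ...]:
    return (
        AgeBin("<40", 0.0, 40.0),
        AgeBin("40-49", 40.0, 50.0),
        AgeBin("50-59", 50.0, 60.0),
        AgeBin("60-69", 60.0, 70.0),
        AgeBin("70-100", 70.0, 100.0),
    )


@dataclass(frozen=True)
class StratumSpec:
    """Stratification request: by sex, or by age over ordered bins."""

    variable: Literal["sex", "age"]
    bins: tuple[AgeBin, ...] = field(default_factory=_default_age_bins)

    def __post_init__(self) -> None:
        if self.variable not in ("sex", "age"):
            raise DataError(f"unknown stratifier {self.variable!r}")
        if self.variable == "age":
            for prev, nxt in zip(self.bins, self.bins[1:]):
                if prev.high > nxt.low:
                    raise DataError(f"overlapping age bins {prev.label!r}/{nxt.label!r}")


def build_contingency(
    reports: Iterable[CaseReport],
    exposure_drug: str,
    event_terms: EventTermSet,
) -> ContingencyTable:
    """Cross-classify reports by exposure drug and event into a 2x2 table.

    ``exposure_drug`` is matched exactly against the canonical drug names of
    each report.  An empty report list yields the degenerate (0,0,0,0) table
    object (allowed only here).
    """
    a = b = c = d = 0
    terms = event_terms.terms
    for r in reports:
        exposed = exposure_drug in r.drugs
        event = bool(r.reactions & terms)
        if exposed:
            if event:
                a += 1
            else:
                b += 1
        elif event:
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        table = object.__new__(ContingencyTable)
        for name, v in zip("abcd", (0, 0, 0, 0)):
            object.__setattr__(table, name, v)
        return table
    return ContingencyTable(a, b, c, d)


def _fisher_exact_smalln(a: int, b: int, c: int, d: int) -> float:
    # Exact two-sided p at fixed margins: with row margins r1 = a+b,
    # r2 = c+d and column margin m = a+c, every achievable table has
    # probability C(r1, k) * C(r2, m - k) / C(n, m); all terms share the
    # denominator, so tables "as or more extreme" are found by integer
    # comparison of numerators -- no floating-point ties.
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(m, r1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    kept = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, m - k)
        total += w
        if w <= obs:
            kept += w
    return kept / total


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value.

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric probabilities no larger than that of the observed table.
    Tables with n <= 1000 are evaluated in exact integer arithmetic; larger
    tables fall back to :func:`scipy.stats.fisher_exact`.
    """
    a, b, c, d = table.cells()
    if table.n == 0:
        raise DataError("cannot test an empty table")
    if table.n <= _EXACT_FISHER_N:
        return _fisher_exact_smalln(a, b, c, d)
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def classify_signal(ci_low: float, ci_high: float) -> Literal["positive", "inverse", "none"]:
    """Signal class from the CI-versus-1 rule."""
    if ci_low > 1.0:
        return "positive"
    if ci_high < 1.0:
        return "inverse"
    return "none"


def ror(
    table: ContingencyTable,
    alpha: float = 0.05,
    zero_correction: Literal["haldane", "error"] = "haldane",
    with_p: bool = True,
    label: str | None = None,
) -> SignalResult:
    """ROR point estimate with log-scale Wald CI and Fisher p-value.

    A zero cell under policy ``"haldane"`` adds 0.5 to all four cells
    (flagged via ``corrected``); policy ``"error"`` raises.  The p-value is
    always computed on the uncorrected counts.  ``with_p=False`` skips the
    (comparatively expensive) exact test and reports NaN, which simulation
    loops use when only the CI matters.
    """
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha must be in (0,1), got {alpha}")
    a, b, c, d = (float(x) for x in table.cells())
    corrected = False
    if min(a, b, c, d) == 0.0:
        if zero_correction == "error":
            raise DataError(f"zero cell in table {table.cells()}")
        if zero_correction != "haldane":
            raise DataError(f"unknown zero_correction {zero_correction!r}")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True

    point = (a / b) / (c / d)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    # 1.96 exactly at the conventional level, precise quantile otherwise
    z = 1.96 if alpha == 0.05 else float(stats.norm.ppf(1.0 - alpha / 2.0))
    log_r = math.log(point)
    ci_low = math.exp(log_r - z * se)
    ci_high = math.exp(log_r + z * se)
    p = fisher_exact(table) if with_p else math.nan
    return SignalResult(
        table=table,
        ror=point,
        ci_low=ci_low,
        ci_high=ci_high,
        alpha=alpha,
        p_value=p,
        corrected=corrected,
        signal_class=classify_signal(ci_low, ci_high),
        label=label,
    )


def _age_in_bin(age: float, b: AgeBin, last: bool) -> bool:
    if last:
        return b.low <= age <= b.high
    return b.low <= age < b.high


def stratified_ror(
    reports: Sequence[CaseReport],
    exposure_drug: str,
    event_terms: EventTermSet,
    spec: StratumSpec,
    alpha: float = 0.05,
    with_p: bool = True,
) -> list[tuple[str, SignalResult | None]]:
    """One ROR per stratum; reports with a missing stratifier join no stratum.

    Returns ``(label, SignalResult)`` pairs in bin order; a stratum whose
    table is empty or has an undefined ROR margin yields ``(label, None)``
    ("insufficient").
    """
    if spec.variable == "sex":
        groups: list[tuple[str, list[CaseReport]]] = [
            ("M", [r for r in reports if r.sex == "M"]),
            ("F", [r for r in reports if r.sex == "F"]),
        ]
    else:
        nbins = len(spec.bins)
        buckets: list[list[CaseReport]] = [[] for _ in spec.bins]
        for r in reports:
            if r.age_years is None:
                continue
            for i, b in enumerate(spec.bins):
                if _age_in_bin(r.age_years, b, last=(i == nbins - 1)):
                    buckets[i].append(r)
                    break
        groups = [(b.label, bucket) for b, bucket in zip(spec.bins, buckets)]

    out: list[tuple[str, SignalResult | None]] = []
    for label, members in groups:
        table = build_contingency(members, exposure_drug, event_terms)
        if table.n == 0 or (table.a + table.b) == 0 or (table.c + table.d) == 0:
            out.append((label, None))
            continue
        out.append((label, ror(table, alpha=alpha, with_p=with_p, label=label)))
    return out


def round_half_up(x: float, digits: int = 2) -> float:
    """Presentation rounding (half away from zero), e.g. 68.75% -> 69%.

    Works on the shortest decimal representation of ``x`` so that values
    entered as decimals (2.445) round the way a reader expects.
    """
    import decimal

    q = decimal.Decimal(1).scaleb(-digits)
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def format_signal_table(
    results: Iterable[tuple[str, str, SignalResult | None]],
) -> str:
    """Render (exposure, event, result) triples as the canonical TSV table."""
    lines = ["exposure\tevent\ta\tb\tc\td\tror\tci_low\tci_high\tp\tclass"]
    for exposure, event, res in results:
        if res is None:
            lines.append(f"{exposure}\t{event}\t\t\t\t\t\t\t\t\tinsufficient")
            continue
        t = res.table
        lines.append(
            f"{exposure}\t{event}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
            f"{round_half_up(res.ror):.2f}\t{round_half_up(res.ci_low):.2f}\t"
            f"{round_half_up(res.ci_high):.2f}\t{res.p_value:.4g}\t{res.signal_class}"
        )
    return "\n".join(lines) + "\n"
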