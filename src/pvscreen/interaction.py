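"""Comedication screen: which co-reported drugs modify an event's odds?

Restricted to the reports that mention a base drug, every other co-reported
drug with enough co-reports gets its own within-stratum 2x2 table
(exposure = candidate drug, event = the configured term set) and ROR.  Drugs
whose CI lies entirely below 1 are inverse signals - candidate mitigators of
the base drug's event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from pvscreen.errors import ConfigError, DataError
from pvscreen.faers_io import CaseReport, EventTermSet
from pvscreen.signal_stats import ContingencyTable, SignalResult, ror, round_half_up

__all__ = ["ScreenConfig", "ScreenRow", "screen_comedications", "screen_summary"]


@dataclass(frozen=True)
class ScreenConfig:
    """Configuration of one comedication screen run."""

    base_drug: str
    event_terms: EventTermSet
    min_coreports: int = 100
    alpha: float = 0.05
    direction_filter: Literal["inverse", "positive", "both"] = "both"

    def __post_init__(self) -> None:
        if self.min_coreports < 1:
            raise ConfigError(f"min_coreports must be >= 1, got {self.min_coreports}")
        if self.direction_filter not in ("inverse", "positive", "both"):
            raise ConfigError(f"bad direction_filter {self.direction_filter!r}")


@dataclass(frozen=True)
class ScreenRow:
    """One candidate drug's within-base-drug 2x2 and signal result."""

    candidate_drug: str
    n_with: int
    n_event_with: int
    n_without: int
    n_event_without: int
    result: SignalResult


def screen_comedications(
    reports: Sequence[CaseReport], cfg: ScreenConfig
) -> list[ScreenRow]:
    """Screen every co-reported drug for modification of the event's odds.

    Within reports mentioning ``cfg.base_drug``, each distinct other drug
    with at least ``cfg.min_coreports`` co-reports is tested as the exposure
    of a 2x2 table against the event terms.  Rows passing the direction
    filter are returned sorted by ascending ROR (ties broken by drug name),
    so the run is deterministic for a fixed input.
    """
    base = [r for r in reports if cfg.base_drug in r.drugs]
    if not base:
        raise DataError(f"base drug {cfg.base_drug!r} absent from all reports")

    n_base = len(base)
    terms = cfg.event_terms.terms
    events = [bool(r.reactions & terms) for r in base]
    n_event_total = sum(events)

    with_counts: Counter[str] = Counter()
    event_counts: Counter[str] = Counter()
    for r, ev in zip(base, events):
        for drug in r.drugs:
            if drug == cfg.base_drug:
                continue
            with_counts[drug] += 1
            if ev:
                event_counts[drug] += 1

    rows = []
    for drug, n_with in with_counts.items():
        if n_with < cfg.min_coreports:
            continue
        a = event_counts[drug]
        b = n_with - a
        c = n_event_total - a
        d = (n_base - n_with) - c
        table = ContingencyTable(a, b, c, d)
        result = ror(table, alpha=cfg.alpha, label=drug)
        if cfg.direction_filter != "both" and result.signal_class != cfg.direction_filter:
            continue
        rows.append(
            ScreenRow(
                candidate_drug=drug,
                n_with=n_with,
                n_event_with=a,
                n_without=n_base - n_with,
                n_event_without=c,
                result=result,
            )
        )
    rows.sort(key=lambda r: (r.result.ror, r.candidate_drug))
    return rows


def _bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    # Benjamini-Hochberg step-up; returns monotone q-values in input order.
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def screen_summary(rows: Iterable[ScreenRow], qvalues: bool = False) -> str:
    """Render screen rows as a TSV table with count/percentage columns.

    Layout per row: events without the candidate over its denominator with
    the percentage to 2 decimals, the same with the candidate, then ROR, CI,
    p and class.  ``qvalues=True`` appends a Benjamini-Hochberg q column.
    """
    rows = list(rows)
    header = (
        "drug\tevent_without_drug\tevent_with_drug\tror\tci_low\tci_high\tp\tclass"
    )
    if qvalues:
        header += "\tq_bh"
        qs = _bh_qvalues([r.result.p_value for r in rows])
    lines = [header]
    for i, row in enumerate(rows):
        pct_without = round_half_up(100.0 * row.n_event_without / row.n_without)
        pct_with = round_half_up(100.0 * row.n_event_with / row.n_with)
        res = row.result
        line = (
            f"{row.candidate_drug}\t"
            f"{row.n_event_without}/{row.n_without} ({pct_without:.2f})\t"
            f"{row.n_event_with}/{row.n_with} ({pct_with:.2f})\t"
            f"{round_half_up(res.ror):.2f}\t{round_half_up(res.ci_low):.2f}\t"
            f"{round_half_up(res.ci_high):.2f}\t{res.p_value:.4g}\t{res.signal_class}"
        )
        if qvalues:
            line += f"\t{qs[i]:.4g}"
        lines.append(line)
    return "\n".join(lines) + "\n"
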