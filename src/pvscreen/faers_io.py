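"""Reading, validating, and deduplicating spontaneous-report files.

The on-disk layout mirrors the FAERS quarterly ASCII extracts: three
"$"-delimited tables (DEMO, DRUG, REAC) keyed by a case number, where a case
may be re-reported under increasing version numbers.  Deduplication keeps,
for every case number, only the rows belonging to its most recent version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pvscreen.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Conversion factors from FAERS age-unit codes to years.
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

_SEX_CODES = {"M": "M", "F": "F"}


@dataclass(frozen=True)
class Dialect:
    """Column layout of a report-file triplet.

    ``demo_columns`` / ``drug_columns`` / ``reac_columns`` name the fields in
    file order.  Recognized names: ``case_id``, ``version``, ``age``,
    ``age_unit``, ``sex``, ``drug_name``, ``reaction``; anything else is
    carried but ignored.  ``version`` in DRUG/REAC rows ties detail rows to a
    specific report version; without it, detail rows attach to the case as a
    whole.
    """

    delimiter: str = "$"
    has_header: bool = True
    demo_columns: tuple[str, ...] = ("case_id", "version", "age", "age_unit", "sex")
    drug_columns: tuple[str, ...] = ("case_id", "version", "drug_name")
    reac_columns: tuple[str, ...] = ("case_id", "version", "reaction")

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "Dialect":
        kwargs = {}
        for key in ("delimiter", "has_header"):
            if key in cfg:
                kwargs[key] = cfg[key]
        for key in ("demo_columns", "drug_columns", "reac_columns"):
            if key in cfg:
                kwargs[key] = tuple(cfg[key])
        return cls(**kwargs)


@dataclass
class RawRecordSet:
    """Loaded but not-yet-deduplicated report tables.

    ``rejects`` maps a source path to the (line number, line) pairs that had
    the wrong column count; they are reported, never silently dropped.
    """

    demo: pd.DataFrame
    drugs: pd.DataFrame
    reacs: pd.DataFrame
    rejects: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    @property
    def n_rejects(self) -> int:
        return sum(len(v) for v in self.rejects.values())

    def case_ids(self) -> set[str]:
        return set(self.demo["case_id"])


@dataclass(frozen=True, slots=True)
class CaseReport:
    """One deduplicated spontaneous report."""

    case_id: str
    age_years: float | None
    sex: str  # "M", "F", or "unknown"
    drugs: frozenset[str]
    reactions: frozenset[str]


@dataclass(frozen=True)
class EventTermSet:
    """A named set of preferred terms defining one clinical event."""

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ConfigError(f"event term set {self.name!r} is empty")
        object.__setattr__(self, "terms", frozenset(t.strip().upper() for t in self.terms))

    def __contains__(self, term: str) -> bool:
        return term.strip().upper() in self.terms


def load_term_set(path: str | Path, name: str | None = None) -> EventTermSet:
    """Load an event term set from a plain-text file, one term per line.

    Blank lines and ``#`` comment lines are skipped; matching is
    case-insensitive.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"term set file not found: {path}")
    terms = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.upper())
    return EventTermSet(name=name or path.stem, terms=frozenset(terms))


def load_synonym_map(path: str | Path) -> dict[str, str]:
    """Load ``VERBATIM<TAB>CANONICAL`` lines into a synonym mapping.

    Keys are normalized like verbatim drug strings (upper, trimmed); values
    are canonical uppercase ingredient names.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"synonym file not found: {path}")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 tab-separated fields")
        verbatim, canonical = (p.strip().upper() for p in parts)
        mapping[" ".join(verbatim.split())] = " ".join(canonical.split())
    return mapping


def normalize_drug_name(verbatim: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Canonicalize a verbatim drug string.

    Uppercases, trims, and collapses internal whitespace, then maps through
    ``synonyms`` when an entry exists.
    """
    if verbatim is None or not str(verbatim).strip():
        raise DataError("empty drug name")
    norm = " ".join(str(verbatim).strip().upper().split())
    if synonyms:
        return synonyms.get(norm, norm)
    return norm


def _parse_file(
    path: Path, columns: Sequence[str], dialect: Dialect
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    rows: list[list[str]] = []
    rejects: list[tuple[int, str]] = []
    ncol = len(columns)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 1 if dialect.has_header and lines else 0
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        parts = line.split(dialect.delimiter)
        if len(parts) != ncol:
            rejects.append((lineno, line))
        else:
            rows.append(parts)
    frame = pd.DataFrame(rows, columns=list(columns))
    if rejects:
        logger.warning("%s: %d malformed row(s) rejected", path, len(rejects))
    return frame, rejects


def _float_or_nan(value) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        return float("nan")


def _convert_age(demo: pd.DataFrame) -> pd.Series:
    if "age" not in demo.columns:
        return pd.Series(float("nan"), index=demo.index)
    # full-precision parse: pd.to_numeric round-trips doubles lossily
    age = demo["age"].map(_float_or_nan)
    if "age_unit" in demo.columns:
        unit = demo["age_unit"].astype(str).str.strip().str.upper()
        factor = unit.map(AGE_UNIT_TO_YEARS)
        age = age * factor  # unmapped unit -> NaN -> missing
    return age


def _convert_sex(demo: pd.DataFrame) -> pd.Series:
    if "sex" not in demo.columns:
        return pd.Series("unknown", index=demo.index)
    sex = demo["sex"].astype(str).str.strip().str.upper()
    return sex.map(_SEX_CODES).fillna("unknown")


def read_reports(
    paths: Mapping[str, Sequence[str | Path] | str | Path],
    dialect: Dialect | None = None,
) -> RawRecordSet:
    """Load DEMO/DRUG/REAC files into a :class:`RawRecordSet`.

    Parameters
    ----------
    paths:
        Mapping with keys ``demo``, ``drug``, ``reac``; each value is one
        path or a sequence of paths (e.g. several quarters).
    dialect:
        File layout; defaults to the "$"-delimited layout of
        :class:`Dialect`.

    Malformed rows (wrong column count) are collected in ``rejects`` and
    logged; a missing file is fatal.
    """
    dialect = dialect or Dialect()
    frames: dict[str, pd.DataFrame] = {}
    rejects: dict[str, list[tuple[int, str]]] = {}
    specs = {
        "demo": dialect.demo_columns,
        "drug": dialect.drug_columns,
        "reac": dialect.reac_columns,
    }
    for kind, columns in specs.items():
        if kind not in paths:
            raise ConfigError(f"missing {kind!r} paths")
        entry = paths[kind]
        file_list = [entry] if isinstance(entry, (str, Path)) else list(entry)
        parts = []
        for p in file_list:
            frame, bad = _parse_file(Path(p), columns, dialect)
            parts.append(frame)
            if bad:
                rejects[str(p)] = bad
        frames[kind] = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=columns)

    demo, drugs, reacs = frames["demo"], frames["drug"], frames["reac"]
    if demo.empty:
        logger.warning("DEMO table is empty")
    if drugs.empty:
        logger.warning("DRUG table is empty")
    if reacs.empty:
        logger.warning("REAC table is empty")

    demo = demo.copy()
    demo["age_years"] = _convert_age(demo)
    demo["sex_norm"] = _convert_sex(demo)
    demo["version"] = pd.to_numeric(demo.get("version"), errors="coerce")
    if demo["version"].isna().any():
        raise DataError("DEMO rows with unparseable version key")

    known = set(demo["case_id"])
    for name, frame in (("DRUG", drugs), ("REAC", reacs)):
        orphans = set(frame["case_id"]) - known
        if orphans:
            raise DataError(f"{name} rows reference unknown case_ids: {sorted(orphans)[:5]} ...")

    return RawRecordSet(demo=demo, drugs=drugs, reacs=reacs, rejects=rejects)


def deduplicate(
    raw: RawRecordSet, synonyms: Mapping[str, str] | None = None
) -> list[CaseReport]:
    """Collapse a raw record set to one :class:`CaseReport` per case number.

    For every case the row with the maximum version key wins; drug and
    reaction rows are unioned within that version only (when the detail
    tables carry a version column).  Ties on the version key keep the row
    appearing last in file order and log a warning.
    """
    demo = raw.demo
    if demo.empty:
        return []

    dup_versions = demo.duplicated(subset=["case_id", "version"], keep=False)
    if dup_versions.any():
        n = demo.loc[dup_versions, "case_id"].nunique()
        logger.warning("version-key ties in %d case(s); keeping last row in file order", n)

    # stable sort + keep last == max version, last-in-file tie break
    latest = (
        demo.sort_values("version", kind="stable")
        .drop_duplicates(subset="case_id", keep="last")
        .set_index("case_id")
    )

    drug_map = _detail_map(raw.drugs, "drug_name", latest, synonyms=synonyms)
    reac_map = _detail_map(raw.reacs, "reaction", latest, synonyms=None)

    reports = []
    for case_id, row in latest.iterrows():
        age = row["age_years"]
        reports.append(
            CaseReport(
                case_id=str(case_id),
                age_years=None if pd.isna(age) else float(age),
                sex=row["sex_norm"],
                drugs=drug_map.get(case_id, frozenset()),
                reactions=reac_map.get(case_id, frozenset()),
            )
        )
    return reports


def _detail_map(
    frame: pd.DataFrame,
    value_col: str,
    latest: pd.DataFrame,
    synonyms: Mapping[str, str] | None,
) -> dict[str, frozenset[str]]:
    if frame.empty:
        return {}
    frame = frame.copy()
    if "version" in frame.columns:
        version = pd.to_numeric(frame["version"], errors="coerce")
        want = latest["version"]
        keep = version.values == want.reindex(frame["case_id"]).values
        frame = frame[keep]
    values = frame[value_col].map(lambda v: normalize_drug_name(v, synonyms))
    out: dict[str, frozenset[str]] = {}
    for case_id, group in values.groupby(frame["case_id"]):
        out[case_id] = frozenset(group)
    return out


def has_event(report: CaseReport, terms: EventTermSet) -> bool:
    """True iff the report lists at least one reaction in the term set."""
    return bool(report.reactions & terms.terms)


def write_reports(reports: Iterable[CaseReport], path: str | Path) -> None:
    """Write the canonical tab-separated case table used by downstream stages."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("case_id\tage_years\tsex\tdrugs\treactions\n")
        for r in reports:
            age = "" if r.age_years is None else repr(r.age_years)
            fh.write(
                f"{r.case_id}\t{age}\t{r.sex}\t"
                f"{'|'.join(sorted(r.drugs))}\t{'|'.join(sorted(r.reactions))}\n"
            )


def read_case_table(path: str | Path) -> list[CaseReport]:
    """Read a case table written by :func:`write_reports`."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"case table not found: {path}")
    reports = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["case_id", "age_years", "sex", "drugs", "reactions"]:
            raise DataError(f"unexpected case-table header in {path}")
        for lineno, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise DataError(f"{path}:{lineno}: expected 5 fields")
            case_id, age, sex, drugs, reactions = parts
            reports.append(
                CaseReport(
                    case_id=case_id,
                    age_years=float(age) if age else None,
                    sex=sex,
                    drugs=frozenset(d for d in drugs.split("|") if d),
                    reactions=frozenset(r for r in reactions.split("|") if r),
                )
            )
    return reports
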