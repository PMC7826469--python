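"""Synthetic data generators for every pipeline stage.

All generators are pure functions of (config, seed): rerunning with the same
seed reproduces byte-identical output.  Report generation separates *truth
assignment* (case-level exposure/event draws, vectorized) from downstream
*presentation* (noise drugs, duplicate versions, file encoding) on
independent child seed streams, so deduplicating a set generated with
duplication gives exactly the set generated without it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pvscreen.cohort import CohortPatient
from pvscreen.errors import ConfigError
from pvscreen.expression import ExpressionMatrix
from pvscreen.faers_io import CaseReport
from pvscreen.signal_stats import ContingencyTable

__all__ = [
    "CohortGenConfig",
    "ComedicationSpec",
    "ReportGenConfig",
    "SimulatedReports",
    "contingency_from_truth",
    "gen_cohort",
    "gen_expression",
    "gen_reports",
]


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must be a probability in [0,1], got {p}")


@dataclass(frozen=True)
class ComedicationSpec:
    """One planted comedication: prevalence among base-drug reports and its
    multiplicative event-odds effect within those reports."""

    name: str
    prevalence_among_base: float
    or_within_base: float = 1.0

    def __post_init__(self) -> None:
        _check_prob(f"comedication {self.name}: prevalence", self.prevalence_among_base)
        if self.or_within_base <= 0:
            raise ConfigError(f"comedication {self.name}: odds multiplier must be > 0")


@dataclass(frozen=True)
class ReportGenConfig:
    """Configuration of the spontaneous-report generator.

    Event generation is multiplicative on the odds scale: a report's event
    odds are ``baseline odds x or_base_drug^exposed x prod(or_within_base)``
    over its comedications, so every configured multiplier equals the true
    conditional odds ratio and parameter-recovery checks are well defined.
    """

    n_cases: int
    p_baseline_event: float = 0.0226
    base_drug_prevalence: float = 0.0076
    or_base_drug: float = 1.0
    comedications: tuple[ComedicationSpec, ...] = ()
    background_drug_pool: int = 50
    duplication_rate: float = 0.0
    missing_age_rate: float = 0.1
    missing_sex_rate: float = 0.05
    age_mean: float = 58.0
    age_sd: float = 15.0
    base_drug: str = "BEVACIZUMAB"
    event_term: str = "HYPERTENSION"
    noise_term: str = "NAUSEA"

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ConfigError(f"n_cases must be >= 1, got {self.n_cases}")
        _check_prob("p_baseline_event", self.p_baseline_event)
        _check_prob("base_drug_prevalence", self.base_drug_prevalence)
        _check_prob("duplication_rate", self.duplication_rate)
        _check_prob("missing_age_rate", self.missing_age_rate)
        _check_prob("missing_sex_rate", self.missing_sex_rate)
        if self.or_base_drug <= 0:
            raise ConfigError("or_base_drug must be > 0")
        if self.background_drug_pool < 0:
            raise ConfigError("background_drug_pool must be >= 0")


@dataclass
class SimulatedReports:
    """A generated report set: case-level truth plus file materialization."""

    config: ReportGenConfig
    seed: int
    truth: pd.DataFrame  # per case: exposed, event, one column per comedication

    def contingency(self) -> ContingencyTable:
        """Base-drug x event table straight from the truth assignment."""
        return contingency_from_truth(self.truth)

    def to_case_reports(self) -> list[CaseReport]:
        """Materialize deduplicated-equivalent case reports (no duplicates)."""
        cfg = self.config
        comed_names = [c.name for c in cfg.comedications]
        noise = self._noise_drugs()
        reports = []
        # positional access: comedication names need not be identifiers
        columns = ["case_id", "exposed", "event", "age", "sex", *comed_names]
        for i, row in enumerate(self.truth[columns].itertuples(index=False, name=None)):
            case_id, exposed, event, age, sex = row[:5]
            drugs = set(noise[i])
            if exposed:
                drugs.add(cfg.base_drug)
                drugs.update(name for name, has in zip(comed_names, row[5:]) if has)
            reactions = {cfg.event_term} if event else {cfg.noise_term}
            reports.append(
                CaseReport(
                    str(case_id),
                    None if math.isnan(age) else float(age),
                    str(sex),
                    frozenset(drugs),
                    frozenset(reactions),
                )
            )
        return reports

    def _noise_drugs(self) -> list[list[str]]:
        cfg = self.config
        n = len(self.truth)
        if cfg.background_drug_pool == 0:
            return [["BACKGROUND_000"]] * n
        rng = np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[1])
        # Zipf-like report frequencies over the noise pool
        weights = 1.0 / np.arange(1, cfg.background_drug_pool + 1)
        weights /= weights.sum()
        n_extra = rng.poisson(1.0, size=n)
        picks = [
            rng.choice(cfg.background_drug_pool, size=1 + k, p=weights) for k in n_extra
        ]
        return [[f"BACKGROUND_{j:03d}" for j in set(p)] for p in picks]

    def write(self, out_dir: str | Path, quarter: str = "23Q1") -> dict[str, Path]:
        """Write DEMO/DRUG/REAC files in the "$" dialect plus a truth sidecar.

        Case duplication happens here: a case is re-reported with
        probability ``duplication_rate``; extra versions (1 + geometric)
        carry the same payload under lower version numbers, so dedup must
        recover exactly the truth-level set.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[2])
        reports = self.to_case_reports()

        demo_lines = ["case_id$version$age$age_unit$sex"]
        drug_lines = ["case_id$version$drug_name"]
        reac_lines = ["case_id$version$reaction"]

        dup_mask = rng.random(len(reports)) < cfg.duplication_rate
        n_versions = np.ones(len(reports), dtype=int)
        if dup_mask.any():
            n_versions[dup_mask] += 1 + rng.geometric(0.5, size=int(dup_mask.sum()))

        for report, versions in zip(reports, n_versions):
            age = "" if report.age_years is None else repr(report.age_years)
            unit = "YR" if age else ""
            sex = report.sex if report.sex in ("M", "F") else "UNK"
            for v in range(1, versions + 1):
                demo_lines.append(f"{report.case_id}${v}${age}${unit}${sex}")
                for drug in sorted(report.drugs):
                    drug_lines.append(f"{report.case_id}${v}${drug}")
                for reaction in sorted(report.reactions):
                    reac_lines.append(f"{report.case_id}${v}${reaction}")

        paths = {
            "demo": out_dir / f"DEMO{quarter}.txt",
            "drug": out_dir / f"DRUG{quarter}.txt",
            "reac": out_dir / f"REAC{quarter}.txt",
            "truth": out_dir / "truth.json",
        }
        paths["demo"].write_text("\n".join(demo_lines) + "\n", encoding="utf-8")
        paths["drug"].write_text("\n".join(drug_lines) + "\n", encoding="utf-8")
        paths["reac"].write_text("\n".join(reac_lines) + "\n", encoding="utf-8")
        truth_payload = {
            "seed": self.seed,
            "config": _config_dict(cfg),
            "table": list(self.contingency().cells()),
            "n_cases": int(len(self.truth)),
            "n_duplicated": int(dup_mask.sum()),
        }
        paths["truth"].write_text(json.dumps(truth_payload, indent=2), encoding="utf-8")
        return paths


def _config_dict(cfg) -> dict:
    d = asdict(cfg)
    return d


def contingency_from_truth(truth: pd.DataFrame) -> ContingencyTable:
    exposed = truth["exposed"].to_numpy()
    event = truth["event"].to_numpy()
    a = int((exposed & event).sum())
    b = int((exposed & ~event).sum())
    c = int((~exposed & event).sum())
    d = int((~exposed & ~event).sum())
    return ContingencyTable(a, b, c, d)


def gen_reports(cfg: ReportGenConfig, seed: int) -> SimulatedReports:
    """Draw the case-level truth table for a synthetic report set.

    Per case: base-drug exposure ~ Bernoulli(prevalence); comedications are
    drawn only within exposed cases; the event probability combines the
    baseline odds with the multiplicative odds effects of the base drug and
    any comedications; demographics get configurable missingness.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[0])
    n = cfg.n_cases

    exposed = rng.random(n) < cfg.base_drug_prevalence
    odds = np.full(n, cfg.p_baseline_event / (1.0 - cfg.p_baseline_event))
    odds[exposed] *= cfg.or_base_drug

    comed_cols = {}
    for comed in cfg.comedications:
        has = np.zeros(n, dtype=bool)
        has[exposed] = rng.random(int(exposed.sum())) < comed.prevalence_among_base
        odds[has] *= comed.or_within_base
        comed_cols[comed.name] = has

    p_event = odds / (1.0 + odds)
    event = rng.random(n) < p_event

    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n).clip(18.0, 100.0)
    age[rng.random(n) < cfg.missing_age_rate] = np.nan
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    sex = np.where(rng.random(n) < cfg.missing_sex_rate, "unknown", sex)

    truth = pd.DataFrame(
        {
            "case_id": np.arange(n),
            "exposed": exposed,
            "event": event,
            "age": age,
            "sex": sex,
            **comed_cols,
        }
    )
    return SimulatedReports(config=cfg, seed=seed, truth=truth)


# ---------------------------------------------------------------------------
# cohort generator


@dataclass(frozen=True)
class CohortGenConfig:
    """Configuration of the synthetic chart-review cohort generator."""

    n_per_arm: tuple[int, int]  # (non-PPI, PPI)
    response_probs: tuple[tuple[float, float, float, float], ...] = (
        (0.0, 0.5, 0.4, 0.1),
        (0.0, 0.25, 0.45, 0.3),
    )  # CR/PR/SD/PD per arm
    sbp_baseline: tuple[tuple[float, float], ...] = ((130.0, 15.0), (120.0, 5.0))
    sbp_delta: tuple[tuple[float, float], ...] = ((13.5, 5.0), (13.9, 5.0))
    p_xelox: tuple[float, float] = (0.5, 0.75)
    p_antihypertensive: tuple[float, float] = (0.17, 0.19)

    def __post_init__(self) -> None:
        if min(self.n_per_arm) < 1:
            raise ConfigError(f"both arms must be non-empty, got {self.n_per_arm}")
        for probs in self.response_probs:
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(f"response probabilities must sum to 1, got {probs}")
            if min(probs) < 0:
                raise ConfigError("negative response probability")


def gen_cohort(cfg: CohortGenConfig, seed: int) -> list[CohortPatient]:
    """Draw a synthetic two-arm cohort (arm 0: non-PPI, arm 1: PPI)."""
    rng = np.random.default_rng(seed)
    responses = ("CR", "PR", "SD", "PD")
    stages = ("I", "II", "IIIa", "IV")
    patients = []
    pid = 1
    for arm, n in enumerate(cfg.n_per_arm):
        resp = rng.choice(4, size=n, p=cfg.response_probs[arm])
        base_mu, base_sd = cfg.sbp_baseline[arm]
        delta_mu, delta_sd = cfg.sbp_delta[arm]
        baseline = rng.normal(base_mu, base_sd, size=n).clip(80.0, 220.0)
        delta = rng.normal(delta_mu, delta_sd, size=n)
        after = (baseline + delta).clip(60.0, 260.0)
        for i in range(n):
            patients.append(
                CohortPatient(
                    patient_id=f"S{pid:03d}",
                    age_years=float(rng.integers(40, 87)),
                    sex="M" if rng.random() < 0.5 else "F",
                    stage=stages[int(rng.choice(4, p=(0.02, 0.02, 0.1, 0.86)))],
                    ps=int(rng.choice(3, p=(0.5, 0.45, 0.05))),
                    regimen="XELOX" if rng.random() < cfg.p_xelox[arm] else "mFOLFOX6",
                    ppi_user=bool(arm),
                    antihypertensive_baseline=bool(rng.random() < cfg.p_antihypertensive[arm]),
                    response=responses[int(resp[i])],
                    sbp_series=((0, float(baseline[i])), (1, float(after[i]))),
                )
            )
            pid += 1
    return patients


# ---------------------------------------------------------------------------
# expression generator


def gen_expression(
    n_genes: int,
    group_sizes: Sequence[tuple[str, int]],
    sigma: float,
    planted_effects: dict[str, float] | None = None,
    seed: int = 0,
    baseline_range: tuple[float, float] = (4.0, 12.0),
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Gaussian log2 expression with planted per-gene group shifts.

    ``planted_effects`` maps gene id -> log2 shift added to every
    non-first group (the first group is the reference/vehicle).  Returns the
    matrix and a truth sidecar of the planted shifts.  Gene ids are
    ``G0000``-style unless a planted gene name falls outside that range, in
    which case planted names replace the leading generated ids.
    """
    if n_genes < 1:
        raise ConfigError("n_genes must be >= 1")
    if any(size < 1 for _, size in group_sizes):
        raise ConfigError("every group needs at least 1 sample")
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    planted_effects = dict(planted_effects or {})

    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    extra = [g for g in planted_effects if g not in genes]
    for i, name in enumerate(sorted(extra)):
        genes[i] = name

    baseline = rng.uniform(*baseline_range, size=n_genes)
    shift = np.array([planted_effects.get(g, 0.0) for g in genes])

    columns: dict[str, np.ndarray] = {}
    labels = []
    for gi, (group, size) in enumerate(group_sizes):
        group_shift = shift if gi > 0 else np.zeros(n_genes)
        for s in range(size):
            name = f"{group}_{s + 1}"
            columns[name] = baseline + group_shift + rng.normal(0.0, sigma, size=n_genes)
            labels.append((name, group))

    values = pd.DataFrame(columns, index=genes)
    groups = pd.Series({name: group for name, group in labels})
    mat = ExpressionMatrix(values=values, groups=groups.loc[values.columns])
    return mat, {g: float(planted_effects.get(g, 0.0)) for g in genes if planted_effects.get(g)}
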