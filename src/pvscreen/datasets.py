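"""Embedded reference fixtures and packaged term/gene lists.

The published analysis this package re-implements prints aggregate counts
(four-group contingency tables, per-stratum counts, comedication tables,
cohort response counts, group-mean expression values) rather than raw data.
Those counts are embedded here and can be materialized into full report
sets, cohorts, and matrices so every pipeline stage is exercisable end to
end without any external download.
"""

from __future__ import annotations

import itertools
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from pvscreen.cohort import CohortPatient
from pvscreen.expression import ExpressionMatrix, PathwayGeneSet
from pvscreen.faers_io import CaseReport, EventTermSet, load_term_set
from pvscreen.signal_stats import ContingencyTable

__all__ = [
    "BASE_DRUG",
    "COMEDICATION_COUNTS",
    "EXPRESSION_GROUP_MEANS",
    "REFERENCE_TOTAL",
    "RESPONSE_COUNTS",
    "STRATUM_COUNTS",
    "default_event_terms",
    "default_pathway_genes",
    "packaged_data_path",
    "reference_base_drug_reports",
    "reference_cohort",
    "reference_expression_matrix",
    "reference_report_set",
    "reports_from_table",
]

BASE_DRUG = "BEVACIZUMAB"
EVENT_TERM = "HYPERTENSION"
NON_EVENT_TERM = "NAUSEA"

#: Deduplicated four-group counts for the bevacizumab-hypertension pair:
#: (a, b, c, d) = (drug+event, drug only, event only, neither).
REFERENCE_TOTAL = (1520, 26768, 83559, 3611907)

#: Per-stratum four-group counts (sex strata and age strata).  Strata do
#: not sum to the total: reports with a missing stratifier join no stratum.
STRATUM_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "M": (414, 11052, 28076, 1246677),
    "F": (776, 12882, 51603, 2038494),
    "<40": (60, 1172, 8342, 519527),
    "40-49": (104, 1894, 7758, 313800),
    "50-59": (214, 3848, 13054, 457493),
    "60-69": (299, 5177, 14250, 457846),
    "70-100": (248, 4415, 15478, 513762),
}

#: Within-base-drug comedication tables: candidate -> (a, b, c, d) where the
#: exposure is the candidate drug and the population is base-drug reports.
COMEDICATION_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "EPIRUBICIN": (8, 421, 1512, 26347),
    "ERLOTINIB": (34, 864, 1486, 25904),
    "OMEPRAZOLE": (18, 578, 1502, 26190),
}

#: Chart-review response counts per arm (CR, PR, SD, PD).
RESPONSE_COUNTS: dict[str, dict[str, int]] = {
    "non_ppi": {"CR": 0, "PR": 21, "SD": 17, "PD": 4},
    "ppi": {"CR": 0, "PR": 4, "SD": 7, "PD": 5},
}

#: Group-mean log2 intensities (treated, vehicle) for the VEGF-pathway
#: genes of the reference two-group comparison.
EXPRESSION_GROUP_MEANS: dict[str, tuple[float, float]] = {
    "VEGFA": (11.57, 11.07),
    "SPHKAP": (5.05, 5.69),
    "NRAS": (7.31, 7.53),
    "RAF1": (10.52, 11.01),
    "NFATC4": (4.44, 6.54),
    "RAC1": (10.79, 10.43),
    "NOS3": (5.23, 5.78),
}

# representative in-bin ages used when materializing stratum counts
_AGE_REPRESENTATIVE = {"<40": 25.0, "40-49": 45.0, "50-59": 55.0, "60-69": 65.0, "70-100": 80.0}


def packaged_data_path(name: str) -> Path:
    """Path of a data file shipped inside the package."""
    return Path(str(resources.files("pvscreen").joinpath("data", name)))


def default_event_terms() -> EventTermSet:
    """The packaged default hypertension term set."""
    return load_term_set(packaged_data_path("hypertension_smq.txt"), name="hypertension_smq")


def default_pathway_genes() -> PathwayGeneSet:
    """The packaged VEGF-pathway gene set."""
    from pvscreen.expression import load_gene_set

    return load_gene_set(packaged_data_path("vegf_pathway_map04370.txt"), name="vegf_pathway_map04370")


def _merge_runs(total: int, *marginals: Sequence[tuple[object, int]]):
    """Merge several run-length partitions of ``range(total)`` into joint
    homogeneous segments.

    Each marginal is ``[(label, count), ...]`` summing to at most ``total``;
    a shortfall is padded with ``None``.  Yields ``(length, labels)`` where
    ``labels`` has one entry per marginal.  Pairing marginals positionally
    preserves every marginal distribution exactly, which is all the
    stratified analyses require.
    """
    padded = []
    for marginal in marginals:
        counted = sum(c for _, c in marginal)
        runs = [(label, c) for label, c in marginal if c > 0]
        if counted < total:
            runs.append((None, total - counted))
        padded.append(runs)

    cuts = sorted(
        set(itertools.chain.from_iterable(
            itertools.accumulate(c for _, c in runs) for runs in padded
        )) | {0, total}
    )
    # per-marginal label lookup by segment start
    starts = []
    for runs in padded:
        table = []
        pos = 0
        for label, c in runs:
            table.append((pos, pos + c, label))
            pos += c
        starts.append(table)

    def label_at(table, i):
        for lo, hi, label in table:
            if lo <= i < hi:
                return label
        return None

    for lo, hi in zip(cuts, cuts[1:]):
        yield hi - lo, tuple(label_at(t, lo) for t in starts)


def reports_from_table(
    table: ContingencyTable | tuple[int, int, int, int],
    exposure_drug: str = BASE_DRUG,
    event_term: str = EVENT_TERM,
    start_id: int = 0,
) -> list[CaseReport]:
    """Materialize a 2x2 count table into a list of minimal case reports."""
    if isinstance(table, ContingencyTable):
        cells = table.cells()
    else:
        cells = tuple(table)
    reports: list[CaseReport] = []
    counter = itertools.count(start_id)
    specs = [
        (cells[0], frozenset({exposure_drug}), frozenset({event_term})),
        (cells[1], frozenset({exposure_drug}), frozenset({NON_EVENT_TERM})),
        (cells[2], frozenset({"PLACEBOMAB"}), frozenset({event_term})),
        (cells[3], frozenset({"PLACEBOMAB"}), frozenset({NON_EVENT_TERM})),
    ]
    for count, drugs, reactions in specs:
        reports.extend(
            CaseReport(str(next(counter)), None, "unknown", drugs, reactions)
            for _ in range(count)
        )
    return reports


def _cell_marginal(counts: Mapping[str, tuple[int, int, int, int]], keys: Iterable[str], cell: int):
    return [(k, counts[k][cell]) for k in keys]


def reference_report_set(scale: int = 1, exposed_only: bool = False) -> list[CaseReport]:
    """Materialize the full embedded reference counts as case reports.

    Builds one report per counted case with drugs, reactions, sex, and age
    assigned so that the total table, every sex/age stratum table, and every
    comedication table are reproduced exactly (at ``scale=1``).  ``scale``
    divides every cell count (floor, minimum 1 where the original count is
    positive) to produce structurally identical but smaller sets for fast
    tests; scaled sets no longer match the printed statistics.
    """

    def scaled(v: int) -> int:
        if scale == 1:
            return v
        return max(1, v // scale) if v > 0 else 0

    sexes = ("M", "F")
    ages = tuple(_AGE_REPRESENTATIVE)
    comed_names = tuple(COMEDICATION_COUNTS)

    reports: list[CaseReport] = []
    counter = itertools.count()
    cell_specs = [
        # (cell index, has base drug, has event)
        (0, True, True),
        (1, True, False),
        (2, False, True),
        (3, False, False),
    ]
    base_only = frozenset({BASE_DRUG})
    no_drug = frozenset({"PLACEBOMAB"})
    event_rx = frozenset({EVENT_TERM})
    other_rx = frozenset({NON_EVENT_TERM})
    comed_sets = {name: frozenset({BASE_DRUG, name}) for name in comed_names}

    for cell, exposed, event in cell_specs:
        if exposed_only and not exposed:
            continue
        total = scaled(REFERENCE_TOTAL[cell])
        sex_runs = [(s, scaled(STRATUM_COUNTS[s][cell])) for s in sexes]
        age_runs = [(a, scaled(STRATUM_COUNTS[a][cell])) for a in ages]
        if exposed:
            # comedications live only in base-drug reports (cells a and b)
            comed_runs = [(n, scaled(COMEDICATION_COUNTS[n][0 if event else 1])) for n in comed_names]
        else:
            comed_runs = [(None, total)]
        reactions = event_rx if event else other_rx

        for length, (sex, age_label, comed) in _merge_runs(total, sex_runs, age_runs, comed_runs):
            if exposed:
                drugs = comed_sets[comed] if comed else base_only
            else:
                drugs = no_drug
            sex_value = sex if sex else "unknown"
            age_value = _AGE_REPRESENTATIVE[age_label] if age_label else None
            reports.extend(
                CaseReport(str(next(counter)), age_value, sex_value, drugs, reactions)
                for _ in range(length)
            )
    return reports


def reference_base_drug_reports(scale: int = 1) -> list[CaseReport]:
    """Only the base-drug reports of the reference set (the screen's input)."""
    return reference_report_set(scale=scale, exposed_only=True)


def reference_cohort() -> list[CohortPatient]:
    """Materialize the embedded chart-review counts as 58 patients.

    Response counts, sex, stage, regimen, and baseline-antihypertensive
    counts follow the published table; performance status is adjusted to
    sum to the arm sizes (the printed column does not); ages and SBP series
    are deterministic filler with the published arm means.
    """
    arms = {
        "non_ppi": {
            "n": 42,
            "responses": RESPONSE_COUNTS["non_ppi"],
            "sex": [("M", 21), ("F", 21)],
            "stage": [("I", 1), ("II", 1), ("IIIa", 5), ("IV", 35)],
            "ps": [(0, 21), (1, 21), (2, 0)],
            "regimen": [("XELOX", 21), ("mFOLFOX6", 21)],
            "antihypertensive": [(True, 7), (False, 35)],
            "sbp_before": 130.0,
            "sbp_delta": 13.0,
            "ppi": False,
        },
        "ppi": {
            "n": 16,
            "responses": RESPONSE_COUNTS["ppi"],
            "sex": [("M", 10), ("F", 6)],
            "stage": [("I", 0), ("II", 0), ("IIIa", 1), ("IV", 15)],
            "ps": [(0, 8), (1, 7), (2, 1)],
            "regimen": [("XELOX", 12), ("mFOLFOX6", 4)],
            "antihypertensive": [(True, 3), (False, 13)],
            "sbp_before": 120.0,
            "sbp_delta": 14.0,
            "ppi": True,
        },
    }

    patients: list[CohortPatient] = []
    counter = itertools.count(1)
    for arm, spec in arms.items():
        n = spec["n"]
        response_seq = [
            r for r in ("CR", "PR", "SD", "PD") for _ in range(spec["responses"][r])
        ]
        assert len(response_seq) == n
        seqs = {
            key: [v for v, c in spec[key] for _ in range(c)]
            for key in ("sex", "stage", "ps", "regimen", "antihypertensive")
        }
        for i in range(n):
            jitter = (i % 5) - 2  # deterministic, mean-zero over full cycles
            before = spec["sbp_before"] + jitter
            after = before + spec["sbp_delta"] + ((i % 2) * 2 - 1)
            patients.append(
                CohortPatient(
                    patient_id=f"P{next(counter):03d}",
                    age_years=40.0 + (i * 46.0 / max(n - 1, 1)),
                    sex=seqs["sex"][i],
                    stage=seqs["stage"][i],
                    ps=seqs["ps"][i],
                    regimen=seqs["regimen"][i],
                    ppi_user=spec["ppi"],
                    antihypertensive_baseline=seqs["antihypertensive"][i],
                    response=response_seq[i],
                    sbp_series=((0, before), (1, after)),
                )
            )
    return patients


def reference_expression_matrix(n_per_group: int = 3) -> ExpressionMatrix:
    """Expression matrix whose group means equal the embedded reference means.

    Every sample in a group carries the group-mean value, so fold changes
    computed downstream equal ``2**(mean_treated - mean_vehicle)`` exactly.
    """
    genes = list(EXPRESSION_GROUP_MEANS)
    treated = [f"treated_{i + 1}" for i in range(n_per_group)]
    vehicle = [f"vehicle_{i + 1}" for i in range(n_per_group)]
    values = pd.DataFrame(
        {
            **{s: [EXPRESSION_GROUP_MEANS[g][0] for g in genes] for s in treated},
            **{s: [EXPRESSION_GROUP_MEANS[g][1] for g in genes] for s in vehicle},
        },
        index=genes,
    )
    groups = pd.Series(
        ["treated"] * n_per_group + ["vehicle"] * n_per_group, index=treated + vehicle
    )
    return ExpressionMatrix(values=values, groups=groups)
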