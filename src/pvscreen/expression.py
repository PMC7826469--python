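"""Two-group expression comparison and qPCR relative quantification.

The expression stage compares log2 intensity values between two sample
groups on a pathway gene subset: per-gene group means, the fold change
2**(meanA - meanB) on the original scale, and a Welch t-test p-value.  The
qPCR stage implements ddCq quantification (target Cq normalized to a
reference gene, then to a control condition; relative expression
2**(-ddCq)) and a Monte-Carlo Dunnett many-to-one test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pvscreen.errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PathwayGeneSet",
    "QpcrPlate",
    "ddct",
    "dunnett",
    "load_expression_matrix",
    "load_gene_set",
    "load_qpcr_plate",
    "pathway_compare",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities with a group label per sample."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: pd.Series  # index: sample ids, values: group labels

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise DataError(f"samples without group labels: {missing[:5]}")
        if self.groups.isna().any():
            raise DataError("missing group labels")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class PathwayGeneSet:
    """A named, non-empty set of gene identifiers."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"gene set {self.name!r} is empty")


def load_gene_set(path: str | Path, name: str | None = None) -> PathwayGeneSet:
    """Load a gene set from a text file, one identifier per line."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"gene set file not found: {path}")
    genes = {
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    }
    return PathwayGeneSet(name=name or path.stem, genes=frozenset(genes))


def load_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a series-matrix-style TSV into an :class:`ExpressionMatrix`.

    Layout: an ``ID_REF``-led header row of sample identifiers, one
    ``!group`` line mapping samples to group labels, then one row per gene.
    Lines starting ``!`` other than ``!group`` (as found in GEO
    series-matrix exports) are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"expression matrix not found: {path}")
    header: list[str] | None = None
    group_row: list[str] | None = None
    data_rows: list[list[str]] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "!group":
            group_row = parts[1:]
        elif parts[0].startswith("!"):
            continue
        elif header is None:
            header = parts
        else:
            data_rows.append(parts)
    if header is None or group_row is None or not data_rows:
        raise DataError(f"incomplete expression matrix in {path}")
    samples = header[1:]
    if len(group_row) != len(samples):
        raise DataError("group line and sample header disagree in length")
    values = pd.DataFrame(
        [[float(v) for v in row[1:]] for row in data_rows],
        index=[row[0] for row in data_rows],
        columns=samples,
    )
    groups = pd.Series(group_row, index=samples)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        samples = list(mat.values.columns)
        fh.write("ID_REF\t" + "\t".join(samples) + "\n")
        fh.write("!group\t" + "\t".join(mat.groups[s] for s in samples) + "\n")
        for gene, row in mat.values.iterrows():
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def pathway_compare(
    mat: ExpressionMatrix,
    genes: PathwayGeneSet,
    group_a: str,
    group_b: str,
    equal_var: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-group comparison per pathway gene.

    Returns a frame indexed by gene with columns ``mean_a``, ``mean_b``
    (log2 scale), ``fold_change`` (original scale, ``2**(mean_a -
    mean_b)``) and ``p`` (two-sided Welch t-test on the log2 values; pooled
    t with ``equal_var=True``), plus the list of requested genes absent from
    the matrix.  With a single sample in either group the fold change is
    still reported and ``p`` is NaN.
    """
    cols_a = mat.samples_in(group_a)
    cols_b = mat.samples_in(group_b)
    if not cols_a or not cols_b:
        raise DataError(f"both groups must have samples: {group_a!r}, {group_b!r}")

    present = [g for g in sorted(genes.genes) if g in mat.values.index]
    skipped = [g for g in sorted(genes.genes) if g not in mat.values.index]
    if skipped:
        logger.warning("%d gene(s) absent from matrix: %s ...", len(skipped), skipped[:5])

    records = []
    for gene in present:
        va = mat.values.loc[gene, cols_a].to_numpy(dtype=float)
        vb = mat.values.loc[gene, cols_b].to_numpy(dtype=float)
        mean_a, mean_b = float(va.mean()), float(vb.mean())
        if len(va) < 2 or len(vb) < 2:
            p = math.nan
        elif va.std() == 0.0 and vb.std() == 0.0:
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=equal_var).pvalue)
        records.append(
            {
                "gene": gene,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": 2.0 ** (mean_a - mean_b),
                "p": p,
            }
        )
    frame = pd.DataFrame.from_records(records).set_index("gene") if records else pd.DataFrame(
        columns=["mean_a", "mean_b", "fold_change", "p"]
    )
    return frame, skipped


@dataclass
class QpcrPlate:
    """Long-format qPCR results: one row per well aggregate."""

    wells: pd.DataFrame  # columns: sample, condition, gene, cq

    def __post_init__(self) -> None:
        required = {"sample", "condition", "gene", "cq"}
        missing = required - set(self.wells.columns)
        if missing:
            raise DataError(f"qPCR plate missing columns: {sorted(missing)}")
        cq = self.wells["cq"]
        if ((cq <= 0) | (cq >= 45)).any():
            raise DataError("Cq values must lie in (0, 45)")


def load_qpcr_plate(path: str | Path) -> QpcrPlate:
    """Load a long-format CSV (sample, condition, gene, cq)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"qPCR plate not found: {path}")
    return QpcrPlate(wells=pd.read_csv(path))


def ddct(
    plate: QpcrPlate,
    control_condition: str,
    target_gene: str,
    reference_gene: str = "36B4",
) -> pd.DataFrame:
    """Relative expression per condition by the ddCq method.

    Per sample: dCq = Cq(target) - Cq(reference).  Per condition:
    ddCq = mean dCq - mean control dCq, relative expression = 2**(-ddCq).
    The SEM column is that of the per-sample fold changes
    2**(-(dCq_i - mean control dCq)).  Samples missing either well are
    excluded with a warning.
    """
    wells = plate.wells
    target = wells[wells["gene"] == target_gene].set_index("sample")
    reference = wells[wells["gene"] == reference_gene].set_index("sample")
    if target.empty:
        raise DataError(f"no wells for target gene {target_gene!r}")
    if reference.empty:
        raise DataError(f"no wells for reference gene {reference_gene!r}")

    shared = target.index.intersection(reference.index)
    dropped = target.index.difference(reference.index)
    if len(dropped):
        logger.warning("samples lacking a reference well excluded: %s", list(dropped))

    dcq = (target.loc[shared, "cq"] - reference.loc[shared, "cq"]).astype(float)
    condition = target.loc[shared, "condition"]
    if control_condition not in set(condition):
        raise DataError(f"control condition {control_condition!r} absent")
    control_mean = float(dcq[condition == control_condition].mean())

    rows = []
    for cond, values in dcq.groupby(condition):
        ddcq = float(values.mean()) - control_mean
        folds = 2.0 ** (-(values - control_mean))
        sem = float(folds.std(ddof=1) / math.sqrt(len(folds))) if len(folds) > 1 else math.nan
        rows.append(
            {
                "condition": cond,
                "n": len(values),
                "ddcq": ddcq,
                "rel_expression": 2.0 ** (-ddcq),
                "sem": sem,
            }
        )
    out = pd.DataFrame(rows).set_index("condition")
    return out.loc[sorted(out.index, key=lambda c: (c != control_condition, c))]


def dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Many-to-one comparisons against a control with family-wise adjustment.

    For each non-control group a pooled-variance t statistic against the
    control is computed.  The family-wise null distribution of max |t| is
    sampled by Monte Carlo (``n_draws`` simulated experiments with the
    observed group sizes under a common normal); the adjusted p-value for
    group i is the fraction of draws whose max |t| reaches |t_i|, floored
    at the unadjusted two-sided pooled-t p so that adjusted >= unadjusted
    always holds.
    """
    if control not in groups:
        raise ConfigError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ConfigError("need at least one non-control group")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise DataError(f"group {name!r} has fewer than 2 samples")

    names = [k for k in arrays if k != control]
    x0 = arrays[control]
    sizes = [x0.size] + [arrays[k].size for k in names]
    n_total = sum(sizes)
    df = n_total - len(sizes)

    ss = sum(float(((arr - arr.mean()) ** 2).sum()) for arr in arrays.values())
    s2 = ss / df
    if s2 == 0.0:
        # all groups constant; any mean difference is degenerate
        t_obs = np.array(
            [math.inf if arrays[k].mean() != x0.mean() else 0.0 for k in names]
        )
    else:
        t_obs = np.array(
            [
                (arrays[k].mean() - x0.mean())
                / math.sqrt(s2 * (1.0 / arrays[k].size + 1.0 / x0.size))
                for k in names
            ]
        )

    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n_draws, n_total))
    bounds = np.cumsum([0] + sizes)
    means = np.empty((n_draws, len(sizes)))
    ss_sim = np.zeros(n_draws)
    for j in range(len(sizes)):
        block = draws[:, bounds[j] : bounds[j + 1]]
        means[:, j] = block.mean(axis=1)
        ss_sim += ((block - means[:, j : j + 1]) ** 2).sum(axis=1)
    s2_sim = ss_sim / df
    max_abs_t = np.zeros(n_draws)
    for j, k in enumerate(names, start=1):
        scale = np.sqrt(s2_sim * (1.0 / sizes[j] + 1.0 / sizes[0]))
        t_sim = (means[:, j] - means[:, 0]) / scale
        np.maximum(max_abs_t, np.abs(t_sim), out=max_abs_t)

    rows = []
    for j, k in enumerate(names):
        t = float(t_obs[j])
        if math.isinf(t):
            p_unadj = 0.0
            p_adj = 0.0
        else:
            p_unadj = float(2.0 * stats.t.sf(abs(t), df))
            p_adj = float((max_abs_t >= abs(t)).mean())
            p_adj = min(1.0, max(p_adj, p_unadj))
        rows.append(
            {
                "group": k,
                "mean_diff": float(arrays[k].mean() - x0.mean()),
                "t": t,
                "p_unadjusted": p_unadj,
                "p_adjusted": p_adj,
            }
        )
    return pd.DataFrame(rows).set_index("group")
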