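"""Expression-table and label I/O, qPCR relative quantification, bundled fixtures.

The central container is :class:`ExpressionMatrix`: a genes x samples matrix
of non-negative expression values with a declared scale:

* ``identity`` — values on their natural (linear) scale, e.g. qPCR relative
  copy counts; must be non-negative.
* ``log2`` — platform-provided log2 intensities (microarray/RNA-seq style).
* ``ln1p`` — values already transformed as ln(x + 1).

Gene and sample identifiers are matched case-insensitively (tables from
different sources mix e.g. ``FCAR``/``Fcar``); duplicates after case-folding
are rejected. Missing values are a hard error everywhere — the classifiers
use at most five genes per factor and silent imputation would corrupt them.

The module also bundles, as plain-text package data, the printed tables of
the study this package reproduces: the self-collected 50-subject plasma
RT-qPCR cohort, the published per-cohort classifier coefficients, and the
cohort metadata. See :func:`load_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FixtureLookupError, ParseError, ValidationError

SCALES = ("identity", "ln1p", "log2")
TISSUES = ("whole_blood", "plasma", "pbmc")

FIXTURE_NAMES = ("table2_cohort", "table4_panels", "table1_meta", "pbmc_panels")


def _check_unique_casefold(ids: Iterable[str], what: str) -> None:
    seen: dict[str, str] = {}
    for i in ids:
        key = str(i).strip().casefold()
        if key in seen:
            raise ValidationError(
                f"duplicate {what} identifier {i!r} (clashes with {seen[key]!r} "
                "after case-folding)"
            )
        seen[key] = i


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared scale tag."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    scale: str = "identity"

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g).strip() for g in self.gene_ids)
        self.sample_ids = tuple(str(s).strip() for s in self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r} (missing values are not imputed)"
            )
        if self.scale == "identity" and np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r} on identity scale"
            )
        _check_unique_casefold(self.gene_ids, "gene")
        _check_unique_casefold(self.sample_ids, "sample")
        self._gene_index = {g.casefold(): i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene: str) -> np.ndarray:
        """Expression of one gene over all samples (case-insensitive lookup)."""
        key = gene.strip().casefold()
        if key not in self._gene_index:
            raise ValidationError(f"gene {gene!r} not present in matrix")
        return self.values[self._gene_index[key]]

    def has_gene(self, gene: str) -> bool:
        return gene.strip().casefold() in self._gene_index

    def sample_expression(self, sample_id: str) -> dict[str, float]:
        """gene -> value mapping for one sample."""
        if sample_id not in self._sample_index:
            raise ValidationError(f"sample {sample_id!r} not present in matrix")
        col = self.values[:, self._sample_index[sample_id]]
        return dict(zip(self.gene_ids, col.tolist()))

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        rows = np.stack([self.gene_row(g) for g in genes])
        return ExpressionMatrix(tuple(genes), self.sample_ids, rows, self.scale)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self._sample_index]
        if missing:
            raise ValidationError(f"samples not present in matrix: {missing}")
        cols = [self._sample_index[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, cols], self.scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass
class SampleLabels:
    """Binary phenotype labels over an ordered set of samples."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    positive_class: str
    control_class: str

    def __post_init__(self) -> None:
        self.sample_ids = tuple(str(s).strip() for s in self.sample_ids)
        self.labels = tuple(str(l).strip() for l in self.labels)
        if len(self.sample_ids) != len(self.labels):
            raise ValidationError("sample_ids and labels differ in length")
        _check_unique_casefold(self.sample_ids, "sample")
        classes = {self.positive_class, self.control_class}
        unknown = sorted(set(self.labels) - classes)
        if unknown:
            raise ValidationError(
                f"labels contain classes {unknown} besides "
                f"{self.positive_class!r}/{self.control_class!r}"
            )
        if self.n_positive == 0 or self.n_control == 0:
            raise ValidationError("need at least one sample of each class")

    @property
    def n_positive(self) -> int:
        return sum(l == self.positive_class for l in self.labels)

    @property
    def n_control(self) -> int:
        return sum(l == self.control_class for l in self.labels)

    def is_positive(self) -> np.ndarray:
        """Boolean mask over samples in order."""
        return np.array([l == self.positive_class for l in self.labels])

    def label_of(self, sample_id: str) -> str:
        try:
            return self.labels[self.sample_ids.index(sample_id)]
        except ValueError:
            raise ValidationError(f"sample {sample_id!r} has no label") from None

    def subset(self, sample_ids: Iterable[str]) -> "SampleLabels":
        sample_ids = list(sample_ids)
        labels = [self.label_of(s) for s in sample_ids]
        return SampleLabels(tuple(sample_ids), tuple(labels), self.positive_class, self.control_class)


@dataclass
class CohortMeta:
    """Metadata of one cohort (accession, tissue, class sizes)."""

    cohort_id: str
    accession: str
    tissue: str
    population: str
    n_case: int
    n_control: int
    severity_split: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("n_case and n_control must both be >= 1")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path: str | Path,
    orientation: str = "genes_in_rows",
    scale: str = "identity",
) -> ExpressionMatrix:
    """Read a delimited expression table into a genes x samples matrix.

    The delimiter is inferred from the extension (``.csv`` -> comma,
    anything else -> tab). The first column holds row identifiers and the
    header row column identifiers. ``orientation`` says whether rows are
    genes or samples; the returned matrix is always genes x samples.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    numeric = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            numeric[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ParseError(
                f"{path.name}: non-numeric cell at row {row!r}, column {col!r}"
            ) from None
    rows = tuple(str(r) for r in df.index)
    cols = tuple(str(c) for c in df.columns)
    if orientation == "samples_in_rows":
        return ExpressionMatrix(cols, rows, numeric.T, scale)
    return ExpressionMatrix(rows, cols, numeric, scale)


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, orientation: str = "genes_in_rows"
) -> None:
    """Write a matrix as delimited text, round-tripping values exactly."""
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    df = matrix.to_frame()
    if orientation == "samples_in_rows":
        df = df.T
    df.index.name = "gene_id" if orientation == "genes_in_rows" else "sample_id"
    # str(float) is the shortest round-tripping decimal representation
    df.to_csv(path, sep=_sep_for(path))


def read_labels(
    path: str | Path, positive_class: str, control_class: str
) -> SampleLabels:
    """Read a two-column ``sample_id, label`` delimited file."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path.name}: expected two columns sample_id,label")
    sample_ids = tuple(df.iloc[:, 0].astype(str))
    labels = tuple(df.iloc[:, 1].astype(str))
    return SampleLabels(sample_ids, labels, positive_class, control_class)


def write_labels(labels: SampleLabels, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def relative_copy_count(ct_target: float, ct_reference: float) -> float:
    """qPCR relative quantification: 2**(Ct_reference - Ct_target).

    The reference gene (beta-actin in the bundled cohort) calibrates the
    cycle-threshold of the target gene; each cycle of difference is a factor
    of two in abundance. Equal thresholds give 1.0.
    """
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValidationError("cycle-threshold values must be finite")
    return float(2.0 ** (float(ct_reference) - float(ct_target)))


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

@dataclass
class Table2Cohort:
    """The self-collected plasma cohort: matrix plus both label sets."""

    matrix: ExpressionMatrix
    sepsis_vs_healthy: SampleLabels
    shock_vs_sepsis: SampleLabels  # over the 32 patients only
    subjects: pd.DataFrame = field(repr=False)


def _data_path(name: str) -> Path:
    return Path(str(resources.files(__package__) / "data" / name))


def _load_table2() -> Table2Cohort:
    matrix = read_expression_table(_data_path("table2_expression.tsv"), scale="identity")
    subjects = pd.read_csv(_data_path("table2_subjects.tsv"), sep="\t", dtype=str)
    sid = tuple(subjects["sample_id"])
    diag = subjects["diagnosis"]
    svh = SampleLabels(
        sid,
        tuple("healthy" if d == "Healthy control" else "sepsis" for d in diag),
        positive_class="sepsis",
        control_class="healthy",
    )
    patients = subjects[diag != "Healthy control"]
    shock = SampleLabels(
        tuple(patients["sample_id"]),
        tuple(
            "septic_shock" if "SEPTIC SHOCK" in d else "sepsis"
            for d in patients["diagnosis"]
        ),
        positive_class="septic_shock",
        control_class="sepsis",
    )
    return Table2Cohort(matrix, svh, shock, subjects)


def _load_panels(filename: str):
    from .max_logistic_core import panel_from_dict  # local import: avoid cycle

    raw = json.loads(_data_path(filename).read_text())
    return {name: panel_from_dict(d) for name, d in raw.items()}


def _load_meta() -> list[CohortMeta]:
    raw = json.loads(_data_path("table1_meta.json").read_text())
    return [CohortMeta(**d) for d in raw]


def load_fixture(name: str):
    """Load one of the bundled printed tables.

    ``table2_cohort`` -> :class:`Table2Cohort`;
    ``table4_panels`` / ``pbmc_panels`` -> dict of panel name ->
    :class:`~maxlogit.max_logistic_core.MaxLogisticPanel`;
    ``table1_meta`` -> list of :class:`CohortMeta`.
    """
    if name == "table2_cohort":
        return _load_table2()
    if name == "table4_panels":
        return _load_panels("table4_panels.json")
    if name == "pbmc_panels":
        return _load_panels("pbmc_panels.json")
    if name == "table1_meta":
        return _load_meta()
    raise FixtureLookupError(
        f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
    )
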