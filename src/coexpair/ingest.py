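"""Input readers and probe-to-gene collapse.

Reads a log2-normalised expression matrix (TSV, samples in columns), a
two-class sample assignment file, and an Affymetrix-style annotation CSV,
then collapses probe-set rows to gene-level rows by the per-sample maximum
rule: for every sample independently, a gene's value is the maximum over
its mapped probe sets in that sample.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: Missing-annotation marker used by Affymetrix NetAffx exports.
MISSING_MARKER = "---"
#: Separator indicating a probe set maps to more than one gene.
MULTI_MAP_SEPARATOR = "///"

#: Default NetAffx column names for each supported annotation ID type.
ANNOTATION_COLUMNS = {
    "unigene": "UniGene ID",
    "gene_symbol": "Gene Symbol",
    "ensembl": "Ensembl",
    "entrez": "Entrez Gene",
}

#: Smallest per-class sample count for which the Fisher z variance
#: 1/(n-3) is defined and positive.
MIN_SAMPLES_PER_CLASS = 4


@dataclass
class ExpressionMatrix:
    """Gene-by-sample (or probe-by-sample) log2 intensity table.

    Parameters
    ----------
    data:
        DataFrame with row identifiers in the index and sample names in
        the columns; values are log2 intensities.
    id_level:
        ``"probe"`` before annotation collapse, ``"gene"`` after.
    """

    data: pd.DataFrame
    id_level: str = "gene"

    def __post_init__(self):
        if self.id_level not in ("probe", "gene"):
            raise InputError(f"id_level must be 'probe' or 'gene', got {self.id_level!r}")
        if self.data.shape[0] < 2:
            raise InputError("expression matrix needs at least 2 rows")
        if self.data.shape[1] < 2:
            raise InputError("expression matrix needs at least 2 samples")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise InputError(f"duplicate sample names: {dups}")
        if self.id_level == "gene" and self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise InputError(f"duplicate gene identifiers: {dups}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise InputError(
                f"non-finite value at row {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class ClassMap:
    """Sample-to-class assignment for exactly two classes.

    ``class_names`` is ordered by first appearance in the input file and
    defines which class is "class 1" throughout the pipeline.
    """

    assignments: dict[str, str]
    class_names: tuple[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        labels = list(dict.fromkeys(self.assignments.values()))
        if self.class_names is None:
            self.class_names = tuple(labels)
        if len(self.class_names) != 2 or len(labels) != 2:
            raise InputError(
                f"exactly two classes required, got {len(labels)}: {labels}"
            )
        for cls in self.class_names:
            n = sum(1 for c in self.assignments.values() if c == cls)
            if n < MIN_SAMPLES_PER_CLASS:
                raise InputError(
                    f"class {cls!r} has {n} samples; minimum "
                    f"{MIN_SAMPLES_PER_CLASS} per class (Fisher z variance "
                    f"1/(n-3) requires n > 3)"
                )

    def samples(self, class_label: str) -> list[str]:
        """Sample IDs assigned to ``class_label``, in input order."""
        if class_label not in self.class_names:
            raise InputError(f"unknown class {class_label!r}")
        return [s for s, c in self.assignments.items() if c == class_label]

    def class_sizes(self) -> tuple[int, int]:
        return tuple(len(self.samples(c)) for c in self.class_names)


@dataclass
class AnnotationMap:
    """Single-mapped probe-set-ID -> annotation-ID lookup."""

    probe_to_id: dict[str, str]
    id_type: str = "gene_symbol"

    def __post_init__(self):
        if self.id_type not in ANNOTATION_COLUMNS:
            raise InputError(
                f"id_type must be one of {sorted(ANNOTATION_COLUMNS)}, "
                f"got {self.id_type!r}"
            )
        for probe, gene in self.probe_to_id.items():
            if not gene or gene == MISSING_MARKER or MULTI_MAP_SEPARATOR in gene:
                raise InputError(
                    f"annotation for probe {probe!r} is missing or multi-mapped: {gene!r}"
                )


def read_expression_matrix(
    path, delimiter: str = "\t", id_level: str = "gene"
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    First row: sample names. First column: row identifiers. All remaining
    cells must be numeric; a non-numeric cell is reported with its row and
    column labels.
    """
    with open(path) as handle:
        text = handle.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise InputError(f"{path}: empty file")
    header = lines[0].split(delimiter)
    sample_names = header[1:]
    if len(sample_names) != len(set(sample_names)):
        dups = sorted({s for s in sample_names if sample_names.count(s) > 1})
        raise InputError(f"{path}: duplicate sample names: {dups}")
    if len(lines) < 2:
        raise InputError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO(text), sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    # pandas reads literal "NA" cells as NaN, so treat missing source cells
    # as parse errors as well
    bad |= df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise InputError(
            f"{path}: non-numeric cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), id_level=id_level)


def read_class_assignments(path) -> ClassMap:
    """Read a sample-to-class file in either of two dialects.

    Two-column: one ``sample<TAB>class`` pair per line. Per-class listing:
    exactly two non-comment lines, each ``class<TAB>sample<TAB>sample...``.
    Lines starting with ``#`` are ignored.
    """
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise InputError(f"{path}: no class assignments found")
    assignments: dict[str, str] = {}
    if len(rows) == 2 and all(len(r) > 2 for r in rows):
        # per-class listing dialect
        for fields in rows:
            cls, samples = fields[0].strip(), [f.strip() for f in fields[1:] if f.strip()]
            for s in samples:
                if s in assignments:
                    raise InputError(f"{path}: sample {s!r} assigned twice")
                assignments[s] = cls
    else:
        for fields in rows:
            if len(fields) != 2:
                raise InputError(
                    f"{path}: expected 'sample<TAB>class', got {fields!r}"
                )
            sample, cls = fields[0].strip(), fields[1].strip()
            if sample in assignments:
                raise InputError(f"{path}: sample {sample!r} assigned twice")
            assignments[sample] = cls
    return ClassMap(assignments)


def read_annotation(
    path,
    id_type: str = "gene_symbol",
    probe_column: str = "Probe Set ID",
    annotation_column: str | None = None,
) -> AnnotationMap:
    """Read an Affymetrix NetAffx-style annotation CSV.

    Probes whose annotation cell is empty, the missing marker ``---``, or
    contains the multi-mapping separator ``///`` are excluded: only probes
    that map to a single identifier are retained.
    """
    if annotation_column is None:
        try:
            annotation_column = ANNOTATION_COLUMNS[id_type]
        except KeyError:
            raise InputError(
                f"id_type must be one of {sorted(ANNOTATION_COLUMNS)}, got {id_type!r}"
            ) from None
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in (probe_column, annotation_column):
        if col not in df.columns:
            raise InputError(
                f"{path}: column {col!r} not found; available columns: "
                f"{list(df.columns)}"
            )
    probe_to_id: dict[str, str] = {}
    for probe, gene in zip(df[probe_column], df[annotation_column]):
        if pd.isna(probe) or pd.isna(gene):
            continue
        gene = gene.strip()
        if not gene or gene == MISSING_MARKER or MULTI_MAP_SEPARATOR in gene:
            continue
        probe_to_id[probe.strip()] = gene
    if not probe_to_id:
        warnings.warn(
            f"{path}: no single-mapped probes found; annotation map is empty",
            stacklevel=2,
        )
    return AnnotationMap(probe_to_id, id_type=id_type)


def collapse_probes(expr: ExpressionMatrix, annot: AnnotationMap) -> ExpressionMatrix:
    """Collapse probe-level rows to gene-level rows.

    For each sample independently, the gene value is the maximum over the
    values of the probe sets mapped to that gene in that sample. Probes
    absent from the annotation map are dropped. Gene rows are ordered by
    identifier.
    """
    if expr.id_level != "probe":
        raise InputError("collapse_probes expects a probe-level matrix")
    mapped = [p for p in expr.row_ids if p in annot.probe_to_id]
    if not mapped:
        raise InputError("no probe in the expression matrix is present in the annotation map")
    dropped = len(expr.row_ids) - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropped %d unannotated probes", dropped)
    sub = expr.data.loc[mapped]
    genes = pd.Series([annot.probe_to_id[p] for p in mapped], index=sub.index)
    collapsed = sub.groupby(genes, sort=True).max()
    logger.info(
        "collapse_probes: %d probes -> %d genes", len(mapped), collapsed.shape[0]
    )
    return ExpressionMatrix(collapsed, id_level="gene")


def check_consistency(expr: ExpressionMatrix, cls: ClassMap) -> None:
    """Verify every matrix sample is assigned and vice versa."""
    matrix_samples = set(expr.sample_ids)
    assigned = set(cls.assignments)
    missing = matrix_samples - assigned
    extra = assigned - matrix_samples
    if missing or extra:
        raise InputError(
            f"sample mismatch between matrix and class file: "
            f"unassigned={sorted(missing)}, unknown={sorted(extra)}"
        )
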