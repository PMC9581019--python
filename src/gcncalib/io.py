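"""Reading and writing the delimited-text formats the toolkit touches.

Expression matrices are stored as delimited text (TSV or CSV, auto-detected)
with a header row of gene identifiers and an optional first column of sample
identifiers.  GEO "series matrix" style tables (genes as rows) are accepted
via ``orientation="genes_by_samples"`` and transposed on load.  Values are
used exactly as deposited — no log transform or normalization is applied.

Annotation maps are three-column delimited text: term id, namespace
(BP/CC/MF), gene id.  Module assignments are two-column text: gene id,
integer label (0 = unassigned).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "AnnotationMap",
    "ModuleAssignment",
    "ValidationError",
    "ParseError",
    "NAMESPACES",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_modules",
    "write_modules",
]

NAMESPACES = ("BP", "CC", "MF")


class ValidationError(ValueError):
    """Input violates a structural invariant (shape, duplicates, domain)."""


class ParseError(ValueError):
    """Input file could not be parsed as the expected format."""


@dataclass
class ExpressionMatrix:
    """A samples x genes grid of finite, real expression levels.

    ``values`` has shape (m, n) with m = number of samples and n = number
    of genes.  Identifier lists carry the deposited order; loading never
    reorders genes or samples.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValidationError(
                f"expression matrix needs at least 2 samples and 2 genes, got {m}x{n}"
            )
        if len(self.sample_ids) != m:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {m} rows"
            )
        if len(self.gene_ids) != n:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {n} columns")
        if len(set(self.gene_ids)) != n:
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != m:
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class AnnotationMap:
    """term id -> (namespace, set of gene ids); the carrier for enrichment.

    Namespaces mirror the three Gene Ontology ontologies (BP, CC, MF) but
    the map itself is a generic flat term -> gene-set table.
    """

    entries: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (ns, genes) in self.entries.items():
            if ns not in NAMESPACES:
                raise ValidationError(
                    f"term {term!r}: namespace {ns!r} not in {NAMESPACES}"
                )
            if not genes:
                raise ValidationError(f"term {term!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.entries)

    def terms(self) -> list[str]:
        return list(self.entries)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, gs in self.entries.values():
            out |= gs
        return frozenset(out)


@dataclass
class ModuleAssignment:
    """gene id -> integer module label, 0 meaning unassigned.

    Non-zero labels are contiguous integers 1..n_modules ordered by
    decreasing module size (renumbering happens at detection time).
    """

    labels: dict[str, int]

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("empty module assignment")
        for g, lab in self.labels.items():
            if not isinstance(lab, (int, np.integer)) or lab < 0:
                raise ValidationError(f"gene {g!r}: label {lab!r} is not an int >= 0")
        self.labels = {g: int(v) for g, v in self.labels.items()}

    @property
    def n_modules(self) -> int:
        return len({v for v in self.labels.values() if v > 0})

    @property
    def n_genes(self) -> int:
        return len(self.labels)

    def module_members(self, label: int) -> list[str]:
        return [g for g, v in self.labels.items() if v == label]

    def unassigned_fraction(self) -> float:
        return sum(1 for v in self.labels.values() if v == 0) / len(self.labels)

    def as_array(self, gene_order: list[str] | None = None) -> np.ndarray:
        order = gene_order if gene_order is not None else list(self.labels)
        return np.array([self.labels[g] for g in order], dtype=int)


def _sniff_delimiter(sample: str) -> str:
    """Auto-detect tab vs comma; header is required so the first line decides."""
    first = sample.splitlines()[0] if sample else ""
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


_NA_TOKENS = {"", "na", "nan", "null", "none"}


def read_expression(
    path: str | Path,
    orientation: str = "samples_by_genes",
    missing: str = "error",
) -> ExpressionMatrix:
    """Load a delimited expression table into samples x genes orientation.

    Parameters
    ----------
    path
        Delimited text file.  Header row of identifiers; first column holds
        row identifiers (sample ids, or gene ids when
        ``orientation="genes_by_samples"``).
    orientation
        ``"samples_by_genes"`` (default) or ``"genes_by_samples"`` (the GEO
        series-matrix layout; transposed on load).
    missing
        ``"error"`` (default): an NA/empty cell is a parse error — the
        method assumes a complete matrix.  ``"impute"``: missing cells are
        filled with the gene's mean over the observed samples.

    Raises
    ------
    ParseError
        Non-numeric cell (missing values too, under the default policy).
    ValidationError
        Duplicate identifiers, fewer than 2 rows/columns, or a gene with
        no observed values under ``missing="impute"``.
    """
    path = Path(path)
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if missing not in ("error", "impute"):
        raise ValidationError(f"unknown missing policy {missing!r}")
    text = path.read_text()
    delim = _sniff_delimiter(text)
    rows = [r for r in csv.reader(text.splitlines(), delimiter=delim) if r]
    if len(rows) < 2:
        raise ValidationError(f"{path}: fewer than 2 data rows")
    header = [h.strip().strip('"') for h in rows[0]]
    body = rows[1:]
    ncols = len(body[0])
    # Header may or may not carry a label for the id column.
    if len(header) == ncols:
        col_ids = header[1:]
    elif len(header) == ncols - 1:
        col_ids = header
    else:
        raise ParseError(
            f"{path}: header has {len(header)} fields but body rows have {ncols}"
        )
    row_ids: list[str] = []
    data = np.empty((len(body), ncols - 1), dtype=float)
    for i, row in enumerate(body):
        if len(row) != ncols:
            raise ParseError(f"{path}: row {i + 2} has {len(row)} fields, expected {ncols}")
        row_ids.append(row[0].strip().strip('"'))
        for j, tok in enumerate(row[1:]):
            token = tok.strip().strip('"')
            if token.lower() in _NA_TOKENS:
                if missing == "error":
                    raise ParseError(
                        f"{path}: missing value at row {i + 2}, "
                        f"column {col_ids[j]!r} (use missing='impute' to fill)"
                    )
                data[i, j] = np.nan
                continue
            try:
                data[i, j] = float(token)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} at row {i + 2}, "
                    f"column {col_ids[j]!r}"
                ) from None
    if missing == "impute" and np.isnan(data).any():
        # per-gene mean over observed cells; genes are columns unless the
        # table is in genes-by-samples layout
        gene_axis = 0 if orientation == "genes_by_samples" else 1
        import warnings

        with warnings.catch_warnings():
            # a fully-missing gene yields an empty-slice warning here and a
            # ValidationError just below
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(data, axis=1 - gene_axis)
        if np.isnan(means).any():
            raise ValidationError(f"{path}: a gene has no observed values")
        rows, cols = np.where(np.isnan(data))
        data[rows, cols] = means[rows if gene_axis == 0 else cols]
    if orientation == "genes_by_samples":
        return ExpressionMatrix(values=data.T, sample_ids=col_ids, gene_ids=row_ids)
    return ExpressionMatrix(values=data, sample_ids=row_ids, gene_ids=col_ids)


def write_expression(
    expr: ExpressionMatrix,
    path: str | Path,
    orientation: str = "samples_by_genes",
    delimiter: str = "\t",
) -> None:
    """Write an expression matrix as delimited text (inverse of read)."""
    df = expr.to_frame()
    if orientation == "genes_by_samples":
        df = df.T
    df.to_csv(path, sep=delimiter, index_label="id")


def read_annotation(path: str | Path) -> AnnotationMap:
    """Load a three-column (term, namespace, gene) table into an AnnotationMap.

    Rows are grouped by term; a term listed under two namespaces is a
    validation error, as is an unknown namespace token or an empty file.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValidationError(f"{path}: empty annotation file")
    delim = _sniff_delimiter(text)
    entries: dict[str, tuple[str, set[str]]] = {}
    for lineno, row in enumerate(csv.reader(text.splitlines(), delimiter=delim), 1):
        if not row or not "".join(row).strip():
            continue
        if lineno == 1 and [c.strip().lower() for c in row[:3]] == [
            "term", "namespace", "gene",
        ]:
            continue  # optional header
        if len(row) < 3:
            raise ParseError(f"{path}: line {lineno} has {len(row)} fields, expected 3")
        term, ns, gene = (c.strip() for c in row[:3])
        if ns not in NAMESPACES:
            raise ValidationError(
                f"{path}: line {lineno}: unknown namespace {ns!r} (expected BP/CC/MF)"
            )
        if term in entries:
            prev_ns, genes = entries[term]
            if prev_ns != ns:
                raise ValidationError(
                    f"{path}: term {term!r} listed under both {prev_ns!r} and {ns!r}"
                )
            genes.add(gene)
        else:
            entries[term] = (ns, {gene})
    if not entries:
        raise ValidationError(f"{path}: no annotation rows")
    return AnnotationMap({t: (ns, frozenset(gs)) for t, (ns, gs) in entries.items()})


def write_annotation(anno: AnnotationMap, path: str | Path) -> None:
    """Write an AnnotationMap as (term, namespace, gene) TSV."""
    with open(path, "w") as fh:
        fh.write("term\tnamespace\tgene\n")
        for term, (ns, genes) in anno.entries.items():
            for g in sorted(genes):
                fh.write(f"{term}\t{ns}\t{g}\n")


def write_modules(assignment: ModuleAssignment, path: str | Path) -> None:
    """Write gene -> module label as two-column TSV, preserving gene order."""
    with open(path, "w") as fh:
        fh.write("gene\tmodule\n")
        for g, lab in assignment.labels.items():
            fh.write(f"{g}\t{lab}\n")


def read_modules(path: str | Path) -> ModuleAssignment:
    """Read back a two-column (gene, label) table written by write_modules."""
    path = Path(path)
    labels: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if lineno == 1 and parts[0].strip().lower() == "gene":
            continue
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields")
        try:
            labels[parts[0].strip()] = int(parts[1])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-integer label {parts[1]!r}"
            ) from None
    return ModuleAssignment(labels)
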