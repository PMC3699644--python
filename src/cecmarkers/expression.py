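"""Core containers for gene-level expression data and their TSV readers/writers.

The analysis revolves around three small tables:

* a gene x sample expression matrix holding either raw uniquely-mapped read
  counts or depth-normalized reads-per-million (RPM),
* per-sample metadata (class label + library size, i.e. total uniquely
  mapping reads), and
* per-gene annotation (functional categories plus an externally sourced
  cross-tissue specificity verdict).

Gene identifiers are matched case-insensitively but preserved exactly as
given; no alias resolution is attempted (symbols such as ZO-1 vs TJP1 are
taken verbatim). Duplicate gene rows are a hard error, never merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the four sample classes of the core study design
CORE_CLASSES = ("cec_young", "cec_old", "cec_culture", "stroma")

#: recognised units for an expression matrix
UNITS = ("counts", "rpm")


class ExpressionError(ValueError):
    """Raised for malformed expression, metadata or annotation inputs."""


def _check_unique_genes(gene_ids, where: str = "table") -> None:
    lowered = pd.Index([str(g).casefold() for g in gene_ids])
    if lowered.has_duplicates:
        dupes = sorted({g for g, low in zip(gene_ids, lowered)
                        if (lowered == low).sum() > 1})
        raise ExpressionError(
            f"duplicate gene identifier(s) in {where}: {', '.join(map(str, dupes))}"
        )


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample expression values with a declared unit.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, one column per sample.
    unit
        ``"counts"`` (raw uniquely-mapped reads) or ``"rpm"``.
    """

    values: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ExpressionError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.values, pd.DataFrame):
            raise ExpressionError("values must be a pandas DataFrame")
        _check_unique_genes(self.values.index, "expression matrix")
        if pd.Index(self.values.columns).has_duplicates:
            raise ExpressionError("duplicate sample identifiers in expression matrix")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ExpressionError("missing cells are not allowed; encode absence as 0")
        if (arr < 0).any():
            raise ExpressionError("expression values must be non-negative")
        # case-insensitive gene lookup map
        self._lookup = {str(g).casefold(): g for g in self.values.index}

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def resolve_gene(self, gene_id: str):
        """Return the stored spelling for *gene_id*, or None if absent."""
        return self._lookup.get(str(gene_id).casefold())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        resolved = [self.resolve_gene(g) for g in gene_ids]
        present = [g for g in resolved if g is not None]
        return ExpressionMatrix(self.values.loc[present].copy(), unit=self.unit)


@dataclass
class SampleMetadata:
    """Per-sample class label and sequencing depth.

    ``table`` is indexed by sample_id with columns ``class_label`` and
    ``library_size`` (total uniquely mapping reads; must be positive when the
    matrix it describes holds raw counts).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"class_label", "library_size"}
        missing = required - set(self.table.columns)
        if missing:
            raise ExpressionError(f"metadata missing column(s): {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ExpressionError("duplicate sample_id in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def class_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "class_label"])

    def library_size(self, sample_id: str) -> int:
        size = self.table.loc[sample_id, "library_size"]
        if pd.isna(size) or size <= 0:
            raise ExpressionError(f"sample {sample_id!r} has no positive library size")
        return int(size)

    def samples_of_class(self, class_label: str) -> list[str]:
        mask = self.table["class_label"] == class_label
        return list(self.table.index[mask])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must have exactly one metadata row."""
        missing = [s for s in matrix.sample_ids if s not in self.table.index]
        if missing:
            raise ExpressionError(f"samples without metadata: {missing}")


@dataclass
class GeneAnnotation:
    """Per-gene category memberships and external tissue-specificity verdict.

    The verdict is one of ``specific``, ``ubiquitous``, ``inconclusive`` or
    ``restricted:<site>`` and encodes an external cross-tissue expression
    judgement (e.g. a BioGPS-style lookup); it is consumed as an input, never
    computed here. Unannotated genes default to ``inconclusive``.
    """

    categories: dict = field(default_factory=dict)   # gene_id -> frozenset of labels
    specificity: dict = field(default_factory=dict)  # gene_id -> verdict string

    def __post_init__(self) -> None:
        self.categories = {str(g): frozenset(c) for g, c in self.categories.items()}
        self.specificity = {str(g): str(v) for g, v in self.specificity.items()}
        for gene, verdict in self.specificity.items():
            if verdict not in ("specific", "ubiquitous", "inconclusive") \
                    and not verdict.startswith("restricted:"):
                raise ExpressionError(
                    f"gene {gene!r}: unknown specificity verdict {verdict!r}")
        self._cat_lookup = {g.casefold(): g for g in self.categories}
        self._spec_lookup = {g.casefold(): g for g in self.specificity}

    def categories_of(self, gene_id: str) -> frozenset:
        key = self._cat_lookup.get(str(gene_id).casefold())
        return self.categories.get(key, frozenset()) if key else frozenset()

    def specificity_of(self, gene_id: str) -> str:
        key = self._spec_lookup.get(str(gene_id).casefold())
        return self.specificity.get(key, "inconclusive") if key else "inconclusive"

    def known_categories(self) -> set:
        out: set = set()
        for cats in self.categories.values():
            out |= cats
        return out

    def genes_in_category(self, category: str) -> list[str]:
        return [g for g, cats in self.categories.items() if category in cats]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_numeric_cell(raw: str, gene, column: str) -> float:
    """Parse one body cell, stripping thousands separators ("2,312" -> 2312)."""
    text = str(raw).strip().replace(",", "")
    try:
        value = float(text)
    except ValueError:
        raise ExpressionError(
            f"non-numeric cell {raw!r} at gene {gene!r}, sample {column!r}"
        ) from None
    return value


def read_expression_table(path, unit: str) -> ExpressionMatrix:
    """Read a tab-separated expression table (genes in rows, samples in columns).

    The first column holds gene identifiers and the header row sample
    identifiers. Thousands separators in numeric cells are accepted and
    stripped, so a printed value like ``2,312`` parses as 2312.
    """
    if unit not in UNITS:
        raise ExpressionError(f"unknown unit {unit!r}; expected one of {UNITS}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.map(str)
    _check_unique_genes(raw.index, f"expression table {path}")
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for gene, cell in raw[col].items():
            if pd.isna(cell):
                raise ExpressionError(
                    f"missing cell at gene {gene!r}, sample {col!r}")
            parsed.loc[gene, col] = _parse_numeric_cell(cell, gene, col)
    return ExpressionMatrix(parsed, unit=unit)


def write_expression_table(matrix: ExpressionMatrix, path, float_format="%.2f") -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=float_format)


def read_sample_metadata(path) -> SampleMetadata:
    """Read metadata TSV with fixed header ``sample_id  class_label  library_size``."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "class_label": str})
    if "sample_id" not in table.columns:
        raise ExpressionError("metadata must carry a 'sample_id' column")
    table = table.set_index("sample_id")
    table["library_size"] = pd.to_numeric(
        table["library_size"].astype(str).str.replace(",", "", regex=False))
    return SampleMetadata(table)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    out = meta.table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read annotation TSV (``gene_id``, semicolon-delimited ``categories``,
    ``specificity``)."""
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("gene_id", "categories", "specificity"):
        if col not in table.columns:
            raise ExpressionError(f"annotation must carry a {col!r} column")
    categories, specificity = {}, {}
    for _, row in table.iterrows():
        gene = str(row["gene_id"])
        cats = frozenset(c.strip() for c in row["categories"].split(";") if c.strip())
        categories[gene] = cats
        if row["specificity"].strip():
            specificity[gene] = row["specificity"].strip()
    return GeneAnnotation(categories=categories, specificity=specificity)


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    genes = sorted(set(annotation.categories) | set(annotation.specificity))
    rows = [{
        "gene_id": g,
        "categories": ";".join(sorted(annotation.categories_of(g))),
        "specificity": annotation.specificity_of(g),
    } for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "categories", "specificity"]).to_csv(
        path, sep="\t", index=False)


def matrix_from_arrays(gene_ids, sample_ids, values, unit="counts") -> ExpressionMatrix:
    """Build an ExpressionMatrix from plain arrays/lists."""
    frame = pd.DataFrame(np.asarray(values, dtype=float),
                         index=list(gene_ids), columns=list(sample_ids))
    return ExpressionMatrix(frame, unit=unit)


def metadata_from_records(records) -> SampleMetadata:
    """Build SampleMetadata from (sample_id, class_label, library_size) triples."""
    frame = pd.DataFrame(
        [{"sample_id": s, "class_label": c, "library_size": n} for s, c, n in records]
    ).set_index("sample_id")
    return SampleMetadata(frame)
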