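"""Marker-candidate selection: rankings, filter cascades, and the flaw taxonomy.

Two filter cascades screen the four-class corneal design (young CEC-DM,
old CEC-DM, CEC culture, corneal stroma):

* the *stable-CEC* filter keeps genes expressed above an RPM floor in all
  three CEC classes, at least two-fold higher in young CEC than in stroma,
  and within two-fold between young and old CEC (a stable, culture-surviving
  CEC signal);
* the *stroma-absent* filter keeps genes above the same CEC floor but
  essentially silent in stroma (RPM below 1), the property that separates
  CECs from contaminating keratocytes/stromal fibroblasts.

Threshold comparisons are strict (>, <) on unrounded values, with one
deliberate exception: both fold-change criteria of the stable filter are
evaluated on the fold rounded half-up to one decimal, the age window being
the inclusive interval [1/max_age_fold, max_age_fold]. Published candidate
tables print their own fold-change columns computed from unrounded source
values; when such columns are supplied via ``fold_overrides`` they take
precedence over folds recomputed from the (rounded) RPM columns, treating
each input table as authoritative for itself.

The four-way flaw taxonomy disqualifies previously proposed markers:
``low_in_young`` (young RPM < 100), ``absent_in_culture`` (culture RPM < 10),
``no_stroma_contrast`` (young/stroma fold defined and < 5) and
``nonspecific`` (external verdict: ubiquitously expressed across tissues).
A ``restricted:<site>`` or ``inconclusive`` verdict populates the record's
specificity note without raising the flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .expression import (CORE_CLASSES, ExpressionError, ExpressionMatrix,
                         GeneAnnotation, SampleMetadata)
from .normalize import FoldChange, fold_change, round_half_up

FLAW_LABELS = ("low_in_young", "absent_in_culture", "no_stroma_contrast",
               "nonspecific")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the filter cascades (defaults are the study's)."""

    min_rpm_expressed: float = 10.0     # RPM floor in the three CEC classes
    min_fold_vs_stroma: float = 2.0     # young/stroma contrast
    max_age_fold: float = 2.0           # two-sided young/old window
    max_stroma_rpm_absent: float = 1.0  # stroma ceiling of the absence filter

    def __post_init__(self) -> None:
        for name in ("min_rpm_expressed", "min_fold_vs_stroma",
                     "max_age_fold", "max_stroma_rpm_absent"):
            if getattr(self, name) <= 0:
                raise ExpressionError(f"criterion {name} must be > 0")


@dataclass(frozen=True)
class MarkerRecord:
    """Per-gene RPMs, fold changes, flaw flags and specificity note."""

    gene_id: str
    rpm: dict  # class label -> RPM
    fold_young_old: FoldChange
    fold_young_culture: FoldChange
    fold_young_stroma: FoldChange
    flaws: frozenset = frozenset()
    specificity_note: str = ""


def class_rpms(matrix: ExpressionMatrix, meta: SampleMetadata,
               classes=CORE_CLASSES) -> pd.DataFrame:
    """Per-class RPM (mean over the samples of each class), genes in rows."""
    if matrix.unit != "rpm":
        raise ExpressionError("class_rpms expects an RPM matrix")
    meta.validate_against(matrix)
    columns = {}
    for label in classes:
        samples = [s for s in meta.samples_of_class(label) if s in matrix.sample_ids]
        if not samples:
            raise ExpressionError(f"no sample of class {label!r} in the matrix")
        columns[label] = matrix.values[samples].mean(axis=1)
    return pd.DataFrame(columns)


def build_record(gene_id: str, rpms: dict) -> MarkerRecord:
    y, o, c, s = (rpms[k] for k in CORE_CLASSES)
    return MarkerRecord(
        gene_id=gene_id,
        rpm=dict(rpms),
        fold_young_old=fold_change(y, o, "cec_young", "cec_old"),
        fold_young_culture=fold_change(y, c, "cec_young", "cec_culture"),
        fold_young_stroma=fold_change(y, s, "cec_young", "stroma"),
    )


def _ranked(records: list[MarkerRecord]) -> list[MarkerRecord]:
    """Descending young-CEC RPM, ties broken lexicographically by gene id."""
    return sorted(records, key=lambda r: (-r.rpm["cec_young"], r.gene_id))


def rank_top_expressed(matrix: ExpressionMatrix, meta: SampleMetadata,
                       class_label: str, n: int) -> list[str]:
    """Top-*n* genes by descending RPM in one class (lexicographic ties)."""
    if n < 1:
        raise ExpressionError("n must be >= 1")
    values = class_rpms(matrix, meta, classes=(class_label,))[class_label]
    if n > len(values):
        warnings.warn(
            f"requested top {n} of only {len(values)} genes; returning all",
            stacklevel=2)
        n = len(values)
    order = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [gene for gene, _ in order[:n]]


def _fold_for_test(recomputed: FoldChange, override) -> FoldChange:
    if override is None or pd.isna(override):
        return recomputed
    return replace(recomputed, value=float(override))


def stable_cec_filter(matrix: ExpressionMatrix, meta: SampleMetadata,
                      criteria: FilterCriteria = FilterCriteria(),
                      fold_overrides: pd.DataFrame | None = None
                      ) -> list[MarkerRecord]:
    """Keep genes with a stable, culture-surviving CEC expression signal.

    Criteria: RPM strictly above ``min_rpm_expressed`` in young, old and
    cultured CEC; young/stroma fold (rounded to 1 decimal) at least
    ``min_fold_vs_stroma`` — an undefined fold from stroma RPM 0 counts as
    maximal contrast and passes; young/old fold rounded to 1 decimal inside
    the inclusive window [1/max_age_fold, max_age_fold].

    ``fold_overrides``, if given, is a gene-indexed frame with optional
    ``fold_young_stroma`` / ``fold_young_old`` columns whose values replace
    the recomputed folds in the threshold tests (for tables that publish
    folds computed from unrounded source values).
    """
    table = class_rpms(matrix, meta)
    kept = []
    for gene, row in table.iterrows():
        record = build_record(gene, row.to_dict())
        if not all(row[c] > criteria.min_rpm_expressed
                   for c in ("cec_young", "cec_old", "cec_culture")):
            continue
        overrides = (fold_overrides.loc[gene]
                     if fold_overrides is not None and gene in fold_overrides.index
                     else {})
        f_stroma = _fold_for_test(record.fold_young_stroma,
                                  overrides.get("fold_young_stroma")
                                  if len(overrides) else None)
        if f_stroma.defined and f_stroma.rounded < criteria.min_fold_vs_stroma:
            continue
        f_age = _fold_for_test(record.fold_young_old,
                               overrides.get("fold_young_old")
                               if len(overrides) else None)
        if not f_age.defined:
            continue
        low = round_half_up(1.0 / criteria.max_age_fold, 1)
        if not low <= f_age.rounded <= criteria.max_age_fold:
            continue
        kept.append(record)
    return _ranked(kept)


def stroma_absent_filter(matrix: ExpressionMatrix, meta: SampleMetadata,
                         criteria: FilterCriteria = FilterCriteria()
                         ) -> list[MarkerRecord]:
    """Keep genes expressed in all three CEC classes but silent in stroma."""
    table = class_rpms(matrix, meta)
    kept = []
    for gene, row in table.iterrows():
        if not all(row[c] > criteria.min_rpm_expressed
                   for c in ("cec_young", "cec_old", "cec_culture")):
            continue
        if not row["stroma"] < criteria.max_stroma_rpm_absent:
            continue
        kept.append(build_record(gene, row.to_dict()))
    return _ranked(kept)


def classify_flaws(record: MarkerRecord, annotation: GeneAnnotation
                   ) -> MarkerRecord:
    """Attach the marker-adequacy flaw set to a record (total, idempotent)."""
    flaws = set()
    if record.rpm["cec_young"] < 100:
        flaws.add("low_in_young")
    if record.rpm["cec_culture"] < 10:
        flaws.add("absent_in_culture")
    f = record.fold_young_stroma
    if f.defined and f.value < 5:
        flaws.add("no_stroma_contrast")
    verdict = annotation.specificity_of(record.gene_id)
    note = ""
    if verdict == "ubiquitous":
        flaws.add("nonspecific")
    elif verdict.startswith("restricted:"):
        note = verdict.split(":", 1)[1]
    elif verdict == "inconclusive":
        note = "inconclusive"
    return replace(record, flaws=frozenset(flaws), specificity_note=note)


def select_category(matrix: ExpressionMatrix, meta: SampleMetadata,
                    annotation: GeneAnnotation, category: str,
                    criteria: FilterCriteria = FilterCriteria(),
                    fold_overrides: pd.DataFrame | None = None
                    ) -> list[MarkerRecord]:
    """The stable-CEC filter restricted to genes annotated with *category*."""
    known = annotation.known_categories()
    if category not in known:
        raise ExpressionError(
            f"unknown category {category!r}; known: {sorted(known)}")
    members = {str(g).casefold() for g in annotation.genes_in_category(category)}
    sub = matrix.subset_genes(
        [g for g in matrix.gene_ids if str(g).casefold() in members])
    if not sub.gene_ids:
        return []
    return stable_cec_filter(sub, meta, criteria, fold_overrides)


def extract_gene_set(matrix: ExpressionMatrix, meta: SampleMetadata,
                     genes) -> tuple[list[MarkerRecord], list[str]]:
    """Rows for an explicit gene list, ranked by descending young-CEC RPM.

    Returns ``(records, missing)`` where *missing* lists requested genes not
    present in the matrix (matching is case-insensitive).
    """
    genes = list(genes)
    if not genes:
        raise ExpressionError("gene list must be non-empty")
    present, missing = [], []
    for gene in genes:
        resolved = matrix.resolve_gene(gene)
        (present if resolved is not None else missing).append(
            resolved if resolved is not None else gene)
    table = class_rpms(matrix.subset_genes(present), meta) if present else None
    records = [build_record(g, row.to_dict()) for g, row in table.iterrows()] \
        if table is not None else []
    return _ranked(records), missing


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["gene_id", "rpm_cec_young", "rpm_cec_old", "rpm_cec_culture",
                   "rpm_stroma", "fold_young_old", "fold_young_culture",
                   "fold_young_stroma", "flaws", "specificity_note"]


def write_marker_report(records: list[MarkerRecord], path) -> None:
    """Write a deterministic TSV report plus a full-precision JSON twin.

    RPMs print at 2 decimals and folds at 1 decimal (half-up) in the TSV;
    the JSON twin (same path with ``.json`` suffix) keeps full precision.
    """
    rows = []
    for r in records:
        rows.append({
            "gene_id": r.gene_id,
            "rpm_cec_young": f"{round_half_up(r.rpm['cec_young'], 2):.2f}",
            "rpm_cec_old": f"{round_half_up(r.rpm['cec_old'], 2):.2f}",
            "rpm_cec_culture": f"{round_half_up(r.rpm['cec_culture'], 2):.2f}",
            "rpm_stroma": f"{round_half_up(r.rpm['stroma'], 2):.2f}",
            "fold_young_old": r.fold_young_old.display,
            "fold_young_culture": r.fold_young_culture.display,
            "fold_young_stroma": r.fold_young_stroma.display,
            "flaws": ";".join(sorted(r.flaws)),
            "specificity_note": r.specificity_note,
        })
    frame = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False)

    twin = str(path)
    twin = twin[:-4] + ".json" if twin.endswith(".tsv") else twin + ".json"
    payload = [{
        "gene_id": r.gene_id,
        "rpm": r.rpm,
        "fold_young_old": r.fold_young_old.value,
        "fold_young_culture": r.fold_young_culture.value,
        "fold_young_stroma": r.fold_young_stroma.value,
        "flaws": sorted(r.flaws),
        "specificity_note": r.specificity_note,
    } for r in records]
    with open(twin, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1)
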