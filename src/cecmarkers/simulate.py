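"""Seeded generators for count matrices and qPCR plates with planted structure.

The count generator emulates the study design the pipeline targets: one
pooled library per class for the four corneal classes (young CEC-DM, old
CEC-DM, CEC culture, corneal stroma), sequencing depths drawn uniformly from
1.8–4.6 million uniquely mapping reads, and negative-binomial counts
(var = m + φ·m²) around archetype-specific class-mean RPM templates:

* ``pan_cec``        — expressed in all three CEC classes, essentially absent
                       from stroma (the CYYR1-like panel archetype);
* ``in_vivo_only``   — high in fresh CEC-DM, lost in culture (CA3-like);
* ``culture_induced``— strongly up in culture (MGP-like);
* ``stroma_marker``  — stroma-restricted;
* ``ubiquitous``     — uniform housekeeping-level expression, annotated
                       ubiquitous (must never pass the screens);
* ``ocular_non_cec`` — CEC-expressed but flagged ``restricted:<site>`` by the
                       external specificity verdict (MYOC-like);
* ``background``     — a shared low lognormal baseline, identical across
                       classes so expected fold changes are 1.

The dispersion default (0.05) keeps the planted archetypes recoverable by
construction through the two-fold young/old window of the stable-CEC filter
with a single library per class; see the methods note for the calculation.
Donor-level biological variance is unidentifiable in a pooled design and
defaults to off (``donor_ct_sd`` applies only to the qPCR generator).

The Ct generator inverts an abundance table to threshold cycles,
Ct = base − log2(abundance) + Gaussian replicate noise, with housekeeping
assays at constant unit abundance, so a noiseless plate round-trips through
ΔΔCt quantification exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import (CORE_CLASSES, ExpressionError, ExpressionMatrix,
                         GeneAnnotation, SampleMetadata)
from .qpcr import DEFAULT_HOUSEKEEPING, CtTable

#: class-mean RPM templates (young, old, culture, stroma) per archetype
ARCHETYPE_TEMPLATES = {
    "pan_cec": (150.0, 140.0, 60.0, 0.1),
    "in_vivo_only": (400.0, 350.0, 2.0, 100.0),
    "culture_induced": (60.0, 50.0, 800.0, 10.0),
    "stroma_marker": (6.0, 5.0, 4.0, 600.0),
    "ubiquitous": (500.0, 500.0, 500.0, 500.0),
    "ocular_non_cec": (300.0, 280.0, 150.0, 30.0),
}

DEFAULT_QUOTAS = {
    "pan_cec": 10,
    "in_vivo_only": 10,
    "culture_induced": 5,
    "stroma_marker": 10,
    "ubiquitous": 20,
    "ocular_non_cec": 5,
}

_SPECIFICITY = {
    "pan_cec": "specific",
    "in_vivo_only": "specific",
    "culture_induced": "specific",
    "stroma_marker": "specific",
    "ubiquitous": "ubiquitous",
    "ocular_non_cec": "restricted:retina",
    "background": "inconclusive",
}


@dataclass
class SimulationConfig:
    """Study-condition knobs of the count generator."""

    n_genes: int = 200
    classes: tuple = CORE_CLASSES
    library_size_range: tuple = (1_800_000, 4_600_000)
    dispersion: float = 0.05
    quotas: dict = field(default_factory=lambda: dict(DEFAULT_QUOTAS))
    background_log_median: float = np.log(3.0)   # lognormal baseline, median 3 RPM
    background_log_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ExpressionError("dispersion must be >= 0")
        unknown = set(self.quotas) - set(ARCHETYPE_TEMPLATES)
        if unknown:
            raise ExpressionError(f"unknown archetype(s) in quotas: {sorted(unknown)}")
        if any(q < 0 for q in self.quotas.values()):
            raise ExpressionError("archetype quotas must be non-negative")
        if sum(self.quotas.values()) > self.n_genes:
            raise ExpressionError(
                f"infeasible quotas: {sum(self.quotas.values())} planted genes "
                f"exceed n_genes={self.n_genes}")


@dataclass
class Truth:
    """Per-gene archetype label and the class-mean RPMs used for generation."""

    table: pd.DataFrame  # index gene_id; columns archetype + one per class

    def archetype_genes(self, archetype: str) -> list[str]:
        mask = self.table["archetype"] == archetype
        return list(self.table.index[mask])

    def mean_rpms(self) -> pd.DataFrame:
        return self.table.drop(columns="archetype")


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """NB draws with var = m + φ·m²; φ = 0 degenerates to rounded means."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.rint(mean).astype(np.int64)
    out = np.zeros(mean.shape, dtype=np.int64)
    positive = mean > 0
    r = 1.0 / dispersion
    p = r / (r + mean[positive])
    out[positive] = rng.negative_binomial(r, p)
    return out


def generate_counts(config: SimulationConfig
                    ) -> tuple[ExpressionMatrix, SampleMetadata, GeneAnnotation, Truth]:
    """Draw a seeded four-class count matrix with planted marker archetypes.

    Returns the count matrix (one sample per class, sample ids equal to the
    class labels), its metadata, an annotation carrying archetype categories
    and specificity verdicts, and the generating truth table.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.classes)

    gene_ids, archetypes, mean_rows = [], [], []
    for archetype in sorted(config.quotas):
        for i in range(config.quotas[archetype]):
            gene_ids.append(f"{archetype.upper()}_{i + 1:03d}")
            archetypes.append(archetype)
            template = dict(zip(CORE_CLASSES, ARCHETYPE_TEMPLATES[archetype]))
            mean_rows.append([template.get(c, template["cec_young"])
                              for c in classes])
    n_background = config.n_genes - len(gene_ids)
    base = np.exp(rng.normal(config.background_log_median,
                             config.background_log_sigma, size=n_background))
    for i in range(n_background):
        gene_ids.append(f"BG_{i + 1:04d}")
        archetypes.append("background")
        mean_rows.append([base[i]] * len(classes))

    means = pd.DataFrame(mean_rows, index=gene_ids, columns=classes)
    depths = rng.integers(config.library_size_range[0],
                          config.library_size_range[1] + 1, size=len(classes))

    counts = pd.DataFrame(index=gene_ids, columns=classes, dtype=float)
    for j, label in enumerate(classes):
        expected = means[label].to_numpy() * depths[j] / 1e6
        counts[label] = _negative_binomial(rng, expected, config.dispersion)

    matrix = ExpressionMatrix(counts.astype(float), unit="counts")
    meta = SampleMetadata(pd.DataFrame(
        {"class_label": classes, "library_size": depths.astype(int)},
        index=pd.Index(classes, name="sample_id")))
    annotation = GeneAnnotation(
        categories={g: frozenset([a]) for g, a in zip(gene_ids, archetypes)},
        specificity={g: _SPECIFICITY[a] for g, a in zip(gene_ids, archetypes)})
    truth = Truth(pd.DataFrame(means).assign(archetype=archetypes)
                  [["archetype", *classes]])
    return matrix, meta, annotation, truth


def expected_outcome(truth: Truth, predicate) -> pd.Series:
    """Apply a per-gene predicate to the noise-free truth-table mean RPMs."""
    rpms = truth.mean_rpms()
    return pd.Series({gene: bool(predicate(row.to_dict()))
                      for gene, row in rpms.iterrows()})


def generate_ct(relative_abundances: pd.DataFrame, noise_sd: float,
                n_replicates: int, seed: int, base_cycle: float = 30.0,
                housekeeping=DEFAULT_HOUSEKEEPING) -> CtTable:
    """Invert an assay x sample abundance table to a replicated Ct plate.

    ``relative_abundances`` is indexed by assay with one column per sample;
    all entries must be positive. Housekeeping assays are appended at
    constant unit abundance. Ct = base_cycle − log2(abundance) + N(0, noise_sd)
    independently per replicate.
    """
    values = relative_abundances.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ExpressionError("relative abundances must be positive")
    if n_replicates < 1:
        raise ExpressionError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)

    table = relative_abundances.copy()
    for hk in housekeeping:
        if hk not in table.index:
            table.loc[hk] = 1.0

    rows = []
    for assay, row in table.iterrows():
        for sample, abundance in row.items():
            ideal = base_cycle - np.log2(abundance)
            noise = rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd > 0 \
                else np.zeros(n_replicates)
            for r in range(n_replicates):
                rows.append({"assay_id": str(assay), "sample_id": str(sample),
                             "replicate": r + 1, "ct": float(ideal + noise[r])})
    return CtTable(pd.DataFrame(rows), frozenset(housekeeping))
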