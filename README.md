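# cecmarkers

Marker-gene discovery for **human corneal endothelial cells (CECs)** from
bulk gene-expression tables.

Corneal endothelial grafts engineered *ex vivo* need a way to prove the
cells they carry really are CECs. The classic immunostaining pair (ZO-1 +
Na⁺/K⁺-ATPase) marks functional tight junctions and ion pumps but is
expressed in many other cell types, and the tissue most likely to
contaminate a CEC culture — corneal stroma keratocytes and their
serum-activated fibroblasts — must be excluded explicitly. `cecmarkers`
implements the comparative expression screen that addresses this: starting
from gene-level read counts for four sample classes (young CEC with
Descemet's membrane, old CEC-DM, cultured CEC, corneal stroma), it derives
and validates candidate marker panels such as SLC4A11 / COL8A2 / CYYR1.

## What it computes

With per-gene reads-per-million `RPM(g, s) = count(g, s) / librarySize(s) × 10⁶`
and fold change `F(a, b) = RPM_a / RPM_b` (undefined, printed `n/a`, when
the denominator class is silent):

* **Stable-CEC screen** — keep genes with RPM > 10 in young, old and
  cultured CEC, young/stroma fold ≥ 2, and young/old fold within
  [0.5, 2.0] (folds evaluated at one-decimal precision).
* **Stroma-absent screen** — keep genes with RPM > 10 in all three CEC
  classes and RPM < 1 in stroma.
* **Marker-flaw taxonomy** — disqualify previously proposed markers that
  are low in young CEC (RPM < 100), silent in culture (RPM < 10), lack
  stroma contrast (young/stroma < 5), or are ubiquitous across tissues
  (external specificity verdict).
* **Category screens** — the stable screen restricted to an annotated
  functional category (transporters, cytokine receptors, transcription
  factors, …) and explicit gene-set extraction (e.g. the SMAD family).
* **Enrichment arithmetic** — category percentages over the annotated
  («recognized») subset of a ranked gene list, with a one-sided
  hypergeometric over-representation tail and Benjamini–Hochberg report.
* **Sample clustering** — average-linkage trees on log₂(RPM+1) profiles,
  exported as newick.
* **qPCR validation** — comparative-Ct quantification
  `rel(a, s) = 100 · 2^−(ΔCt(a,s) − ΔCt(a,ref))` with ΔCt taken against the
  arithmetic mean Ct of a housekeeping set (GAPDH, ATP6V0E1, H2AFY by
  default), plus Welch two-sample t-tests with `*` / `**` significance
  stars.
* **Synthetic data** — a seeded negative-binomial count generator that
  plants marker archetypes (pan-CEC, in-vivo-only, culture-induced,
  stroma-restricted, ubiquitous, ocular-non-CEC) at the study's library
  depths, and a Ct-plate generator, so every stage is testable end to end.

The published candidate tables of the underlying study are curated in
`cecmarkers.reference` and double as regression fixtures.

## Worked example

```python
from cecmarkers import (fold_change, stable_cec_filter, stroma_absent_filter,
                        cluster_samples)
from cecmarkers import reference

meta = reference.reference_metadata()
candidates, printed_folds = reference.load_top50_stable()

kept = stable_cec_filter(candidates, meta, fold_overrides=printed_folds)
print(f"stable-CEC screen keeps {len(kept)}/{len(candidates.gene_ids)} candidates")

slc4a11 = next(r for r in kept if r.gene_id == "SLC4A11")
print("SLC4A11 young/stroma fold:", slc4a11.fold_young_stroma.display)

absent = stroma_absent_filter(reference.load_stroma_absent(), meta)
print("stroma-absent screen admits", len(absent), "genes; top:",
      ", ".join(r.gene_id for r in absent[:3]))

print("sample tree:", cluster_samples(candidates).to_newick())
```

prints

```
stable-CEC screen keeps 51/51 candidates
SLC4A11 young/stroma fold: 25.7
stroma-absent screen admits 19 genes; top: OLFML1, CYYR1, HEMK1
sample tree: (((cec_old:3.1647,cec_young:3.1647):9.45517,cec_culture:12.6199):4.86916,stroma:17.489);
```

Every published candidate row survives its own screen (the 25.7-fold
young/stroma contrast of SLC4A11 is recomputed from the stored RPMs, not
copied); CYYR1 sits near the top of the stroma-absent list while SLC4A11
and COL8A2 are excluded from it by their residual stroma signal — which is
exactly why the three genes are complementary as a panel. The sample tree
recovers the expected biology: young and old CEC first, then culture, with
stroma outermost.

The same stages are available from a shell:

```bash
cecmarkers simulate --seed 1 --out-dir study/
cecmarkers run --expression study/counts.tsv --metadata study/metadata.tsv \
    --annotation study/annotation.tsv --unit counts --out-dir study/out
cecmarkers select-markers --help   # documents every threshold default
```

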