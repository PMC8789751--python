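# gcrep

Paired single-cell transcriptome + immunoglobulin-repertoire analysis of
germinal center (GC) B cells.

GC B cells diversify their B-cell receptors by somatic hypermutation (SHM)
and class switch recombination (CSR) while transitioning through dark-zone
(DZ), light-zone (LZ), memory-precursor (PreM/MP) and plasmablast (PBL)
states. `gcrep` integrates 10x-style V(D)J contig annotations with sparse
UMI expression matrices to ask how mutational load and isotype class are
distributed across those states:

- **QC and chain pairing** — keeps cells with expression data and exactly
  one productive, full-length, high-confidence heavy and light chain with
  more than 3 UMIs each, removing IGHD cells, with a per-rule drop audit.
- **Germline identity** — combines heavy- and light-chain V-region germline
  identity (percent nucleotide identity to the inferred germline segment;
  100% = unmutated) into one per-cell value (unweighted mean) and bins it
  into five strata: exactly 100, [98,100), [96,98), [94,96), <94.
- **Isotype classes** — collapses constant-gene calls to IGHM/IGHG/IGHA/IGHE
  (IGHG1–4 → IGHG, IGHA1–2 → IGHA).
- **Clonotypes** — cells sharing identical V(D)J gene calls and identical
  concatenated heavy+light CDR3 nucleotide sequences, per donor; clone-size
  summaries and the fraction of clones (≥ 5 cells) mixing isotype classes.
- **Enrichment statistics** — for each cluster × category (identity bin,
  isotype class, or gene set) an exact hypergeometric test: enrichment
  p = P(X ≥ k), depletion p = P(X ≤ k) with X ~ Hypergeom(N, K, n), with
  Benjamini–Hochberg FDR control per direction and flags at q ≤ 0.05.
- **Expression summaries** — library-size normalization (counts per 10⁴),
  Wilcoxon rank-sum differential expression with the reporting filter
  (fold change ≥ 1.2, detection ≥ 25% in either group, q ≤ 0.05), and
  dot-plot statistics (percent detected, z-scored mean log₂ expression).
- **Synthetic cohorts** — a seeded generator emulating the 14-cluster GC
  structure, per-cluster identity mixtures (including the bimodal PreM),
  per-cluster isotype probabilities, donor-scoped clones with irreversible
  intraclonal switching, and negative-binomial counts with hallmark-gene
  fold-ups, written in exactly the formats the pipeline reads.

## Worked example

```python
import numpy as np
from gcrep import (default_profile, generate_cohort, load_cohort,
                   filter_paired_cells, annotate_cells, call_clonotypes,
                   clone_size_summary, categorical_enrichment_by_cluster,
                   composition_table)

profile = default_profile()
profile.n_cells = 8000
profile.seed = 17
generate_cohort(profile, "cohort/")
contigs, expressed, annotations, matrices = load_cohort("cohort/")

cells, audit = filter_paired_cells(contigs, expressed)
annotate_cells(cells, annotations)
print("QC audit:", audit)

identity = np.array([c.germline_identity_pct for c in cells])
print(f"median germline identity: {np.median(identity):.1f}%")

comp = composition_table(cells, "isotype_class")
print(comp[comp.cluster.isin(['DZ-1', 'PreM', 'PBL-1'])].round(1).to_string(index=False))
```

prints

```
QC audit: {'not_in_expression': 30, 'no_eligible_heavy': 63, 'multiple_eligible_heavy': 33,
 'no_eligible_light': 0, 'multiple_eligible_light': 0, 'heavy_missing_c_gene': 0,
 'heavy_ighd': 33, 'kept': 7841}
median germline identity: 95.5%
cluster   n  IGHM  IGHG  IGHA  IGHE
   DZ-1 945  20.3  46.1  33.5   0.0
  PBL-1 255   9.0  69.4  21.6   0.0
   PreM 316  53.8  32.3  13.9   0.0
```

The audit shows the 159 injected QC-violating cells dropped for the right
reasons; the composition table shows the expected repertoire structure —
bulk GC clusters dominated by switched isotypes, memory precursors by IGHM,
plasmablasts by IGHG. Enrichment testing makes those biases formal:

```python
records = categorical_enrichment_by_cluster(cells, "isotype_class")
[(r.cluster, r.category, r.flag) for r in records if r.flag != "none"][:3]
# [('DZ-1', 'IGHM', 'depleted'), ('FCRL2/3', 'IGHM', 'enriched'),
#  ('FCRL2/3', 'IGHG', 'depleted')]

summary, hist = clone_size_summary(call_clonotypes(cells))
# per donor ~74-75% of cells carry a unique (singleton) clonotype
```

The same stages are available as a CLI:

```sh
gcrep simulate --n-cells 40000 --seed 1 --out cohort/
gcrep qc --cohort-dir cohort/ --out cells.tsv
gcrep clonotypes --cells cells.tsv --out clones.tsv
gcrep enrich --cells cells.tsv --by identity_bin --out enrich.tsv
gcrep run --out results/ --seed 1          # full pipeline + manifest
```

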