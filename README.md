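# sdparalog

Toolkit for characterizing high-identity segmental-duplication (SD) gene
families from haplotype-resolved assemblies, built around the human
*NOTCH2NL* family: the ancestral gene *NOTCH2*, the nearby pseudogene
*NOTCH2NLR*, and the human-specific copies *NOTCH2NLA/B/C* on chromosome 1.
Because these paralogs share >99% identity over hundreds of kilobases,
interlocus gene conversion (IGC) can silently overwrite one copy with
another's sequence, making the gene body alone an unreliable witness of
which locus you are looking at.

## What it does

* **Synteny engine** — anchor-chained pairwise alignment of paralog
  regions; longest non-overlapping syntenic block length and percent
  identity (the pairwise homology matrix), 1 kbp windowed identity
  profiles, and CIGAR-derived insertion/deletion tables.
* **Duplicon barcodes** — the ordered, oriented duplicon annotations
  within ±1 Mbp of a gene form a "barcode" of its long-range genomic
  context; nearest-barcode assignment (token-level edit distance) gives a
  locus its map position independently of its gene-body sequence.
* **Tripartite paralog identity** — each locus is called from three
  signals: (i) best transcript match (fewest CDS mismatches against the
  reference panel), (ii) phylogenetic clade (nearest reference by
  patristic distance in a neighbor-joining tree of intron-2 sequence,
  Jukes–Cantor distances), and (iii) map location (barcode). Agreement is
  a clean call; transcript+clade against location is an IGC call with
  donor and acceptor (a *NOTCH2* donor at the *NOTCH2NLR* position is the
  converted pseudogene state *NOTCH2tv*); a transcript tied between A and
  B at the C position is the A/B hybrid state.
* **Haplotype configurations** — per-haplotype position-state vectors are
  matched against a catalog of configurations (H1–H10: canonical,
  deletion classes, conversion carriers, hybrid) and summarized at cohort
  level (percentages, copy numbers, invariant checks such as
  NLA + NLB identity copies = 2).
* **Strict-clock dating** — split time T = (d_pair / mean d_outgroup) ×
  T_cal with JC69 distances, calibrated on the human–orangutan split
  (15.2 MYA), percentile bootstrap over alignment columns for CIs.
* **Regulatory element sharing** — single-fiber chromatin accessibility
  peaks (percent actuation = 100·fire/total fibers) are lifted through
  synteny blocks to the other paralog regions and categorized as unique,
  shared-and-accessible-elsewhere, shared-but-accessible-once, or
  duplicated only outside the paralog set.
* **Synthetic cohorts** — a fully seeded generator producing haploid
  records with five paralogous loci, configurable divergence times
  (ladder tree at 4.5 / 2.8 / 1.6 MYA anchored at 15.2 MYA), IGC tracts,
  deletions, inversions and configuration frequencies, with complete
  ground truth, so every stage is testable without downloads.

## Worked example

Simulate a 69-haplotype cohort with the documented configuration
composition, run the tripartite workflow blind, and summarize:

```python
import numpy as np
from sdparalog import SimConfig, simulate_cohort, analyze_cohort

cfg = SimConfig(n_haplotypes=69)
cohort, truth = simulate_cohort(cfg, np.random.default_rng(1), exact_counts=True)
panel = cohort.panel
result = analyze_cohort(
    cohort.haplotypes,
    panel.cds_panel(),
    panel.intron_panel(),
    panel.barcodes(),
    panel.regions(),
)
s = result.summary
print(s.config_counts)
print(s.percent_lacking_nlr, s.percent_b_to_a, s.percent_notch2tv,
      s.percent_igc_union)
```

prints

```
{'H1': 30, 'H2': 10, 'H3': 5, 'H4': 4, 'H5': 8, 'H6': 2, 'H7': 2, 'H8': 2, 'H9': 5, 'H10': 1}
43 20 10 28
```

i.e. 43% of haplotypes lack the *NOTCH2NLR* pseudogene, 20% carry a
B→A conversion, 10% carry *NOTCH2tv*, and 28% carry at least one IGC
event (two haplotypes carry both). One of the recovered conversion calls:

```
hap001_L1 igc donor=NOTCH2 acceptor=NOTCH2NLR tract=(9000, 15000)
```

— a locus whose barcode sits at the pseudogene position but whose
transcript and intron phylogeny both name the ancestral gene: *NOTCH2tv*,
with the conversion tract delineated from the ≥99.9%-identity windows.

A command-line layer mirrors the library
(`sdparalog simulate|synteny|barcode|evidence|date|classify|summarize|elements`).

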