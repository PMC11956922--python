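# Methods

## The analysis problem

Five paralogous loci of the *NOTCH2/NOTCH2NL* family sit in segmental
duplications that are >99% identical over 100 kbp–0.5 Mbp. Two mutational
processes confound naive genotyping: interlocus gene conversion (IGC),
which copies one paralog's sequence non-reciprocally over another, and
recurrent deletion via non-allelic homologous recombination. The package
implements the resulting identity problem as three independent witnesses
per locus — what its coding sequence says, what its intron phylogeny
says, and where its long-range duplicon context says it sits — and reads
IGC off their disagreement.

## Synteny and identity

Pairwise alignment is anchor-based: maximal exact matches seeded from
k-mers (k = 21 by default, k ≥ 8 enforced) that are unique in both
sequences, on both strands, chained colinearly (score = anchored bases −
gap penalties; default max gap 10 kbp, minimum chain span 1 kbp). Chains
are made non-overlapping on the query by score (ties to the leftmost) and
extended outward past isolated mismatches with an X-drop walk (+1 match,
−2 mismatch, drop 20), then each block span is aligned end-to-end by
unit-cost global alignment (edlib) to obtain the path. Identity is "blast
identity", 100·matches/aligned-columns with every indel base one column;
a gap-compressed variant is exposed separately. Case is ignored and N
never matches, including N-to-N.

Choices worth noting:

* *Longest non-overlapping syntenic stretch* is the single longest
  chain's query span after overlap resolution; the identity reported for
  a pair is that block's identity.
* Unit-cost co-optimal paths can split one structural indel into several
  runs separated by coincidental matches. The indel table therefore
  merges same-type runs separated by ≤ 20 aligned columns before applying
  the ≥ 50 bp threshold. Identity accounting is untouched by this.
* Windowed profiles tile the acceptor with non-overlapping 1 kbp windows;
  a window is assigned to the argmax candidate only at ≥ 99.9% identity,
  with ties unassigned. The column-weighted mean of window identities
  equals the global block identity by construction.
* Oversized inter-anchor gaps (default > 50 kbp) split a block rather
  than being aligned; `block_identity` therefore returns a list, normally
  of length one.

## Barcodes

A locus barcode is the ordered, oriented duplicon tokens whose midpoints
fall within ±1 Mbp of the gene. Barcodes are compared by Levenshtein
distance over (token id, orientation) pairs with unit costs; token
lengths are ignored, mirroring the qualitative use of duplicon tracks.
Assignment takes the nearest reference barcode; the margin to the second
nearest is reported and a zero margin yields "ambiguous" rather than an
arbitrary pick. Duplicon annotation from raw sequence uses repeated
best-infix search (edlib mode HW) with masking, both orientations, at
≥ 90% identity, followed by greedy non-overlapping selection by
identity×span — infix search rather than unique-k-mer seeding because
duplicons recur many times in a flank.

## Tripartite calling

Rule order, applied per locus:

1. transcript = clade = location → **clean**;
2. transcript = clade ≠ location → **igc**, donor = transcript label,
   acceptor = location; donor *NOTCH2* at the *NOTCH2NLR* position is the
   **NOTCH2tv** state;
3. transcript tied exactly between {NLA, NLB} at the NLC location →
   **hybrid** (the H10 state);
4. anything else (transcript/clade conflict, ambiguous location) →
   **ambiguous**, no hard label; tract delineation is still attempted.

Conversion tracts are the longest run of ≥ 3 consecutive windows whose
identity to the donor clears 99.9% and beats the location reference.

The configuration catalog is data (an editable TSV), not code. The
default encodes: H1 canonical; H2/H4/H8/H9 deletion classes; H3/H6
carrying *NOTCH2tv*; H4/H5/H6 carrying the B→A conversion; H7/H8 lacking
NLC; H10 the NLC hybrid. Where the documented descriptions do not pin a
configuration's full composition, the defaults make the minimal choices
that keep the catalog mutually distinct and keep the documented cohort
arithmetic exact: H7 lacks the pseudogene position as well as NLC, and H8
and H9 carry an inverted NLB (an orientation flag only — inversions are
not simulated at sequence level). This also preserves the observation
that NLA-identity plus NLB-identity copies sum to 2 in every haplotype;
`cohort_summary` flags violators. Cohort percentages are rounded half
away from zero, which is required to reproduce whole-percent values such as
28% from 19/69. The IGC union counts B→A and *NOTCH2tv* carriers (the
hybrid state is tallied separately).

## Phylogeny and dating

Distances are Jukes–Cantor: p is the mismatch fraction over comparable
sites (positions with N or gaps excluded from both numerator and
denominator), d = −(3/4)·ln(1 − 4p/3), with an error past p = 0.75.
Neighbor joining is implemented in-package: standard Q-criterion
agglomeration, deterministic tie-breaks by label order, negative branch
lengths clamped to zero; it is cross-checked in the tests against both an
exhaustive least-squares topology oracle and an independent library
implementation. Clade assignment takes the reference leaf nearest by
patristic distance; monophyly means the smallest clade containing query
and winner holds no other reference. Trees are built per haplotype
(queries + the five reference paralogs), which is equivalent to placement
in a cohort-wide tree for nearest-reference assignment and keeps the
matrix small.

Dating assumes a strict clock: T = (d_pair / mean d_to_outgroup) ×
T_cal, with T_cal = 15.2 MYA (human–orangutan). Confidence intervals are
a percentile bootstrap (default 1000 replicates) over alignment columns,
resampling one column index set applied to all alignments; the interval
is widened to include the point estimate if a resample excludes it. These
CIs are a generic nonparametric substitute for tool-specific dating
intervals and are not expected to match any other tool's CI
convention numerically.

## The synthetic cohort

The generator emulates the study conditions, not any particular genome:

* **Geometry** — 20 kbp gene body, five exons (CDS 1.7 kbp, intron 2 =
  4.65 kbp used for phylogeny), 8 kbp flanks tiled with duplicons from a
  12-token library (300–550 bp each).
* **Tree** — an ultrametric ladder: NOTCH2 splits from the derived copies
  at 4.5 MYA, the pseudogene at 3.5 MYA (a free parameter placed between
  the documented 4.5 and 2.8 MYA splits), NLC at 2.8, the NLA/NLB cherry
  at 1.6, all anchored at a 15.2 MYA outgroup.
* **Substitutions** — Jukes–Cantor-style: Poisson(μ·t·L) hits per branch,
  each hit changing a site to one of the other three bases (a site hit
  twice in one branch changes once); no indels in gene bodies, so
  positional coordinates stay homologous. Default μ = 1.6 × 10⁻³
  /site/Myr, chosen once so the youngest pair sits at ≈ 99.7% identity —
  the identity the real A/B pair shows — and so the minimum inter-paralog
  divergence is ≥ 0.5%. Per-haplotype private variation adds
  Poisson(5 × 10⁻⁴ per site) substitutions per locus.
* **Barcodes** — each paralog's flank token list receives 4 + Poisson(1)
  token edits (delete / orientation flip / insert), redrawn until all
  pairwise barcode distances are ≥ 6; haplotypes add Poisson(0.3) further
  edits. Flank sequences are rebuilt to match the edited token lists, so
  annotation from sequence and the BED tokens agree.
* **Configurations** — drawn from the catalog frequencies (default: the
  69-haplotype composition 30/10/5/4/8/2/2/2/5/1 for H1…H10;
  `exact_counts=True` realises those counts exactly via largest
  remainder). Conversion tracts cover the gene core (the promoter plus
  first four exons for *NOTCH2tv*; the whole gene for B→A) extended each
  side by geometric draws targeting a mean tract of 8 kbp, clamped to the
  body; the donor is the same haplotype's own copy, so truth tracts are
  exact copies by construction. The H10 hybrid CDS is built from the two
  reference CDSs split at the median difference site so its mismatch
  counts to A and B tie exactly (an odd difference count is resolved by a
  third-allele middle site, adding one mismatch to each); subsequent
  allelic noise on its exons is restricted to sites where A and B agree,
  which preserves the tie.
* **Determinism** — one seeded generator consumed in a fixed order
  (ancestor → family → cohort); identical configurations give
  byte-identical cohorts and truth.

What the generator does *not* emulate: sequence-level inversion
breakpoints, flank indels, assembly error, read-level noise, and
recombination within gene bodies. Passing recovery tests therefore shows
the workflow is correct under clean assemblies with the stated divergence
structure — the regime the method targets — not robustness to assembly
artifacts, which the source workflow handles by upstream QC.

## Problem sizes and numerical choices

The shipped checks run at desk scale by design: cohorts of 69–100
haplotypes with 20 kbp loci (the real regions are 1 Mbp; the engine is
the same, the anchors merely fewer), 200 alignment-oracle pairs ≤ 2 kbp,
50 dating replicates with 300-replicate bootstraps, and exhaustive 4- and
5-taxon topology sweeps. The homology-matrix statistics of the five real
reference regions are computed from the packaged reference matrix; the
recomputation from the full reference assembly needs the assembly itself
and is out of the desk-scale surface. All percentages print rounded half
away from zero; exact fractions are carried alongside. Alignment
"exactness" is asserted as path optimality: the block path's unit cost
must equal an independent full-matrix DP distance (a unique number),
since co-optimal unit-cost paths can legitimately differ in
match/column composition.

## Known limitations

* The identity between flank tokens and gene bodies is taken as given by
  the annotations; no repeat masking is performed.
* Barcode comparison ignores token lengths and spacing.
* Clade monophyly is evaluated on the NJ tree as rooted by its output
  trifurcation; for the ladder-like trees at hand this matches the
  intended reading, but deep-coalescing topologies could blur it.
* The ambiguous catch-all in calling never guesses: loci whose transcript
  and clade disagree (e.g. a conversion tract covering the CDS but not
  intron 2) are surfaced for inspection rather than auto-resolved.
* Fisher's exact test is provided for carrier-enrichment contrasts
  (scipy's exact implementation); no ancestry inference is attempted.
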