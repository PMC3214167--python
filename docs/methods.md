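# Methods

## The object under study

*gau* is modelled as a fixed-geometry antisense ORF overlapping *cox1*
in the −2 reading frame of the complementary strand. For a sense
sequence read as codons 0..m−1, the antisense codon indexed by sense
codon k is

```
gau_k = ( comp(sense[3k+4]), comp(sense[3k+3]), comp(sense[3k+2]) )
```

i.e. antisense positions 1 and 2 come from positions 2 and 1 of sense
codon k+1, and antisense position 3 pairs with position 3 of sense codon
k. Equivalently, `gau_k` is codon `m−2−k` of the −2 frame translation;
this equivalence is property-tested exhaustively on random sequences.
The consequence that drives every analysis here: a synonymous
third-position change in the sense gene touches only the third position
of one antisense codon, while first/second-position changes hit both
proteins at once.

The region is defined rigidly from the conserved GSPPP pentapeptide:
residue 1 is the codon immediately upstream of the anchor glycine
(candidate initiation site; AUG/AUA/AUU/AUC/GUG are accepted), residues
2–6 are GSPPP, and residue 101 is the candidate terminator, giving 101
codons / 303 nt. Coordinates are 0-based half-open internally and
reported 1-based inclusive (GenBank convention). Where published
coordinates could include or exclude the position-101 codon, the
extractor documents its own convention and downstream checks tolerate a
one-codon offset.

## Genetic codes

Built-in tables are NCBI translation tables 1 (standard), 2 (vertebrate
mitochondrial), 3 (yeast mt), 4 (mold/protozoan mt) and 5 (invertebrate
mt), taken from Biopython's codon-table data and wrapped in a single
64-entry map with '\*' for stops. The vertebrate mt table treats AGA/AGG
(AGR) as terminators — the property at the heart of the contrast
analysis. Codons containing N or other ambiguity codes translate to 'X'
and never count as stops. DNA and RNA are both accepted (U is
normalised to T). User tables load from TSV (codon, aa, is_start).

Published analyses do not always state which code variant was used to
count stops outside vertebrates; the scanner therefore takes a
per-record code (default invertebrate mt for the synthetic genome sets)
and accepts a record→code override map rather than asserting any one
choice.

## Shuffle null model

Codon usage is tabulated from the analysed gene itself (not a
genome-wide table): within each amino-acid family, observed relative
frequencies, with unobserved synonyms at 0. A replicate redraws every
codon independently from its family's distribution; the terminal stop
codon is kept verbatim; six-fold families (Leu, Ser) are treated as
single families so reassignment may cross codon blocks. Sense-protein
preservation is asserted on every replicate, not assumed. Replicate
seeds are derived counter-style from one master seed and logged.

Metrics per replicate: % sense codons altered over the whole CDS, the
same restricted to codons overlapping the antisense region, % of the
101 antisense residues unchanged, % of altered in-region codons that
changed at least one antisense residue, and the antisense stop count.
The closed form for the expected altered fraction of a family with
frequencies p is 1 − Σp², which the Monte-Carlo estimate must approach
at the 1/√n rate; this is tested at 10⁵ draws. Aggregation uses a
two-tailed paired t (gene-wide vs in-region altered fractions, n−1 df)
and, when a reference antisense protein is supplied, a one-sample t of
replicate similarity against the natural value. Zero variance is
flagged degenerate and the p omitted rather than reported as 0 or 1.

Stop counting inside the antisense region defaults to the vertebrate mt
code (AGR as stops), switchable per run. `enumerate_stop_sites` is
deliberately brute force — every synonymous alternative of every sense
codon, retranslating the region each time — because the quantity is an
exhaustive catalogue, not an estimate; a second, structurally different
brute force (via the codon-geometry primitive) serves as its test
oracle.

## Conservation tables

Pairwise comparison uses Needleman–Wunsch global alignment (affine
gaps; defaults match +1 / mismatch −1 / open −5 / extend −2,
configurable and documented rather than asserted, since published
tables rarely state alignment parameters). Regions are ranges on the
first sequence's coordinates; gap columns attach to the preceding
position. For each region × frame, codon columns are anchored on the
first sequence's frame; columns where either sequence gaps inside a
codon are excluded from the amino-acid comparison and counted as indel
events. Stop percentages are computed per sequence under its own code
with gaps excluded from the denominator. Similarity uses a named
partition of the amino acids. Because the scheme type requires pairwise
disjoint families, the default is the Dayhoff-style six-class partition
(AGPST / DENQ / HKR / ILMV / FWY / C) rather than the overlapping
ClustalW "strong" groups; the small conservative families observed to
dominate antisense-column variation (FLIMV / KN / QH) ship as scheme
`gau-families`.

## Contrast statistics

A contrast is mean(with-tRNA AGR counts) − mean(without-tRNA counts)
for one matched pair of monophyletic groups. The sign test is exact:
P(X ≥ k | n, ½) by integer binomial arithmetic (`Fraction`), zeros
dropped with an explicit count. Note that exact tails differ from some
published one-tailed values for the same (n, k); this implementation
reports the exact tails and makes no attempt to reproduce variant
calculations. Spearman rs is the Pearson correlation of average ranks;
p is exact by full permutation enumeration for n ≤ 8 and a t
approximation with n−2 df otherwise. Reporting follows the analysis
design: one-sided sign tests and one-sided Spearman for gains,
two-sided for losses. tRNA presence is an input column; when scenarios
are not supplied, Fitch parsimony on a user tree labels each contrast
node gain or loss (root ambiguity resolves to absence; the top-down
pass realises a minimum-change history, verified against brute-force
minimisation over internal labelings). Divergence times are
user-supplied; no dating is performed.

## Stop scan

Window *i* is the 100 codons upstream of the anchor glycine, window
*ii* the 100 codons from the glycine (identically residues 2–101 of the
extracted region — asserted cross-module), window *iii* the next 100.
Window *i* reports the decile of the LAST stop (how close truncation
approaches the ORF), windows *ii*/*iii* the FIRST. Deciles are position
bin upper bounds, ceil(pos/10)·10 ∈ {10..100}. Records with multiple
anchor hits use the frame −2 hit if present, else the 5′-most.

## Synthetic data

The generators define the study conditions for every test and for the
acceptance script. `make_overlap_cds` is constructive, not
rejection-based: sense codons are chosen left to right, each choice
satisfying (a) the constraint class of the antisense codon it completes
and (b) a third-base lookahead for the next antisense codon. Constraint
classes cover the anchor residues, an optional planted start codon
(default AUA, a common mitochondrial initiator), planted stops,
planted AGR codons, and stop-free elsewhere within the three scan
windows. All constrained non-AGR classes also exclude AGA/AGG so the
planted AGR count is exact under every code. Planted truth is therefore
recovered with zero error by construction, which is what the end-to-end
oracle tests assert. Defaults: 520 sense codons (cox1-scale), anchor at
−2-frame codon 110 so all three windows fit inside the CDS, background
codons uniform within the allowed candidate sets.

Divergent pairs place exactly round((1−identity)·L) substitutions
outside the 15-nt anchor span, so realised positional identity is exact
and both sequences retain the anchor. Contrast tables draw with-tRNA
counts from round(N(μ+δ, σ)) clipped at 0 (baseline μ = 10 AGR codons,
matching the ~9–11 counts reported for cercopithecid antisense
regions); the acceptance run uses 13 groups, δ = 1, σ = 1.5. Genome
sets embed anchored CDSs between anchor-free random flanks (30–90 nt)
with per-window stop counts Poisson(1), and emit a truth table the
scanner must match exactly.

What the generators do **not** emulate: real mitochondrial genome
architecture (tRNA/rRNA genes, control regions, circularity), realistic
codon usage bias, phylogenetic correlation between sequences, or
alignment-fragmenting indels. Passing tests therefore demonstrate
correctness of the machinery and exact recovery of planted signal, not
that real genomes carry that signal; analyses of published accession
sequences require those sequences to be supplied locally (see README).

## Problem sizes and numerics

Test and acceptance runs use CDSs of 360–520 codons, 20 shuffle
replicates (matching the published replication count), 13–40 contrast
groups, and genome sets of 25–40 records — sizes chosen so a complete
run finishes in seconds while keeping every statistic away from its
small-sample degeneracies. Ties in alignment traceback resolve to the
first optimal path the aligner reports; rank ties use average ranks;
hydropathy windows exclude '\*' positions from the mean and default to
width 9; charge domains are windows ≥ 10 with net charge ≥ +3
(K,R = +1; D,E = −1; H = 0) and hydrophobic domains windows ≥ 15 with
mean Kyte–Doolittle ≥ 1.5 — numeric conventions documented here because
published figures do not define them.

## Known limitations

- The frame-comparison table anchors codon framing on the first
  sequence; heavily gapped alignments shift the second sequence's
  effective frame within a region, which mirrors how published
  six-frame tables are built but is not symmetric in the two inputs.
- The exact Spearman permutation enumerates n! permutations and is
  capped at n = 8.
- `enumerate_stop_sites` retranslates the whole region per candidate
  substitution; it is O(region · synonyms) and intended for single-gene
  scale, not genome scale.
- The locator assumes the anchor pentapeptide is exact; degenerate
  motifs are not matched.
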