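# Methods

## Site grammar

Myrf's DNA-binding domain belongs to the Ndt80 family and the protein
binds as a trimer after self-cleavage. The package models its
high-affinity binding unit as a *composite site*: two CTGGYAC heptamers
(IUPAC Y = C or T) whose central nucleotides lie one helical turn
(10 bp) or one and a half turns (14 bp) apart, so both motifs present on
the same side or on opposite sides of the double helix. Coordinates are
0-based half-open internally; the heptamer centre is `start + 3` on the
forward strand regardless of strand, and the *spacer* is defined as the
bases strictly between the two heptamers, so centre distance = spacer + 7.

Two spacer sets are deliberately kept as separate modes:

- `high_affinity`: spacer ∈ {3, 7} — the arrangements validated
  directly by gel shift;
- `candidate`: spacer ∈ [3, 8] inclusive — the broader "1 to 1.5
  helical turns" window used when searching genomic regions for
  potential sites.

Both are configuration, not code. A candidate site with an off-phase
spacer (4, 5, 6, 8) is reported but classified `none`, reflecting that
even a single extra base pair between the motifs abolishes strong
binding.

Orientation never filters: head-to-tail (both motifs on one strand) and
head-to-head (downstream motif reverse-complemented) bind comparably in
vitro. Tail-to-tail (upstream motif on the minus strand) was never
tested in that assay series; it is scored like the others but flagged
`untested_orientation` in all outputs so downstream users can treat it
separately.

## Mismatch penalties and affinity classes

Single-base changes were assayed with one transversion per position
(purine → non-complementary pyrimidine and vice versa: A→C, C→A, G→T,
T→G). The qualitative outcomes order the positions: a position-4 change
is nearly neutral, position 1 mild, positions 2/3/5/6 intermediate, and
position 7 disqualifying; combinations of two mild changes (4+4, 4+1)
still bind detectably while any intermediate second change does not.
The default weights

    p = (1, 2, 2, 0.5, 2, 2, 5),   strong ≤ 0.5 < weak ≤ 2 < none

are the simplest assignment consistent with every one of those
outcomes; the panel-concordance test verifies the full 28-oligo truth
table and would catch any regression. Because only one of three
possible substitutions per position was assayed, penalties are
per-position, not per-base — a deliberate limitation of the data, not
an oversight. The total mismatch budget ("fewer than three mismatches
in total") is read as ≤ 2 summed over both heptamers, and the same cap
applies per heptamer during matching. `N` in input sequence counts as
a mismatch at every position.

Clusters merge sites sharing a heptamer (union-find on match identity);
cluster affinity and score are the best member's, never a sum, because
a third in-phase motif does not increase binding. Ties in cluster
ordering break by leftmost start, then `+` before `−`, for fully
deterministic output. BED scores scale penalties as
`round(1000 · max(0, 1 − P / weak_threshold))`.

## Oligo panel reconstruction

Panel oligos are named by the grammar `(m)s(m)...` — motif token `c`
(consensus realisation CTGGCAC), `r` (its reverse complement) or a
digit 1–7 (consensus with the transversion at that position), joined by
integer spacers. The original flanking sequences are not reproduced in
the available material; since the binding outcomes are attributed to
motif content, spacing and orientation only, flanks and spacers are
synthesized motif-free under a fixed seed (default 7), rejection-sampled
until a both-strand scan of the assembled oligo finds exactly the
planted heptamers. Total length is kept within the 33–41 bp window the
assays used wherever the motif content allows. Concordance is
seed-invariant by construction and the suite checks it across five
seeds. The three-motif orientation/spacing variants are a
representative reconstruction (marked `reconstructed`) because the
exact set was not enumerated in text.

The single-motif oligo `(c)` maps to `none` at the composite level; the
marginal complex it forms in vitro is recorded as a tolerated boundary
note in the concordance report, not a failure, because the model's unit
of prediction is the trimer-engaging composite site.

## Region classification and editing

Sox10 sites are taken as supplied annotations (e.g. the dimeric C/C′
site); no Sox10 motif model is fitted. Classification is a pure
function of (Sox10-site presence, best Myrf cluster affinity); the
affinity floor `min_affinity` defaults to `strong` because co-activated
regions characterised experimentally all carry at least one strongly
bound site. When weak sites are allowed to qualify, the region is
flagged `weak_only_support`.

Site destruction applies the position-7 transversion — the most
disruptive tested change — to every heptamer of the targeted cluster
(on the motif's own strand, written back through reverse
complementation for minus-strand matches), then rescans and verifies
that no cluster of weak or better affinity overlaps the original span;
residual weak arrangements trigger further rounds on the offending
heptamers (bounded, error on failure). Insertion splices a
CTGGCAC + 3 bp + CTGGCAC cassette (17 bp) at the requested offset,
rejection-sampling the spacer until the planted pair returns as a
strong site inside the cassette interval; annotations downstream of the
offset shift by 17 bp. Junction context can add a stray near-consensus
match that widens the enclosing cluster, which is harmless because
cluster affinity is max-combined.

## Target-gene triage

"Downregulated at least 2-fold" is interpreted on the linear scale as
log2 fold change ≤ −log2(fold_cutoff) with fold_cutoff = 2, at
p ≤ 0.05; both cutoffs are parameters. Differential testing itself and
the peak-to-gene association rule are out of scope — the module
consumes finished tables (the upstream study used standard RNA-Seq
differential testing and a peak-intersection tool, and does not state
the association window). A nearest-TSS assigner is included as a
convenience but marked non-canonical. ΔΔCt percent-of-input recovery is
`100 · 2^((Ct_input − log2(1/input_fraction)) − Ct_IP)` — the dilution
correction in log2 space is this package's stated convention, unit-tested
against hand arithmetic. Fold induction is the mean ± SEM of paired
per-replicate activity ratios with the no-effector baseline at exactly 1
(SEM undefined for a single replicate).

## Synthetic data

Generators emulate the *structure* of the study's inputs, never their
content. Background DNA is i.i.d. with a specified GC fraction
(default 0.45); motif-freeness is enforced incrementally — each new base
must not complete a heptamer window matching either strand within the
mismatch budget, with bounded backtracking — because a random 500-mer
would contain roughly twenty qualifying windows in expectation, making
whole-sequence rejection infeasible. This is not a Markov genome model:
the goal is guaranteed absence of confounding motifs, not realism, so
passing recovery tests demonstrates correctness of the scanner and
classifier logic, not performance on real genomic sequence with its
repeat structure and compositional heterogeneity.

Region sets realise the three regulatory scenarios (Sox10 + cassette,
Sox10 only, neither) plus decoys carrying only non-functional
arrangements (single heptamers; spacers 4–6, 8, 13). Planted cassettes
are spliced over background with an exact post-splice scan check
(retrying spacer seeds and jittering the offset by a few bp when a
junction creates a stray match); truth tables record the realised
coordinates. Triage tables plant Venn/stage cardinalities — the default
shape is 594 genes passing the DE filter, 203 of them peak-associated,
partitioned 64/48/91 — with fold changes and p-values drawn uniformly at
a 10% margin from the cutoffs so comparisons never sit on a
floating-point boundary. The count of peak-associated genes failing the
DE filter is not part of that shape; the default of 1500 reflects a
typical ChIP-derived gene list. All generators are deterministic per
seed and return machine-checkable truth.

## Problem sizes and numerical choices

The test suite and the acceptance script run the scanner-vs-oracle
comparison on ~100 random sequences up to 2 kb at every budget 0–2,
planted-recovery on ~100 mixed 300-bp regions, flip experiments on 20
regions per direction, and triage closure at full scale and 10×
reduced — sizes chosen so the whole suite completes in seconds while
still exercising every code path at the study's own cardinalities.
Affinity thresholds are compared with `≤` (a penalty exactly at a
threshold belongs to the better class); scanning output ordering is
fully specified (start, then strand) so results are byte-stable across
runs.

## Known limitations

- Penalties are per-position, calibrated from one substitution per
  position in one sequence context; other substitutions or contexts may
  behave differently.
- The classifier is deliberately categorical: repression strength does
  not scale with Myrf dose or Sox10-site affinity, and quantitative
  fold-induction values are wet-lab measurements outside the model.
- The monomeric DNA-binding domain's failure to shift DNA on its own is
  a documentation note, not a modelled species.
- Genomic coordinates of the experimentally characterised regulatory
  regions are published only as distances from transcription start
  sites, so their exact site counts cannot be reproduced from sequence
  here; the synthetic region sets stand in for them structurally.
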