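# Methods

This note documents the models, procedures and numerical choices behind
`kolodom`, and what its synthetic-data tests do and do not demonstrate.

## Coordinate and ORF conventions

Internally every interval is 0-based half-open with an explicit strand;
report output is 1-based inclusive (`Chr05:4592573..4595167(-)`), the style
of the published locus tables. An open reading frame runs ATG→stop and its
nucleotide length *includes* the stop codon, so a 2352 bp CDS encodes a
783-residue protein; protein strings never carry the terminal stop. Codons
containing `N` are not translated and terminate any ORF crossing them —
assembly gaps are not guessed through. ORF search always covers all six
frames of an extracted region; the original description leaves the strand
handling of extracted fragments unstated, and searching both strands is the
conservative reading.

## Homology search

The search engine is exact-word-seeded gapped Smith–Waterman. Seeds (word
size 5 for protein/translated modes, 12 for nucleotide) are clustered by
diagonal band (±16) and position (gap ≤ 1200); clusters with fewer than
three seeds are discarded — lone random seeds otherwise flood desk-scale
targets with windows. Full affine-gap local DP runs inside each cluster
window (±200 padding); masking the best alignment and recursing on the
flanks recovers secondary HSPs. Scoring: BLOSUM62 with gap open 11 / extend
1 (protein), +2/−3 with gap open 5 / extend 2 (nucleotide) — a gap of
length k costs open + k·extend. E-values follow the Karlin–Altschul form
E = K·m·n·exp(−λS) with fixed constants (λ=0.267, K=0.041 protein;
λ=0.625, K=0.41 nucleotide). These are documented approximations: the
pipeline only needs e-values monotone in score for its cutoffs (1e-5
translated/protein, 1e-100 nucleotide) to behave as intended; matching NCBI
BLAST statistics bit-exactly is out of scope. Adjacent HSPs of one query
merge into a single hit region when the gap between their subject intervals
is smaller than the query length; merging is transitive (the only
order-independent reading of the pairwise rule) and never crosses strands,
since a transposase CDS lies on one strand.

## Discovery, trimming, deduplication

Hit regions are widened by 1800 bp per side (clipped to contig ends;
overlapping widened regions on one contig and strand are unioned), the
longest ORF ≥ 1800 bp is called per region (ties: leftmost genomic start,
then '+' strand), and a candidate survives only if its protein hits at
least five distinct query transposases below 1e-5 in a backward protein
search. Candidates whose loci overlap ≥ 50% collapse to the longer ORF.
Start-codon trimming is automated: candidate proteins are aligned, the
modal alignment column of start methionines defines the majority start, and
any candidate starting earlier is cut back to the methionine aligned
nearest at-or-after that column (a candidate with no such methionine is
left untrimmed and flagged). Trimming operates in whole codons, so frames
and stop codons are preserved by construction. Serial names
(`<tag>1`, `<tag>2`, …) follow descending longest-ORF length.

## Repetitiveness

Truncated copies of a prospective CDS are its merged nucleotide hit regions
(e < 1e-100) that do not overlap — by even one base, the strictest reading
— any prospective CDS locus. Zero copies ⇒ nonrepetitive.
Semi-nonrepetitive requires every hit to be explainable as (a) a copy on
the homeologous partner chromosome (a degraded homeolog), (b) a tandem
neighbour within 50 kb of the CDS or of a phylogenetically grouped paralog
(the known tandem cases lie within ~4.6–8 kb; 50 kb adds margin while
excluding interspersed copies; configurable), or (c) an apparent assembly
artifact spanning an entire contig shorter than 1 kb. Anything else ⇒
repetitive. A CDS on an unplaced scaffold cannot use rule (a).

## Motif conservation

Five motif fields are read from the master protein alignment at 20 anchor
columns (3+4+4+3+6 residues: DDE, H2CH, C2CH, PWF, AVPTIF), located by
mapping the known motif positions of a reference sequence into the
alignment. "++" requires every consensus residue; "+" requires the first
four motifs exact and each AVPTIF position at least chemically similar.
The similarity predicate is necessarily reverse-engineered (the source
never defines "chemically similar"): identical, or BLOSUM62-positive, with
two amendments — V/F counts as similar (both purely hydrophobic) and Y/F
does not (tyrosine's hydroxyl moves it to the polar class despite a
positive BLOSUM62 score). This is the simplest rule that recomputes every
published motif count and flag; it is configurable and may not be the
authors' exact rule.

## Phylogeny and orthology

Distances are maximum-likelihood under the empirical JTT model with
gamma-distributed rate variation (shape 1, four discrete equal-probability
categories with mean-rate representatives), computed from the 20×20
site-pattern count matrix of each pair after removing alignment columns
with < 60% site coverage; pairs with fewer than 10 comparable columns are
errors, and optima at the saturation bound (t = 10) are flagged. The
original analysis used a desktop package whose internal "JTT
matrix-based" formula is not printed; ML under JTT(+Γ) is the standard
interpretation, and a Poisson-corrected distance is provided as a
cross-check. Neighbour joining is the classic Q-criterion algorithm with a
deterministic lexicographic tie-break and negative branch lengths clamped
to zero; bootstrap support is column resampling (default 500 replicates),
made cheap by the count-matrix formulation. Ortholog clusters are tree
clades holding exactly one diploid gene (or a tandem pair within 50 kb)
plus tetraploid genes confined to the corresponding L/S homeologous
chromosomes; among nested candidates the synteny-verified clade wins over a
larger mixed clade, so a gene grouping with non-syntenic extras stays with
its syntenic core. Synteny holds when every tetraploid member shares at
least two neighbour gene symbols (within ten gene models per side,
L/S suffixes stripped) with the diploid member; two operationalizes
"multiple orthologous neighbour genes". Diploid genes on unplaced
scaffolds skip the chromosome test and are annotated as uncertain.

## dN/dS

Codon alignments are protein-guided (gaps back-propagated in whole codons;
internal stops are errors). The primary estimator follows the Yang–Nielsen
(2000) outline: F3×4 codon frequencies pooled over the pair; kappa from
fourfold-degenerate and nondegenerate sites via K80, combined by site
counts; synonymous/nonsynonymous site counts weighted by kappa and
F3×4 target-codon frequency, averaged over the observed codons; observed
differences partitioned into transition/transversion × syn/nonsyn with
equal weighting over stop-free mutational pathways for multi-hit codons;
and K80-type multiple-hit corrections applied separately to the synonymous
and nonsynonymous classes. dS > 3 (or a collapsing logarithm) flags
saturation; dS = 0 rows report no ratio rather than a number, matching how
the published table prints them. Nei–Gojobori (1986) is implemented
independently (unweighted sites, Jukes–Cantor correction) as the in-package
oracle, and Biopython's codon-alignment dN/dS serves as a third-party
cross-check in the tests. Matching the original `yn00` binary bit-for-bit
is not attempted: its exact settings are unstated, and the published
per-pair values require the authors' cloned sequences. Simulation recovery
(median within 25% of the generating omega at t = 0.3, kappa = 2) plus
NG86 agreement within 1.5× per pair is the acceptance standard instead.

## Full-length element reconstruction

Copies of a repetitive subfamily share the transposon body and diverge into
unrelated flanks, so each element edge is a change point of cross-copy
identity. Walking outward from the CDS, per-position mean pairwise identity
is accumulated against the reference level (`drop_threshold`, default 0.5,
between within-element identity and the 25% background); the boundary is
the first position attaining the maximum cumulative excess (a CUSUM
argmax). This replaces a literal sliding-window contiguity rule, which
systematically overshoots by about two-thirds of the window even on
identical copies; the CUSUM form is exact when the flanks genuinely differ
at the element edge and stays within ±10 bp at 5% copy divergence (the
simulation standard used in the tests). The window parameter is retained as
the smoothing width of the identity track. Because the TTAA target-site
duplication is host sequence carried identically by every copy, identity
alone cannot exclude it; boundaries are therefore snapped inward to the
smallest shift placing an intact TTAA just outside each end (≤ 12 bp), and
a side lacking a TTAA — a mutated target site — borrows the other side's
shift, the overshoot being symmetric. Validation reads both TIRs 5'→3'
inward (the right end reverse-complemented, the convention under which both
TIR strings of an intact element begin `AG`): `terminal_ok` iff both start
`AG`, `tsd_ok` iff both 4 bp flanks equal TTAA. TIR length defaults to
16 bp, the length of the published TIR strings; left/right TIRs need only
be similar, not identical. One copy cannot define a boundary and is
reported as undetermined. How the original analysis fixed exact boundary
bases when copies disagreed is unstated; the change-point rule is this
package's own resolution.

## Status rules

The published per-gene status column is reproduced by four structural
rules (R1–R4 in the README) using repetitiveness, the motif flag and
synteny-verified cluster membership only. dN/dS is reported as
corroborating evidence but deliberately excluded from the decision: no
published status contradicts the structural rules, and the source presents
dN/dS as confirmation of purifying selection rather than as a criterion.
Semi-nonrepetitive genes follow the nonrepetitive branch. The rules are
total, mutually exclusive and order-independent; they are flagged as
reverse-engineered since the source states no explicit rule list.

## Synthetic data: what it emulates and what it does not

The generator builds one diploid genome (ChrN contigs) and one tetraploid
genome (chrNL/chrNS pairs) of i.i.d. background sequence (default GC 0.40,
100 kb contigs, two chromosome pairs — sizes chosen so a ten-genome-pair
end-to-end run stays desk-scale) carrying: two domesticated ortholog sets
(diploid + L + S copies, omega 0.2, total divergence t = 0.3 per codon,
each embedded in a cassette of three shared neighbour genes per side, with
additional background gene models every 9 kb keeping neighbour windows
local); two active families (intact copies at t = 0.01 inside full
elements — 16 bp `AG…` TIRs, 900 bp internal pads, TTAA TSD written at
insertion — plus dispersed 450–1500 bp truncated fragments, with at least
one fragment guaranteed outside every copy's neighbourhood/homeolog scope
so the interspersal signature is well defined); and one decayed fossil no
discovery stage should call. All transposases descend from one deep
ancestor (family branches t = 0.8) carrying the 20 motif residues at fixed
positions; query sets are eight relatives at t = 0.3–0.7. Codon evolution
is Goldman–Yang-style (transition/transversion kappa = 2, nonsynonymous ×
omega, stops forbidden), with two absolute constraints restored after
mutation: the initiation codon of every emitted gene copy (a gene whose ATG
mutated away would by definition stop being an intact ORF) and the motif
codons of intact active copies (an active transposase keeps its catalytic
residues). Insertions keep ≥ 6 kb of background between them so the
1800 bp extraction flanks of neighbouring planted genes can never fuse.

Passing end-to-end tests on these genomes demonstrates that the pipeline's
logic recovers the planted repetitiveness classes, clusters, elements and
statuses under clean conditions. It does not demonstrate robustness to
real-genome features deliberately absent here: indels (alignment and
boundary inference rely on substitution-only divergence), repeat-rich or
low-complexity background (an option exists to stress the search, off by
default), fragmented assemblies, nested insertions, or gene-model noise.
Claims about real assemblies rest on the method descriptions above, not on
these tests.

## Determinism and defaults

Every stochastic component takes an explicit seed; identical inputs and
seeds give byte-identical outputs (FASTA emission, bootstrap, reports).
All thresholds live in two dataclasses (`SearchConfig`,
`PipelineThresholds`) with the defaults stated above and in the stage
docstrings.

## Known limitations

* E-values are calibrated only up to monotonicity; absolute values differ
  from NCBI BLAST.
* The progressive aligner is adequate for the homologous, indel-poor
  proteins of this pipeline; badly gapped or very divergent sets should be
  aligned externally (a mafft wrapper is provided).
* The YN00-style estimator uses equal pathway weighting for multi-hit
  codons and a K80-type correction; at high divergence it can differ from
  the original program by more than its small-divergence agreement.
* Boundary inference assumes copies share a substitution-only history;
  large indels between copies shift the offset anchoring.
* The homeology map treats chr9_10-style fused chromosomes by listing the
  same L/S pair for both diploid chromosomes; finer breakpoints are not
  modelled.
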