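# Methods

`trimscape` implements a complete discovery-and-analysis chain for
terminal-repeat retrotransposons in miniature (TRIMs): small
(< 1,500 bp) non-autonomous LTR retroelements consisting of two short
terminal direct repeats (LTRs, 30–500 bp) around a non-coding internal
region (30–2,000 bp), flanked by a 4–6 bp target-site duplication (TSD).
Every stage is validated against synthetic genomes with exact ground
truth; this note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Synthetic genomes (`synthetic_data`)

The background is i.i.d. nucleotide sequence with configurable GC
content (default 0.40).  Gene models (2–6 exons of 150–400 bp, introns
200–800 bp) are laid down first; insertions are then placed uniformly at
random with a 60-bp minimum separation between insertion points and a
150-bp element-free margin at the chromosome ends, optionally biased
into introns by a configurable weight (default unbiased).  An insertion
at background position *p* with TSD length *t* duplicates the host bases
`bg[p-t:p]`, so the final genome reads `bg[:p] + element + bg[p-t:p] +
bg[p:]`.  Deleting every element plus its 3' TSD copy restores the
background byte-for-byte — the generator's central testable invariant.

Elements are built from per-subfamily master sequences (LTRs start
`TG` and end `CA`, as real LTRs overwhelmingly do).  For each copy the
3' LTR diverges from the 5' LTR by a substitution rate drawn uniformly
from [0, `divergence`]; copies diverge from the master at half that
rate.  The mutation model is substitution-only (no indels) — stated as a
non-goal — which downstream lets breakpoint analysis use colinear
coordinates.  Tandem arrays are alternating L/I segments (`"L3I2"`); a
trailing `!` appends the reverse complement of the forward unit,
modelling two inverted elements.  A "decoy" option inserts satellite
tandem repeats, the dominant false-positive class a structural scan must
reject.

Autonomous partners are built by *inserting* a deleted segment
(`M + D'`) into a TRIM at the breakpoint coordinate, where `D'` is a
near-identical copy of the `dup_seq_length` bases immediately 5' of the
breakpoint — the *duplicated internal sequence* relating the partner to
its derivative.  The breakpoint coordinate counts from the element
start, so the duplicated sequence may overlap the LTR end (the published
example geometry — breakpoint near nucleotide 130 with a 115-bp LTR and
25-bp duplication — requires this).  The edge columns of the deleted
segment are forced to mismatch their counterparts so the emitted
duplication is exactly the requested length; without this, chance
matches extend the duplication and the generator's own postcondition
("the emitted dup has length N") would hold only probabilistically.

Methylomes are per-cytosine (forward strand) binomial draws at
per-context rates with Poisson coverage (mean 20).  The three family
archetypes: Type I — body high in CG/CHG/CHH, flanks low (sharp
borders); Type II — CG+CHG high in body *and* flanks; Type III — CG
only.  Defaults: high 0.85, low 0.05.  Small-RNA alignments put
Poisson(40) 24-nt reads on Type I bodies, stray reads elsewhere, plus a
sparse genomic background; the reported library size (default 2,000,000
mapped reads) is the TPM denominator, so stray single reads stay well
below the abundance threshold, as in a realistically deep library.

What the simulations do **not** emulate: indels and nested insertions,
repeat-rich backgrounds beyond the decoy option, sequencing error in
counts, CHH islands, strand-specific methylation, and population-level
variation.  Passing tests therefore demonstrate algorithmic correctness
under the stated model, not performance on real assemblies.

## Structural scan (`structural_scanner`)

Candidates are direct-repeat pairs found by exact k-mer seeding
(k = 12) and ungapped score-maximising extension; the module docstring
gives the precise enumerable definition (anchored ends, one window per
seed run, score = matches − mismatches).  Score-maximising extension was
chosen after identity-maximising extension proved degenerate: at 5%
divergence the highest-identity window is a short perfect sub-repeat,
not the full LTR.  LTR-pair identity is thresholded at 0.80 by default,
aligned with the 80/80 clustering rule; primer-binding-site and
polypurine-tract features are deliberately not scored.

Two artefact classes arise when two copies of one element lie within the
spacing window of each other: a "giant" pair whose repeat unit is a
whole element, and a "spacer" pair borrowing one LTR from each
neighbour.  These are removed before overlap resolution by
witness-based rules (a candidate is dropped when a credible candidate
lies wholly inside it minus one LTR, strictly contains one of its LTR
windows, or donates both of its LTR windows).  Witness credibility is
enforced by judging candidates shortest-first against already-accepted
ones and sweeping the survivors once — a simultaneous or fixed-point
formulation lets artefacts kill the genuine elements they overlap.
Overlap resolution proper keeps the higher-identity, then longer, then
leftmost candidate.  Closely spaced same-subfamily copies remain the
main residual failure mode (~2–4% of elements at realistic densities),
and three or more equally spaced copies are better handled by the
tandem-array module.

Boundary refinement is two-stage.  `refine_boundaries` hill-climbs LTR
window placements (±15 bp) on alignment identity with 5'-TG…CA-3'
preference.  `polish_boundaries_tsd` then snaps element boundaries onto
an exact flanking TSD within ±25 bp, ranking placements by: any TSD >
intact TG…CA termini > identity quantised into 0.02 bins > smallest
shift > longest TSD.  The quantisation makes substitution-noise ties
break on the biological signals; the termini dominate because chance
placements essentially never show all four.  This automates the manual
exact-boundary inspection of a curated survey.  TSD readings are
genuinely ambiguous when the element's first base equals the base after
the 3' TSD copy (both a k and a k+1 reading exist); the ranking prefers
the reading consistent with intact termini.

## TRIM criteria (`trim_filter`)

A candidate is a TRIM iff (1) it is < 1,500 bp, gap-free (no `N`) and
TSD-delimited; (2) its provisional 80/80 cluster contains either ≥ 2
complete copies with *different* TSD sequences or ≥ 1 complete copy plus
≥ 1 solo LTR; (3) it has no retrotransposase coding capacity.  Identical
TSDs at different loci conservatively count as one supporting copy: the
criterion exists to reject segmental duplications and tandem repeats,
which replicate the flanks together with the "element".  Coding capacity
means a stop-free six-frame peptide of ≥ 100 residues aligning to a
supplied retroelement protein at ≥ 50% identity over ≥ 80 residues — an
identity-based stand-in for an E-value cutoff, since no external search
engine is invoked.  Solo LTRs are genomic matches of the LTR alone at
≥ 80% identity over ≥ 80% of its length outside all candidate spans (the
threshold is adopted from the subfamily rule; the original choice is not
recorded anywhere).

## Clustering (`clustering`)

Subfamilies: single-linkage within a genome under identity ≥ 0.80 and
coverage ≥ 0.80 of the shorter element (best local alignment, masking
scores +1/−1/−5/−1).  Consensus building uses a star alignment to the
longest member with majority vote per reference column — deterministic
and linear, at the cost of ignoring insertions relative to the
reference.  Families: single-linkage across genomes where the best local
alignment spans ≥ 50 bp and ≥ 5% of the query consensus at ≥ 70%
identity, required in at least one direction; the identity floor
replaces the published E-value threshold.  Conservation labels follow
directly from a genome → plant-family taxonomy table.

## Library masking (`library_masker`)

Each subfamily consensus (layout LTR + internal + LTR) is aligned
locally to both strands via seeded windows; within a window, alignment
is repeated left and right of each accepted hit so tandem copies are all
recovered.  Scores use the masking convention (match +1, mismatch −1,
gap open −5, extend −1) scaled ×10, with cutoff 250 and a 50-bp length
floor; no low-complexity pre-filtering is applied.  Completeness:
*complete* = footprint covers ≥ 80% of the consensus and reaches into
both terminal 20-bp windows; *solo LTR* = confined to one LTR's
coordinates covering ≥ 80% of it; else *fragmented*.  The published
analysis never states its complete/fragmented rule; these thresholds are
this package's definition and are exposed as parameters.  Summaries
count copies and masked bp on interval unions (overlaps counted once).

## Tandem arrays (`tandem_array`)

Runs of LTR/internal segments with inter-segment gaps ≤ 10 bp (the
adjacency tolerance is ours; nothing is published) containing ≥ 3 LTRs
are arrays; `L2I1` elements are not.  Structure strings count segments
(`L3I2` = two elements sharing the middle LTR, represented once);
`inverted` flags strand changes within the run; runs not delimited by
LTRs are flagged `non_canonical` rather than rejected.  Whole-array TSDs
are reported but never used as a filter, since the evidence on whether
curated TA-TRIM calls required one is ambiguous.

## Gene context (`genic_context`)

Insertions take one category with precedence exon > intron > 1.5-kb
upstream > intergenic, so boundary-spanning hits are counted once;
"near" means upstream only, and a hit in two genes goes to the gene
whose exon it touches, else the longer.  TRG/NTRG comparisons use
two-sample t-tests on log-transformed metrics.  Size classes are the
bottom/top 20% of genes by length; densities are reported per gene
(2 decimals) and per kb (4 decimals), which on the published soybean
inputs reproduces 0.17 insertions/gene and 0.0183 vs 0.0028
insertions/kb.  Gene capture aligns element internal regions to spliced
transcripts (≥ 70% identity over ≥ 50 bp); `exon_only` is decided by
whether the unspliced-gene alignment beats the transcript alignment and
overlaps an intron.

Ka/Ks is the Nei–Gojobori (1986) estimator: fractional synonymous site
counts per codon (mutations to stops excluded from the denominator),
pathway-averaged difference counts for multi-substitution codons
(stop-passing pathways excluded unless all are blocked), and
Jukes–Cantor correction.  This is a deliberate, documented substitute
for a maximum-likelihood codon-model chain; it requires pre-aligned,
in-frame sequence pairs.  Identical inputs give Ka = Ks = 0 with an
undefined ratio; proportions ≥ 3/4 give an infinite corrected rate.

## Epigenetics (`epigenetics`)

Methylation calls: one-sided binomial tails against the bisulfite
non-conversion rate, Benjamini–Hochberg corrected across covered
positions (α = 0.01); uncovered positions are skipped.  Weighted levels
are Σ mC / Σ coverage over a region's cytosines of one context, NA when
uncovered — invariant under count-weighted splitting and pooling.
Metaprofiles rescale bodies into 20 bins with fixed-width flank bins
over 2 kb.  sRNA abundance is TPM with 1/k weight for a read mapped at
k loci; the denominator is the library's total mapped reads when known,
else the table's distinct reads.

Family typing thresholds (all exposed, reported in output metadata,
and calibrated by this package — the source analysis describes the
classes only qualitatively): Type I requires 24-nt body abundance
≥ 5 TPM, body CHH ≥ 0.10 and a summed body-minus-flank excess ≥ 0.10;
Type III requires low sRNA, body CG ≥ 0.40 with CHG and CHH below 0.10;
everything else is Type II, and missing levels give `unclassified`.
Gene bodies are `C_methylated` when CHG or CHH is ≥ 0.05 and binomially
enriched over background, `CG_body_methylated` when only CG is, else
`unmethylated`; < 5 reads per context is `uncallable`.

## Comparative analyses (`comparative`)

Partners are genomic LTR-pair matches of a query element's LTR
(≥ 0.79 identity, span ≥ 3 kb) whose intervening region also shares
≥ 100 bp with the query internal region.  Breakpoints come from a
colinear prefix/suffix scan: the junction maximises prefix + suffix
matches, ties resolved to the 3'-most placement so a duplicated internal
sequence sits immediately 5' of the breakpoint; both blocks must match
at ≥ 85%.  The duplicated sequence is the score-maximal left extension
from the junction at ≥ 90% identity and ≥ 8 bp.  The colinear scan is
valid under the substitution-only divergence model; real data with
indels would need the blocks aligned first.  Autonomy uses a 900-residue
stop-free-frame floor (configurable) plus coding capacity, calibrated so
~1,200–1,600-residue retrotransposases pass and ~400-residue truncations
fail.

Polymorphisms between two assemblies: both 500-bp flanks of an annotated
element are mapped onto the other genome (falling back to 250-bp flanks
when another polymorphic insertion sits inside the flank); a call
requires unique placements at ≥ 90% identity on one chromosome whose
junction overlap is a single 4–6 bp TSD copy.  Multi-locus flanks are
returned as ambiguous, not called.  Calls are symmetric under swapping
genome roles.

## Problem sizes and numerical conventions

Validation sizes were chosen to exercise realistic densities while
staying cheap: scanner recovery at 100 elements in 2 Mb (≈ the published
per-genome copy density), oracle equivalence on 8-kb genomes with
reduced structural bounds, fraction accuracy on 300 kb / 30 elements,
typing on 50 families in 400 kb, polymorphisms on 10 + 10
genome-specific insertions in 300-kb genome pairs.  All coordinates are
0-based half-open internally; GFF3 is written 1-based inclusive.  All
randomness flows from explicit integer seeds; identical spec + seed
yields byte-identical outputs.  Alignment ties resolve deterministically
(documented sort keys).  Degenerate inputs (empty regions, zero
coverage, zero-length deletions) return empty/NA results rather than
raising, except where the input violates a stated precondition.
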