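# Methods

This note documents the models and procedures implemented in ltrscape,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Life-cycle model and census statistics

An intact LTR retrotransposon is modelled as TSD + 5'LTR + internal
(Gag-Pol) + 3'LTR + TSD. Unequal intra-element recombination collapses an
intact element to a solo LTR flanked by a single TSD; decay and nested
deletion produce truncated elements retaining one LTR and a partial
internal fragment on one side. The census statistics treat counts of
intact (I), solo (S) and truncated (T) loci as proxies for the balance of
element birth (I) and removal (S, T):

- S:I, T:I, (S+T):I, and the total S+T+I, genome-wide;
- per-family ratios and the proportion of families with S:I > 3
  ("high elimination"). Families with I = 0 but S+T > 0 count as high
  elimination: their ratio is effectively infinite and they represent
  complete removal, the extreme of the signal this statistic measures;
  the output notes them.

Ratios are held at full precision internally. Formatted output renders
the ratio columns half-up to two decimals and the family percentage by
truncation to two decimals, matching the established reporting convention
for these statistics.

### Classification by flanking homology

Intact elements come from the input annotation (de novo discovery and
superfamily classification are out of scope; family labels are trusted).
Per family, the first intact element supplies an LTR reference and an
internal reference. The LTR reference is searched genome-wide; hits
overlapping any annotated intact span are the intacts' own LTRs and are
excluded. Each remaining hit is classified by searching a flank window on
each side for homology to the internal reference: neither side → solo,
one side → truncated, both sides → "intact-overlap", returned to the
caller for reconciliation rather than silently dropped.

Parameters:

- `min_identity` (default 0.8), `min_length` (100 bp), `word_size`
  (11 bp): floor of the homology search, BLASTN-like defaults.
- flank window: 1.5 × internal-reference length, capped at 15 kb. It must
  span a displaced internal domain without reaching the next element.

The search is seed-and-extend: exact `word_size`-mers are indexed over
the genome (packed 2-bit words, sorted array + binary search), seeds are
extended gaplessly along their diagonal with an X-drop rule (match +1,
mismatch −2, X = 30), and overlapping hits on one scaffold/strand are
merged keeping the higher-identity extent. Extension is gapless by
design: the divergence regime the census operates in (≥ 80% identity
within a family) is substitution-dominated, and the simulator's mutation
model is substitution-only, so a gapless search is the exactly matching
model and stays checkable against an exhaustive Smith-Waterman oracle
(the test suite does this on ≤ 100 kb genomes, both strands). Genomes
with indel-rich families would need a gapped extension stage; that is a
known limitation.

### Scaffold-length stabilization scan

Short scaffolds are enriched for unassembled repeats and carry solo LTRs
without their intact counterparts, inflating S:I. The scan computes S:I
over a grid of minimum-scaffold-length filters (default: 0 plus the
deciles of the scaffold-length distribution) and selects the first grid
point after which the relative change in S:I stays below `tolerance`
(default 0.01) for `patience` (default 2) consecutive steps. A grid that
eliminates every intact element truncates the scan with a flag; a ratio
that never settles selects 0 and reports `stable=False`. The thresholds
chosen on real assemblies by this rule are a property of the rule and the
assembly, not comparable to any particular published filter length.

## Insertion dating

The two LTRs of an intact element are extracted in element orientation
and aligned globally under an affine scheme (match +2, mismatch −3, gap
open −5, gap extend −2; a gap of length L costs open + L·extend). The
aligner is a Gotoh three-state dynamic program with a deterministic
traceback preferring a diagonal step over a gap at every tie; its optimal
score is verified in the tests against an independent full-matrix
implementation. Transition (P) and transversion (Q) proportions are
computed over ungapped, non-ambiguous columns only.

Distances:

- K2P (default): K = −½ ln(1−2P−Q) − ¼ ln(1−2Q); standard for LTR
  dating because transitions dominate early divergence.
- JC69: K = −¾ ln(1−4p/3), p = P+Q.
- raw: K = P+Q.

Inputs outside a model's log domain raise a saturation error naming the
model; the element-level pipeline reports such elements with NaN K/T
rather than aborting. Insertion time is T = K/(2r), r = 1.3×10⁻⁸
substitutions·site⁻¹·yr⁻¹ by default and configurable. Histograms of T
use half-open bins [k·w, (k+1)·w) per superfamily.

Because published insertion-time distributions depend on the upstream
annotation software's internal distance estimator, absolute ages from
real data are not a validation surface; the validation here is exact
recovery of planted P, Q and the closed-form K on simulated elements.

## Structural-variant enrichment

Region classes (INV/SPE/SYN, others carried through) are merged within
class on load; cross-class overlaps are left intact and classes are
evaluated independently. The overlap statistic is the number of query
intervals overlapping a class by ≥ 1 bp (half-open intervals; abutment is
not overlap). The null redraws each interval uniformly on a scaffold
chosen with probability proportional to scaffold length among scaffolds
it fits, preserving the length multiset but not inter-interval spacing —
mirroring shuffle-style randomization, so intervals may overlap each
other under the null. With n_perm permutations (default 1000, minimum
99), z = (obs − mean)/sd of the null and the empirical p-values carry the
+1 correction, p_enrich = (1 + #{null ≥ obs})/(n_perm + 1), so p is never
0 and the test is valid (super-uniform under the null).

Coverage tables (percent of class bases covered by ≥ 1 LTR interval) are
base-pair based — whether published per-class proportions are count- or
base-based is ambiguous, and base-pair coverage is the idempotent choice
(overlapping elements cannot double-count). Three decimals are reported.

Seeding: replicated calibration studies must give each replicate
independent generator streams for its data draw and its permutation draw
(`numpy.random.SeedSequence.spawn`). Reusing arithmetically related
integer seeds across the two roles measurably distorted the empirical-p
distribution in one configuration and is avoided throughout.

## Gene duplication, pseudogenes, expression

Genes are ranked per scaffold by start (ties by end, then id), so
ranking is invariant to input order. For a homologous pair on one
scaffold, intervening = |rank_a − rank_b| − 1; TD ⟺ 0, PD ⟺ 1..10
(`--max-proximal`), otherwise none; cross-scaffold pairs are none.
"Adjacent" is purely positional, irrespective of strand. Pseudogene
candidates are kept iff identity > 30 and parent coverage > 50, both
strict inequalities; whether the upstream pipeline's similarity is
matrix-weighted or exact identity is an input-semantics question — the
column is named `identity` and the thresholds are configurable.

For expression, each gene is assigned to the class (SPE or SYN) holding
> 50% of its combined SPE+SYN overlap bases; no overlap → none (excluded
downstream), an exact tie → ambiguous (also excluded). With two classes
the majority rule can only fail on an exact tie, so "ambiguous" is a
knife-edge case by construction; it exists so that a future third class
or a stricter majority threshold slot in without changing the contract.
Values are transformed log2(x+1) (expression units are taken as given;
the transform makes the planted log-scale effect additive) and compared
with a two-sided two-sample t test per stage and gene set. Welch's
unequal-variance form is the default for robustness; the pooled-variance
Student form is available by flag. Significance tiers: *** p<0.001,
** p<0.01, * p<0.05, ns.

## The simulator: what it emulates, and what it does not

`SimConfig` defaults describe the study conditions used throughout the
tests: 12 scaffolds, 80–500 kb, lengths from a truncated power law
(exponent 1.6) so the stabilization scan has structure to find; 6
families alternating Copia/Gypsy; 50 intact, 100 solo, 30 truncated
elements (~2 Mb genome); 300 bp LTRs, 2 kb internal domains, 5 bp TSDs
(typical LTR-RT biology); LTR-pair divergence uniform on P ≤ 0.05,
Q ≤ 0.02 (young elements, safely above the 80% search identity floor);
region fractions INV 0.14 / SPE 0.38 / SYN 0.42, inside the ranges
whole-genome comparisons of congeneric plants report; five expression
stages around a log2 baseline of 6 with sd 1.5.

Mutations are placed at distinct sites, so planted P and Q are exactly
recoverable — dating recovery is an exact test, not a statistical one.
Placement draws a scaffold proportional to length and a uniform start,
accepts with probability proportional to the region-class bias weight,
and enforces a minimum inter-element gap (default 4 kb, wider than the
classification flank window, so a planted solo's flanks can never contain
a neighbour's internal domain). Two consequences worth knowing:

- At high element density the gap constraint drives placement toward the
  1-D random-parking jamming limit; strongly biased configurations can
  then not realize their bias because the favoured class fills up. The
  enrichment power analyses therefore use a 500 bp gap — the 4 kb gap is
  a census artifact, not an enrichment condition.
- Placement with a non-overlap constraint is *not* the randomization null
  of the permutation test (which allows overlaps); calibration studies
  draw their replicate data from `randomize_intervals` itself.

Not emulated: nested insertions, indels between LTR pairs, base
composition and methylation context, family sequence similarity across
families, read-level data, and assembly artifacts other than the
scaffold-length effect. Passing tests therefore demonstrate correctness
of the statistics and their implementations under the stated generative
model — not robustness to everything real assemblies do.

## Coordinates, formats, determinism

All in-memory intervals are 0-based half-open; GFF3 is written/read
1-based closed; BED is 0-based half-open with the class in column 4;
FASTA goes through Biopython. Every stochastic routine takes a seed or a
`numpy.random.Generator`; a fixed `SimConfig.seed` makes the whole bundle
byte-identical, with child streams for the gene set and expression
derived deterministically from it. Problem sizes in the test suite
(2 Mb genomes, 999-permutation tests, 200-replicate calibrations at
n_perm = 199) were chosen as the smallest sizes at which the planted
effects and calibration bands are unambiguous.
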