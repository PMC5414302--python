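# Methods

This note documents the statistical model behind `lactamir`, the defaults
it ships with, the simulator's scope, and the design choices made where the
underlying workflow is conventionally underspecified.

## The two-library design

The package targets the classic pooled design: RNA from many individuals is
pooled into one small-RNA library per condition, so there is no
biological-replicate variance to estimate. Inference is therefore
conditional and exact: given the count *x* of a miRNA in library 1, the
count *y* in library 2 under the null hypothesis of equal underlying
abundance follows

p(y|x) = (N₂/N₁)^y (x+y)! / ( x! y! (1 + N₂/N₁)^(x+y+1) ),

where N₁, N₂ are the clean-read totals. This is the negative-binomial
posterior predictive that arises from placing a flat prior on the common
Poisson rate — depth imbalance enters only through N₂/N₁. Both tails
include the observed point: C = Σ_{y′≤y} p(y′|x), D = Σ_{y′≥y} p(y′|x)
(so C + D = 1 + p(y|x)), and the two-sided p-value is min(1, 2·min(C, D)).
One caveat worth knowing: because the doubled tail includes the observed
point, the two-sided p-value is not exactly invariant under swapping the
libraries — the swapped value differs by at most twice the larger of the
two observed-point probabilities, which matters only at very small counts.
A one-sided variant (`sided="one"`) returns the smaller tail itself.

The test consumes **raw counts**, not normalized values: the factorials in
the formula require integers, and depth differences are what the N₂/N₁
factor is for. Normalized expression — NE = count/N × 10⁶, reads per
million — drives only the fold change and the filters.

Filtering follows the conventional order of operations and its reasons:

1. **Low-expression exclusion first.** A miRNA with NE < 3 in *both*
   libraries is excluded before anything else. Evaluating this before zero
   substitution is deliberate: substituting first would lift true zeros to
   0.001 but never above 3, yet it would blur the rule's intent — the
   filter is about observed expression, so it sees the raw NE values.
2. **Zero substitution.** Surviving NE values of exactly zero become 0.001
   so log₂(NE₁/NE₂) is always finite; a count of zero against a deeply
   sequenced signal then yields a fold change near ±20 rather than ±∞.
3. **Calling.** up ⇔ log₂fc > 1 ∧ p < 0.05 ∧ FDR < 0.05 (down is the
   mirror image). FDR is Benjamini–Hochberg computed over the tested
   (non-excluded) miRNAs only, via `statsmodels`. All four thresholds are
   `DEParams` fields.

Numerics: the pmf is evaluated in log space with `gammaln`; tails are
accumulated with `logsumexp`, which is insensitive to summation order; the
upper tail is 1 − (C − p(y|x)), floored at the observed pmf and capped at
1. Agreement with an exact-rational oracle (Fraction arithmetic over the
printed formula) is within ~3 × 10⁻¹³ across x, y ≤ 200 and depth ratios
½–2.

## Cleaning rules

The six rule names are standard; their thresholds usually are not
published, so the package declares them explicitly (constants shared with
the simulator, overridable via `CleanParams`):

| rule | default |
|---|---|
| low quality | > 50 % of bases below Phred 20 (Phred+33) |
| 5' adapter contaminant | read starts with ≥ 12 nt of the 5' adapter |
| no 3' adapter | leading 8 nt of the 3' adapter absent |
| poly(A) | trimmed insert ≥ 80 % A |
| no insert | trimmed insert empty |
| too short / overlong | trimmed insert outside 18–30 nt |

A read is charged to the **first** rule it violates, which makes the
removal ledger additive: raw = clean + Σ ledger, asserted on every run.
The `overlong` class enforces the upper end of the gel size selection and
is reported separately from the six named rules. Because a clean read is
stored adapter-trimmed, literal re-cleaning of the output would remove
everything under "no 3' adapter"; the meaningful idempotence property —
re-cleaning the inserts with the adapter re-appended removes nothing — is
what the test suite asserts.

## Annotation

Contaminant ncRNA classes are screened before miRNA matching, in the fixed
priority rRNA > tRNA > snRNA > snoRNA > scRNA > srpRNA, by exact substring
match against the class references (a short read is a fragment of a longer
ncRNA). miRNA assignment is near-full-length: a read is comparable to a
mature sequence when their lengths differ by ≤ 2 nt, mismatches are counted
ungapped over the common prefix, and up to 2 substitutions are allowed.
Ties at the minimal mismatch count go to the lexicographically smallest
miRNA id and are tallied in an `ambiguous` counter — family members
(-5p/-3p arms, lettered paralogues) do collide in practice, and silent
arbitrary assignment would hide that. Matching is sense-strand only, as
small-RNA protocols ligate adapters directionally. Degraded-mRNA and
repeat classes fold into `unannotated` unless references are supplied;
genome mapping and novel-miRNA discovery (hairpin folding, precursor
calling) are out of scope.

## Enrichment

The hypergeometric upper tail P(X ≥ m) is computed by direct log-space
summation from i = m to min(n, M) — analytically identical to
1 − Σ_{i<m}, numerically stabler for small P. The universe defaults to
all genes with at least one annotation in the supplied file; an explicit
universe can be passed. BH correction runs across the terms of one call,
so GO namespaces and KEGG should be supplied as separate files to be
corrected per family. No ontology-graph propagation is performed; the
annotation is taken as given. Because the test is exact and discrete, its
null rate at p ≤ 0.05 is conservative (≈ 2–4 % in the shipped
calibration), not anti-conservative.

## Network

Nodes are the up/down miRNAs and their targets from the supplied pair
table; the "relative weight" of an edge is defined here as the miRNA's
|log₂fc| — a declared choice, since degree (the hub criterion) ignores
weights entirely and the weight only decorates exports (edge-list TSV and
GraphML, both Cytoscape-friendly). Duplicate pairs collapse with a count;
DE miRNAs without targets remain as isolated nodes; hub ranking sorts by
descending degree with lexicographic tie-break, per partition.

## qPCR

Comparative-Ct (Livak) with technical replicates averaged on the Ct scale,
per-sample ΔCt against the reference assay (default 18S rRNA), group-mean
ΔΔCt against an explicitly named calibrator group, relative expression
2^−ΔΔCt. The calibrator's own ratio is exactly 1; ratios are invariant to
any constant Ct shift and invert under group swap. Between-group
significance is a two-sample t-test on per-sample ΔCt values (a declared
choice; the test itself is plumbing). Amplification-efficiency correction
is out of scope. Concordance with sequencing counts an assay as agreeing
when a significant ratio > 1 meets an "up" call, a significant ratio < 1
meets "down", or neither platform calls it differential.

## The simulator

What it emulates: a log-normal relative-abundance profile (σ = 1.5 by
default) whose heavy tail makes a handful of miRNAs dominate the library,
as real small-RNA libraries do; an insert-length profile peaked at 22 nt
(mode weight ≈ ⅓, with the most abundant miRNA pinned to the modal
length); contaminant fragments sampled as 18–25 nt windows of 60–120 nt
ncRNA references; planted differential expression as per-miRNA log₂
effects multiplying the library-2 Poisson expectation (so a +2 effect is a
"down" call on the library-1-over-library-2 fold change); and junk reads
built per class against the same constants the cleaner uses, so each junk
read is removed by exactly its intended rule. Contaminant references are
rejection-sampled so that no 18–25 nt window comes within 2 mismatches of
any miRNA, guaranteeing clean category separation. Read ids carry no truth
information; truth lives in a separate table (per-miRNA counts and
effects, per-read categories in emission order). A single seed determines
every output byte-for-byte.

Default fractions: contaminants {rRNA 5 %, tRNA 3 %, snRNA 1 %, snoRNA
1 %, scRNA 0.5 %, srpRNA 0.5 %}, junk {low quality 2 %, 5' contaminant
1 %, no 3' adapter 2 %, poly(A) 1 %, no insert 1 %, too short 2 %} — a
plausible mid-quality run with ~83 % usable reads.

What it does **not** emulate, hence what passing tests cannot show:
sequencing errors (every legitimate read is an exact reference copy, so
annotation sensitivity at 1–2 mismatches is exercised only by dedicated
fixtures, not by the bulk simulation); isomiR length/edit heterogeneity;
hairpin precursors or genome coordinates; and biological replicate
variance — the planted-recovery benchmark validates the pipeline's
machinery under its own Poisson model, not the adequacy of a
no-replicate design for real tissue.

Replicate pools: the generator emits one FASTQ per library by default;
splitting a library across multiple files is possible by running the
generator per group seed, but the analysis treats one pooled library per
condition, matching the design it implements.

## Benchmark sizes

The shipped end-to-end benchmark (also run by `scripts/acceptance.py`)
uses 300 miRNAs, 30 planted effects at |log₂| = 2, and 2 × 10⁶ reads per
library; at that depth every planted miRNA is recovered with an empirical
false-discovery proportion of 0 at the default thresholds, and the run
completes in well under a minute on one core. The oracle grids (201 × 201
counts × 3 depth ratios; all hypergeometric configurations with N ≤ 12)
are exhaustive rather than sampled. Null calibration uses 1000 draws of
100 targets from a 2000-gene universe over twenty 100-gene terms.
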