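# Methods

This note documents the models, conventions and numerical choices behind `mirseq`,
and what the synthetic-data tests do and do not demonstrate about real data.

## Sequence conventions

All sequences are held in the DNA alphabet; miRBase-dialect catalogs (RNA alphabet)
are converted U→T on load, since sequenced tags are cDNA. Records containing N are
rejected at load; mature sequences must be 18–30 nt. Coordinates in reports are
1-based inclusive; the seed region is positions 2–8 of the mature sequence, derived
on demand and never stored. Catalog entries with identical sequences under different
names (miRNA families such as let-7) are kept and flagged; quantification credits a
shared tag fully to every member, because with exact-match assignment any fractional
split would be arbitrary. The multimap flag in the output lets users collapse
families afterwards if they prefer.

## Cleaning

Raw reads are filtered with a fixed rule precedence — low mean quality (< Q20), any
N, 5′-adapter contamination (read starts with the 5′ adapter), missing 3′ adapter
(first 8 nt of the adapter not found; when found the read is trimmed there),
homopolymer insert (one base ≥ 80% of the insert), and insert length outside
18–30 nt (the gel-excision window of small-RNA library preps). The first matching
rule claims the read, so the removal categories plus survivors always partition the
raw reads; this conservation law is property-tested on arbitrary inputs and is the
pipeline's primary bookkeeping guarantee. Adapter matching is exact (no
mismatch-tolerant alignment): vendor cleaning pipelines vary, and an exact,
auditable rule was preferred over emulating any one of them. Either adapter may be
omitted, in which case its rule is skipped — simulated libraries are written
insert-only.

## Quantification and TPM

Tag→miRNA assignment is exact full-sequence identity (a hash lookup), the
zero-mismatch criterion that short-read aligners are usually configured for at
catalog scale; an aligner adds nothing when only perfect matches count. Unmatched
tags form the unannotated pool consumed by variant profiling. TPM uses the library's
**total clean reads** as denominator — not the miRNA-assigned subtotal — so values
are comparable across stages that see different annotated fractions. Zero counts are
reported, not dropped: a miRNA absent in one library is the "specifically expressed"
case the differential stage must handle. IsomiR reads are *not* added to canonical
counts (config flag `include_isomirs` is deliberately absent from the default path;
canonical counting is exact-match only, and variant profiling is reported
separately).

## The exact conditional test

For two pooled libraries there are no replicates, so the comparison uses the exact
conditional statistic for two counts (Audic–Claverie family):

p(x|y) = (N₂/N₁)^y · (x+y)!/(x!·y!) · (1+N₂/N₁)^−(x+y+1)

- **x and y are raw counts.** The factorials require non-negative integers;
  normalized expressions are used only for fold changes. This is stated prominently
  because two-library pipelines often describe the inputs loosely as "normalized
  expression".
- **Implementation.** The point mass is computed in log-gamma space (finite and in
  (0,1] for counts up to ~10⁷). Tail sums use the algebraic identity
  p(x|y) = (N₁/N₂)·NB(x; y+1, N₂/(N₁+N₂)) = NB(y; x+1, N₁/(N₁+N₂)), so cumulative
  probabilities come from the negative-binomial CDF rather than explicit series —
  numerically stable and O(1). An exact-rational oracle (Python fractions,
  x+y ≤ 200) provides the independent check; the log-space path agrees with it to
  < 10⁻¹³ relative error over the tested grid.
- **Two-sided construction.** p = min(1, 2·min(lower, upper)) with
  lower = Σ_{k≤x} p(k|y) and upper = 1 − Σ_{k<x} p(k|y) clipped to [0,1]. A point
  mass is not a p-value; doubling the smaller tail is the conventional exact-test
  construction. Note Σ_x p(x|y) = N₁/N₂ (the distribution is conditional over y, not
  x — Σ_y p(x|y) = 1), so for unequal depths the complement-based upper tail is a
  definition, not an identity; at N₁ = N₂ the two coincide. `mode="point"` retains
  the literal point mass for users reproducing the printed formula.
- **Calibration.** On 10,000 null miRNAs (equal abundance, multinomial libraries of
  10⁶ reads, expected count 100) the two-sided rejection fraction at α = 0.05 is
  ≈ 0.045 — mildly conservative, as expected for an exact test on discrete counts.

## DEM calling

Filters first: miRNAs with TPM below the floor (default 1) in **both** libraries are
removed — "both" rather than "either", since an either-rule would erase exactly the
library-exclusive miRNAs the analysis wants to surface. A per-miRNA confidence
column (meant for externally predicted novel miRNAs; default 1.0) is floored at 0.95.
BH-FDR is applied over the surviving tests only (filters are independent of the
statistic). Calls use strict inequalities: adjusted P < α (0.05) and
|log₂FC| > 1. Fold change is log₂(TPM₂/TPM₁) with optional pseudocount; with
pseudocount 0, one-sided zeros produce ±inf and an exclusive status, and such rows —
which necessarily pass the floor on their nonzero side — are called up/down on
adjusted P alone with direction from the nonzero library. Both count-based and
TPM-based fold changes can be had (pass counts as TPM columns if desired); neither is
privileged.

## Variant profiling

IsomiR classes are defined purely positionally, with precedence trim3 > add3 >
shift5: 3′ trims and additions of 1–2 nt, and ±1 nt 5′ shifts whose 3′ end lies
within ±2 nt of the mature. Position-1 substitutions are classified as
`nonseed_sub`, not 5′ variants: a "one-nucleotide 5′ change" is ambiguous between
shift and substitution, and the seed definition (2–8) cleanly excludes position 1.
Seed-edit candidates must have the mature's exact length and differ at exactly one
position in 2–8; combined length-variant + substitution tags are out of detection
scope (no unambiguous event definition exists for them). Detection builds a
one-substitution neighborhood index over **all** positions (L×3 variants per mature,
~20k index entries for a 300-miRNA catalog) so each tag is one lookup and seed and
non-seed substitutions fall out of the same query; the quadratic all-pairs scan is
kept as a test oracle and the two routes are asserted identical. The default
supporting-count floor is 5 reads — an explicit, configurable guard against
sequencing-error artifacts, not a biological claim. The substitution spectrum counts
distinct (miRNA, position, from, to) events, not reads, so one abundant edited tag
cannot dominate the 12-cell table.

## Enrichment and ΔΔCt

Term enrichment is a plain hypergeometric upper tail P(X ≥ k) over a user-supplied
term→gene TSV with an explicit universe (no ontology files, no DAG propagation —
term content is database-version-bound and out of scope). Q-values reuse the same BH
step-up as the expression stage. The 2^−ΔΔCt computation subtracts the reference
gene (e.g. U6 snRNA) per sample, then differences treatment and control group means;
per-sample fold changes are also reported for paired designs. It is invariant to
any per-sample additive Ct shift, which the tests assert.

## The simulator

`SimulationConfig` defaults define the standard study conditions used throughout the
tests: 300 miRNAs of 18–25 nt, two libraries of 10⁶ reads, log-normal(0, 1.5)
baseline abundance floored at 50 TPM (waterfilling, then renormalized to 10⁶ TPM),
10% of miRNAs given a ±2 log₂ fold change in condition B (random sign, B
renormalized — so non-DE miRNAs carry the small compositional shift a closed
composition implies), per-read isomiR probabilities trim3 0.15 / add3 0.05 / shift5
0.02, seed-edit rate 0.002, 5% contaminants (poly-A runs, 8–15 nt fragments, random
18–30-mers in equal parts), and 0.1% per-base substitution error applied last. The
isomiR/edit rates are test-power placeholders, not biological estimates. Trim and
addition lengths are geometric(½) truncated at 2 nt, keeping tags inside the
18–30 nt window. Reads are generated in collapsed form (sequence→count), which makes
full-depth simulation effectively free; FASTQ expansion (constant Phred-40
qualities) happens only on write. Quality filtering is therefore exercised by
crafted fixtures with planted low-quality reads, not by the simulator.

What passing these tests shows: the pipeline's bookkeeping is exact, the test is
calibrated under its own sampling model (multinomial counts from a fixed
composition), and planted effects of the stated size are recovered. What it does not
show: robustness to biological replication variance (the pooled design has none),
adapter-sequence artifacts at the nucleotide level, indels, position-dependent error
profiles, or isomiR distributions of real tissues.

## Determinism and problem sizes

A single global seed drives every stochastic stage through per-stage SHA-derived
sub-seeds, so adding a stage never perturbs another's stream; two runs of the full
pipeline under one seed are byte-identical (run-metadata files record input paths
and checksums, so comparisons are made from identical working layouts). The test
suite and the acceptance script run the calibration at 10,000 null miRNAs, the
recovery analysis at the standard 300-miRNA/10⁶-read conditions, variant recovery at
40 miRNAs × 150k reads with an elevated edit rate (so planted templates clear the
count floor), and the end-to-end determinism check at 10⁵ reads per library —
determinism is size-independent, so the smaller depth is used there.

## Known limitations

- The exact conditional test models sampling noise only; with biological replicates
  a dispersion-aware model (negative-binomial GLM) should be preferred.
- Exact-match quantification ignores isomiR mass by design; heavily 3′-modified
  miRNAs will be under-counted relative to isomiR-aware quantifiers.
- Seed-edit detection cannot see edits co-occurring with length variation, and makes
  no claim about the biological mechanism (e.g. A-to-I editing) behind a
  substitution.
- The enrichment module tests over-representation only, against whatever term map it
  is given.
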