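# Methods

This note documents the models and procedures implemented in
`primerval`, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that
affect results.

## IUPAC matching semantics

A degenerate primer position denotes a set of concrete bases. Two
distinct semantics are used deliberately:

- **Binding analysis (boolean).** A template code matches a primer
  code iff the template's base set is a subset of the primer's set.
  A concrete template base matches iff the primer set contains it; an
  ambiguous template code that only partially overlaps the primer set
  counts as a full mismatch.  The binding decision needs to be crisp,
  and the subset rule equals the "some expansion of the primer matches"
  rule for concrete templates (verified against exhaustive enumeration
  over all code pairs in the tests).
- **Penalty scoring (fractional).** The per-position penalty is the
  mean over all ordered concrete (primer base, template base)
  combinations of 0 for equality and the type weight otherwise, so a
  wobble position that partially matches scores between a match and a
  full mismatch.  Template gap and N characters are scored through
  dedicated weight columns rather than expanded.

Input is case-insensitive and U is read as T. Gaps are legal only in
templates.

## Consensus and similarity index

The consensus code of a column is the minimal IUPAC code covering
every base whose frequency among non-gap residues is ≥ the inclusion
threshold, always including the single most frequent base. Ambiguous
input residues contribute fractionally to each base of their set.
**Inclusion threshold default 0.05**: rare variants and sequencing
noise below 5% would otherwise inflate degeneracy at genuinely
conserved columns; the value is exposed in the API and config.
All-gap columns are called N with coverage 0; columns with < 50%
coverage are flagged but still called — the coverage track, not the
index, carries that information.

The similarity index of a window is `1/D` with `D` the product of
per-column set sizes (window 20 bp, step 1 by default). `1/D` lies in
(0, 1]; windows are indexed by their start column. The windowed `D` is
computed from cumulative log set-sizes and rounded back to the nearest
integer, which is exact for any D below ~2^52 (a fully degenerate
20-bp window has D = 4^20 ≈ 1.1e12).

## Binding rule

Defaults follow the stricter published form of the mismatch rule: at
most **3 mismatches** over the primer, **0 mismatches within the
terminal 2 bases** of the 3′ end (the extension end; a terminal
mismatch is disproportionately disruptive to the polymerase). Both
caps and the window width are parameters. Reverse primers are
evaluated after reverse-complementing the plus-strand site so the
terminal window always refers to the primer's own 3′ end.

Gap-containing sites are governed by `missing_policy`:
`missing_if_gap_or_incomplete` (default) treats such a site as neither
bound nor unbound — excluded from bound numerators, retained in
denominators — while `score_as_mismatch` counts each gapped position
as a mismatch. Both readings are plausible for curated alignments with
ragged ends, hence the flag.

When a pair carries no stored site intervals, each primer is placed at
the window of the consensus minimising its total mismatch count, ties
resolved toward the 5′-most start column; placement is therefore
deterministic for a given alignment.

Species-level success means ≥ 1 sequence of the species is bound by
both primers — detection-coverage semantics: one amplifiable template
per species suffices for the species to be detectable.

## Penalty scoring and classification

The score of a primer against a site is

    score = Σ_positions position(dist from 3′) × pair_penalty × adjacency,

with `position(1)` the 3′-terminal multiplier, `pair_penalty` the
fractional type-weighted mismatch credit above, and `adjacency` an
optional extra multiplier when a neighbouring position also
mismatches (default 1 = disabled). Forward and reverse scores are
summed; **Working requires combined < 150 strictly** (exactly 150 is
Failed), the midpoint of the empirical 100–200 zone in which predicted
amplification transitions from success to failure. Missing arises only
from sites that cannot be scored: all-gap (truncated) sites, or any
gap/N when the `gap_as_missing`/`n_as_missing` switches are enabled
(both default off, so gaps and Ns are scored via their weight
columns).

**The shipped weight tables are synthetic.** The packaged file
`penalty_matrices_synthetic_v1.yaml` is a stand-in constructed to have
the structure the method requires — position factor non-increasing
with distance from the 3′ terminus (120 at the terminal base decaying
to 1 past position 23), type factor zero on matches, transitions
weighted below transversions with the comparatively stable G:T pairing
lowest among transversions, and dedicated template gap (2.0) and N
(1.0) columns. Score *magnitudes* under these tables are not
comparable to scores produced under other published weight tables;
every operation accepts a `PenaltyMatrices`, so a transcription of any
published table can be dropped in as a YAML file without code changes.
The classification machinery (threshold, strict boundary, Missing
semantics, per-taxon percentages) is independent of the table values.

## Logistic mixed model

Comparing two primer sets on the same sequences is a paired design
with strong species-level clustering (species differ in how diverged
their binding sites are), so the per-sequence binary success is
modelled with a species random intercept:

    logit P(success_ij) = β₀ + β₁·[improved_j] + u_s(i),   u_s ~ N(0, σ²).

The marginal likelihood is maximised directly: each species' integral
is evaluated by **adaptive Gauss–Hermite quadrature** (15 nodes,
centred at the per-species Laplace mode and scaled by the local
curvature, both obtained by a vectorised Newton iteration), the outer
optimisation is L-BFGS-B over (β₀, β₁, log σ), and Wald standard
errors come from the central-difference Hessian at the optimum
(step 1e-4). With σ fixed at 0 the fit reduces to ordinary logistic
regression and matches `statsmodels.Logit` to ~1e-7, which the tests
use as an oracle; parameter recovery and confidence-interval coverage
are checked by simulation from the model's own generative process.
The default outcome source is binding success (bound/unbound);
penalty-based Working/Failed is available via `outcome="penalty"` but
can be completely separated when one primer set never works, in which
case the fit raises a separation error rather than returning a
divergent estimate. p-values below 1e-16 are reported as "< 1e-16"
alongside the Wald z.

## K80 distances and the barcoding gap

`d = −½·ln((1−2P−Q)√(1−2Q))` with P and Q the transition and
transversion proportions over compared sites. **Pairwise deletion**:
only columns where both sequences have a concrete A/C/G/T are
compared — mini-barcode alignments are short and ragged, and complete
deletion would discard most of the signal. Ambiguous codes are
excluded rather than fractionally counted, keeping P and Q
integer-ratio based as in standard distance software.
**Minimum overlap default 100 sites**; pairs below it, or with a
non-positive log argument (saturation), are retained with
`valid=False`, excluded from the gap statistics and counted in a
saturation report — saturated pairs are a data property worth
surfacing, not an error. The gap is `min(inter) − max(intra)` and is
reported negative when the classes overlap (no clamping). Histograms
use 0.01 (1%) bins by default.

## Synthetic data generator

The generator emulates a curated single-locus barcode alignment:

- a random root sequence; species ancestors evolved from it at half
  the interspecific rate; per-species sequences evolved from their
  ancestor at half the intraspecific rate, all under K80 with a
  transition:transversion event ratio parameter (R = α/2β, so the
  realised substitution spectrum converges to it);
- point gaps and ambiguity codes (N or a two-fold code covering the
  true base) injected at configurable rates outside constrained
  columns;
- primer binding sites **overwritten** to carry exactly the designed
  per-record mismatch counts (total and 3′-terminal) against specified
  primers, built from a random concrete expansion of the primer with
  mismatching bases placed 5′-first (3′-terminal designs occupy the
  terminal-most eligible positions); the generator asserts the
  realised counts equal the design;
- optional designed-missing records whose site is written as all gaps.

Defaults (the desk-scale study conditions): 40 species × 6 sequences,
700 columns, intraspecific rate 0.02 and interspecific rate 0.35
substitutions/site, ts:tv 2.0, gap rate 0.01, ambiguity rate 0.002 —
the shape of a real curated COI dataset (many species, short ragged
alignment, intra ≪ inter divergence) at a size where the whole
pipeline runs in seconds. The default two-pair scenario places the
four primers at disjoint sites and designs reverse-site failures in
~25% (reference pair) vs ~15% (improved pair) of records, reproducing
the qualitative published pattern that reverse-primer binding drives
the pair-level contrast.

What the generator does **not** emulate: phylogenetic tree structure
beyond a star-within-star (no coalescent, no rate heterogeneity),
codon/amino-acid constraint, alignment error, indel evolution
(gaps are i.i.d. noise), or taxon-specific base composition. Passing
tests on synthetic data therefore demonstrate correctness of the
*computations* and recoverability of designed truth — not that any
particular real primer pair achieves the published coverage numbers,
which requires the real curated alignments as input.

All randomness is a pure function of the seed; identical truth
parameters produce byte-identical FASTA.

## Degenerate inputs and edge cases

- Empty alignments, single-species gap analyses, and disjoint record
  sets raise typed errors naming the offending stage/record.
- `expected_amplicon` on a primer pair is stored as supplied and never
  recomputed: published amplicon sizes refer to unaligned fragment
  lengths, which need not equal alignment-column spans.
- Published binding-site coordinates are carried only where they span
  the primer exactly; otherwise placement falls back to the consensus
  scan.
- A combined penalty exactly at the threshold is Failed; a K80 log
  argument exactly at 0 is invalid; a window count is
  `floor((L − w)/step) + 1`.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: the 240-sequence default scenario for pipeline-level checks,
10-kb single-pair simulations for distance consistency, and 200
replicates of 50 species × 20 sequences for mixed-model coverage.
These sizes keep a full run under a minute while leaving estimator
noise well below the tested tolerances.
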