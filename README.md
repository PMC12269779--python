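# primerval

In-silico validation of degenerate PCR primers for mini-barcoding and
eDNA metabarcoding, built around the workflow used to evaluate
group-specific COI mini-barcode primer pairs (the packaged examples are
the ascidian-specific pairs AscCOI and AscCOI2): how well does a primer
pair bind across a curated, aligned reference dataset, how specific is
it against non-target groups, and does the amplified fragment retain a
usable barcoding gap?

It is aimed at people who design or assess group-specific markers from
alignment data: molecular ecologists, barcoding/metabarcoding method
developers, and biodiversity-survey labs.

## What it computes

Given one or more aligned FASTA datasets (gap character `-`, headers
`>id|species[|taxon]` or a separate species-map TSV) and primer
definitions (5′→3′ IUPAC sequences with orientation):

1. **Conservation profile.** An IUPAC consensus of the alignment and a
   sliding-window similarity index `1/D` (window 20 bp, step 1), where
   `D` is the degree of degeneration of the window — the product of
   per-column ambiguity-set sizes.  A parallel track reports the
   proportion of sequences with a residue at each position.
2. **Binding analysis.** Subset-rule IUPAC matching of each primer to
   its binding site in every sequence; a primer binds when mismatches
   ≤ 3 overall and 0 within the terminal 2 bases of the 3′ end.
   Results are aggregated per sequence and per species (a species
   counts as covered when ≥ 1 of its sequences is bound by both
   primers).
3. **Penalty classification.** A position- and type-weighted mismatch
   penalty per primer per sequence, with fractional credit for
   partially matching wobble positions; forward + reverse scores are
   summed and classified Working (< 150), Failed (≥ 150) or Missing.
   Weight tables are a packaged, editable YAML file (the shipped
   defaults are synthetic stand-in tables — see `docs/methods.md`).
4. **Mixed-model comparison.** A logistic GLMM,
   `logit P(success) = β₀ + β₁·[improved] + u_species`,
   `u_s ~ N(0, σ²)`, fitted by adaptive Gauss–Hermite quadrature;
   reports the log-odds effect β₁, Wald z and p, and the odds ratio
   `exp(β₁)` of the improved pair versus the reference pair.
5. **Barcoding gap.** All pairwise Kimura two-parameter distances
   `d = −½·ln((1−2P−Q)√(1−2Q))` (P transitions, Q transversions,
   pairwise deletion), partitioned into intra- and interspecific sets;
   the gap is `min(inter) − max(intra)`.
6. **Synthetic data.** A seeded generator producing aligned COI-like
   datasets with two-level K80 divergence, gaps/ambiguities, and primer
   sites engineered to carry exact designed mismatch counts — ground
   truth for every stage above.

## Worked example

Generate a synthetic study dataset (40 species × 6 sequences, 700
columns, designed binding-site mismatches for both primer pairs) and
run the whole workflow:

```bash
primerval simulate --seed 7 --outdir syn
primerval run-all --target syn/synthetic_alignment.fasta --outdir out
```

which prints

```
primer_pair  taxon    level  total  forward  forward_pct  reverse  reverse_pct  pair  pair_pct
     AscCOI target  species     40       40        100.0       40        100.0    40     100.0
     AscCOI target sequence    240      240        100.0      180         75.0   180      75.0
    AscCOI2 target  species     40       40        100.0       40        100.0    40     100.0
    AscCOI2 target sequence    240      240        100.0      204         85.0   204      85.0
GLMM: effect=0.6555 OR=1.93 p=0.005959
barcoding gap: 0.2076
```

Reading the output: at the sequence level the reference pair (AscCOI)
binds 75% of sequences and the improved pair (AscCOI2) 85% — exactly
the failure fractions the generator designed into their reverse
binding sites.  The mixed model estimates the improvement as a
log-odds effect of 0.66 (odds ratio 1.93, p ≈ 0.006), and the
intra/interspecific K80 distance distributions are separated by a
positive barcoding gap of 0.21 substitutions/site (intra divergence
was simulated at 0.02, inter at 0.35).  `out/` contains the
per-sequence TSVs, summary tables, `glmm.json`, `gap_summary.json` and
a run manifest; every summary number can be recomputed from the
per-sequence files.

Each stage is also available separately (`primerval similarity`,
`bind`, `penalty`, `glmm`, `gap`) and as library functions
(`primerval.evaluate_pair`, `primerval.fit_glmm`, ...).

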