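# Methods

## Statistical procedure

All probe-level comparisons are two-sample Student's t tests with pooled
variance (df = n₁ + n₂ − 2) and two-sided p-values; Welch's correction is
available via `equal_var=False` but is off by default because the
classical test is the procedure being reproduced.  No multiple-testing
correction is applied by default, again for fidelity to the procedure;
region-level false positives are controlled instead by the dual condition
and the run-length requirement (below).  Degenerate inputs follow fixed
conventions: two constant, equal groups give p = 1; constant, unequal
groups give p = 0; a probe with fewer than two replicate values in either
group is *untestable* and is excluded — it never enters a filter fraction
and never seeds or extends a called run.

### Polymorphism filter

For two genetic backgrounds the undigested-gDNA (reference channel)
signals are tested per probe.  A window is **analyzable** iff the fraction
of its testable probes with p > α (α = 0.05) is ≥ `min_fraction` (0.5,
inclusive: exactly half passes).  Untestable probes are excluded from both
numerator and denominator; a window with no testable probe is
conservatively polymorphic.  The verdict is monotone in both α and
`min_fraction`, and symmetric in its two inputs.

### NP calling

Within each analyzable window a probe **qualifies** when
p(nucleosomal) ≤ α **and** p(reference) > α, both tests testable.  A
**run** is a maximal sequence of qualifying probes in layout order in
which consecutive probe starts differ by at most `max_gap`; the default
`max_gap` is the tiling step, so one missing or disqualified tile breaks a
run.  A run is emitted as a call iff the union span of its probes
(last end − first start + 1) is ≥ `min_span` = 140 bp — with the default
50 bp / 50 bp probe geometry that means at least three consecutive probes,
just under one nucleosome footprint.  Span is read as probe-covered
genomic span, not probe count.  Direction is **gain** iff the mean of the
replicate-averaged (query − wild type) nucleosomal signal over the run's
probes is > 0; an exact zero is tie-broken as loss and flagged
(`zero_tie`), since an exactly balanced run is meaningless at float
precision but must not crash.  Two qualifying runs separated by a single
disqualifying probe are separate calls, named `<gene>_NP1`, `_NP2`, … in
5′→3′ order.  The same dual condition is applied to same-background
mutant/wild-type comparisons (the reference-channel condition is the
control against lineage-specific insertions), with an all-analyzable mask.

The caller is verified against an exhaustive oracle that enumerates every
contiguous probe segment, applies the dual condition, gap and span rules
independently (textbook t formula, separate p-value route), and keeps
maximal qualifying segments.

### NOL classification

For each call, the NOL track is sampled at the probe midpoints of the
call's probes (optionally widened by `flank` bp; default 0 — the paper
trail does not fix the comparison span, so it is configurable) and the
Pearson correlation of each genotype's averaged profile with those samples
is compared.  Verdict: **mutant** iff r_query > r_wt strictly;
**indeterminate** when either correlation is undefined (constant profile
or flat NOL) or |r_query − r_wt| < `tie_epsilon` (1e−9).  The verdict is
invariant under positive affine transforms of any input and symmetric
under label swap.

One structural caveat: a *pure height-scaling* loss leaves the two
genotypes' log-scale profiles nearly affinely related over the call
region, and Pearson correlation is affine-invariant, so NOL comparison at
such a region is a near-tie and the verdict is fragile.  Positional
changes — a nucleosome present in one genotype and absent in the other —
are the configuration the comparison actually discriminates, and the
classification tests use those.

### qPCR

Technical replicates are averaged on the Ct scale before any Δ.
Relative nucleosome protection per sample is
rNP = 2^−[Ct(MNase) − Ct(gDNA)], reported as rNP(target)/rNP(control
locus); because the control-locus normalization is a second Δ, this equals
a 2^−ΔΔCt with the control playing the reference role.  Relative
expression is 2^−ΔΔCt against a reference gene with a calibrator genotype
whose mean ΔCt defines the baseline, so the calibrator's mean fold is 1
exactly.  Amplification efficiency is fixed at 2.0 (the formulas assume
it); no standard-curve correction.  Group summaries are mean ± SD on the
fold scale (mirroring error-bar convention) with a pooled t test between
genotypes.

## Synthetic-data model

The generator emulates the study design: 400 windows of 3000 bp around a
TSS, fully tiled with 50-bp probes at 50-bp steps (60 probes/window),
three replicate pools per genotype, ~10% polymorphic windows.  Scales are
configurable; tests and the acceptance script use 40–400 windows so the
default suite runs in well under a minute per scenario.

**Occupancy.** A genotype's occupancy at base x is
clamp(Σᵢ hᵢ·exp(−(x−cᵢ)²/2sdᵢ²), 0, 1), with nucleosome sd 30 bp
(≈150-bp footprint), slot centers every 200 bp with ±10 bp jitter, heights
U(0.5, 0.9), and each slot left empty with probability 0.25 to create
valleys.  **Signals.** The nucleosomal probe value is
log2(mean-occupancy-over-probe · dynamic_range + floor) + N(0, σ), with
dynamic_range = 4 and floor = 0.0625 — a background at 1/64 of the peak
scale, chosen so a 2^−Δ occupancy drop maps to ≈ −Δ log2 signal across the
footprint; the reference value is a flat baseline (0) + N(0, σ).  Default
replicate noise σ = 0.2 log2 units, chosen so Δ = 1 changes are
recoverable at n = 3 but not trivially so.

**Planted features.** A *loss* multiplies the heights of nucleosomes
inside its interval by 2^−Δ; a *gain* empties a base slot in both
genotypes and adds a nucleosome of height (2^Δ − 1)·0.75 (clipped to 1) to
the mutant; a *shift* is a linked loss + adjacent gain, scored as one unit
recovered if either half is called.  A *polymorphism* shifts the signal of
the non-reference haplotype by −divergence (default 3 log2 units) in
**both** channels inside its interval — mismatched probes hybridize less
regardless of what was loaded — whereas planted NP changes perturb only
the nucleosomal channel.  The NOL track is the occupancy of a designated
sequence-favored genotype sampled every 10 bp, optionally distorted with
smooth noise.  Ct tables follow Ct = intercept − log2(quantity) + N(0, σ)
with two technical replicates per well.

Every generator output is a deterministic function of the seed (streams
are keyed by seed plus genotype/channel labels), so runs are byte-for-byte
reproducible.

**What the generator does not model**, hence what passing tests do not
show about real arrays: hybridization normalization artifacts and
dye bias, MNase digestion-sequence bias, probe GC/affinity effects,
spatially correlated noise, partial-overlap dilution of polymorphisms, and
real NOL model error.  Recovery rates measured here characterize the
procedure under idealized Gaussian noise, not expected performance on wet
data.

## Calibrated recovery thresholds

The planted-change recovery checks assert sensitivity ≥ 0.75 and direction
accuracy ≥ 0.95.  These were fixed by a one-time calibration (seeds
20240901, 1, 2, 3, 7, 11; 100 windows, 50 planted 200-bp changes, Δ = 1,
σ = 0.2, n = 3) which measured sensitivity 0.82–0.94 and direction
accuracy 1.00; the thresholds sit below the worst observed value to absorb
seed-to-seed variation and are not revisited.

## Numerical and design notes

- Coordinates are 1-based inclusive (GFF convention) everywhere, including
  call intervals; BED export converts to 0-based half-open.
- Signal files are written with `repr` floats and round-trip bit-faithfully.
- The channel files are tested as given: whether upstream supplies
  normalized ratios or single-channel intensities, the t tests operate on
  the values the file carries, and the units are recorded in metadata.
- Replicate semantics: each replicate column is one pool of three
  biological replicates; pooling is upstream of this package.
- `arraywide_correlation` drops NaN pairs and reports NaN (undefined) for
  constant input rather than raising.
- The pipeline runner writes every stage output plus a JSON report with
  version, seed and full parameter values for provenance; reruns with the
  same seed are byte-identical.

## Known limitations

- The run-based caller is deliberately not a changepoint/HMM segmenter;
  faithfulness to the run-of-significant-probes procedure is the point.
- With zero replicate noise, any infinitesimal occupancy difference is
  "significant" (constant-unequal convention), so zero-noise runs extend
  over a nucleosome's full numerical tail; zero noise is useful for exact
  construction tests, not as a realistic regime.
- Losses are height scalings, so NOL verdicts at loss regions are
  near-ties (see above).
- qPCR efficiency is fixed at 2.0; no efficiency estimation or melt-curve
  QC.
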