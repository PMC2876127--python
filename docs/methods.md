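# Methods

## The question and the device

Cross-species aCGH infers relative genomic copy number from competitive
two-color hybridization of test-species and platform-species DNA to a
platform-species probe array.  Its two systematic failure modes are (1)
sequence divergence of the test-species ortholog, which depresses the
ratio and masks true duplications, and (2) normalization against a
feature population whose median ratio is itself depressed by divergence,
which shifts the baseline and manufactures false "excess" calls.  To
measure both with known truth, the package simulates a female-test versus
male-reference design: every X-linked feature is a planted 2:1
"duplication" (expected M = +1), every autosomal feature a 2:2 null
(M = 0), and heterologous species are emulated by a per-feature sequence
identity distribution.  Roughly 16.7% of 18,849 features are X-linked;
replicate designs are six dye-swapped arrays (within-species and the
nearer heterologous species) or four (the farther one).

## Generative model

Per feature i and test species s:

- identity `id_is` ~ Normal(μ_s, σ_s) clipped to `[min_identity, 1]`,
  with μ = 1 (platform), 0.96/sd 0.02 ("simulans-like"), 0.92/sd 0.025
  ("yakuba-like"), and correlation 0.8 across species through a shared
  per-feature conservation score (slowly evolving genes are conserved in
  all lineages — this is what makes a single conserved normalization set
  work for every species).
- efficiency `h(id) = max(0, 1 − β(1 − id))` with β = 13 (calibrated, see
  below); channel sums are `Σ copies·h` over the probe's target locus and
  any paralog-family loci, plus a nonspecific binding floor (2.5% of a
  two-copy signal) applied to DNA that is present: severely diverged
  orthologs bottom out at a reliably negative ratio instead of vanishing,
  while deleted DNA gives no signal at all and fails QC.
- observed per-array M = expected M + probe effect + orientation-signed
  dye bias + per-array noise.  The probe effect (shared across arrays) is
  Normal with SD `sqrt(0.18² + (13·(1−id))²)`: a baseline term for
  probe-sequence idiosyncrasies plus a divergence-coupled term, because
  mismatch placement, indels and GC content can only perturb
  hybridization when mismatches exist.  Per-array noise variances are
  drawn per feature from a scaled inverse chi-square
  (`0.33²·5/χ²₅`) — the variance heterogeneity that makes empirical-Bayes
  moderation worthwhile and lets the pipeline's prior estimate be
  checked against the generating values.
- dye bias is a scaled third Hermite polynomial in centered A (amplitude
  0.15, mean zero under the A distribution), sign-flipped by dye
  orientation; A ~ Normal(12, 1) per feature with 0.1 per-array jitter;
  backgrounds Normal(100, 15) truncated at zero.
- confounders, drawn independently per feature (deletion 1%, movement off
  the X 1%, onto the X 1%, paralog family 2%, heterochromatic 0.7%), are
  mirrored into fabricated BLAST-tabular hit tables: deletions emit no
  heterologous hit, moved features hit the wrong chromosome class,
  paralog families emit extra hits on one or both genomes, and
  heterochromatic features hit a scaffold flagged heterochromatic while
  their signal is suppressed (×0.5) with independent per-channel
  lognormal jitter (SD 0.6 log2) that corrupts their ratios.

A `null_copy_ratio` switch forces all copy ratios to 1 for false-discovery
checks.

### Calibration

β and the noise scales were fixed once, by grid search at scaled size
(`analysis/00_calibrate.py`), against four simultaneous anchors: ≥ 90%
(≈ 93%) within-species recovery with FP rate ≤ 20%; ~50% detection of X
orthologs at 2–4% divergence; near-zero detection at 9–15%; and an
identity term explaining 35–65% of the variance of the per-feature mean
log ratio.  A purely linear-with-clamp efficiency with a single
homoskedastic probe noise cannot satisfy these jointly — the steep slope
the detection decay demands makes identity explain almost everything —
which is why the divergence-coupled probe-noise term and the nonspecific
floor are part of the model rather than tuning conveniences.  At the
defaults, the shipped seed gives 92% / 12% within species, 58% / 0%
detection in the two divergence windows, and R² = 0.62.

## Pipeline

1. **QC** — a feature fails on an array if, in either channel, foreground
   exceeds background by no more than 2 background-SDs (the boundary
   fails); known technical errors stay flagged.  Features passing on
   fewer than 2 arrays are excluded from analysis.
2. **Background correction ("minimum")** — corrected = fg − bg; values
   ≤ 0 are replaced by half the smallest positive corrected value of that
   array/channel, keeping logs finite while preserving "very low".
3. **M/A with dye-swap resolution** — the design's orientation decides
   which channel is the test sample, so M > 0 always means excess in the
   test sample and the per-feature model reduces to a one-sample mean.
4. **Loess normalization** — per array, a lowess curve (degree 1, span
   0.4) of M on A is fitted on the chosen feature set (all, ~1000
   conserved, ~100 conserved; conserved sets are the top features by
   minimum cross-species identity, 5.3%/0.5% of the array when scaled
   down) and subtracted from every feature at its A, clamping to the
   boundary fitted value outside the fitted A-range.  No robustness
   iterations by default: bisquare reweighting mistakes the tails of a
   strong smooth dye trend for outliers and leaves a residual tilt
   (exposed as a parameter).
5. **Moderated testing** — per-feature mean/variance/df across included
   arrays; prior `(d0, s0²)` by matching the mean and variance of
   `log s²` to its theoretical digamma/trigamma moments (trigamma
   inversion by Newton, tolerance 1e-8, max 100 iterations; `d0 = ∞`
   when the empirical spread does not exceed the sampling spread, making
   the test a z-test on s0²); `s²_mod = (d0·s0² + df·s²)/(d0 + df)`;
   two-sided p from t with `d0 + df` df.  BH step-up adjustment
   (statsmodels), excess called when `q < 0.1` **and** the coefficient is
   positive — a config switch selects a one-sided p instead.
6. **GEL50** — the true log2 level at which detection reaches 50% power:
   features with prior-drawn variances and a 10% alternative fraction are
   simulated on a μ-grid through the same moderation/BH/call path, and
   the 0.5 crossing is linearly interpolated (`+inf` with a warning if
   never reached).  This is how four arrays of a noisier experiment are
   argued equivalent to six of a cleaner one; at the fitted within-species
   prior it comes out ≈ 0.49.

## Evaluation conventions

- TP = called X features, FN = uncalled X features (denominator: all
  analyzable X features); FP rate = autosomal fraction of all excess
  calls, `fp/(tp+fp)`, 0 when nothing is called; a secondary column
  reports the fraction of autosomal features called.  Percentages are
  rounded half-up.
- Detection-by-divergence bins are 1 percentage point wide on
  `100 − top-hit %id`, bins below 1% excluded, bins with n < 5 flagged.
- Confounder categories (FN: no hit, autosome-only hits, tel/het, no
  platform hit, platform hit excess; FP: heterologous-X hit, tel/het,
  heterologous hit excess) use the top-hit threshold E < 1e-14 for
  presence/absence and the permissive E < 1e-10 for counts and movement
  rules, a 25 kb telomere window applied to both hit endpoints, and
  assembly-level heterochromatin flags.  "Total explained" is the size of
  the **union** of category sets.  The "no platform hit" category is
  interpreted as "feature sequence has no qualifying hit to the platform
  genome itself" — a labelled assumption, since that column is not
  otherwise defined.  Top hits are chosen by lowest e-value, then highest
  bitscore, then lowest subject coordinate (a stated convention; any
  deterministic rule would do).

## What the simulation does and does not show

The generator reproduces the statistical structure that drives the
method's error modes: dosage ratios, divergence-dependent efficiency
loss, intensity-dependent dye bias, variance heterogeneity, and
hit-table-visible genome differences.  Passing tests therefore
demonstrate that the pipeline recovers planted truth under that
structure — not that real arrays behave this way.  Known gaps:

- Real error budgets are dominated by the confounders the simulator
  plants at only a few percent, so simulated explained fractions (~3–11%)
  are far below the 23–47% seen in real comparative data; the exact
  published fractions are reproduced as arithmetic on the published
  count tables, not re-derived from simulation.
- The copy-ratio correlation among false negatives is near zero in
  simulation (simulated FNs are almost all single-copy), unlike the weak
  positive correlation reported for real data where multi-copy families
  are common among FNs.
- Identity distributions are clipped normals without the heavy divergence
  tail of real genomes, so the 9–15% divergence window is sparse
  (~10–30 features) and its detection is ~0 rather than ~10%.
- The "yakuba-like" condition is harsher than its real counterpart
  (11% vs 26% recovery): with a single global efficiency slope the model
  cannot match both heterologous species at once; the nearer species was
  prioritized because the divergence-decay anchors are defined on it.
- No print-tip structure, between-array normalization, intensity-dependent
  variance, or nucleotide-level sequence evolution.

## Problem sizes

Module tests run at 400–10,000 features; the acceptance checks and
`analysis/` scripts use the full 18,849-feature design (a run takes a
few seconds, the ten-seed contrasts a couple of minutes).
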