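# Methods

`xicquant` implements identification-driven, label-free quantification of
(phospho)peptide ions from MS1 survey scans, together with the simulation
and statistics needed to characterise precision, linearity and accuracy of
such measurements. This note documents the model, the defaults and the
numerical choices.

## Quantification model

The unit of quantification is a *peptide ion*: a sequence with
modifications, a charge state `z`, and a reference retention time `tR`
taken from an identification database. Quantification is targeted: every
database ion is extracted from every run, whether or not it was selected
for fragmentation there. This sidesteps the undersampling of
data-dependent acquisition, where the stochastic choice of MS2 precursors
makes identification lists differ between replicate runs even when the
underlying MS1 signal is reproducible.

For each ion the first three isotopes (A, A+1, A+2) are extracted as
intensity-vs-time traces (XICs). A quantification must pass three gates:

1. **m/z**: per scan and per isotope, the trace takes the maximum centroid
   intensity within a *closed* ±7 ppm window around that isotope's own
   theoretical m/z (a centroid at exactly 7.0 ppm is included). Maximum
   intensity, not nearest m/z, is used to select among multiple centroids
   in the window.
2. **Retention time**: only scans within ±5 min of the reference tR are
   considered.
3. **Isotope distribution**: the Pearson correlation between the three
   observed apex-scan intensities and the theoretical relative abundances
   must exceed 0.95. Zero variance in the observed vector yields r = 0 and
   rejection.

The peak apex is the scan maximising the *summed* three-isotope trace
(robust to noise in a single trace); integration bounds extend outward to
the first scan below 5% of the apex or to a local minimum, whichever comes
first. Height is the summed intensity at the apex scan; area is the
trapezoidal integral of the summed trace between the bounds, in
counts·seconds. Whether a peptide's reported intensity should sum the
three isotopes or use the monoisotopic trace alone is a convention, not a
derivable fact; summing is the default and `mono_only` switches to the
monoisotopic readout (the two differ by the constant factor
A/(A + A1 + A2), so all scale-invariant statistics agree). Absence of an
accepted peak is always NA, never 0, and each NA carries exactly one
rejection reason (`out_of_tR_window`, `no_signal`, `low_iso_correlation`).

## Isotope envelopes

Theoretical envelopes are aggregated (unit-mass-binned) isotope
distributions obtained by convolving per-element isotope-abundance
vectors, using exponentiation by squaring truncated to the requested
number of isotopes — truncation is exact because lower mass bins never
depend on higher ones. Isotopic fine structure is irrelevant at the
resolution where a three-point envelope correlation is applied. Element
masses and abundances are frozen in `data/elements.tsv` so envelopes are
bit-reproducible; abundances are rescaled so the most intense isotope is
1 (the Pearson gate is scale-invariant, but serialization needs a fixed
convention). Isotope spacing is 1.0033548/z Th from the monoisotopic m/z.

Modifications are compositional deltas only (registry in
`data/modifications.tsv`): Carbamidomethyl (+C2H3NO on C), Oxidation (+O
on M), Phospho (+HPO3 on S/T/Y), pyroglutamate from N-terminal Q (−NH3) by
default with the N-terminal E variant (−H2O) available separately, since
instrument software rarely states which variant was configured. No MS2 or
neutral-loss modelling.

## Normalization and outliers

Two steps, applied in order and tracked by an append-only state machine
(`raw → total_normalized → percent_of_max`, double application refused):

1. **Total-intensity normalization**: each column is divided by its run's
   total MS1 chromatogram intensity and rescaled by the mean of the
   totals so magnitudes stay near the raw scale. The TIC denominator is
   identification-independent; a `quantified-sum` denominator (column sums
   of the matrix) is available as an alternative reading. The rescaling
   constant is immaterial downstream: percent-of-max, CV, R² and %Acc are
   all invariant to it.
2. **Percent of maximum**: each peptide row is scaled so its largest
   non-missing value is 100; all-missing rows stay missing.

**Outlier replicates** are flagged when the median across peptides of
|log2(cell / median of the same peptide over the other replicates)|
exceeds a threshold (default 1.0); at least 3 replicates are required. The
flag is deliberately separate from removal — the analyst confirms, then
calls `remove_runs`. Detection is most sensitive on the *raw* matrix:
total-intensity normalization absorbs the mean of a distorted replicate's
deviations, leaving only their spread (we measure a residual median
|log2| of ≈0.5 after normalizing a replicate distorted by per-peptide
factors U(0.1, 0.5), versus ≈1.9 before). This mirrors the observation
that normalization compensates outliers only partially — removal after
normalization still improves precision. With very wide per-run scale
ranges a grossly off-scale (but undistorted) run can also be flagged on
raw data; that is accepted flag-then-confirm behaviour.

## Evaluation statistics

* **Precision**: CV = 100·sd/mean per peptide across replicates (sample
  sd, n−1), NA for fewer than two values or non-positive mean; summarised
  as the mean CV and a histogram over fixed bins 0–10, 10–20, …, ≥100%.
* **Linearity**: per-peptide ordinary least squares of normalized
  intensity on mixing proportion; R² is the squared Pearson correlation.
  Significance uses the exact two-sided critical value of r for the n
  points actually used: r* = t/√(t² + n − 2) with t the 0.975 Student
  quantile on n−2 df, giving 0.878 at n = 5. The widely quoted rule
  "R² > 0.878 for five points" applies the critical *r* to R² (the
  critical R² at n = 5 would be ≈0.771); the implementation tests |r| > r*
  and reports both r and R² so the discrepancy stays visible. The fold
  change is log2 of the ratio of fitted values at the endpoint
  proportions.
* **Accuracy**: per dilution point, %dev = |fitted − observed|/observed ·
  100. The denominator is the observed value; the absolute value prevents
  cancellation. Because the formula degenerates as the observation
  approaches zero (e.g. the 0% point of a fully responsive peptide),
  points below a floor (default 1% of the row maximum) are excluded from
  the per-peptide mean and counted. The global %Acc is the mean of
  per-peptide means.
* **Site localization**: a phosphosite assignment is `localized` when the
  score margin between the best and second-best site permutation reaches a
  user-supplied threshold; no default threshold is claimed.

## The simulator

The generator emulates a data-dependent Orbitrap acquisition as the
quantification engine sees it: survey scans every 2.5 s (the duty cycle),
Gaussian elution peaks 30 s at the base, modelled with σ = base/4 (base
read as ±2σ, i.e. ≈95% of the peak), which places ≥10 survey points under
every peak — the sampling density the XIC readout requires. Each peptide
contributes its three theoretical isotopes, with per-isotope amplitudes
scaled so the *summed* trace apex equals the nominal height.

Variability model, per peptide-and-run:

* multiplicative lognormal noise on the whole elution profile (σ_log,
  default 0.04), the replicate-level variability of sample handling — not
  per-scan shot noise, which the replicate-level CV readout cannot see;
* one global scale factor per run, log-uniform (default [0.7, 1.4]),
  emulating injection/spray efficiency;
* retention-time jitter across runs (σ = 0.3 min, inside the ±5 min
  matching window) and uniform ±2 ppm centroid mass error (inside the
  7 ppm window); both can be widened to exercise window rejections;
* optionally an *outlier* replicate whose per-peptide factors are drawn
  independently from U(0.1, 0.5) — a wide, non-global distortion that
  normalization cannot fully repair. This failure mode is a synthetic
  stand-in: real outlier replicates are not characterised well enough to
  model mechanistically.

Designs: `simulate_replicates` (shared true heights, log-uniform over
three decades by default) and `simulate_mixing_series` (responsive
peptides rise linearly from 20 to 100 arbitrary units as the stimulated
extract goes 0→100%). The mixing design additionally includes flat,
unmodified background peptides (default: as many as there are responsive
ones) so the total chromatogram intensity is design-independent — the
mixtures hold total protein constant, and without a stable bulk signal,
normalizing to the run total would divide out the very trend the design
injects. Responsive-peptide statistics are computed over the responsive
subset.

Ground truth records, per peptide and run, the clean height, the
noise-and-scale height actually applied, the *grid-sampled* apex (the
applied Gaussian's maximum on the scan grid) and the closed-form area
height·σ·√(2π). The 2.5 s grid can undershoot a σ = 7.5 s Gaussian's
apex by up to 1.39% depending on phase, so noise-free recovery is exact
(float precision) against the sampled apex, within 2% against the analytic
amplitude, and within 3% against the closed-form area (5%-of-apex bounds
truncate ≈1.4% of the Gaussian's tails). Fixed seeds give byte-identical
mzML output.

What the simulator does *not* model — and what passing tests therefore do
not establish about real data: peak tailing and shape drift, co-eluting
interferences and chimeric envelopes, detector noise floors and
saturation, cross-run retention drift requiring alignment, and the
enrichment chemistry upstream of the mass spectrometer. The synthetic
recovery results bound the *algorithmic* error of the pipeline, not the
biological or chromatographic error of an experiment.

## Benchmark problem sizes

The packaged evaluation (`scripts/acceptance.py`, mirrored by the
acceptance tests) uses a 5 × 200-peptide mixing series with σ_log = 0.04
and run scales in [0.7, 1.4], and a 6 × 900-peptide replicate experiment
with σ_log = 0.198 (lognormal CV √(exp(σ²)−1) ≈ 20%) and scales in
[0.5, 2] — sizes chosen so a full simulate-quantify-normalize-evaluate
cycle runs in seconds on one core while the Monte-Carlo error of the
summary statistics stays well inside the tolerances quoted for them.

## Known limitations

* No cross-run retention-time alignment; the reference tR plus a ±5 min
  window must suffice.
* No untargeted feature detection; only database ions are quantified.
* The isotope-distribution gate is evaluated at the apex scan only.
* Identifications are consumed as tables; search-engine output parsing
  (and FDR control) is out of scope.
* The outlier criterion is a heuristic with an invented default; treat
  flags as candidates for inspection, not verdicts.
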