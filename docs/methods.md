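# Methods

This note documents the models behind ndiasim: what is simulated, the
defaults and why, the numerical choices, and what the synthetic benchmarks
do and do not establish about real instrument data.

## Acquisition timing model

MS/MS scans are serial with period `maxIT + τ` (ms), giving a rate of
`1000/(maxIT + τ)` Hz.  τ lumps every fixed per-scan cost (isolation,
fragmentation, transfer, detection of the pipelined ion path) into one
constant.  Instrument methods do not print τ, but they print rates, so τ
is calibrated by inversion: the DIA default `τ = 1000/170 − 3.5 ≈
2.382 ms` comes from the published 170 Hz at 3.5-ms fills, and the DDA
default `τ = 1000/150 − 2.5 ≈ 4.167 ms` from the ~150-Hz top speed at
2.5-ms fragment fills.  With the DIA calibration, a 2.5-ms fill yields
204.8 Hz — the >200-Hz operating point.

MS1 runs on a parallel analyzer and adds no serial time; a `serial_ms1`
switch exists for non-parallel instruments.  Ion packets move through a
pipelined accumulation/processing/detection path with at most five packets
in flight; when a `packet_residence_ms` is set, the scheduler throttles
scan spacing to `residence / max_parallel_packets` so the concurrency cap
is respected by construction (and asserted during simulation).

**Window geometry.**  Windows are half-open `[low, high)` so precursor
assignment at shared edges is unambiguous; overlapping schemes assign a
precursor to every window containing it.  When the step does not divide
the range, the last window extends past the range end and the scheme is
flagged `clipped` — full precursor coverage is preferred over exact range
alignment.

**Width/maxIT scaling.**  `scale_maxit` holds the total per-cycle
accumulation `n_windows × maxIT` constant, reproducing the 3.5/7/14/28-ms
ladder for 2/4/8/16-Th windows.  Note that with τ > 0 the *cycle time*
`n·(maxIT + τ)` is then not exactly constant (overhead amortizes as
windows widen), so the product `sampling_fraction × n_windows` is
width-invariant only in the τ = 0 limit; the property tests assert the
exact statements (invariance at τ = 0, exact 1/n proportionality at fixed
timing) and the duty-cycle model reports the τ > 0 behavior as is.

**Beam utilization.**  Two inequivalent definitions circulate: the
temporal one (`maxIT / cycle_time`, ≈0.20% for the 300×2-Th method) and
the m/z one (`width / span`, ≈0.33%).  `ion_beam_utilization` reports
both rather than committing to a single headline number.

## Synthetic samples

The generator produces the statistical structure the benchmarks assume,
not biological sequences:

* **Proteins** — random sequences (150–600 residues) drawn from average
  vertebrate residue frequencies, per-species seeded streams.
* **Digestion** — trypsin specificity (cleave after K/R, never before P;
  LysC termini are a subset), 0..k missed cleavages, 7–30-residue
  detectability filter.  Shared (non-proteotypic) peptides are dropped
  before quantification.
* **Masses** — monoisotopic residue sums + water + charge protons, fixed
  carbamidomethyl-C (+57.02146 Da).  Singly charged b/y ions, no neutral
  losses, for the interference topology.
* **Retention** — mean Kyte–Doolittle hydropathy mapped linearly onto the
  gradient plus a small (±3% of gradient) sequence-keyed jitter modeling
  orthogonal retention effects.  Deterministic per sequence.
* **Abundance** — protein log10 abundances are normal with spread set 15%
  above `dynamic_range_logs / (2 z_0.99)` so the empirical 1st–99th
  percentile span exceeds the 6-log target at realistic database sizes.
  Peptide flux = protein abundance × a log-normal per-sequence ionization
  response (σ = 0.5 log10).
* **Charge states** — one of {2+: 0.7, 3+: 0.3} per sequence.  The
  underlying study reports no charge or peak-width distributions, so these
  are declared defaults, not fits; peak FWHM defaults to 6 s (3–5 s is
  sensible for 5-min gradients).
* **Determinism** — everything keyed to a peptide (charge, response,
  retention jitter) is an MD5 hash of the sequence, so the same peptide is
  identical across runs, designs and replicate samples.  This is what
  makes the mixture benchmark's "human background identical across
  designs" property exact.

**Mixtures** scale each species' fluxes by its percentage (human fixed at
50% in the six benchmark designs), so every E. coli peptide is exactly 9×
more abundant in E45H50Y5 than in E5H50Y45.  **Entrapment databases**
permute each target sequence (shuffled mode; composition preserved,
cleavage sites re-drawn, mimic ≠ source enforced for length > 3) or
synthesize foreign-composition sequences, at an integer size ratio r.
**Fractionation** quantile-bins peptides by hydrophobicity into 46 (or n)
first-dimension fractions; concatenation pools fraction i into pool
`i mod n_pools`.

## Acquisition simulation

Per MS2 fill at time t, each candidate peptide (m/z in window, |t − rt| ≤
4σ) contributes `Poisson(flux(t) · maxIT · faims_transmission)` ions.
If the expected total exceeds the AGC charge capacity the fill is
shortened proportionally (all means scaled by `cap/expected`, recorded as
a reduced effective injection time); any residual Poisson overshoot is
thinned without replacement so no scan ever records more than the cap.
Shortening instead of clipping keeps count-rate quantification linear
below and at saturation.

DDA cycles are fixed-length: an MS1 survey at cycle start ranks eluting
precursors by instantaneous expected yield; the top N above an intensity
floor (`dda_min_intensity`, expected ions per fill, default 1.0) and off
the exclusion list are isolated at the DDA width, then excluded for
`dynamic_exclusion_s`.  The intensity floor is required for dynamic
exclusion arithmetic to be meaningful (without it a Gaussian peak is
"eluting" over its full ±4σ support) and mirrors real instrument minimum
thresholds.

Random streams are split per scan from the master seed (`[seed, cycle,
scan-in-cycle]`), so changing the window order or gradient length never
cascades into unrelated scans; runs serialize byte-identically under a
fixed seed and config.

Mass errors are `N(drift(t), σ)` in ppm with linear-in-time drift;
recalibration subtracts the per-time-bin (default 60 s) median error
estimated against the true m/z available in simulation.  This removes
drift and bias but of course not per-ion scatter.

**Identification proxy.**  Spectral matching is out of scope, so
"identification" is proxied by `detectability`: sampled in ≥ min_points
MS2 scans with ≥ min_ions total ions.  All benchmark claims consumed here
are trends (monotonicity in load, DDA abundance bias, coverage
completeness), which the proxy preserves; absolute identification counts
are not meaningful in this model and are never asserted.

## Quantification

XIC areas integrate the count rate (counts / effective injection time)
over scan times by the trapezoid rule; a single-point trace falls back to
rate × cycle time.  The noise-free path (`theoretical_quant_matrix`) uses
the closed-form Gaussian area `flux_apex · σ · √(2π)` and is the exact
deterministic limit of the simulator — the "noise-free end-to-end"
benchmark runs sample construction → mixtures → closed-form areas →
rollups, and recovers every expected log2 ratio to better than 1e-6.

Top-N ranks precursors once per protein by mean intensity across runs
(run-wise re-ranking would break ratio interpretability; the reference
implementation's internals are proprietary, so fixed-set top-3 is the
declared stand-in).  MaxLFQ forms the median log2 ratio over shared
precursors for every run pair, solves the damped normal equations
(Tikhonov 1e-10; missing ratios simply omitted) per connected component
of the run graph, and anchors each component so summed linear protein
intensity equals summed observed precursor intensity.  Per-precursor
response factors cancel in the pairwise ratios, hence exact recovery on
complete noise-free data for arbitrary responses.  Cross-run median
normalization exists but is off by default.

## FDR estimation

Both the raw entrapment fraction (`n_e/(n_t+n_e)`, a lower-bound-style
rate) and the size-corrected estimate (`(n_e/r)/n_t`) are always reported,
because the correction convention is stated but not formalized in the
sources this mirrors; the corrected form divides entrapment hits by r on
the reasoning that false hits land in an r×-larger entrapment partition r
times as often.  The estimator-recovery simulation (planted false-hit
rates 0.5%, 1%, 5%; 100 seeds) confirms the corrected form is unbiased.
Bootstrap intervals resample hits with replacement at the protein level;
B defaults to 23 to mirror the benchmark convention but a warning is
emitted below B = 100 since percentile intervals are then crude.

## Problem sizes

Defaults are desk-scale by design: the benchmark uses 45–60 synthetic
proteins per species (~3,000 peptide ions across three species), 1–3
replicates per design, 10 noise seeds; simulations use 60–180-s gradients
with up to ~30,000 MS2 scans per run.  These sizes make every property
sharp (noise-free recovery to 1e-6, clean monotonicity across the
2–24-Th width ladder) while a full suite run stays under a minute.

## Limitations

* Synthetic sequences have no homology structure; shared-peptide and
  protein-inference effects are absent by construction (protein groups
  are taken as given).
* No retention-time alignment, match-between-runs, isotope envelopes,
  quadrupole edge effects, ion mobility, or detector noise beyond Poisson
  counting; FAIMS is a scalar transmission factor.
* Passing benchmarks demonstrate correctness of the estimators and the
  internal consistency of the acquisition model — not instrument-level
  accuracy.  Absolute spectra/ID counts, real CV levels and empirical FDR
  values from instrument data depend on search engines and hardware that
  are explicitly out of scope.
* mzML export is not provided; runs serialize to a JSON-lines scan log
  and long-format TSV, which round-trip losslessly.
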