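# Methods

This note records the models, parameter choices and numerical decisions
behind `laborhrv`, and what the synthetic validation does and does not
establish about real recordings.

## Signal model and R-peak extraction

Both supported modalities carry the maternal QRS complex: directly in ECG,
and as interference riding on uterine electrical activity in the abdominal
EHG. Uterine surface EMG occupies roughly 0.1–3 Hz and baseline wander
sits below 0.1 Hz, while QRS energy is concentrated near 10–40 Hz, so a
high-pass filter separates them cleanly. The filter is a 4th-order
Butterworth applied forward–backward (`sosfiltfilt`), which has exactly
zero phase and therefore cannot shift R-peak positions; the cutoff
defaults to 5 Hz for EHG and 0.5 Hz for clean ECG (where only drift
removal is needed). Both are configurable.

The filtered trace is scaled so its maximum absolute amplitude is 1, and
peaks are kept when they exceed 0.4 of that maximum and are separated by
at least 250 ms (no adult sinus rhythm at term is faster than 240 bpm);
when two candidates violate the refractory period the larger is kept.
The 0.4 threshold assumes the QRS dominates the filtered, normalized
trace; it is deliberately simple rather than adaptive, and both threshold
and refractory are exposed in the configuration.

### Segment selection

Frequency-domain HRV needs 5 minutes of data, so non-overlapping 300-s
windows are evaluated from the start of the record — the first window is
preferred, later ones are fallbacks. A window qualifies when at least 150
beats are detected and at most 5% of its intervals are flagged by the
ectopy screen. Records with no qualifying window are excluded as having
poorly detectable R peaks; in cohort runs this is a logged per-subject
exclusion, never a fatal error, mirroring how unusable clinical records
are handled in practice.

### Ectopy screening and correction

Clinical practice often corrects RR series manually; that step is not
reproducible, so the screen here is automated and its review output can be
overridden. An interval is flagged when it deviates more than 20% from
the running median of the five preceding accepted intervals (a bootstrap
median over the leading in-range intervals serves as reference before the
running window is primed), and intervals outside 250–2000 ms are always
flagged. Each maximal run of flagged intervals is replaced by equal
intervals summing to the run's duration — the run mean — so the total
record time is conserved to machine precision and the operation is
idempotent. The alternative reading of run correction (neighbor
interpolation) was considered and rejected because it does not conserve
duration, which would shift all downstream beat times.

A consequence of screen + quality gate worth knowing: subjects with
genuinely large beat-to-beat variability trip the 20% rule more often and
can fail the 5% segment-quality gate. In synthetic cohorts with a strong
negative RMSSD–TTD relation this removes a few high-RMSSD subjects, a
selection effect visible as a small bias in recovered correlations (the
planted-recovery check measures it; it stays well inside the stated
tolerance).

## HRV metrics

Time domain: mean RR; SDNN as the sample standard deviation (n − 1); and
RMSSD as the root mean square of successive differences, all in ms.

Frequency domain: the interval series is interpolated with a cubic spline
onto a uniform 4 Hz grid (each interval anchored at the beat ending it),
linearly detrended to suppress within-segment drift, and its power
spectral density estimated by Welch's averaged modified periodogram with
150-s Hann-tapered segments at 50% overlap. At 4 Hz and 150 s the
resolution is 1/150 ≈ 0.0067 Hz, adequate for the LF and HF bands.
Band powers are trapezoidal integrals of the one-sided density over
VLF 0.0033–0.04, LF 0.04–0.15 and HF 0.15–0.4 Hz, with band edges
interpolated between frequency bins; they are reported as natural logs of
absolute power in ms², and LF/HF is the ratio of raw powers (so
`lf_hf == exp(lf_ln − hf_ln)` identically). A 300-s segment covers about
one cycle of the lowest VLF frequency, so VLF values carry an explicit
low-reliability flag and should not support inference.

The estimator integrates back to the series variance within taper-leakage
tolerance (checked at ~10% for sinusoids, ~15% for white noise). A
single-tone series at 0.01 Hz places ≈ 90.3% of its power inside VLF —
the remainder is Hann main-lobe leakage below 0.0033 Hz — which is why
the band-placement property sits close to its 90% bound for VLF and far
above it for LF and HF.

## Synthetic data

**RR series (IPFM).** Beats fire when the integral of the instantaneous
rate (1 + Σ aᵢ sin(2π fᵢ t + φᵢ))/T̄ crosses an integer; the integral has
closed form and crossings are located on a 1 ms grid with linear
interpolation, giving timing error far below 1 ms. The integrator reset
at t = 0 counts as the first beat. IPFM was chosen because tone
amplitudes map directly to tachogram spectral content; note that interval
sampling attenuates a rate tone by sinc(f·T̄), which matters when planting
exact band-power ratios (≈ 6% power at 0.25 Hz with T̄ = 0.8 s).

**Waveforms.** The QRS is a single Gaussian pulse, default 20 ms FWHM —
full P-QRS-T morphology adds nothing to R-peak logic. A 0.3-s lead-in
keeps the first beat interior to the record. The EHG adds uterine bursts
(band-limited 0.1–3 Hz noise under raised-cosine envelopes of 30–60 s, at
a default 2 bursts per 5 min), sinusoidal wander at 0.02 Hz, and white
noise; the generator records each component's mean-square power so the
cardiac-to-background ratio of any realization is known exactly, and a
helper computes the ECG gain that achieves a requested ratio in dB.

**Ectopics.** At each site the interval is shortened by the prematurity
factor and the next interval absorbs the remainder (compensatory pause),
conserving total duration exactly; sites are kept ≥ 3 apart so each
produces its own unambiguous two-interval run.

**Cohorts.** Time to delivery is uniform on 0–9.3 weeks (the plausible
window between a third-trimester recording and delivery); GA at delivery
is uniform on 37–41 weeks with GA at recording set so the difference is
exactly TTD. Delivery modes default to proportions 35:4:6
(spontaneous:induced:cesarean). Rank correlations are planted through a
Gaussian copula: a target Spearman ρ is converted to the latent Pearson
r = 2 sin(πρ/6), and the latent drives a monotone map onto the physical
parameter. RMSSD is planted as a lognormal around 25 ms (dispersion
0.45, giving roughly 25 ± 13 ms across subjects) and converted to the HF
tone amplitude in closed form given the LF/HF ratio — the
successive-difference amplitude of tone (f, a) at mean interval T̄ is
2aT̄ sin(πfT̄) — so the planted RMSSD relation is free of LF cross-talk.
LF/HF is planted as a lognormal ratio around 0.7 (dispersion 0.6), and
mean RR defaults to 677 ± 25 ms. With zero extra subject noise the
population rank correlation equals the target; the generator's truth
table records the achieved parameters per subject for recovery tests.
A metrics-only mode skips waveform synthesis for statistical studies that
only need the true metric values (e.g. large null-cohort sweeps).

**What the generator does not emulate:** realistic QRS morphology and its
variants, fetal ECG, electrode artifacts, non-stationary noise floors,
respiration-driven amplitude modulation, or the empirical noise statistics
of clinical EHG. Passing the synthetic checks therefore establishes the
correctness of the algorithms under the stated signal model, not detector
performance on any particular clinical database.

## Cohort statistics

Exclusions remove induced and cesarean deliveries and quality failures,
each subject counted once (delivery mode takes precedence); the operation
is idempotent and order-independent. Gestational ages are decimal weeks,
"W weeks + D days" read as W + D/7.

Normality is screened with the Lilliefors variant of Kolmogorov–Smirnov
(mean and SD estimated from the sample). Because the classical tables are
approximations, the null is simulated: Gaussian samples of the same size
with the same estimation step, 10,000 by default, with the add-one
Monte-Carlo p-value. The null depends only on n, so a precomputed table
can be reused across many tests; calibration at n = 50 puts the empirical
size within the binomial band around 0.05.

Associations use Spearman's rank correlation with mid-ranks for ties.
The p-value is the exact two-sided permutation probability for n ≤ 9
(full enumeration; 10! is impractical) and the t-approximation with
n − 2 degrees of freedom otherwise. The 95% CI uses Fisher's z with the
Bonett–Wright standard error √((1 + ρ²/2)/(n − 3)), a standard choice for
Spearman when an r [CI] p report format is needed. No
multiple-testing correction is applied by default — the correlation table
reports one row per HRV metric against GA at recording, GA at delivery
and TTD, with TTD as the primary outcome — but a Benjamini–Hochberg
adjusted p can be reported alongside the raw p.

## Problem sizes and determinism

All randomness descends from explicit seeds; generators are
bit-reproducible, and running the pipeline twice on the same inputs gives
byte-identical tables. The validation suite uses 5-minute segments
throughout, 20-seed sweeps for recovery/robustness properties, 1,000
random series for formula equivalence, 2,000 replicates for Lilliefors
calibration, one 200-subject cohort for planted-correlation recovery, and
200 null cohorts of 37 subjects (metrics-only) for the false-positive
rate — sizes at which the binomial/Fisher-z sampling bands quoted in the
tests are comfortably wider than the estimator noise.

## Known limitations

- The peak detector is a fixed relative threshold, not an adaptive or
  matched-filter detector; it is adequate for the stated signal model and
  for clean clinical segments but will underperform on records whose QRS
  amplitude varies strongly within a segment.
- VLF at 5 minutes is reported but unreliable by construction.
- The automated ectopy screen is a surrogate for manual review; its 20%
  rule slightly penalizes genuinely high-variability subjects (see above).
- The exact-permutation Spearman p is limited to n ≤ 9; beyond that the
  t-approximation is used rather than a sampled permutation p.
- The PhysioNet-record reader requires the optional `wfdb` package; the
  core pipeline reads CSV only.
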