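# Methods

## The estimator and its bias

Spectrally resolved functional connectivity between two narrow-band neural
signals is measured here as the amplitude envelope correlation (AEC): the
Pearson correlation of the squared Hilbert envelopes,
`AEC = corr(A_x^2, A_y^2)` with `A = |H(x)|`. Working with squared envelopes
(power envelopes) is a deliberate choice: it is the level at which the
renormalization algebra below is exact, because the squared envelope of a sum
of independent processes decomposes sample-wise as
`A_x^2 = A_{x0}^2 + A_{ex}^2 + 2 Re(z_{x0} conj(z_{ex}))`. Plain-envelope
correlation is available as a variant (`envelope_kind="amplitude"`).

Each measured signal is modelled as `x = x0 + eps_x`, where `x0` is the
*connectivity process* (the part of neural activity that carries amplitude
coupling) and `eps_x` is *background noise* (everything else). Independent
noise attenuates the AEC by a per-signal factor `std(A_{x0}^2)/std(A_x^2)`:
the power bias. The bias is nonlinear in the SNR, so low-SNR frequency bands
show spuriously low connectivity, which can mimic spectral specificity.

## Renormalization

The corrected estimate is

    AEC_ren = [ AEC - cov(A_ex^2, A_ey^2)/(s_x s_y)
                    - (L(x,y) + L(x,Hy))/(s_x s_y) ]
              / [ sqrt(1 - SNR_x^-2) sqrt(1 - SNR_y^-2) ]

with `s_x = std(A_x^2)`, the linear-synchronization term
`L(x,y) = 8[cov(x,y) cov(ex,ey) - cov(ex,ey)^2]`, and the
amplitude-specific SNR

    SNR_x = std(A_x^2) / sqrt( std(A_ex^2)^2 + 2<A_x^2><A_ex^2> - 2<A_ex^2>^2 ).

Two exact identities justify the formula and are enforced by tests:

- for circular-gaussian noise independent of the signal,
  `1 - SNR_x^-2 = var(A_{x0}^2)/var(A_x^2)` exactly — the denominator undoes
  the per-signal attenuation whatever the (possibly non-gaussian)
  connectivity process;
- for a narrow-band gaussian measured signal this reduces to
  `sqrt(1 - SNR_x^-2) = 1 - var(eps_x)/var(x)`.

The subtraction of `cov(A_ex^2, A_ey^2)` removes spurious noise amplitude
correlation (so the correction remains valid with correlated noise), and the
`L` terms remove residual zero-lag (linear) synchronization effects; the
`-cov^2` part of `L` makes its plug-in estimate unbiased under independent
noise. `L(x, Hy)` substitutes the Hilbert transform of the second signal
into the same template; the noise-free identity limit (all noise moments
zero implies `AEC_ren = AEC` exactly) fixes signs and normalizations.

The procedure is ill-conditioned as `SNR -> 1` (noise as variable as the
signal). Estimates with `SNR_ampl <= 1 + 1e-6` are flagged and reported as
missing, never silently returned; a flat spectrum can therefore not be an
artifact of failed cells.

Symmetrization: leakage orthogonalization (below) is directional, so the
pair estimate is the mean of the (x, y-orthogonalized-to-x) and
(y, x-orthogonalized-to-y) values, applied after, not before, the
correction terms.

## Spectral decomposition and leakage correction

Recordings are decomposed with a zero-phase Butterworth (order 4,
second-order sections) filterbank; the default grid is 1-Hz-wide bands
centered at 1, 2, ..., 45 Hz (bandwidth is a full width). After filtering,
`ceil(3/bandwidth)` seconds are trimmed at each end to remove filter
transients. Envelopes come from the FFT-based analytic signal.

Zero-lag mixing between signals ("spatial leakage" of source-projected
MEG/EEG) is removed by pairwise orthogonalization: the real part of y is
regressed on the real part of x and the residual re-analyzed, giving
`cov(x, Re y_orth) = 0`. A pair that orthogonalizes to (numerically)
nothing — total leakage — is flagged degenerate rather than scored.

## Burst/non-burst noise model

The renormalization needs moments of the background noise. For resting-state
brain signals the package models background noise as *non-bursting*
oscillatory activity: a two-state gaussian HMM is fitted to the Hilbert
envelope of each node in each narrow band separately (per-band fitting is an
assumption; cross-band pooling is not implemented), the low-mean state is
the non-bursting state, and the state path is decoded with Viterbi. All
noise moments for a pair are computed over samples where *both* nodes are
simultaneously non-bursting; by default at least 10 seconds of coincident
non-bursting data are required, otherwise the pair/band is flagged.

EM details: hmmlearn's Baum-Welch with 5 restarts from seeds derived from
the master seed, keeping the best final log-likelihood; tolerance 1e-2 on
the absolute log-likelihood gain, max 200 iterations. A fit whose state
means differ by less than 0.05 envelope standard deviations is declared
collapsed (`DegenerateFitError`) — this is the expected failure mode for
signals without bursting dynamics, and it propagates as a flagged (missing)
cell, not a number.

The alternative noise model — measurement noise from a separate noise
recording with the same channel layout and filters (the empty-room
analogue) — uses whole-recording moments without masking.

## Synthetic pairs

The generator produces the study conditions: pairs of 8–12 Hz band-filtered
gaussian white noises at 1 kHz lasting 5 minutes, 31 repetitions per cell
(matching a typical resting-state cohort), with three controls:

- **Coupling AEC0.** The squared envelope of y0 is replaced by
  `A_{y0}^2 + k A_{x0}^2` with
  `k = AEC0/sqrt(1-AEC0^2) * std(A_{y0}^2)/std(A_{x0}^2)`; phases are
  untouched. With `c = AEC0/sqrt(1-AEC0^2)` the population correlation of
  the squared envelopes is `c/sqrt(1+c^2) = AEC0` exactly, for any
  independent inputs. Mixing plain envelopes instead
  (`mixing="amplitude"`) moves the same identity to plain-envelope
  correlation; squared-envelope mixing is the default so that the generator
  ground truth and the estimator live on the same scale (with plain-envelope
  mixing the squared-envelope coupling deviates from AEC0 by up to ~15% at
  low AEC0 — a Rayleigh-moment computation reproduced in scratch analyses —
  which would contaminate the correction-accuracy experiment).
- **Noise coupling AECnoise**, same rule applied to the noise pair
  (default 0).
- **SNR.** Noise is rescaled relative to the coupled connectivity process.
  The default convention (`snr_convention="amplitude"`) interprets the SNR
  parameter as the amplitude-specific SNR of a gaussian signal with that
  variance ratio, using the exact inversion
  `var(eps)/var(x0) = sqrt(s^2/(s^2-1)) - 1`; this is the SNR scale that can
  be estimated from measured data via envelope moments, and the scale on
  which the headline numbers are quoted. The raw process-std ratio
  (`"process"`, the "gaussian" simulation knob) and the measured-signal
  ratio (`"measured"`) are switches. The three are deterministic monotone
  transforms of one another; the amplitude convention was adopted because it
  is the only one under which the two quoted regimes (large bias ~60% at
  SNR 1.4 and negligible bias <10% above 3) are simultaneously
  reproduced — under the process convention the deviation at SNR 3.5 is
  still ~15–25%.

Experiments:

- **Bias experiment** (`run_bias_experiment`): grid of SNR pairs x AEC0
  levels; per cell the mean estimated AEC, the OLS slope of AEC on AEC0,
  and the power bias measure `PBM = 100 |mean AEC - AEC0| / AEC0`.
- **Correction experiment** (`run_correction_experiment`): same cells, with
  the renormalization applied per repetition using ground-truth noise
  statistics from the retained simulated noise processes. The pooled
  correction error is the through-origin-slope deviation
  `100 |sum ref_i (ren_i - ref_i)| / sum ref_i^2` over all repetitions and
  coupling levels — how far the corrected-vs-true calibration scatter
  departs from the identity line. The default reference is the *realized*
  noise-free coupling of each repetition (sample squared-envelope
  correlation of the retained connectivity processes; its expectation is
  AEC0), so that generator sampling noise, which is not correction error, is
  not attributed to the correction; the nominal-AEC0 reference is also
  reported. A signed, pooled statistic is the only aggregation whose
  Monte-Carlo noise at this problem size (~0.06 per-repetition SD of AEC_ren
  at amplitude SNR 1.4) resolves sub-percent accuracy; per-cell unsigned
  errors would be dominated by sampling noise. For the same reason the
  correction experiment uses a dense coupling grid
  (AEC0 = 0.05, 0.10, ..., 0.80).

## Power bias measure over spectra

For whole connectivity spectra, `pbm(spectrum, reference)` aggregates as
100 x RMS(difference)/RMS(reference) across the supplied bands (RMS ratio
chosen for symmetry and robustness); a mean-of-relative-differences variant
is behind a switch. Degenerate bands carry NaN and are excluded, never
imputed as zeros.

## Spectral-similarity statistics

Correlations between spectra (e.g. raw vs corrected AEC spectra, whole vs
non-bursting power spectra) are tested one-sided via the Fisher transform,
`z = atanh(r)`, gaussian under the null with variance `1/(n_eff - 3)`. The
effective spectral degrees of freedom `n_eff` are the eigenvalue
participation ratio `(tr C)^2 / tr(C^2)` of the cross-frequency correlation
matrix of individual (per-subject/per-repetition) spectra, computed after
averaging the two spectra entering the correlation. Because `n_eff` is
estimated from few observations (~31) over many bins (45), `tr(C^2)` uses a
Srivastava-type unbiased moment estimate; without that debiasing the
sample participation ratio is roughly halved and the test's empirical
type-I error collapses to ~0.005 instead of 0.05. The debiased plug-in is
validated by a simulated-null calibration test (2000 replicates, AR(1)
cross-frequency correlation 0.5 over 45 bins, 31 subjects): empirical
one-sided type-I error within 0.03–0.07 at alpha = 0.05. Family-wise error
is Bonferroni-controlled with m = rho (node-level) or rho(rho-1)/2
(connection-level), rho supplied by the caller; in simulations rho defaults
to the number of channels, as no forward model exists.

## Fixtures and what the synthetic data do not show

The `burst_gated` scenario builds two channels of sustained alpha background
plus high-amplitude alpha bursts switched by a shared smoothed Markov gate
plus independent broadband noise: coupling exists only through burst
co-occurrence. On it the pipeline reproduces, at desk scale, the qualitative
signatures of the resting-state analysis: an alpha-peaked raw AEC spectrum,
a flat near-zero non-bursting AEC spectrum, and a renormalized in-band
estimate above the raw one.

The generators emulate stationary, single-band, linearly mixed processes
with gaussian backgrounds. They do not emulate 1/f spectra, multi-band
rhythms, non-stationary artifacts, realistic sensor-noise covariance, or
source-space leakage fields (the orthogonalization stand-in removes zero-lag
mixing only). Passing tests therefore certify the estimator algebra and the
burst-based noise-model logic, not performance on real recordings.

## Numerical conventions

Population (ddof = 0) moments throughout; all frequencies in Hz, times in
seconds, 0-based samples, half-open windows; analytic signals via FFT padded
to the next fast length; Pearson correlations computed on demeaned arrays
with exact zero-variance guards (`DegenerateEnvelopeError` when the envelope
coefficient of variation is below 1e-3, e.g. pure tones); Viterbi ties
resolved towards the lower state index; experiment tables bit-reproducible
from the master seed (per-cell, per-repetition seeds derived via
`SeedSequence`).

## Problem sizes

The study-scale experiments (tests and the acceptance script) use the native
conditions: 31 repetitions of 5-minute 1 kHz pairs per cell, amplitude-SNR
cells (1.4, 1.4) and (3.5, 5.0), PBM at AEC0 = 0.5, correction error pooled
over the 16-level coupling grid. Unit and property tests use shorter, lower
rate simulations (typically 250–500 Hz, 20–400 s) with tolerances set from
the effective number of independent envelope samples (~1.5 x bandwidth x
duration).
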