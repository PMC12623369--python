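# Methods

This note documents the models and procedures implemented in `sleepconn`,
the assumptions behind the synthetic-data generator, the numerical choices
made where the design was genuinely open, and the limits of what the test
suite demonstrates.

## Preprocessing

**Decimation.** Wideband input is low-pass filtered with a Hamming-windowed
linear-phase FIR (cutoff 300 Hz, transition ≤ 15% of the cutoff) applied
forward–backward (zero phase, squared magnitude response), then
downsampled to 1 kHz — by simple stride when the rate ratio is an integer,
by polyphase resampling otherwise. Band power up to ~290 Hz is preserved
within a few percent; content above the new Nyquist is suppressed well
beyond 80 dB after the double pass.

**Bipolar montage.** The default montage subtracts spatially adjacent
electrodes within each array (1−2, 3−4, …). Local referencing suppresses
common-mode and volume-conducted activity; any montage can be supplied
explicitly, with the constraints that pairs never span regions and no
electrode serves twice as anode. Whether a recording system references
adjacent wires or an array-common wire is a per-experiment choice; both are
expressible through the montage table.

**Mains band-stop.** A single multiband linear-phase FIR with 1 Hz stop
bands centered at 50 Hz and every harmonic below Nyquist. The
Hamming-window design is a natural fit here: its ~53 dB side-lobe floor is
exactly the suppression target, so the filter length is chosen to place a
full transition inside the 0.5 Hz half-width (13201 taps at 1 kHz, i.e.
13.2 s of impulse response; the achieved attenuation at the stop centers is
~64 dB single-pass). The design is verified at construction and an
unattainable length budget raises with the attenuation actually reached.
Filtering is applied after decimation, forward–backward.

**Channel screening.** Clipping is detected as *saturation plateaus*:
samples within 0.1% of the observed amplitude rails that also repeat a
neighbouring sample. The plateau requirement matters — clean oscillations
dwell near their extrema (a pure sine spends ~4% of samples within 0.1% of
its peaks) but never flat-line there, while amplifier saturation produces
runs of identical rail values. A channel is flagged clipped above a 2%
plateau fraction, and drifting when power below 0.5 Hz (mean removed)
exceeds half its total power. Both thresholds are configurable; they
operationalize what is ultimately a visual-inspection judgement, and real
data may need tuning.

## Sleep staging

Per channel and 2-s Hann-tapered window (1-s step) two periodogram band
ratios are computed: ratio 1 = (0.5–20)/(0.5–55) Hz and
ratio 2 = (0.5–4.5)/(0.5–9) Hz. The epochs × channels matrix of each ratio
is reduced to its first principal component, oriented to correlate
positively with the cross-channel mean (PCA signs are otherwise
arbitrary), and smoothed with a 20-s unit-sum Hanning kernel. Smoothing is
mean-preserving by construction: edge windows are renormalized to the
kernel mass actually applied and the series re-centered, so the global
mean survives exactly.

The (x = ratio-2 PC, y = ratio-1 PC) map is standardized per axis and
clustered with k-means (k = 3, 20 restarts, fixed seed). Cluster→state
assignment is positional: SWS is the cluster with the highest mean x
(delta-dominant); of the remainder REM has the higher y (slow power
without delta) and WK is the rest. This rule is an operationalization
validated by recovery on synthetic three-state sessions (≥ 90% epoch
accuracy enforced in the tests, ~99% typical); it is not guaranteed for
pathological spectra, and a degenerate (zero-variance) map yields
UNSCORED everywhere rather than arbitrary labels.

SWS analysis segments tile maximal SWS runs with non-overlapping 120-s
windows; a window is dropped if any good channel exceeds 8 robust
standard deviations (median/MAD) anywhere inside it. Normalized SWS
duration is the fraction of scored session time labeled SWS — a
scale-free quantity comparable across sessions of different lengths.

## Spectra, PLV, PAC

**Welch PSD.** Hann windows of 4096 samples with 50% overlap at 1 kHz
(resolution fs/nperseg ≈ 0.244 Hz), constant detrend, density scaling.
Region spectra average channels then segments; group intervals use a
percentile bootstrap (n = 1000, 97%, seeded) resampling *animals*, since
the relevant spread in a group plot is inter-subject.

**Wavelet bank.** 43 complex Morlet kernels, log-spaced 1.2–200 Hz. The
width parameter m = 7.5 is interpreted as the cycle-count convention,
σ_t = m/(2πf) — conventions differ across packages, so this is stated
explicitly. Kernels are unit-energy, truncated at ±4σ_t; samples within
half a support of either segment edge are excluded from every estimate
(boundary coefficients carry systematic phase bias). Log spacing is chosen
because the PAC low-frequency grid is itself near-geometric; linear
spacing is available.

**PLV.** The complex phase-locking value is the mean unit phasor of the
coefficient phase difference; its magnitude is bounded by construction in
[0, 1], symmetric, and invariant to channel amplitude scaling. K is the
count of valid samples per 120-s segment; segment PLV matrices are
averaged afterwards. The chance level of |mean of K unit phasors| for
independent phases is √π/(2√K) for i.i.d. samples, but narrow-band
filtering leaves far fewer effective samples, so the pipeline reports a
surrogate reference spectrum (circular-split, below) rather than the
analytic i.i.d. value.

**PAC.** For each (LF, ratio) cell with HF = LF·ratio ≤ 200 Hz: the phase
channel's LF phase, the amplitude channel's HF envelope (modulus of the HF
wavelet coefficients), the envelope's own LF phase (mean-removed, filtered
at the same LF), and the resultant of their phase difference. Cells with
HF > 200 Hz never enter any output. One reading note: the coupling
statistic contrasts the LF phase of x with the *phase of the LF-filtered
envelope* of y. Treating the envelope term as an amplitude would leave the
phasor expression undefined, so the envelope-phase reading is implemented;
a band-pass + analytic-signal envelope variant is available
(`envelope_method="hilbert"`).

Kernels are centered at the exact LF/HF values of the grid, not snapped to
the 43-point bank. nPAC divides the observed PAC by the mean over 50
circular-split surrogates (seeded), giving ≈ 1 under the null. The LF×ratio
grid is projected to an LF×HF comodulogram and averaged across LF per HF
bin (24 logarithmic bins over 2–200 Hz — the binning is a convention of
this implementation). Intra-areal directions couple distinct electrodes
within a region; inter-areal directions take LF phase in one region and HF
amplitude in the other, which makes PAC directional (S1→RFA ≠ RFA→S1).

The comodulogram inner loops filter in the frequency domain (cached kernel
spectra, one FFT per channel per segment); circular convolution differs
from linear only within the margins that are trimmed anyway.

## Surrogates

A surrogate rotates one channel of a pair circularly at a uniformly drawn
interior split point: x_surr = [x(k…T), x(1…k)]. This preserves the sample
multiset, the magnitude spectrum and therefore the full autocorrelation of
the rotated channel exactly, while destroying its temporal alignment with
the partner. Rotations are applied to narrow-band coefficient series
(after filtering), and the split point keeps a minimum distance from the
edges so a draw can never be a near-identity rotation. Where the
descriptive literature speaks of recombining mismatched segments *between*
channels, the defining formula rotates a single channel; the formula is
what is implemented.

## Networks and group statistics

Eigenvector centrality is the leading eigenvector (dense symmetric
eigendecomposition) of the band-averaged PLV matrix with zeroed diagonal,
non-negative (Perron vector) and unit L2 norm; disconnected graphs are
scored per connected component with a warning. Canonical bands: delta
0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–100 Hz; a band average
uses the bank frequencies whose centers fall inside the band.

The sleep–centrality model is `sqrt_evc ~ norm_sws_duration × condition`
with a random intercept per animal (statsmodels MixedLM, REML). Random
slopes are deliberately omitted: with ≤ 5 animals per group they are not
identifiable. Per-condition slopes and their pairwise contrasts are linear
combinations of the fixed effects with delta-method standard errors;
singular mixed fits fall back to OLS with a logged downgrade. The square
root of EVC linearizes a mildly convex duration–centrality relation; no
quadratic term is fitted. Benjamini–Hochberg adjustment is applied within
region across its band × condition tests.

The per-frequency battery: Mann–Whitney U (central tendency) and
Fligner–Killeen (spread) for independent groups; paired t and a
permutation test on ln var differences for within-subject contrasts. The
permutation null swaps each animal's condition pair independently —
exhaustive over all 2ⁿ assignments for n ≤ 12 animals (p on a 1/2ⁿ grid),
otherwise 10,000 seeded draws with add-one smoothing. All tests are
two-sided; CV = SD/mean across animals; lnVR = ln(var_a/var_b) and
Cohen's d (pooled SD) are antisymmetric under group swap; BH across
frequencies at α = 0.05. A Shapiro–Wilk normality report is produced but
never switches the tests — the battery runs as stated regardless, which
reproduces the analysis convention this pipeline follows and is flagged
here rather than resolved. Note the permutation grid implies a minimum
attainable p of 2/2ⁿ: with 4 animals no variance difference can reach
p < 0.125, so "no significant variability change" with small n is partly
a resolution statement.

## Synthetic data

Each channel is 1/f^β background (default β = 1, RMS 20 µV) plus
state-gated narrow-band oscillators (delta 1–4 Hz, theta 5–8 Hz, gamma
30–80 Hz) with per-state RMS gains — SWS delta-dominant (60 µV), REM
theta-dominant (45 µV) with low delta, WK desynchronized — plus common
50 Hz line noise with 1/k harmonics, optional clipping bursts (saturation
at ±1500 µV rails, far above signal SD, as amplifier rails are), and the
injected couplings. States follow a semi-Markov chain with
gamma-distributed dwells (means WK 180 s, SWS 300 s, REM 90 s; shape 2), so
hypnogram segmentation is non-trivial. Everything is reproducible from the
spec seed, and specs serialize to a provenance JSON.

**PLV injection.** Coupled channels share a narrow-band oscillator phase
(15% relative bandwidth Gaussian process — *not* a pure phase ramp, since
a perfectly periodic modulator would survive circular rotation up to a
constant offset and surrogates could not null it) plus independent
slowly-varying Gaussian phase jitter. For slow jitter of SD σ the expected
PLV is exp(−σ²); because background noise at the coupling frequency
dilutes this, the shipped calibration table
(`sleepconn/data/plv_jitter_calibration.csv`, rebuilt by
`scripts/build_plv_calibration.py`) maps jitter SD to the PLV actually
measured under default conditions by Monte Carlo, and requested strengths
are inverted through it. Recovery is within ±0.05 for strengths 0.2–0.8;
the measurable ceiling at default SNR is ~0.98.

**PAC injection.** Amplitude-region channels carry an HF carrier whose
envelope is (1 + m·cos φ_LF)/(1 + m) with φ_LF from the phase region's LF
oscillator. This normalization keeps the envelope *peak* constant across
depths m, so depth recovery is not confounded by HF power changes.

**Studies.** `make_study` mirrors the experimental design — a control
group (n = 5) recorded once and a lesion group (n = 4) recorded at two
paired time points — generating SWS analysis segments per animal with
per-animal Gaussian random intercepts on coupling parameters and sleep
fraction, per-condition injected effects, and a truth table of everything
injected.

**What the generator does not emulate:** volume conduction and reference
contamination across channels, non-stationarity within a state,
waveform-shape asymmetries of real slow oscillations (which can create
spurious PAC in real data), electrode impedance drift, and genuinely
biophysical dynamics. Passing recovery tests therefore demonstrates the
estimators, not robustness to those real-data confounds.

## Problem sizes in the validation suite

The test battery runs the full method at reduced problem sizes chosen to
keep the suite fast while leaving each check statistically meaningful:
120-s segments with one or two channels per region for metric-level
calibration (20 seeds), 1500-s four-channel-per-region sessions for
staging recovery (10 seeds), 20 simulated studies for power and null
control, and 2000 simulations for permutation type-I error. Channel counts
and durations are arguments everywhere, so the same checks scale up
unchanged.

## Known limitations

* The positional cluster→state rule assumes the three states are present
  and spectrally conventional; sessions missing a state entirely still
  produce three clusters, splitting one true state.
* nPAC is noisy for cells whose LF kernel spans a large fraction of the
  segment (LF = 1.2 Hz has ~8-s support); the surrogate normalization
  removes bias but not variance.
* The mixed model treats segments' aggregated centrality as exchangeable
  within animal; serial correlation across segments within a session is
  not modelled.
* EDF files are read (via mne) but sessions are written only to the
  binary-container format.
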