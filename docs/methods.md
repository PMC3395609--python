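# Methods

## The measurement problem

Baseline BP and BFV recordings are nonstationary: oscillation amplitude and
period drift on the scale of a few cycles, and both channels are punctured
by measurement artifacts (probe movement, finger-cuff recalibration,
talking). A Fourier-based transfer function treats the whole record as a
superposition of fixed sinusoids and therefore smears these drifts into its
phase estimate. The approach implemented here instead measures phase on
individual oscillatory cycles of data-adaptive narrowband components, and
rejects — rather than repairs — cycles that look corrupted. The output is a
phase-shift spectrum: mean BFV-minus-BP phase per frequency bin, positive
when flow leads pressure.

## Pipeline stages and the choices behind them

### Resampling (`io_preprocess`)

Recordings are analysed at 50 Hz; higher-rate input is decimated after a
zero-phase (forward-backward) Butterworth low-pass at 0.4 × the target
rate. A zero-phase filter is non-negotiable here: any filter phase response
would bias the very quantity being measured. The passband fidelity is
asserted by test (amplitude within 1%, phase within 1° for tones below
0.4 × rate). Non-finite samples are linearly interpolated when the gap is
≤ 0.5 s and refused otherwise; long gaps should be excluded by the cycle
criteria downstream, not invented by an interpolator.

### Decomposition (`emd`)

Sifting uses natural cubic-spline envelopes through the local extrema, with
two extrema mirrored at each boundary, a Cauchy-type stopping rule
(SD < 0.2 between successive sifts) and a hard cap of 10 sifts per mode —
the standard defaults of the EMD literature. Mode extraction stops when the
residual has fewer than two interior extrema, when ⌊log₂N⌋ − 1 modes have
been extracted (the dyadic filter-bank capacity of EMD), or when the
residual's peak-to-peak amplitude falls below 10⁻¹⁰ of the source's — the
last guard prevents the sifter from decomposing floating-point dust into
spurious "modes", which would otherwise pollute mode pairing.

The ensemble variant (EEMD) averages each mode index over decompositions of
noise-perturbed copies (default 100 members, noise SD 0.2 × signal SD,
seeded); its residual is defined as input minus averaged modes so
completeness holds exactly. Plain EMD is the pipeline default; the ensemble
variant exists because intermittent oscillations can mix scales within one
mode, and a test demonstrates the mixing reduction on a burst fixture.

### Phase, cycles, and the exclusion criteria (`phase_cycles`)

Instantaneous phase is the unwrapped angle of the analytic signal
(Hilbert transform), in degrees; instantaneous frequency is its centred
finite difference divided by 360. Cycles are delimited at successive
upward crossings of the starting phase rounded up to the next multiple of
360°; partial leading/trailing segments are dropped. Because a raw phase
series can decrease locally (that is exactly what criterion 1 detects),
the crossing search runs on the running maximum of the phase, which makes
boundaries well defined without hiding the decreases from the criteria.

BP modes are paired to BFV modes by nearest median instantaneous frequency
(greedy, one-to-one, smallest log-frequency distance), accepting a pair
only when the frequency ratio is within [1/1.5, 1.5] — the same tolerance
the cycle-length criterion uses. Each BP cycle is matched to the BFV cycle
of maximal temporal overlap (ties to the nearest centre). A matched pair is
excluded when any of:

1. the instantaneous phase decreases anywhere within either cycle
   (decreases below 0.01°/sample are treated as numerical jitter);
2. more than 0.2 s of samples in either cycle run at ≥ 2.5 × that cycle's
   mean frequency — the threshold is a duration, not a sample count, so the
   rule is sampling-rate invariant (at 50 Hz, 0.2 s = 10 samples);
3. the BFV/BP cycle-length ratio is ≥ 1.5 or ≤ 1/1.5.

Criteria 1 and 2 are applied to both members of a pair; the rule's wording
("in a cycle") is ambiguous between the channels and applying it to either
is the conservative reading. The phase shift of a retained pair is the mean
over the BP cycle's samples of the per-sample difference φ_BFV − φ_BP, each
difference wrapped to (−180°, 180°] before averaging — without wrapping,
means over independently unwrapped series diverge across cycles. The pair's
binning frequency is 1 / BP-cycle duration, anchoring on the BP cycle.

### Spectrum (`spectrum`)

Retained pairs from all mode couples are pooled (one bin may mix modes) and
assigned to half-open bins [lo, hi); the default grid is 18 bins of 0.02 Hz
over [0.02, 0.38). A pair at exactly 0.38 Hz is out of range — the
half-open convention gives an exhaustive, exclusive partition. Bins report
mean, SD and cycle count; empty bins are NaN, and no minimum-count
threshold is imposed — `n_cycles` is reported so users can threshold.
Group aggregation weights subjects equally: two sides of one subject are
averaged within subject first, the group mean averages the available
subject means per bin, and SE is the between-subject SD / √n.
Records shorter than 60 s are rejected outright: they cannot contain even
two cycles in the slowest bins.

## The validation apparatus

### Aaslid-Tiecks simulator (`tiecks_sim`)

The model is a second-order linear feedback system driven by the normalised
pressure deviation dP = (BP − baseline)/(baseline − CrCP), with critical
closing pressure CrCP = 12 mmHg by default (configurable, down to 0). The
discrete update at sampling rate f_s with a = f_s·T is

    x1[n] = x1[n−1] + (dP[n] − x2[n−1]) / a
    x2[n] = x2[n−1] + (x1[n] − 2·D·x2[n−1]) / a
    BFV[n] = 1 + dP[n] − K·x2[n]

with the canonical (T, D, K) table indexed by ARI 0–9 stored in
`_tiecks_constants.py`. Simulated phase shifts are measured with the same
Hilbert per-cycle machinery as the analysis pipeline (25 drive cycles,
first 5 and the final one discarded), so simulation and measurement share
one phase definition. The independent oracle in the tests is the
closed-form frequency response of this exact recursion obtained by
z-transform; simulation and oracle agree within 0.01°.

Two analytic facts about the canonical parameter table are worth knowing
when reading the phase surface: at 0.02 Hz the ARI 7 and ARI 8 phases tie
to within 0.01° (the low-frequency phase slope K·2DT/(1−K) is not strictly
monotone across the table), and for ARI ≥ 8 the phase *rises* from 0.02 Hz
to a maximum near 0.06 Hz before falling. The headline qualitative claims —
phase grows with ARI, is zero without autoregulation, and is larger at low
than at high frequency, falling monotonically above 0.1 Hz — hold
everywhere, and the tests assert monotonicity exactly where the analytic
response has it.

The pure-delay law, 360·f·Δt, is the discriminating counter-model: a
transmission delay between measurement sites produces a phase shift that
*grows* linearly with frequency, opposite to the autoregulatory trend. A
50 ms delay yields 6.84° at 0.38 Hz and 18° at 1 Hz.

### TFA comparator (`tfa`)

Welch auto/cross-spectra with 100 s Hann segments, 50% overlap, and linear
per-segment detrending — common practice in autoregulation TFA; there is no
canonical setting and everything is configurable. Gain is |S_xy|/S_xx,
phase is the cross-spectrum angle with positive = flow leads, and phase and
gain are conventionally masked at coherence ≤ 0.5, below which the
linear-stationary assumption has no support. On stationary linear fixtures
TFA and the cycle-based spectrum agree; under strong amplitude modulation
they can diverge — that divergence is the reason the cycle-based method
exists and is not asserted as a fixed number.

## The synthetic generator

`synthetic` builds BP/BFV pairs from *phase-integrated oscillators*: each
band's instantaneous frequency is constructed explicitly as
centre + fm_depth·(bandwidth/2)·s(t), with s(t) a smooth seeded modulation
bounded in [−1, 1], and the oscillator phase is its cumulative integral.
Because the BFV copy of each band is generated from the same phase series
advanced by the imposed shift, the per-band ground truth is exact by
construction, not estimated. Amplitude modulation multiplies each band by
1 + am_depth·m(t) with an independent smooth m(t). Defaults emulate the
target recordings: 300 s at 50 Hz, four bands spanning 0.05–0.35 Hz with
amplitudes of a few mmHg, a ~1 Hz cardiac component of 8 mmHg with 3%
frequency wander, baselines of 90 mmHg (BP) and 50 cm/s (BFV). Optional
white measurement noise is scaled to the oscillatory SD; a pure
transmission delay is applied to the flow channel as a fractional-sample
FFT phase ramp, so the delay law is an exact oracle. Artifacts (dropouts of
1–3 s, spikes of a few SD over 0.2 s, slow drifts) are injected separately.

What the generator does *not* emulate: pulse-wave morphology (cycles are
sinusoidal, not skewed pressure waveforms), respiratory coupling,
heteroscedastic or 1/f measurement noise, and any genuine nonlinear
pressure-flow coupling — the imposed shifts are linear phase offsets.
Passing the recovery tests therefore shows the pipeline correctly measures
cycle-wise phase relationships under amplitude/frequency modulation, noise
and artifacts; it does not certify behaviour on real vascular dynamics.

## Measured behaviour under noise

On clean fixtures the pipeline recovers imposed shifts within ~1° across a
grid of shifts (−60° … 60°) and band centres (0.05–0.35 Hz). With 10%
additive white noise and 50% amplitude modulation, recovery over 20 seeded
replicates stays within 10° on average (~8° mean absolute error), but the
retained-cycle fraction drops to roughly a quarter: criterion 1 rejects any
cycle whose phase wiggles backwards, and broadband noise puts such ripples
into many cycles of every mode. This aggressive rejection is the design —
the estimate stays accurate because contaminated cycles are dropped, at the
price of cycle count. Real recordings, whose noise is not white at the mode
scale, retain more.

## Problem sizes and determinism

Tests and the acceptance script use 300 s records at 50 Hz (15,000
samples), 20-replicate Monte Carlo for the noisy condition, a 10 × 10
frequency-by-ARI simulation grid, and 1050 s noise records for the Welch
null — sizes at which every quantity reported is stable to well within its
asserted tolerance. All stochastic steps take explicit integer seeds;
fixed inputs and seeds reproduce spectra bit-for-bit.
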