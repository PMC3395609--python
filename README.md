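# impfa — intrinsic multiscale pressure-flow analysis

Cerebral autoregulation (CA) keeps brain perfusion relatively stable while
arterial blood pressure (BP) fluctuates. A standard non-invasive probe of CA
is the phase relationship between spontaneous BP oscillations and cerebral
blood flow velocity (BFV, from transcranial Doppler): when the vasculature
actively counter-regulates, flow oscillations *lead* pressure oscillations,
and the size of the lead shrinks as oscillation frequency grows. The classic
way to measure this — transfer function analysis (TFA) — assumes stationary,
linear signals, an assumption baseline BP/BFV recordings plainly violate.

`impfa` implements a cycle-by-cycle, nonstationarity-tolerant alternative:

1. **Decompose** BP and BFV into intrinsic mode functions by empirical mode
   decomposition (EMD; ensemble variant available), so each mode is a
   narrowband, amplitude/frequency-modulated oscillation.
2. **Segment and match cycles.** Each mode gets an instantaneous Hilbert
   phase φ(t); every 360° increment of φ is one cycle. BP modes are paired
   with BFV modes of matching frequency, and each BP cycle is matched with
   the maximally overlapping BFV cycle. Matched cycles are discarded when
   (1) the phase decreases anywhere inside a cycle, (2) more than 0.2 s of
   a cycle runs at ≥ 2.5× the cycle's mean frequency, or (3) the two cycle
   lengths differ by ≥ 1.5× — the signatures of noise, artifacts, or
   unrelated transients.
3. **Average and bin.** The phase shift of a retained pair is the mean of
   the wrapped per-sample difference φ_BFV − φ_BP over the BP cycle, with
   positive values meaning flow leads pressure. Retained cycle pairs from
   all modes are pooled into 18 frequency bins of 0.02 Hz covering
   0.02–0.38 Hz, giving a phase-shift spectrum per recording; group
   summaries average subject means with between-subject standard errors.

The package also ships the validation apparatus used to interpret such
spectra: the **Aaslid-Tiecks** second-order autoregulation model (indices
ARI 0–9, from absent to best regulation), the **pure-delay phase law**
(360·f·Δt — the opposite frequency trend, used to rule out transmission
delay as the source of the measured lead), a **TFA comparator** with the
conventional coherence > 0.5 inclusion rule, and a **seeded synthetic
generator** whose per-band imposed phase shifts serve as ground truth.

## Worked example

```python
from impfa import SynthSpec, Band, gen_multiscale_pair, impfa_run

spec = SynthSpec(
    bands=(
        Band(0.05, 0.01, 4.0, 50.0),   # centre Hz, bandwidth, amplitude, shift°
        Band(0.20, 0.04, 2.5, 20.0),
    ),
    am_depth=0.3, noise_sd=0.02, seed=42,
)
bp, bfv, truth = gen_multiscale_pair(spec)
spectrum, qc = impfa_run(bp, bfv)
df = spectrum.to_frame()
print(df[df.n_cycles >= 3].to_string(index=False))
print(f"retained {qc['n_retained']} of {qc['n_cycle_pairs']} matched cycle pairs")
```

```
 bin_lo_hz  bin_hi_hz  mean_shift_deg    sd_deg  n_cycles
      0.02       0.04        6.191815 74.829069         6
      0.04       0.06       46.923076 10.764332         6
      0.18       0.20       18.717700  8.989227        26
      0.20       0.22       20.696516  2.690109        19
      0.22       0.24       14.454586 15.933752         3
retained 1346 of 4270 matched cycle pairs
```

The two imposed shifts are recovered in their covering bins (46.9° vs 50°
imposed at 0.05 Hz; 18.7–20.7° vs 20° imposed around 0.20 Hz). The
0.02–0.04 Hz bin illustrates why `n_cycles` and `sd_deg` matter: it holds
six stray cycles with a 75° spread and carries no usable estimate. The
large excluded count is the filtering criteria rejecting noise-dominated
cycles from the fast modes.

The same analysis runs from the shell:

```sh
impfa synth --spec spec.json --seed 42 --out-bp bp.csv --out-bfv bfv.csv
impfa run --bp bp.csv --bfv bfv.csv --time-column time_s --out spectrum.csv --qc qc.json
impfa tfa --bp bp.csv --bfv bfv.csv --rate 50 --out tfa.csv
impfa simulate tiecks --ari 5 --freq 0.1 --out bfv_sim.csv
impfa simulate delay --dt 0.05 --freq 0.38     # -> 6.84 deg
```

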