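"""Seeded synthetic BP/BFV pairs with known multiscale phase structure.

Real baseline recordings contain amplitude- and frequency-modulated
oscillations across 0.02-0.4 Hz, a ~1 Hz cardiac component, measurement
noise and occasional artifacts.  This module builds such pairs from
phase-integrated narrowband oscillators — the instantaneous frequency is
constructed explicitly and the oscillator phase is its cumulative
integral — so the flow-vs-pressure phase shift imposed per band is exactly
defined and serves as ground truth for the whole pipeline.

An optional pure transmission delay is applied to the flow channel as a
fractional-sample FFT shift, making the delay phase law an exact oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io_preprocess import TimeSeries


@dataclass(frozen=True)
class Band:
    """One narrowband oscillator: centre (Hz), bandwidth (Hz, full width of
    the instantaneous-frequency excursion), amplitude (channel units) and
    the imposed flow-vs-pressure phase shift in degrees."""

    center: float
    bandwidth: float
    amplitude: float
    shift_deg: float = 0.0


@dataclass(frozen=True)
class Artifact:
    """kind: dropout (flat segment), spike (brief excursion) or drift
    (slow baseline ramp); time in s; magnitude: seconds for dropout,
    SD multiples for spike, channel units for drift."""

    kind: str
    time_s: float
    magnitude: float


@dataclass(frozen=True)
class SynthSpec:
    """Generation recipe for one BP/BFV pair; fully determined by seed."""

    duration_s: float = 300.0
    rate: float = 50.0
    bands: tuple[Band, ...] = (
        Band(0.05, 0.02, 4.0, 50.0),
        Band(0.11, 0.04, 3.0, 35.0),
        Band(0.25, 0.08, 2.0, 15.0),
        Band(0.35, 0.10, 1.5, 5.0),
    )
    am_depth: float = 0.3
    fm_depth: float = 1.0
    cardiac_freq: float = 1.0
    cardiac_amplitude: float = 8.0
    noise_sd: float = 0.0   # fraction of oscillatory signal SD
    delay_s: float = 0.0    # pure transmission delay applied to BFV
    bp_baseline: float = 90.0
    bfv_baseline: float = 50.0
    artifacts: tuple[Artifact, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 60:
            raise ValueError("duration must be >= 60 s for the default bins")
        for b in self.bands:
            if not 0 < b.center < self.rate / 4:
                raise ValueError(f"band centre {b.center} outside (0, rate/4)")
            if not -180 < b.shift_deg <= 180:
                raise ValueError("imposed shifts must lie in (-180, 180]")
        bands = sorted(self.bands, key=lambda b: b.center)
        for a, b in zip(bands, bands[1:]):
            if b.center - a.center < 0.5 * (a.bandwidth + b.bandwidth):
                raise ValueError(
                    f"bands at {a.center} and {b.center} Hz overlap: "
                    "ground truth would be unidentifiable"
                )


def _slow_modulation(n: int, rate: float, rng, cutoff_hz: float = 0.01):
    """Smooth zero-mean modulation normalised to max |.| = 1."""
    x = rng.standard_normal(n)
    sigma = rate / (2 * np.pi * cutoff_hz)
    x = gaussian_filter1d(x, sigma, mode="reflect")
    x -= x.mean()
    peak = np.max(np.abs(x))
    return x / peak if peak > 0 else x


def _fractional_delay(x: np.ndarray, delay_samples: float) -> np.ndarray:
    """Band-limited fractional-sample delay via FFT phase ramp."""
    n = x.size
    f = np.fft.rfftfreq(n)
    X = np.fft.rfft(x)
    return np.fft.irfft(X * np.exp(-2j * np.pi * f * delay_samples), n)


def gen_multiscale_pair(
    spec: SynthSpec,
) -> tuple[TimeSeries, TimeSeries, pd.DataFrame]:
    """Generate a (BP, BFV, truth) triple from a :class:`SynthSpec`.

    BP is the sum of AM/FM narrowband oscillators plus cardiac component
    and noise around its baseline; BFV carries the same oscillators, each
    phase-advanced by its imposed shift, with independent noise, an
    optional pure delay, and its own baseline.  The truth table lists each
    band's centre and imposed shift.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate))
    t = np.arange(n) / spec.rate

    bp = np.full(n, spec.bp_baseline)
    bfv_scale = spec.bfv_baseline / spec.bp_baseline
    bfv = np.full(n, spec.bfv_baseline)

    for band in spec.bands:
        fm = _slow_modulation(n, spec.rate, rng)
        am = _slow_modulation(n, spec.rate, rng)
        inst_freq = band.center + spec.fm_depth * (band.bandwidth / 2.0) * fm
        phase = 2 * np.pi * np.cumsum(inst_freq) / spec.rate
        amp = band.amplitude * (1.0 + spec.am_depth * am)
        shift = np.radians(band.shift_deg)
        bp += amp * np.sin(phase)
        bfv += bfv_scale * amp * np.sin(phase + shift)

    if spec.cardiac_amplitude > 0:
        fm = _slow_modulation(n, spec.rate, rng, cutoff_hz=0.05)
        inst = spec.cardiac_freq * (1.0 + 0.03 * fm)
        ph = 2 * np.pi * np.cumsum(inst) / spec.rate
        bp += spec.cardiac_amplitude * np.sin(ph)
        bfv += bfv_scale * spec.cardiac_amplitude * np.sin(ph)

    if spec.noise_sd > 0:
        osc_sd = float(np.std(bp - spec.bp_baseline))
        bp = bp + rng.normal(0, spec.noise_sd * osc_sd, n)
        bfv = bfv + rng.normal(0, spec.noise_sd * osc_sd * bfv_scale, n)

    if spec.delay_s != 0:
        bfv_osc = bfv - spec.bfv_baseline
        bfv = spec.bfv_baseline + _fractional_delay(
            bfv_osc, spec.delay_s * spec.rate
        )

    bp_ts = TimeSeries(bp, rate=spec.rate, label="bp", units="mmHg")
    bfv_ts = TimeSeries(bfv, rate=spec.rate, label="bfv", units="cm/s")
    if spec.artifacts:
        art_rng = np.random.default_rng(spec.seed + 1)
        bfv_ts = inject_artifacts(bfv_ts, spec.artifacts, rng=art_rng)
    truth = pd.DataFrame(
        {
            "center_hz": [b.center for b in spec.bands],
            "bandwidth_hz": [b.bandwidth for b in spec.bands],
            "amplitude": [b.amplitude for b in spec.bands],
            "shift_deg": [b.shift_deg for b in spec.bands],
        }
    )
    return bp_ts, bfv_ts, truth


def inject_artifacts(
    ts: TimeSeries,
    artifacts,
    seed: int | None = None,
    rng=None,
) -> TimeSeries:
    """Corrupt a series with dropouts, spikes or drifts at given times.

    dropout: hold the signal flat for ``magnitude`` seconds (clipped to
    1-3 s).  spike: half-sine excursion of ``magnitude`` signal-SDs over
    0.2 s.  drift: linear baseline ramp of ``magnitude`` units from the
    artifact time to the end of the record.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v = ts.values.copy()
    n = v.size
    sd = float(np.std(v))
    for art in artifacts:
        i0 = int(round(art.time_s * ts.rate))
        if not 0 <= i0 < n:
            raise ValueError(f"artifact time {art.time_s} s outside record")
        if art.kind == "dropout":
            dur = float(np.clip(art.magnitude, 1.0, 3.0))
            i1 = min(n, i0 + int(dur * ts.rate))
            v[i0:i1] = v[i0]
        elif art.kind == "spike":
            if art.magnitude == 0:
                continue
            width = int(0.2 * ts.rate)
            i1 = min(n, i0 + width)
            bump = np.sin(np.linspace(0, np.pi, i1 - i0))
            v[i0:i1] += art.magnitude * sd * bump
        elif art.kind == "drift":
            if art.magnitude == 0:
                continue
            ramp = np.linspace(0, art.magnitude, n - i0)
            v[i0:] += ramp
        else:
            raise ValueError(f"unknown artifact kind {art.kind!r}")
    return TimeSeries(v, rate=ts.rate, label=ts.label, units=ts.units)
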