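"""Aaslid-Tiecks dynamic autoregulation simulator and the pure-delay model.

The Tiecks model is a second-order linear feedback system: normalised
pressure deviations dP drive two internal states whose output subtracts
from the passive pressure transmission, so that flow velocity recovers
after a pressure change at a speed set by the autoregulation index
ARI 0-9.  Driven by sinusoidal pressure it produces a sinusoidal flow
response whose phase lead over pressure grows with ARI and shrinks with
frequency — the opposite frequency dependence to a pure measurement time
delay, whose apparent phase shift 360*f*dt grows linearly with frequency.
That sign contrast is what lets a measured phase-vs-frequency spectrum
discriminate genuine autoregulation from transmission delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tiecks_constants import ARI_TABLE, DEFAULT_CRCP
from .io_preprocess import TimeSeries
from .phase_cycles import (
    cycle_phase_shift,
    hilbert_phase,
    match_and_filter,
    segment_cycles,
)


@dataclass(frozen=True)
class TiecksParams:
    """State parameters of the second-order autoregulation model."""

    ari: int
    T: float  # time constant, s
    D: float  # damping factor
    K: float  # autoregulatory gain
    baseline_bp: float = 90.0  # mmHg
    crcp: float = DEFAULT_CRCP  # critical closing pressure, mmHg

    def __post_init__(self) -> None:
        if not 0 <= self.ari <= 9:
            raise ValueError("ari must be in 0..9")
        if self.T <= 0:
            raise ValueError("time constant T must be positive")
        if not 0.0 <= self.K <= 1.0:
            raise ValueError("gain K must be in [0, 1]")
        if not self.baseline_bp > self.crcp >= 0:
            raise ValueError("require baseline_bp > crcp >= 0")


def tiecks_params(
    ari: int, baseline_bp: float = 90.0, crcp: float = DEFAULT_CRCP
) -> TiecksParams:
    """Canonical (T, D, K) triple for an autoregulation index 0-9."""
    if ari not in ARI_TABLE:
        raise ValueError(f"ari must be an integer in 0..9, got {ari!r}")
    T, D, K = ARI_TABLE[ari]
    return TiecksParams(ari=ari, T=T, D=D, K=K, baseline_bp=baseline_bp, crcp=crcp)


def tiecks_simulate(bp: TimeSeries, params: TiecksParams) -> TimeSeries:
    """Simulate normalised flow velocity (baseline = 1) for a BP input.

    Discrete update at the BP sampling rate f_s, states initialised to 0:

        dP[n] = (BP[n] - baseline) / (baseline - CrCP)
        x1[n] = x1[n-1] + (dP[n] - x2[n-1]) / (f_s * T)
        x2[n] = x2[n-1] + (x1[n] - 2 D x2[n-1]) / (f_s * T)
        BFV[n] = 1 + dP[n] - K * x2[n]
    """
    fs = bp.rate
    fT = fs * params.T
    if fT < 2:
        raise ValueError(
            "T * sampling_rate < 2: discretisation would be unstable"
        )
    dP = (bp.values - params.baseline_bp) / (params.baseline_bp - params.crcp)
    n = dP.size
    x1 = 0.0
    x2 = 0.0
    x2_series = np.empty(n)
    for i in range(n):
        x1 = x1 + (dP[i] - x2) / fT
        x2 = x2 + (x1 - 2.0 * params.D * x2) / fT
        x2_series[i] = x2
    bfv = 1.0 + dP - params.K * x2_series
    return TimeSeries(bfv, rate=fs, label="bfv_sim", units="normalized")


def sinusoid_response_phase(
    f: float,
    ari: int,
    amplitude: float = 10.0,
    baseline_bp: float = 90.0,
    crcp: float = DEFAULT_CRCP,
    rate: float = 50.0,
    n_cycles: int = 25,
    discard_cycles: int = 5,
) -> float:
    """Steady-state flow-vs-pressure phase shift (degrees) for sinusoidal BP.

    Simulates ``n_cycles`` of a sinusoidal pressure drive, discards the
    first ``discard_cycles`` (transient) plus the final cycle (Hilbert edge),
    and measures the phase shift per cycle with the same Hilbert machinery
    used by the analysis pipeline.  Positive = flow leads pressure.
    """
    if not 0 < f < rate / 4:
        raise ValueError("frequency must lie in (0, rate/4)")
    if not amplitude < baseline_bp - crcp:
        raise ValueError("amplitude must be below baseline_bp - crcp")
    params = tiecks_params(ari, baseline_bp, crcp)
    dur = n_cycles / f
    t = np.arange(int(round(dur * rate))) / rate
    bp = TimeSeries(
        baseline_bp + amplitude * np.sin(2 * np.pi * f * t),
        rate=rate, label="bp", units="mmHg",
    )
    bfv = tiecks_simulate(bp, params)

    bp_osc = bp.values - np.mean(bp.values)
    bfv_osc = bfv.values - np.mean(bfv.values)
    bp_ps = hilbert_phase(bp_osc, rate)
    bfv_ps = hilbert_phase(bfv_osc, rate)
    bp_cycles = segment_cycles(bp_ps)
    bfv_cycles = segment_cycles(bfv_ps)
    steady = [
        c for c in bp_cycles[discard_cycles:-1]
    ] if len(bp_cycles) > discard_cycles + 1 else bp_cycles[discard_cycles:]
    pairs = match_and_filter(steady, bp_ps, bfv_cycles, bfv_ps)
    shifts = [
        cycle_phase_shift(p, bp_ps, bfv_ps) for p in pairs if not p.excluded
    ]
    if not shifts:
        raise RuntimeError("no retained cycles in steady state")
    return float(np.mean(shifts))


def phase_surface(
    freqs, aris, normalize: bool = False, **sim_kwargs
) -> np.ndarray:
    """Phase shift on a frequency x ARI grid.

    With ``normalize=True`` each frequency column is expressed as a
    percentage of its ARI 9 value.
    """
    freqs = np.asarray(freqs, float)
    aris = np.asarray(aris, int)
    out = np.empty((freqs.size, aris.size))
    for i, f in enumerate(freqs):
        for j, a in enumerate(aris):
            out[i, j] = sinusoid_response_phase(f, int(a), **sim_kwargs)
    if normalize:
        ref = np.array(
            [sinusoid_response_phase(f, 9, **sim_kwargs) for f in freqs]
        )
        out = 100.0 * out / ref[:, None]
    return out


def delay_phase_shift(delta_t: float, f: float) -> float:
    """Apparent phase shift (degrees) induced by a pure transmission delay.

    A flow channel recorded ``delta_t`` seconds earlier than pressure shows
    an artificial lead of 360 * f * delta_t degrees at frequency f.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    return 360.0 * f * delta_t


def step_response_recovery_time(
    ari: int,
    step_fraction: float = -0.1,
    baseline_bp: float = 90.0,
    crcp: float = DEFAULT_CRCP,
    rate: float = 50.0,
    duration_s: float = 60.0,
    recovery: float = 0.9,
) -> float:
    """Time (s) for flow to regain ``recovery`` x baseline after a BP step.

    The target is an absolute normalised level (default 0.9).  For ARI 0
    flow passively tracks the lowered pressure and never recovers, so inf
    is returned.  Consistency check: higher ARI means faster recovery.
    """
    params = tiecks_params(ari, baseline_bp, crcp)
    n = int(duration_s * rate)
    bp_vals = np.full(n, baseline_bp * (1 + step_fraction))
    bp_vals[: int(rate)] = baseline_bp  # 1 s pre-step baseline
    bfv = tiecks_simulate(TimeSeries(bp_vals, rate=rate), params).values
    step_at = int(rate)
    if bfv[step_at + 1] >= recovery:
        return 0.0
    below = bfv[step_at:] < recovery
    if below[-1]:
        return float("inf")
    return float(np.flatnonzero(~below)[0]) / rate
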