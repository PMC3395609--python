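"""Transfer function analysis (TFA) between pressure and flow velocity.

The classical Fourier comparator: Welch auto- and cross-spectra give
frequency-resolved coherence, gain and phase.  Phase and gain are only
interpretable where coherence is high enough for the underlying
linear-stationary assumption to hold; the conventional rule masks them at
coherence <= 0.5.  Sign convention matches the cycle-based analysis:
positive phase = flow leads pressure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io_preprocess import TimeSeries


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimation settings: 100 s Hann segments, 50% overlap,
    linear detrend — common practice in autoregulation TFA."""

    segment_s: float = 100.0
    overlap: float = 0.5
    window: str = "hann"
    detrend: str = "linear"


@dataclass(frozen=True)
class TFAResult:
    freqs: np.ndarray           # Hz, strictly increasing
    coherence: np.ndarray       # magnitude-squared, in [0, 1]
    gain: np.ndarray            # (cm/s)/mmHg
    phase: np.ndarray           # degrees; positive = flow leads pressure
    welch_config: WelchConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "coherence": self.coherence,
                "gain": self.gain,
                "phase_deg": self.phase,
            }
        )


def tfa_estimate(
    bp: TimeSeries, bfv: TimeSeries, welch_config: WelchConfig | None = None
) -> TFAResult:
    """Welch cross-spectral estimate of coherence, gain and phase."""
    cfg = welch_config or WelchConfig()
    if bp.rate != bfv.rate:
        raise ValueError("BP and BFV must share a sampling rate")
    if bp.n != bfv.n:
        raise ValueError("BP and BFV must have equal length")
    nper = int(round(cfg.segment_s * bp.rate))
    if bp.n < 2 * nper:
        raise ValueError("record must be at least 2 Welch segments long")
    nover = int(round(cfg.overlap * nper))
    kw = dict(
        fs=bp.rate, window=cfg.window, nperseg=nper, noverlap=nover,
        detrend=cfg.detrend,
    )
    f, pxx = sps.welch(bp.values, **kw)
    _, pyy = sps.welch(bfv.values, **kw)
    _, pxy = sps.csd(bp.values, bfv.values, **kw)

    keep = f > 0  # DC bin: detrended anyway, phase meaningless
    f, pxx, pyy, pxy = f[keep], pxx[keep], pyy[keep], pxy[keep]
    coherence = np.abs(pxy) ** 2 / (pxx * pyy)
    gain = np.abs(pxy) / pxx
    # scipy csd(x, y) = conj(X) * Y, so angle(pxy) is the phase of BFV
    # relative to BP: positive when flow leads.
    phase = np.degrees(np.angle(pxy))
    return TFAResult(f, coherence, gain, phase, cfg)


def mask_by_coherence(res: TFAResult, threshold: float = 0.5) -> TFAResult:
    """Flag phase and gain as missing where coherence <= threshold.

    Coherence itself is never masked.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    bad = res.coherence <= threshold
    return replace(
        res,
        gain=np.where(bad, np.nan, res.gain),
        phase=np.where(bad, np.nan, res.phase),
    )
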