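"""Empirical mode decomposition (EMD) by sifting, and its ensemble variant.

EMD adaptively splits a nonstationary signal into intrinsic mode functions
(IMFs): zero-mean oscillations whose extrema and zero-crossing counts differ
by at most one, each occupying a narrow, data-determined frequency band.
Sifting repeatedly subtracts the mean of the cubic-spline envelopes through
the local maxima and minima until the Cauchy-type criterion

    SD = sum((h_prev - h)^2) / sum(h_prev^2) < sd_threshold

is met (default 0.2, hard cap of 10 sifts per mode).  Boundaries are handled
by mirroring two extrema at each end before spline fitting.  Extraction
stops when the residual has fewer than two interior extrema or ``max_modes``
(default ``floor(log2 N) - 1``, the dyadic filter-bank capacity) is reached.

The ensemble variant (EEMD) averages mode k over decompositions of many
noise-perturbed copies of the signal, which suppresses mode mixing caused by
intermittent oscillations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .io_preprocess import TimeSeries


@dataclass(frozen=True)
class SiftConfig:
    """Stopping parameters for one sifting pass."""

    sd_threshold: float = 0.2
    max_sifts: int = 10


@dataclass(frozen=True)
class IMFSet:
    """Ordered intrinsic mode functions plus residual from one decomposition.

    ``modes[0]`` is the highest-frequency mode; the residual is the monotone
    (or single-extremum) trend.  ``sum(modes) + residual`` reconstructs the
    source exactly up to floating-point error.
    """

    modes: tuple[np.ndarray, ...]
    residual: np.ndarray
    source_rate: float

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for m in self.modes:
            out += m
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateau centres count once."""
    dx = np.diff(x)
    # collapse flat steps onto the sign of the previous non-zero step
    sign = np.sign(dx)
    nz = sign != 0
    if not nz.any():
        return np.array([], int), np.array([], int)
    # forward-fill zero signs
    idx = np.where(nz, np.arange(sign.size), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.clip(idx, 0, None)], 0)
    turn = np.diff(filled)
    maxima = np.flatnonzero(turn < 0) + 1
    minima = np.flatnonzero(turn > 0) + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through extrema, mirror-extended 2 per side."""
    t = idx.astype(float)
    v = x[idx]
    k = min(2, idx.size)
    left_t = 2 * 0.0 - t[1 : k + 1][::-1] if idx.size > 1 else 2 * 0.0 - t[:1] - 1
    left_v = v[1 : k + 1][::-1] if idx.size > 1 else v[:1]
    right_t = 2 * (n - 1) - t[-k - 1 : -1][::-1] if idx.size > 1 else 2.0 * (n - 1) - t[-1:] + 1
    right_v = v[-k - 1 : -1][::-1] if idx.size > 1 else v[-1:]
    tt = np.concatenate([np.atleast_1d(left_t), t, np.atleast_1d(right_t)])
    vv = np.concatenate([np.atleast_1d(left_v), v, np.atleast_1d(right_v)])
    order = np.argsort(tt)
    tt, vv = tt[order], vv[order]
    keep = np.concatenate([[True], np.diff(tt) > 0])
    tt, vv = tt[keep], vv[keep]
    if tt.size < 2:
        return np.full(n, vv[0])
    if tt.size < 4:
        return np.interp(np.arange(n), tt, vv)
    return CubicSpline(tt, vv, bc_type="natural")(np.arange(n))


def _sift_one_mode(x: np.ndarray, cfg: SiftConfig) -> np.ndarray | None:
    """Extract one IMF from ``x`` or return None if no oscillation remains."""
    h = x.copy()
    for _ in range(cfg.max_sifts):
        maxima, minima = _local_extrema(h)
        if maxima.size + minima.size < 2 or maxima.size < 1 or minima.size < 1:
            return None if h is x else h
        upper = _mirrored_envelope(h, maxima, h.size)
        lower = _mirrored_envelope(h, minima, h.size)
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        denom = float(np.sum(h**2))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < cfg.sd_threshold:
            break
    return h


def default_max_modes(n: int) -> int:
    return max(1, int(np.floor(np.log2(n))) - 1)


def emd_decompose(
    ts: TimeSeries,
    max_modes: int | None = None,
    sift_config: SiftConfig | None = None,
) -> IMFSet:
    """Decompose a signal into IMFs by sifting.

    A constant (or monotone) input yields zero modes with the input as
    residual.  Raises ``ValueError`` for records shorter than 10 samples or
    containing non-finite values.
    """
    x = np.asarray(ts.values, dtype=float)
    if x.size < 10:
        raise ValueError("record too short for decomposition (< 10 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    cfg = sift_config or SiftConfig()
    cap = max_modes if max_modes is not None else default_max_modes(x.size)

    modes: list[np.ndarray] = []
    residual = x.copy()
    # stop once the residual is numerical dust relative to the source;
    # sifting float noise would fabricate meaningless "modes"
    floor = 1e-10 * np.ptp(x)
    while len(modes) < cap:
        if np.ptp(residual) <= floor:
            break
        maxima, minima = _local_extrema(residual)
        if maxima.size + minima.size < 2:
            break
        imf = _sift_one_mode(residual, cfg)
        if imf is None:
            break
        modes.append(imf)
        residual = residual - imf
    return IMFSet(tuple(modes), residual, ts.rate)


def eemd_decompose(
    ts: TimeSeries,
    ensemble_size: int = 100,
    noise_sd: float = 0.2,
    seed: int = 0,
    max_modes: int | None = None,
    sift_config: SiftConfig | None = None,
) -> IMFSet:
    """Ensemble EMD: average modes over noise-perturbed decompositions.

    ``noise_sd`` is the added white-noise standard deviation as a fraction
    of the signal's SD.  ``ensemble_size=1`` with ``noise_sd=0`` reduces
    exactly to :func:`emd_decompose`.  Fully seeded and reproducible.
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if ensemble_size == 1 and noise_sd == 0:
        return emd_decompose(ts, max_modes=max_modes, sift_config=sift_config)

    x = np.asarray(ts.values, dtype=float)
    sigma = noise_sd * float(np.std(x))
    cap = max_modes if max_modes is not None else default_max_modes(x.size)
    rng = np.random.default_rng(seed)

    acc = np.zeros((cap, x.size))
    counts = np.zeros(cap)
    resid_acc = np.zeros(x.size)
    for _ in range(ensemble_size):
        noisy = TimeSeries(
            x + rng.normal(0.0, sigma, x.size) if sigma > 0 else x.copy(),
            rate=ts.rate,
        )
        dec = emd_decompose(noisy, max_modes=cap, sift_config=sift_config)
        for k, m in enumerate(dec.modes):
            acc[k] += m
            counts[k] += 1
        resid_acc += dec.residual

    keep = counts > 0
    modes = tuple(acc[k] / counts[k] for k in range(cap) if keep[k])
    # residual defined so that completeness holds for the averaged set
    residual = x - np.sum(modes, axis=0) if modes else x.copy()
    return IMFSet(modes, residual, ts.rate)


def mode_mean_frequency(mode: np.ndarray, rate: float) -> float:
    """Median instantaneous frequency of a mode, in Hz.

    A robust scale label used for pairing BP and BFV modes.  Raises for a
    constant mode, whose frequency is undefined.
    """
    mode = np.asarray(mode, dtype=float)
    if np.ptp(mode) == 0:
        raise ValueError("constant mode has undefined frequency")
    from .phase_cycles import hilbert_phase

    ps = hilbert_phase(mode - np.mean(mode), rate)
    # interior samples only: Hilbert edge effects distort the ends
    k = max(1, mode.size // 10)
    inner = ps.inst_freq[k:-k]
    return float(np.median(inner))


def check_imf_property(mode: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most 1 (interior)."""
    maxima, minima = _local_extrema(mode)
    ext = maxima.size + minima.size
    if ext < 2:
        return False
    lo, hi = min(maxima[0], minima[0]), max(maxima[-1], minima[-1])
    seg = mode[lo : hi + 1]
    zc = int(np.sum(np.abs(np.diff(np.signbit(seg)))))
    ext_in = int(np.sum((maxima >= lo) & (maxima <= hi))
                 + np.sum((minima >= lo) & (minima <= hi)))
    return abs(ext_in - zc) <= 2  # 1 boundary oscillation slack each side


def save_imfset(imfs: IMFSet, csv_path, sidecar_path=None) -> None:
    """Serialize as multi-column CSV plus a JSON sidecar for metadata."""
    cols = {f"mode_{k}": m for k, m in enumerate(imfs.modes)}
    cols["residual"] = imfs.residual
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {"source_rate": imfs.source_rate, "n_modes": imfs.n_modes}, fh
            )
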