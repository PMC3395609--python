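"""Reading, validation and resampling of two-channel hemodynamic recordings.

Raw beat-to-beat blood pressure (BP, mmHg) and transcranial-Doppler blood
flow velocity (BFV, cm/s) arrive as delimited text.  Everything downstream
operates on :class:`TimeSeries`: a uniformly sampled channel with an explicit
rate.  Recordings acquired at 500 Hz are decimated to the 50 Hz analysis
rate with a zero-phase anti-alias filter so the resampling itself cannot
bias the phase quantities being measured.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

# Gaps of non-finite samples longer than this are considered unrepairable.
MAX_GAP_S = 0.5


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled signal channel.

    Parameters
    ----------
    values
        Sample values, finite floats (use :func:`repair_nonfinite` first if
        the raw channel contains NaNs).
    rate
        Sampling frequency in Hz, > 0.
    label
        Channel name, e.g. ``"bp"`` or ``"bfv"``.
    units
        Physical units, e.g. ``"mmHg"`` or ``"cm/s"``.
    """

    values: np.ndarray
    rate: float
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("TimeSeries needs a 1-D array of >= 2 samples")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (n samples at 1/rate spacing)."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.rate

    def validate(self) -> dict:
        """Report non-finite samples without modifying the series."""
        bad = np.flatnonzero(~np.isfinite(self.values))
        return {"n_nonfinite": int(bad.size), "nonfinite_indices": bad}


def repair_nonfinite(ts: TimeSeries, max_gap_s: float = MAX_GAP_S) -> TimeSeries:
    """Linearly interpolate across short runs of non-finite samples.

    Gaps longer than ``max_gap_s`` abort with :class:`ValueError`: the
    downstream cycle-exclusion criteria are designed to reject corrupted
    cycles, not to analyse invented data.
    """
    v = np.asarray(ts.values, dtype=float)
    bad = ~np.isfinite(v)
    if not bad.any():
        return ts
    if bad.all():
        raise ValueError("all samples are non-finite")
    # longest run of consecutive bad samples
    edges = np.diff(np.concatenate(([0], bad.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    longest = int((ends - starts).max())
    if longest / ts.rate > max_gap_s:
        raise ValueError(
            f"non-finite gap of {longest / ts.rate:.2f} s exceeds "
            f"{max_gap_s} s; refusing to interpolate"
        )
    idx = np.arange(v.size)
    v = v.copy()
    v[bad] = np.interp(idx[bad], idx[~bad], v[~bad])
    logger.warning(
        "interpolated %d non-finite samples in %r", int(bad.sum()), ts.label
    )
    return replace(ts, values=v)


def load_timeseries(
    path,
    column,
    rate: float | None = None,
    time_column: str | int | None = None,
    label: str | None = None,
    units: str = "",
) -> tuple[TimeSeries, dict]:
    """Load one channel from a delimited-text file.

    Either ``rate`` (Hz) or ``time_column`` must be given.  With a time
    column, uniform spacing is verified to 1e-6 relative tolerance and the
    rate is derived from the median spacing.

    Returns the series plus a validation report listing non-finite samples
    (the series itself is returned unrepaired; see :func:`repair_nonfinite`).
    """
    # sniff the delimiter from the first line; csv.Sniffer misbehaves on
    # single-column files
    with open(path) as fh:
        first = fh.readline()
    sep = next((s for s in ("\t", ";", ",") if s in first), ",")
    df = pd.read_csv(path, sep=sep)
    if isinstance(column, int):
        if column >= df.shape[1]:
            raise ValueError(f"column index {column} out of range")
        col = df.iloc[:, column]
        colname = str(df.columns[column])
    else:
        if column not in df.columns:
            raise ValueError(
                f"column {column!r} not in file (have {list(df.columns)})"
            )
        col = df[column]
        colname = column

    if time_column is not None:
        t = (
            df.iloc[:, time_column]
            if isinstance(time_column, int)
            else df[time_column]
        ).to_numpy(dtype=float)
        if t.size < 2:
            raise ValueError("need at least 2 samples")
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0:
            raise ValueError("time axis is not increasing")
        if np.any(np.abs(dt - med) > 1e-6 * max(abs(med), 1.0) + 1e-12):
            raise ValueError("time axis is not uniform within tolerance")
        rate = 1.0 / med
    elif rate is None:
        raise ValueError("either rate or time_column is required")

    values = col.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples")
    ts = TimeSeries(
        values,
        rate=float(rate),
        label=label if label is not None else colname,
        units=units,
    )
    return ts, ts.validate()


def save_timeseries(ts: TimeSeries, path) -> None:
    """Write a two-column (time, value) CSV for interchange."""
    pd.DataFrame({"time_s": ts.times, ts.label or "value": ts.values}).to_csv(
        path, index=False
    )


def resample_decimate(ts: TimeSeries, target_rate: float) -> TimeSeries:
    """Anti-alias low-pass filter and decimate to ``target_rate``.

    The low-pass is zero-phase (forward-backward Butterworth at
    0.4 x target_rate) so the filter contributes no phase shift in the
    passband.  Integer decimation when the rate ratio is integral,
    polyphase rational resampling otherwise.  No upsampling.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > ts.rate:
        raise ValueError("upsampling is not supported")
    if math.isclose(target_rate, ts.rate):
        return ts

    ratio = ts.rate / target_rate
    sos = sps.butter(8, 0.4 * target_rate, btype="low", fs=ts.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, ts.values)
    if math.isclose(ratio, round(ratio), rel_tol=1e-9):
        out = filtered[:: int(round(ratio))]
    else:
        from fractions import Fraction

        f = Fraction(target_rate / ts.rate).limit_denominator(1000)
        out = sps.resample_poly(filtered, f.numerator, f.denominator)
    return TimeSeries(out, rate=target_rate, label=ts.label, units=ts.units)
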