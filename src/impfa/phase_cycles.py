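"""Instantaneous phase, cycle segmentation, mode pairing and cycle filtering.

Each intrinsic mode is assigned an instantaneous phase via the Hilbert
transform (analytic-signal angle, unwrapped, in degrees).  The phase is cut
into cycles of exactly 360 deg; BP modes are paired with the BFV mode of
nearest median frequency; and each BP cycle is matched with the maximally
overlapping BFV cycle.  Matched pairs that are plausibly contaminated by
noise or artifacts are excluded by three criteria:

1. the instantaneous phase decreases anywhere within either cycle;
2. more than 0.2 s of samples in either cycle have instantaneous frequency
   at least 2.5x that cycle's mean frequency;
3. the BFV cycle lasts >= 1.5x, or <= 1/1.5x, the matched BP cycle.

For retained pairs the phase shift is the mean over the BP cycle's samples
of the BFV-minus-BP instantaneous phase difference, each difference wrapped
to (-180, 180] first.  Positive shift = flow leads pressure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .emd import IMFSet, mode_mean_frequency

logger = logging.getLogger(__name__)

# Phase decreases smaller than this (deg per sample) are numerical jitter,
# not artifact signatures, and do not trigger Criterion 1.
PHASE_DECREASE_TOL_DEG = 0.01


@dataclass(frozen=True)
class PhaseSeries:
    """Unwrapped instantaneous phase (degrees) and frequency (Hz)."""

    phase: np.ndarray
    inst_freq: np.ndarray
    rate: float


@dataclass(frozen=True)
class Cycle:
    """One 360-degree phase increment of one mode; [start, end) samples."""

    mode_index: int
    start: int
    end: int
    phase_at_start: float
    mean_freq: float

    @property
    def duration_samples(self) -> int:
        return self.end - self.start


class ExclusionReason(str, Enum):
    NONE = "none"
    CRITERION1 = "criterion1"
    CRITERION2 = "criterion2"
    CRITERION3 = "criterion3"


@dataclass
class MatchedCyclePair:
    """A BP cycle matched to a BFV cycle, with exclusion bookkeeping."""

    bp_cycle: Cycle
    bfv_cycle: Cycle
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    phase_shift: float | None = None  # degrees, BFV minus BP
    freq: float | None = None  # binning frequency, Hz

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason is not ExclusionReason.NONE


def wrap_degrees(x):
    """Wrap angle(s) in degrees to (-180, 180]."""
    return -((-np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0)


def hilbert_phase(mode: np.ndarray, rate: float) -> PhaseSeries:
    """Analytic-signal phase of a zero-mean narrowband mode.

    Phase is unwrapped and converted to degrees; instantaneous frequency is
    the centred finite difference of phase / 360.
    """
    mode = np.asarray(mode, dtype=float)
    if not np.any(mode):
        raise ValueError("all-zero mode has undefined phase")
    analytic = hilbert(mode)
    phase = np.degrees(np.unwrap(np.angle(analytic)))
    inst_freq = np.gradient(phase) * rate / 360.0
    return PhaseSeries(phase=phase, inst_freq=inst_freq, rate=rate)


def segment_cycles(ps: PhaseSeries, mode_index: int = 0) -> list[Cycle]:
    """Cut a phase series into complete 360-degree cycles.

    Boundaries sit at successive upward crossings of ``phase[0]`` rounded up
    to the next multiple of 360, then every +360.  Partial leading and
    trailing segments are discarded.  A record shorter than one cycle (or a
    non-increasing phase) yields an empty list.
    """
    phase = ps.phase
    first = 360.0 * np.ceil(phase[0] / 360.0)
    if np.isclose(first, phase[0]):
        first += 360.0
    # monotone envelope makes the first-crossing search well defined even
    # when the raw phase briefly decreases (criterion 1 handles those later)
    env = np.maximum.accumulate(phase)
    top = env[-1]
    thresholds = np.arange(first, top + 1e-9, 360.0)
    if thresholds.size < 2:
        return []
    idx = np.searchsorted(env, thresholds, side="left")
    cycles = []
    for k in range(thresholds.size - 1):
        s, e = int(idx[k]), int(idx[k + 1])
        if e <= s:
            continue
        dur = (e - s) / ps.rate
        cycles.append(
            Cycle(
                mode_index=mode_index,
                start=s,
                end=e,
                phase_at_start=float(thresholds[k]),
                mean_freq=1.0 / dur,
            )
        )
    return cycles


def pair_modes(
    bp: IMFSet, bfv: IMFSet, max_ratio: float = 1.5
) -> list[tuple[int, int]]:
    """Pair each BP mode with the BFV mode of nearest median frequency.

    Greedy one-to-one matching by smallest absolute log-frequency distance;
    a candidate pair is accepted only if the frequency ratio lies within
    [1/max_ratio, max_ratio].  Modes with no admissible partner are dropped.
    """
    if bp.n_modes == 0 or bfv.n_modes == 0:
        raise ValueError("both decompositions must contain at least one mode")

    def freqs(s: IMFSet) -> list[float | None]:
        out = []
        for m in s.modes:
            try:
                out.append(mode_mean_frequency(m, s.source_rate))
            except ValueError:
                out.append(None)
        return out

    f_bp, f_bfv = freqs(bp), freqs(bfv)
    cands = []
    for i, fi in enumerate(f_bp):
        if fi is None or fi <= 0:
            continue
        for j, fj in enumerate(f_bfv):
            if fj is None or fj <= 0:
                continue
            ratio = fi / fj
            if 1.0 / max_ratio <= ratio <= max_ratio:
                cands.append((abs(np.log(ratio)), i, j))
    cands.sort()
    used_bp: set[int] = set()
    used_bfv: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_bp or j in used_bfv:
            continue
        pairs.append((i, j))
        used_bp.add(i)
        used_bfv.add(j)
    pairs.sort()
    unmatched = set(range(bp.n_modes)) - used_bp
    for i in sorted(unmatched):
        logger.info("BP mode %d has no BFV partner within ratio bound", i)
    return pairs


def _has_phase_decrease(ps: PhaseSeries, c: Cycle) -> bool:
    d = np.diff(ps.phase[c.start : c.end])
    return bool(np.any(d < -PHASE_DECREASE_TOL_DEG))


def _fast_duration_s(ps: PhaseSeries, c: Cycle, factor: float) -> float:
    f = ps.inst_freq[c.start : c.end]
    return float(np.sum(f >= factor * c.mean_freq)) / ps.rate


def _overlap(a: Cycle, b: Cycle) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_and_filter(
    bp_cycles: list[Cycle],
    bp_ps: PhaseSeries,
    bfv_cycles: list[Cycle],
    bfv_ps: PhaseSeries,
    fast_freq_factor: float = 2.5,
    fast_max_s: float = 0.2,
    length_ratio: float = 1.5,
) -> list[MatchedCyclePair]:
    """Match each BP cycle with the maximally overlapping BFV cycle and
    apply the three exclusion criteria.

    BP cycles with no temporally overlapping BFV cycle are dropped.  Ties in
    overlap are broken toward the BFV cycle whose centre is nearest the BP
    cycle centre.  Criteria 1 and 2 are evaluated on both members of a pair.
    """
    if not bfv_cycles:
        return []
    out: list[MatchedCyclePair] = []
    for bc in bp_cycles:
        best = None
        best_key = None
        bc_centre = 0.5 * (bc.start + bc.end)
        for vc in bfv_cycles:
            ov = _overlap(bc, vc)
            if ov <= 0:
                continue
            key = (-ov, abs(0.5 * (vc.start + vc.end) - bc_centre))
            if best_key is None or key < best_key:
                best, best_key = vc, key
        if best is None:
            continue
        pair = MatchedCyclePair(bp_cycle=bc, bfv_cycle=best)
        if _has_phase_decrease(bp_ps, bc) or _has_phase_decrease(bfv_ps, best):
            pair.exclusion_reason = ExclusionReason.CRITERION1
        elif (
            _fast_duration_s(bp_ps, bc, fast_freq_factor) > fast_max_s
            or _fast_duration_s(bfv_ps, best, fast_freq_factor) > fast_max_s
        ):
            pair.exclusion_reason = ExclusionReason.CRITERION2
        else:
            ratio = best.duration_samples / bc.duration_samples
            if ratio >= length_ratio or ratio <= 1.0 / length_ratio:
                pair.exclusion_reason = ExclusionReason.CRITERION3
        out.append(pair)
    return out


def cycle_phase_shift(
    pair: MatchedCyclePair, bp_ps: PhaseSeries, bfv_ps: PhaseSeries
) -> float:
    """Mean wrapped (BFV - BP) phase difference over the BP cycle's samples.

    The cycle extent is anchored on the BP cycle.  Stores the result and the
    binning frequency (1 / BP cycle duration) on the pair.  Calling this on
    an excluded pair is a contract violation.
    """
    if pair.excluded:
        raise ValueError("phase shift is undefined for an excluded pair")
    s, e = pair.bp_cycle.start, pair.bp_cycle.end
    diff = bfv_ps.phase[s:e] - bp_ps.phase[s:e]
    shift = float(np.mean(wrap_degrees(diff)))
    pair.phase_shift = shift
    pair.freq = pair.bp_cycle.mean_freq
    return shift


def pairs_to_frame(pairs: list[MatchedCyclePair], rate: float) -> pd.DataFrame:
    """Tidy export of matched pairs (retained and excluded)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "mode_index": p.bp_cycle.mode_index,
                "start_s": p.bp_cycle.start / rate,
                "end_s": p.bp_cycle.end / rate,
                "freq_hz": p.bp_cycle.mean_freq,
                "phase_shift_deg": p.phase_shift,
                "exclusion_reason": p.exclusion_reason.value,
            }
        )
    return pd.DataFrame(rows)
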