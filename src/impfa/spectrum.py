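"""Frequency-binned phase-shift spectra and group aggregation.

Retained cycle pairs from all mode couples are pooled and assigned to
non-overlapping frequency bins by their BP-cycle frequency.  The default
grid is 18 bins of 0.02 Hz covering [0.02, 0.38) Hz.  Per-recording spectra
are averaged across subjects with equal subject weighting: when a subject
contributes two sides (left/right insonation), the sides are averaged
within subject first, and the group standard error is computed between
subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emd import SiftConfig, emd_decompose, eemd_decompose
from .io_preprocess import TimeSeries
from .phase_cycles import (
    ExclusionReason,
    MatchedCyclePair,
    cycle_phase_shift,
    hilbert_phase,
    match_and_filter,
    pair_modes,
    segment_cycles,
)

logger = logging.getLogger(__name__)


def default_bin_edges(
    lo: float = 0.02, hi: float = 0.38, width: float = 0.02
) -> np.ndarray:
    """Half-open bin edges [lo, hi) in steps of width; default 18 bins."""
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


@dataclass(frozen=True)
class PhaseSpectrum:
    """Per-bin mean phase shift for one recording/side.

    ``mean_shift`` and ``sd_shift`` are NaN where ``n_cycles`` is zero.
    """

    bin_edges: np.ndarray
    mean_shift: np.ndarray
    sd_shift: np.ndarray
    n_cycles: np.ndarray
    subject_id: str = ""
    side: str = ""

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_hz": self.bin_edges[:-1],
                "bin_hi_hz": self.bin_edges[1:],
                "mean_shift_deg": self.mean_shift,
                "sd_deg": self.sd_shift,
                "n_cycles": self.n_cycles,
            }
        )


def bin_cycles(
    pairs: list[MatchedCyclePair],
    edges: np.ndarray | None = None,
    subject_id: str = "",
    side: str = "",
) -> PhaseSpectrum:
    """Pool retained pairs into half-open frequency bins.

    Excluded pairs are ignored; retained pairs whose frequency falls outside
    [edges[0], edges[-1]) are discarded with a logged count.
    """
    edges = default_bin_edges() if edges is None else np.asarray(edges, float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise ValueError("bin edges must be positive and strictly increasing")

    nb = edges.size - 1
    sums = np.zeros(nb)
    sq = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    out_of_range = 0
    for p in pairs:
        if p.excluded or p.phase_shift is None or p.freq is None:
            continue
        if not (edges[0] <= p.freq < edges[-1]):
            out_of_range += 1
            continue
        b = int(np.searchsorted(edges, p.freq, side="right") - 1)
        sums[b] += p.phase_shift
        sq[b] += p.phase_shift**2
        counts[b] += 1
    if out_of_range:
        logger.info("%d retained pairs outside the bin range", out_of_range)

    mean = np.full(nb, np.nan)
    sd = np.full(nb, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    two = counts > 1
    var = np.zeros(nb)
    var[two] = (sq[two] - counts[two] * mean[two] ** 2) / (counts[two] - 1)
    sd[two] = np.sqrt(np.maximum(var[two], 0.0))
    sd[counts == 1] = 0.0
    return PhaseSpectrum(edges, mean, sd, counts, subject_id, side)


@dataclass(frozen=True)
class GroupSpectrum:
    """Group summary: per-bin mean of subject means and between-subject SE."""

    bin_edges: np.ndarray
    mean_shift: np.ndarray
    se_shift: np.ndarray
    n_subjects: np.ndarray


def aggregate_group(spectra: list[PhaseSpectrum]) -> GroupSpectrum:
    """Average per-subject spectra with equal subject weighting.

    Sides belonging to the same ``subject_id`` are averaged within subject
    first.  A subject missing a bin is omitted from that bin; SE is the
    between-subject SD / sqrt(n) and is NaN where fewer than two subjects
    contribute.
    """
    if not spectra:
        raise ValueError("no spectra to aggregate")
    edges = spectra[0].bin_edges
    for s in spectra[1:]:
        if s.bin_edges.shape != edges.shape or not np.allclose(
            s.bin_edges, edges
        ):
            raise ValueError("spectra have mismatched bin edges")

    by_subject: dict[str, list[PhaseSpectrum]] = {}
    for k, s in enumerate(spectra):
        key = s.subject_id if s.subject_id else f"_anon{k}"
        by_subject.setdefault(key, []).append(s)

    import warnings

    rows = []
    with warnings.catch_warnings():
        # all-NaN bins are expected (subjects can miss bins entirely)
        warnings.simplefilter("ignore", RuntimeWarning)
        for sides in by_subject.values():
            stack = np.vstack([s.mean_shift for s in sides])
            rows.append(np.nanmean(stack, axis=0))
        mat = np.vstack(rows)
        n_sub = np.sum(np.isfinite(mat), axis=0)
        mean = np.where(n_sub > 0, np.nanmean(mat, axis=0), np.nan)
        sd = np.where(n_sub > 1, np.nanstd(mat, axis=0, ddof=1), np.nan)
    se = sd / np.sqrt(np.maximum(n_sub, 1))
    return GroupSpectrum(edges, mean, se, n_sub)


@dataclass(frozen=True)
class ImpfaConfig:
    """Knobs for the end-to-end pipeline."""

    bin_edges: np.ndarray = field(default_factory=default_bin_edges)
    emd_method: str = "plain"  # "plain" or "eemd"
    ensemble_size: int = 100
    noise_sd: float = 0.2
    seed: int = 0
    max_modes: int | None = None
    sift: SiftConfig = field(default_factory=SiftConfig)
    min_duration_s: float = 60.0


def impfa_run(
    bp: TimeSeries,
    bfv: TimeSeries,
    config: ImpfaConfig | None = None,
    subject_id: str = "",
    side: str = "",
) -> tuple[PhaseSpectrum, dict]:
    """Run the full pipeline on one BP/BFV recording pair.

    Decompose both channels, pair modes by frequency, compute Hilbert
    phases, segment cycles, match and filter them, average per-cycle phase
    shifts and bin by frequency.  Returns the spectrum and a QC report with
    retained/excluded cycle counts per criterion.
    """
    cfg = config or ImpfaConfig()
    if bp.rate != bfv.rate:
        raise ValueError("BP and BFV must share a sampling rate; resample first")
    if bp.n != bfv.n:
        raise ValueError("BP and BFV must have equal length")
    if bp.duration < cfg.min_duration_s:
        raise ValueError(
            f"record shorter than {cfg.min_duration_s} s: too few slow "
            "cycles for the lowest frequency bins"
        )

    if cfg.emd_method == "eemd":
        dec_bp = eemd_decompose(
            bp, cfg.ensemble_size, cfg.noise_sd, cfg.seed,
            max_modes=cfg.max_modes, sift_config=cfg.sift,
        )
        dec_bfv = eemd_decompose(
            bfv, cfg.ensemble_size, cfg.noise_sd, cfg.seed + 1,
            max_modes=cfg.max_modes, sift_config=cfg.sift,
        )
    else:
        dec_bp = emd_decompose(bp, max_modes=cfg.max_modes, sift_config=cfg.sift)
        dec_bfv = emd_decompose(bfv, max_modes=cfg.max_modes, sift_config=cfg.sift)

    mode_pairs = pair_modes(dec_bp, dec_bfv)
    all_pairs: list[MatchedCyclePair] = []
    for i, j in mode_pairs:
        bp_mode, bfv_mode = dec_bp.modes[i], dec_bfv.modes[j]
        if not np.any(bp_mode) or not np.any(bfv_mode):
            continue
        bp_ps = hilbert_phase(bp_mode, bp.rate)
        bfv_ps = hilbert_phase(bfv_mode, bfv.rate)
        bp_cycles = segment_cycles(bp_ps, mode_index=i)
        bfv_cycles = segment_cycles(bfv_ps, mode_index=j)
        pairs = match_and_filter(bp_cycles, bp_ps, bfv_cycles, bfv_ps)
        for p in pairs:
            if not p.excluded:
                cycle_phase_shift(p, bp_ps, bfv_ps)
        all_pairs.extend(pairs)

    spectrum = bin_cycles(all_pairs, cfg.bin_edges, subject_id, side)
    reasons = {r.value: 0 for r in ExclusionReason}
    for p in all_pairs:
        reasons[p.exclusion_reason.value] += 1
    qc = {
        "n_mode_pairs": len(mode_pairs),
        "n_cycle_pairs": len(all_pairs),
        "n_retained": reasons["none"],
        "n_excluded_criterion1": reasons["criterion1"],
        "n_excluded_criterion2": reasons["criterion2"],
        "n_excluded_criterion3": reasons["criterion3"],
        "retained_fraction": (
            reasons["none"] / len(all_pairs) if all_pairs else float("nan")
        ),
    }
    return spectrum, qc
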