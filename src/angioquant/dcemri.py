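"""Semi-quantitative DCE-MRI perfusion analysis.

Voxel-wise maps from dynamic contrast-enhanced series:

* ``S0`` — per-voxel baseline, the mean of all pre-injection frames;
* ``RSI_1min`` — relative signal intensity S(t)/S0 at the acquired frame
  nearest one minute post-injection (ties round up; no interpolation);
* ``AUC_1min`` — trapezoidal integral of the relative enhancement
  (S - S0)/S0 over post-injection frames within the first minute.

A voxel is *enhancing* iff RSI_1min >= 1.5 (boundary included); the
fraction of enhancing voxels (FEV) and the median AUC_1min over enhancing
voxels summarize each tumor at each imaging day.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .containers import DynamicSeries

__all__ = [
    "PerfusionMaps",
    "PerfusionSummary",
    "compute_enhancement_maps",
    "summarize_tumor",
    "longitudinal_delta",
]

log = logging.getLogger(__name__)

RSI_THRESHOLD = 1.5
AUC_WINDOW_S = 60.0


@dataclass
class PerfusionMaps:
    """Voxel-wise perfusion maps for one dynamic series."""

    rsi_1min: np.ndarray
    auc_1min: np.ndarray
    enhancing_mask: np.ndarray
    baseline_s0: np.ndarray
    roi: np.ndarray          # valid ROI after removing non-positive-S0 voxels
    rsi_frame: int           # absolute frame index used for RSI_1min


@dataclass
class PerfusionSummary:
    """Per-tumor perfusion summary at one imaging day."""

    median_auc: float        # NaN when no voxel enhances
    fev: float
    n_enhancing: int
    n_roi: int
    timepoint_day: int
    tumor_id: str = ""


def _rsi_frame_offset(frame_interval: float, window_s: float) -> int:
    """Post-injection frame index nearest ``window_s``; ties round up."""
    return int(math.floor(window_s / frame_interval + 0.5))


def compute_enhancement_maps(series: DynamicSeries,
                             rsi_threshold: float = RSI_THRESHOLD,
                             window_s: float = AUC_WINDOW_S) -> PerfusionMaps:
    """Compute S0, RSI_1min, AUC_1min maps and the enhancing mask.

    Requires at least two baseline frames and a post-injection tail
    covering the full window.  Voxels with non-positive baseline are
    flagged invalid and removed from the ROI.  The AUC integrates over
    acquired frames only, from the injection frame to the last frame
    within the window (57.6 s for a 4.8 s grid); no extrapolation to the
    exact window end is performed.
    """
    inj = series.injection_frame
    if inj < 2:
        raise ValueError("need >= 2 baseline frames before injection")
    dt = series.frame_interval
    offset = _rsi_frame_offset(dt, window_s)
    rsi_frame = inj + offset
    if rsi_frame >= series.n_frames:
        raise ValueError(
            f"series too short: frame {rsi_frame} needed for the "
            f"{window_s:g}-s window but only {series.n_frames} acquired")

    s0 = series.signal[..., :inj].mean(axis=3)
    valid = s0 > 0
    roi = series.roi & valid
    n_invalid = int((series.roi & ~valid).sum())
    if n_invalid:
        log.warning("%d ROI voxels with non-positive baseline excluded",
                    n_invalid)

    safe_s0 = np.where(valid, s0, 1.0)
    rsi_1min = np.where(valid, series.signal[..., rsi_frame] / safe_s0, 0.0)

    # trapezoid over acquired frames inside [injection, injection + window]
    n_within = int(math.floor(window_s / dt))  # intervals fully inside window
    stop = min(inj + n_within, series.n_frames - 1)
    rel = (series.signal[..., inj:stop + 1]
           - s0[..., None]) / safe_s0[..., None]
    auc = np.trapezoid(rel, dx=dt, axis=3)
    auc = np.where(valid, auc, 0.0)

    enhancing = roi & (rsi_1min >= rsi_threshold)
    return PerfusionMaps(rsi_1min, auc, enhancing, s0, roi, rsi_frame)


def summarize_tumor(maps: PerfusionMaps, day: int,
                    tumor_id: str = "",
                    median_over: str = "enhancing") -> PerfusionSummary:
    """Summarize one tumor: FEV and median AUC_1min.

    ``median_over`` selects the voxel population for the median AUC:
    ``"enhancing"`` (default, perfused viable tumor only) or ``"roi"``.
    """
    n_roi = int(maps.roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    n_enh = int(maps.enhancing_mask.sum())
    fev = n_enh / n_roi
    if median_over == "enhancing":
        pool = maps.auc_1min[maps.enhancing_mask]
    elif median_over == "roi":
        pool = maps.auc_1min[maps.roi]
    else:
        raise ValueError("median_over must be 'enhancing' or 'roi'")
    median_auc = float(np.median(pool)) if pool.size else float("nan")
    if pool.size == 0:
        log.info("tumor %s day %d: no enhancing voxels; median AUC undefined",
                 tumor_id, day)
    return PerfusionSummary(median_auc, fev, n_enh, n_roi, day, tumor_id)


def longitudinal_delta(summaries: list[PerfusionSummary]) -> list[dict]:
    """Changes in median AUC and FEV between consecutive imaging days.

    ``summaries`` holds one entry per imaging day for a single tumor;
    entries are sorted by day and deltas computed for each consecutive
    pair.  Intervals with a missing (NaN) median are skipped with a log
    entry; FEV deltas are always defined.
    """
    if len(summaries) < 2:
        raise ValueError("need summaries from at least two timepoints")
    ordered = sorted(summaries, key=lambda s: s.timepoint_day)
    deltas = []
    for prev, cur in zip(ordered, ordered[1:]):
        entry = {
            "tumor_id": cur.tumor_id,
            "day_from": prev.timepoint_day,
            "day_to": cur.timepoint_day,
            "delta_fev": cur.fev - prev.fev,
            "delta_median_auc": cur.median_auc - prev.median_auc,
        }
        if math.isnan(entry["delta_median_auc"]):
            log.warning("tumor %s: median AUC missing in interval %d->%d",
                        cur.tumor_id, prev.timepoint_day, cur.timepoint_day)
        deltas.append(entry)
    return deltas
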