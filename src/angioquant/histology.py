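"""Double-stain histology quantification.

Quantifies two readouts from RGB fields of lectin double-stained tumor
sections:

* **Proliferating endothelial cells (PECs)** — Ki67-positive nuclei whose
  centroid lies within a lectin-positive vessel, normalized to the
  lectin-positive vessel area (count per mm² of vessel);
* **Vessel immaturity** — the fraction of lectin-positive vessel area
  belonging to vessels at least 5 μm away from the nearest α-SMA-positive
  (pericyte) pixel.

Stains are segmented in HSV space by fixed hue/saturation bands applied
identically to every field of a study; overlapping nuclei are split by
marker-based watershed on the interior distance transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .containers import StainField

__all__ = [
    "StainMasks",
    "PECResult",
    "MaturityResult",
    "DEFAULT_BANDS",
    "segment_stains",
    "separate_nuclei",
    "pec_density",
    "pool_pec_results",
    "immature_vessel_fraction",
]

log = logging.getLogger(__name__)

#: (hue_lo, hue_hi, sat_lo, sat_hi); hue normalized to [0, 1].
DEFAULT_BANDS: dict[str, tuple[float, float, float, float]] = {
    "lectin": (0.52, 0.72, 0.25, 1.0),   # blue endothelium
    "ki67": (0.03, 0.13, 0.30, 1.0),     # brown proliferating nuclei
    "sma": (0.86, 0.98, 0.30, 1.0),      # red-brown pericytes
}

DEFAULT_NUCLEUS_DIAMETER_UM = 8.0


@dataclass
class StainMasks:
    """Per-stain binary masks plus the threshold record used to make them."""

    lectin_mask: np.ndarray
    ki67_mask: np.ndarray
    sma_mask: np.ndarray
    thresholds_used: dict = field(default_factory=dict)


@dataclass
class PECResult:
    """Proliferating-endothelial-cell count normalized to vessel area."""

    n_pec: int
    vessel_area_mm2: float
    pec_density: float        # per mm² of vessel; NaN when area is zero
    n_ki67_total: int


@dataclass
class MaturityResult:
    """Vessel-immaturity readout (lectin+ / α-SMA- area fraction)."""

    immature_area_px: int
    total_lectin_area_px: int
    immature_fraction: float  # NaN when no lectin-positive area exists


def _check_band(name: str, band) -> tuple[float, float, float, float]:
    h_lo, h_hi, s_lo, s_hi = band
    for v in band:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} band value {v} outside [0, 1]")
    if h_lo >= h_hi or s_lo >= s_hi:
        raise ValueError(f"{name} band bounds must be increasing")
    return float(h_lo), float(h_hi), float(s_lo), float(s_hi)


def segment_stains(fld: StainField,
                   bands: dict | None = None) -> StainMasks:
    """Classify pixels into stains by fixed hue/saturation bands.

    The same band set must be applied to every field of a study; the
    bands actually used are recorded in ``thresholds_used`` so a study
    run can assert that invariant in its provenance log.
    """
    bands = dict(DEFAULT_BANDS if bands is None else bands)
    hsv = rgb2hsv(fld.rgb)
    hue, sat = hsv[..., 0], hsv[..., 1]
    masks = {}
    for name in ("lectin", "ki67", "sma"):
        h_lo, h_hi, s_lo, s_hi = _check_band(name, bands[name])
        masks[name] = ((hue >= h_lo) & (hue <= h_hi)
                       & (sat >= s_lo) & (sat <= s_hi))
    return StainMasks(masks["lectin"], masks["ki67"], masks["sma"],
                      thresholds_used={k: tuple(v) for k, v in bands.items()})


def separate_nuclei(ki67_mask: np.ndarray,
                    nucleus_diameter_px: float = 16.0) -> np.ndarray:
    """Split touching nuclei by marker-based watershed; returns labels.

    Markers are local maxima of the interior Euclidean distance
    transform with a minimum separation of half the expected nucleus
    diameter; the watershed floods the negated distance transform within
    the mask.  The number of labels is the nucleus count.
    """
    mask = np.asarray(ki67_mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    min_sep = max(1, int(round(0.5 * nucleus_diameter_px)))
    peaks = peak_local_max(dist, min_distance=min_sep, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # degenerate blob with no interior maximum
        labels, _ = ndimage.label(mask)
        return labels.astype(np.int32)
    return watershed(-dist, markers, mask=mask).astype(np.int32)


def pec_density(labels: np.ndarray, masks: StainMasks, um_per_px: float,
                rule: str = "centroid") -> PECResult:
    """Count PECs (Ki67+ nuclei within a lectin+ vessel) per mm² of vessel.

    A nucleus belongs to a vessel when its centroid falls inside the
    hole-filled lectin mask (``rule="centroid"``; hole filling restores
    vessel lumen pixels occluded by the overlying nucleus stain) or,
    alternatively, when at least half of its pixels do
    (``rule="overlap"``).  Vessel area is the raw lectin-positive pixel
    count scaled to mm².
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    vessel_region = ndimage.binary_fill_holes(masks.lectin_mask)
    props = regionprops(labels)
    n_total = len(props)
    n_pec = 0
    for p in props:
        if rule == "centroid":
            r, c = (int(round(x)) for x in p.centroid)
            r = min(max(r, 0), vessel_region.shape[0] - 1)
            c = min(max(c, 0), vessel_region.shape[1] - 1)
            inside = bool(vessel_region[r, c])
        elif rule == "overlap":
            rr, cc = p.coords[:, 0], p.coords[:, 1]
            inside = vessel_region[rr, cc].mean() >= 0.5
        else:
            raise ValueError("rule must be 'centroid' or 'overlap'")
        n_pec += inside
    area_mm2 = float(masks.lectin_mask.sum()) * (um_per_px / 1000.0) ** 2
    if area_mm2 == 0:
        log.warning("zero vessel area: PEC density undefined")
        density = float("nan")
    else:
        density = n_pec / area_mm2
    return PECResult(n_pec, area_mm2, density, n_total)


def pool_pec_results(results: list[PECResult]) -> PECResult:
    """Aggregate per-field PEC results to a per-tumor readout.

    Counts and vessel areas are summed *before* dividing, so the pooled
    density is invariant to how fields were partitioned.
    """
    if not results:
        raise ValueError("no field results to pool")
    n_pec = sum(r.n_pec for r in results)
    n_total = sum(r.n_ki67_total for r in results)
    area = sum(r.vessel_area_mm2 for r in results)
    density = n_pec / area if area > 0 else float("nan")
    return PECResult(n_pec, area, density, n_total)


def immature_vessel_fraction(masks: StainMasks, um_per_px: float,
                             min_dist_um: float = 5.0) -> MaturityResult:
    """Area fraction of lectin+ vessels lacking nearby α-SMA (pericytes).

    Each connected lectin component is immature when its minimum
    Euclidean distance to any α-SMA-positive pixel is at least
    ``min_dist_um`` (inclusive).  The fraction is the summed immature
    component area over the total lectin-positive area.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    lectin = np.asarray(masks.lectin_mask, dtype=bool)
    total = int(lectin.sum())
    if total == 0:
        log.warning("empty lectin mask: immature fraction undefined")
        return MaturityResult(0, 0, float("nan"))
    if not np.asarray(masks.sma_mask, dtype=bool).any():
        return MaturityResult(total, total, 1.0)
    dist_um = ndimage.distance_transform_edt(~masks.sma_mask) * um_per_px
    labels, n = ndimage.label(lectin)
    immature_px = 0
    for i in range(1, n + 1):
        comp = labels == i
        if float(dist_um[comp].min()) >= min_dist_um:
            immature_px += int(comp.sum())
    return MaturityResult(immature_px, total, immature_px / total)
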