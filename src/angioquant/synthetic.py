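"""Synthetic phantom generators with exact ground truth.

Every downstream stage of the pipeline has a generator here that emulates
its input data with *known* ground truth: tubular vascular phantoms for
micro-CT morphometry, enhancement time-courses for DCE-MRI, double-stained
RGB fields for histology, and two-class Lorentzian spectra for the
chemometric analysis.  A two-group study generator composes them into a
full control-vs-treated cohort with designed multiplicative effects.

All generators are pure functions of their arguments including the seed:
the same call produces a bit-identical phantom.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import disk

from .containers import DynamicSeries, SpectrumSet, StainField, VolumeImage
from .histology import DEFAULT_BANDS

__all__ = [
    "PhantomGroundTruth",
    "StudyDesign",
    "StudyBundle",
    "generate_vascular_phantom",
    "rasterize_tube",
    "generate_dce_series",
    "generate_histology_field",
    "generate_spectra_cohort",
    "generate_two_group_study",
]


@dataclass
class PhantomGroundTruth:
    """Exact ground truth recorded at generation time."""

    seed: int
    true_fbv: float = 0.0
    vessel_radii: list = field(default_factory=list)      # μm, per segment
    true_fev: float = 0.0
    nucleus_count_in_vessel: int = 0
    nucleus_count_total: int = 0
    vessel_area_px: int = 0
    immature_area_px: int = 0
    class_effects: dict = field(default_factory=dict)
    vessel_mask: np.ndarray | None = field(default=None, repr=False)
    enhancing_mask: np.ndarray | None = field(default=None, repr=False)
    immature_fraction: float = float("nan")

    def __post_init__(self) -> None:
        for frac in (self.true_fbv, self.true_fev):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("ground-truth fractions must be in [0, 1]")
        for count in (self.nucleus_count_in_vessel, self.nucleus_count_total,
                      self.vessel_area_px, self.immature_area_px):
            if count < 0:
                raise ValueError("ground-truth counts must be non-negative")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d.pop("vessel_mask")
        d.pop("enhancing_mask")
        return d


@dataclass
class StudyDesign:
    """Design of a two-arm synthetic study.

    Group sizes and imaging days default to the imaging-cohort layout
    (8 control vs 9 treated, MRI on days 0, 4 and 7); effect sizes are
    multiplicative treated/control ratios and default to the direction
    and approximate magnitude of a vascular-targeting response: lower
    fractional blood volume, fewer immature (pericyte-free) vessels,
    lower endothelial proliferation, and a perfusion drop between the
    day-4 and day-7 scans.
    """

    n_control: int = 8
    n_treated: int = 9
    timepoints: tuple = (0, 4, 7)
    effect_sizes: dict = field(default_factory=lambda: {
        "fbv": 0.73,               # vessel-volume fraction ratio
        "immature_fraction": 0.71,  # pericyte-free vessel area ratio
        "pec_density": 0.85,       # proliferating endothelial cells
        "delta_auc_day7": 0.6,     # day-7 enhancement amplitude ratio
        "fev_day7": 0.8,           # day-7 enhancing-fraction ratio
        "PCho": 1.5,               # treated phosphocholine shift
        "GPC": 0.6,                # treated glycerophosphocholine shift
    })
    noise_levels: dict = field(default_factory=lambda: {
        "microct": 10.0,           # additive signal units
        "dce": 0.01,               # fraction of baseline
        "spectra": 0.01,           # fraction of largest peak
    })
    # desk-scale phantom geometry
    microct_shape: tuple = (48, 48, 48)
    microct_n_segments: int = 18
    microct_radius_range_um: tuple = (18.0, 36.0)
    dce_shape: tuple = (16, 16, 4)
    dce_enhancing_fraction: float = 0.5
    histology_size_px: tuple = (384, 384)
    histology_um_per_px: float = 1.0
    n_spectra_per_class: int = 6

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_treated < 1:
            raise ValueError("need at least one tumor per group")
        if any(e <= 0 for e in self.effect_sizes.values()):
            raise ValueError("effect sizes must be positive")


# ---------------------------------------------------------------------------
# micro-CT vascular phantom

def _paint_ball(mask: np.ndarray, center: np.ndarray, radius: float) -> None:
    """Set mask voxels whose centers lie within ``radius`` of ``center``."""
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1,
                    np.array(mask.shape))
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius ** 2


def rasterize_tube(mask: np.ndarray, p0, p1, radius_vox: float,
                   step: float = 0.5) -> None:
    """Rasterize a straight tube of given radius (voxels) into ``mask``.

    The tube is the union of balls placed every ``step`` voxels along
    the centerline, i.e. voxels whose centers lie within the radius of
    the (capped) segment.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = np.linalg.norm(p1 - p0)
    n_steps = max(1, int(math.ceil(length / step)))
    for t in np.linspace(0.0, 1.0, n_steps + 1):
        _paint_ball(mask, p0 + t * (p1 - p0), radius_vox)


def generate_vascular_phantom(shape=(64, 64, 64), voxel_size: float = 9.0,
                              n_segments: int = 25,
                              radius_range_um=(18.0, 45.0),
                              segment_length_vox: float = 14.0,
                              branch_prob: float = 0.3,
                              vessel_intensity: float = 255.0,
                              background: float = 50.0,
                              noise_sd: float = 0.0,
                              seed: int = 0,
                              ) -> tuple[VolumeImage, PhantomGroundTruth]:
    """Random-walk branching tube tree rasterized into a bright-vessel volume.

    Returns the grayscale volume (vessels bright on a darker background,
    plus optional additive Gaussian noise) together with ground truth
    holding the exact rasterized vessel mask, the per-segment radii and
    the exact voxel-count fractional blood volume.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise ValueError("volume must be at least 32 voxels per axis")
    r_lo, r_hi = (float(r) for r in radius_range_um)
    if n_segments > 0 and r_lo < voxel_size:
        raise ValueError("minimum radius must be at least one voxel")
    if r_hi / voxel_size > min(shape) / 4:
        raise ValueError("degenerate geometry: radius exceeds shape/4")

    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    radii_um: list[float] = []
    shape_margin_lo = [s * 0.15 for s in shape]
    shape_margin_hi = [s * 0.85 for s in shape]

    def random_direction() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    # walkers: (position, direction, depth).  Radii are drawn per
    # segment and walks are restarted after ``max_chain`` segments, so
    # the phantom is a forest of short branching trees; this keeps the
    # total vessel volume concentrated around its expectation instead
    # of being dominated by a single tree's self-overlap.
    max_chain = 6
    lo_bound = np.full(3, 2.0)
    hi_bound = np.array(shape, dtype=float) - 3.0
    walkers: list = []
    remaining = n_segments
    while remaining > 0:
        if not walkers:
            walkers.append((rng.uniform(shape_margin_lo, shape_margin_hi),
                            random_direction(), 0))
        pos, direction, depth = walkers.pop(0)
        direction = direction + 0.4 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        end = pos + direction * segment_length_vox
        # reflect the walk at the volume borders
        for ax in range(3):
            if end[ax] < lo_bound[ax]:
                end[ax] = 2 * lo_bound[ax] - end[ax]
                direction[ax] *= -1
            elif end[ax] > hi_bound[ax]:
                end[ax] = 2 * hi_bound[ax] - end[ax]
                direction[ax] *= -1
        end = np.clip(end, lo_bound, hi_bound)
        r_vox = rng.uniform(r_lo, r_hi) / voxel_size
        rasterize_tube(mask, pos, end, r_vox)
        radii_um.append(r_vox * voxel_size)
        remaining -= 1
        if remaining > 0 and depth + 1 < max_chain:
            walkers.append((end, direction, depth + 1))
            if rng.random() < branch_prob:
                walkers.append((end, random_direction(), depth + 1))

    volume = np.full(shape, background, dtype=float)
    volume[mask] = vessel_intensity
    if noise_sd > 0:
        volume = volume + rng.normal(0.0, noise_sd, shape)
        volume = np.clip(volume, 0.0, None)

    tumor_mask = np.ones(shape, dtype=bool)
    gt = PhantomGroundTruth(seed=seed,
                            true_fbv=float(mask.sum()) / mask.size,
                            vessel_radii=radii_um,
                            vessel_mask=mask)
    return VolumeImage(volume, voxel_size, tumor_mask), gt


# ---------------------------------------------------------------------------
# DCE-MRI series phantom

def generate_dce_series(shape=(16, 16, 4), n_frames: int = 200,
                        frame_interval: float = 4.8,
                        injection_frame: int = 10,
                        enhancing_fraction: float = 0.5,
                        peak_enhancement: float = 2.0,
                        tau_s: float = 15.0,
                        baseline_signal: float = 100.0,
                        noise_sd: float = 0.0,
                        seed: int = 0,
                        ) -> tuple[DynamicSeries, PhantomGroundTruth]:
    """Dynamic series with a designed fraction of enhancing voxels.

    Baseline frames are flat; enhancing voxels then follow a saturating
    exponential ``1 - exp(-t/τ)`` scaled to reach exactly
    ``peak_enhancement`` × baseline at the final frame.  Non-enhancing
    voxels stay flat.  The acquisition grid defaults to the 4.8-s,
    200-frame layout with injection after the tenth baseline frame.
    ``noise_sd`` is a fraction of the baseline signal.
    """
    if not 0.0 <= enhancing_fraction <= 1.0:
        raise ValueError("enhancing_fraction must be in [0, 1]")
    if injection_frame >= n_frames:
        raise ValueError("injection_frame must precede the last frame")
    if enhancing_fraction > 0 and peak_enhancement < 1.5:
        warnings.warn("peak_enhancement < 1.5: designed enhancing voxels "
                      "will not pass the RSI enhancement threshold",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    n_vox = int(np.prod(shape))
    n_enh = int(round(enhancing_fraction * n_vox))
    flat_idx = rng.permutation(n_vox)[:n_enh]
    enh_mask = np.zeros(n_vox, dtype=bool)
    enh_mask[flat_idx] = True
    enh_mask = enh_mask.reshape(shape)

    t_post = (np.arange(n_frames) - injection_frame) * frame_interval
    t_post = np.clip(t_post, 0.0, None)
    curve = 1.0 - np.exp(-t_post / tau_s)
    if curve[-1] > 0:
        curve = curve / curve[-1]
    enhancement = 1.0 + (peak_enhancement - 1.0) * curve  # ratio to baseline

    signal = np.full(shape + (n_frames,), baseline_signal, dtype=float)
    signal[enh_mask] = baseline_signal * enhancement
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd * baseline_signal,
                                     signal.shape)
        signal = np.clip(signal, 0.0, None)

    series = DynamicSeries(signal, frame_interval, injection_frame,
                           roi=np.ones(shape, dtype=bool))
    gt = PhantomGroundTruth(seed=seed, true_fev=n_enh / n_vox,
                            enhancing_mask=enh_mask)
    return series, gt


# ---------------------------------------------------------------------------
# histology field phantom

#: paint colors (hue, sat, value) strictly inside the default bands
_STAIN_HSV = {
    "lectin": (0.62, 0.70, 0.80),
    "ki67": (0.08, 0.70, 0.60),
    "sma": (0.92, 0.70, 0.70),
}
_BACKGROUND_HSV = (0.15, 0.02, 0.97)

_BG, _VESSEL, _NUCLEUS, _SMA = 0, 1, 2, 3


def _assert_color_safety(rgb8: np.ndarray, layer: np.ndarray,
                         bands: dict) -> None:
    """Painted pixels must classify into their band after quantization."""
    hsv = rgb2hsv(rgb8)
    hue, sat = hsv[..., 0], hsv[..., 1]
    for code, name in ((_VESSEL, "lectin"), (_NUCLEUS, "ki67"),
                       (_SMA, "sma")):
        sel = layer == code
        if not sel.any():
            continue
        h_lo, h_hi, s_lo, s_hi = bands[name]
        ok = ((hue[sel] >= h_lo) & (hue[sel] <= h_hi)
              & (sat[sel] >= s_lo) & (sat[sel] <= s_hi))
        if not ok.all():
            raise AssertionError(f"{name} paint drifted out of its HSV band")
    bg = layer == _BG
    if bg.any() and (sat[bg] >= 0.25).any():
        raise AssertionError("background saturation entered a stain band")


def generate_histology_field(size_px=(384, 384), um_per_px: float = 1.0,
                             n_nuclei: int = 25,
                             frac_in_vessel: float = 0.2,
                             with_sma: bool = False,
                             n_vessels: int = 5,
                             frac_unrimmed: float = 0.3,
                             nucleus_diameter_um: float = 8.0,
                             n_overlap_pairs: int | None = None,
                             sma_rim_um: float = 2.0,
                             seed: int = 0,
                             ) -> tuple[StainField, PhantomGroundTruth]:
    """Double-stained RGB field with exact painted ground truth.

    Blue elongated vessel profiles, brown elliptical Ki67 nuclei (with
    some overlapping pairs at 0.6-0.9 diameter separation to exercise
    watershed splitting) and, when ``with_sma`` is set, red-brown
    perivascular α-SMA rims around a subset of vessels chosen so the
    unrimmed vessel area approximates the ``frac_unrimmed`` target
    fraction.  Vessels are
    laid out on a coarse grid so that unrimmed vessels are guaranteed to
    be at least 5 μm from any α-SMA pixel.  Ground truth records exact
    nucleus counts, final painted stain areas, and the area of vessels
    lacking α-SMA coverage.
    """
    rng = np.random.default_rng(seed)
    h, w = (int(s) for s in size_px)
    nuc_d_px = nucleus_diameter_um / um_per_px
    if n_nuclei > 0 and nuc_d_px < 3:
        raise ValueError("nucleus diameter below 3 px at this scale")
    n_in = int(round(frac_in_vessel * n_nuclei))
    if n_in > 0 and n_vessels == 0:
        raise ValueError("invalid design: in-vessel nuclei but no vessels")

    layer = np.zeros((h, w), dtype=np.uint8)
    rim_px = max(1, int(round(sma_rim_um / um_per_px)))
    clearance = int(math.ceil((5.0 + 2 * sma_rim_um) / um_per_px)) + 4

    # --- vessels on a jittered grid with guaranteed clearance
    n_cells = max(1, int(math.ceil(math.sqrt(n_vessels))))
    cell_h, cell_w = h // n_cells, w // n_cells
    cells = [(i, j) for i in range(n_cells) for j in range(n_cells)]
    rng.shuffle(cells)
    vessel_ids = np.zeros((h, w), dtype=np.int32)
    n_placed = 0
    for (ci, cj) in cells[:n_vessels]:
        max_r = (min(cell_h, cell_w) - clearance) // 2
        if max_r < 3:
            raise ValueError("field too small for the requested vessels")
        a = rng.uniform(max_r * 0.5, max_r)          # semi-major (px)
        b = rng.uniform(max(3.0, a * 0.3), a * 0.7)  # semi-minor
        cy = ci * cell_h + cell_h // 2
        cx = cj * cell_w + cell_w // 2
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=rot)
        layer[rr, cc] = _VESSEL
        n_placed += 1
        vessel_ids[rr, cc] = n_placed

    # --- α-SMA rims: leave a subset of vessels unrimmed so that the
    # unrimmed area fraction approximates ``frac_unrimmed`` (greedy
    # area matching over a random vessel order)
    rimmed: set[int] = set()
    if with_sma and n_placed > 0:
        areas = {vid: int((vessel_ids == vid).sum())
                 for vid in range(1, n_placed + 1)}
        total_area = sum(areas.values())
        order = list(rng.permutation(np.arange(1, n_placed + 1)))
        unrimmed: set[int] = set()
        cum = 0
        for vid in order:
            vid = int(vid)
            if abs((cum + areas[vid]) / total_area - frac_unrimmed) \
                    <= abs(cum / total_area - frac_unrimmed):
                unrimmed.add(vid)
                cum += areas[vid]
        rimmed = {vid for vid in areas if vid not in unrimmed}
        for vid in rimmed:
            comp = vessel_ids == vid
            rim = ndimage.binary_dilation(comp, structure=disk(rim_px)) & ~comp
            layer[rim & (layer == _BG)] = _SMA

    # --- nuclei
    nuc_r = nuc_d_px / 2.0
    vessel_mask_now = layer == _VESSEL
    interior = ndimage.binary_erosion(vessel_mask_now,
                                      structure=disk(int(math.ceil(nuc_r)) + 1))
    filled = ndimage.binary_fill_holes(vessel_mask_now)
    outside = ~ndimage.binary_dilation(filled,
                                       structure=disk(int(math.ceil(nuc_r)) + 2))
    outside[:int(nuc_r) + 1, :] = outside[-int(nuc_r) - 1:, :] = False
    outside[:, :int(nuc_r) + 1] = outside[:, -int(nuc_r) - 1:] = False

    def sample_centers(region: np.ndarray, count: int,
                       min_sep: float) -> list[tuple[int, int]]:
        if count == 0:
            return []
        coords = np.argwhere(region)
        if coords.size == 0:
            raise ValueError("no room to place nuclei in the requested region")
        chosen: list[tuple[int, int]] = []
        order = rng.permutation(len(coords))
        for k in order:
            y, x = coords[k]
            if all((y - y0) ** 2 + (x - x0) ** 2 >= min_sep ** 2
                   for y0, x0 in chosen):
                chosen.append((int(y), int(x)))
                if len(chosen) == count:
                    return chosen
        raise ValueError("could not place the requested number of nuclei")

    if n_overlap_pairs is None:
        n_overlap_pairs = (n_nuclei - n_in) // 6
    n_out = n_nuclei - n_in
    n_pair_nuclei = 2 * n_overlap_pairs
    if n_pair_nuclei > n_out:
        raise ValueError("too many overlap pairs for the out-of-vessel count")
    n_single_out = n_out - n_pair_nuclei

    # (y, x, is_pair_member); pair members are painted as full circles so
    # that the interior distance transform keeps one clear maximum per
    # nucleus at 0.6-0.9 diameter separations
    centers: list[tuple[float, float, bool]] = []
    for y, x in sample_centers(interior, n_in, min_sep=2.2 * nuc_d_px):
        centers.append((y, x, False))
    seeds_out = sample_centers(outside, n_single_out + n_overlap_pairs,
                               min_sep=3.2 * nuc_d_px)
    for y, x in seeds_out[:n_single_out]:
        centers.append((y, x, False))
    for y, x in seeds_out[n_single_out:]:
        centers.append((y, x, True))
        sep = rng.uniform(0.6, 0.9) * nuc_d_px
        ang = rng.uniform(0, 2 * np.pi)
        centers.append((y + sep * math.sin(ang), x + sep * math.cos(ang),
                        True))

    for y, x, is_pair in centers:
        if is_pair:
            a = b = nuc_r
            rot = 0.0
        else:
            a = nuc_r * rng.uniform(0.9, 1.1)
            b = nuc_r * rng.uniform(0.75, 0.95)
            rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(y, x, a, b, shape=(h, w), rotation=rot)
        layer[rr, cc] = _NUCLEUS

    # --- render to 8-bit RGB
    hsv = np.empty((h, w, 3), dtype=float)
    hsv[...] = _BACKGROUND_HSV
    for code, name in ((_VESSEL, "lectin"), (_NUCLEUS, "ki67"),
                       (_SMA, "sma")):
        hsv[layer == code] = _STAIN_HSV[name]
    jitter = rng.uniform(-0.008, 0.008, (h, w, 1))
    hsv[..., 2:3] = np.clip(hsv[..., 2:3] + jitter, 0.0, 1.0)
    rgb8 = (hsv2rgb(hsv) * 255.0).round().astype(np.uint8)
    _assert_color_safety(rgb8, layer, DEFAULT_BANDS)

    vessel_area = int((layer == _VESSEL).sum())
    immature_area = 0
    if with_sma and n_placed > 0:
        for vid in range(1, n_placed + 1):
            if vid not in rimmed:
                immature_area += int(((vessel_ids == vid)
                                      & (layer == _VESSEL)).sum())
    gt = PhantomGroundTruth(
        seed=seed,
        nucleus_count_total=len(centers),
        nucleus_count_in_vessel=n_in,
        vessel_area_px=vessel_area,
        immature_area_px=immature_area,
        immature_fraction=(immature_area / vessel_area if with_sma
                           and vessel_area else float("nan")),
    )
    fld = StainField(rgb8, um_per_px,
                     "10x" if um_per_px >= 0.8 else "40x")
    return fld, gt


# ---------------------------------------------------------------------------
# HR MAS MRS spectra phantom

DEFAULT_PEAKS: dict[str, tuple[float, float, float]] = {
    # name: (ppm, FWHM in ppm, base amplitude)
    "PCho": (3.23, 0.005, 1.0),
    "GPC": (3.24, 0.005, 0.8),
    "Cho": (3.21, 0.005, 0.4),
    "Cr": (3.03, 0.006, 0.6),
    "Tau": (3.43, 0.008, 0.5),
    "Gly": (3.55, 0.006, 0.3),
}


def generate_spectra_cohort(n_per_class: int = 6,
                            ppm_axis: np.ndarray | None = None,
                            peaks: dict | None = None,
                            class_effects: dict | None = None,
                            noise_sd: float = 0.01,
                            amplitude_cv: float = 0.1,
                            baseline_amplitude: float = 0.001,
                            seed: int = 0) -> SpectrumSet:
    """Two-class cohort of Lorentzian-line spectra with designed effects.

    Each spectrum is a sum of Lorentzian lines with per-sample lognormal
    amplitude variability, a small residual baseline (the smooth
    remainder one expects after spectrometer-side baseline correction),
    and additive Gaussian noise (``noise_sd`` as a fraction of the
    largest base amplitude).  ``class_effects`` multiplies the named peak amplitudes
    in the treated class; the default raises phosphocholine and lowers
    glycerophosphocholine, the signature of reduced phospholipase
    activity.
    """
    if ppm_axis is None:
        ppm_axis = np.arange(4.0, 2.8, -0.001)
    ppm_axis = np.asarray(ppm_axis, dtype=float)
    peaks = dict(DEFAULT_PEAKS if peaks is None else peaks)
    if class_effects is None:
        class_effects = {"PCho": 1.5, "GPC": 0.6}
    unknown = set(class_effects) - set(peaks)
    if unknown:
        raise ValueError(f"class effects reference unknown peaks: {unknown}")

    rng = np.random.default_rng(seed)
    max_amp = max(a for _, _, a in peaks.values())
    spectra = []
    labels = []
    for cls in ("control", "treated"):
        for _ in range(n_per_class):
            spec = np.zeros_like(ppm_axis)
            for name, (pos, fwhm, amp) in peaks.items():
                if cls == "treated":
                    amp = amp * class_effects.get(name, 1.0)
                amp = amp * rng.lognormal(0.0, amplitude_cv)
                gamma = fwhm / 2.0
                spec += amp * gamma ** 2 / ((ppm_axis - pos) ** 2 + gamma ** 2)
            t = np.linspace(-1, 1, ppm_axis.size)
            coefs = rng.normal(0.0, baseline_amplitude * max_amp, 3)
            spec += coefs[0] + coefs[1] * t + coefs[2] * t ** 2
            if noise_sd > 0:
                spec += rng.normal(0.0, noise_sd * max_amp, ppm_axis.size)
            spectra.append(spec)
            labels.append(cls)
    return SpectrumSet(np.array(spectra), ppm_axis, np.array(labels))


# ---------------------------------------------------------------------------
# full two-group study

@dataclass
class TumorPhantom:
    """All synthetic raw data for one tumor of a study."""

    tumor_id: str
    group: str
    microct: VolumeImage
    microct_gt: PhantomGroundTruth
    dce: dict                 # day -> DynamicSeries
    dce_gt: dict              # day -> PhantomGroundTruth
    ki67_field: StainField
    ki67_gt: PhantomGroundTruth
    sma_field: StainField
    sma_gt: PhantomGroundTruth


@dataclass
class StudyBundle:
    """In-memory bundle of a synthetic two-arm study."""

    design: StudyDesign
    seed: int
    tumors: list[TumorPhantom]
    spectra: SpectrumSet
    manifest: str             # canonical JSON, byte-identical per seed


def generate_two_group_study(design: StudyDesign | None = None,
                             seed: int = 0,
                             include_spectra: bool = True) -> StudyBundle:
    """Generate phantoms for every tumor of a control/treated study.

    Treated-group phantom parameters are scaled by the design's effect
    sizes: fewer vessel segments (lower FBV), fewer unrimmed vessels
    (lower immature fraction), fewer in-vessel nuclei (lower PEC
    density), and a reduced day-7 enhancement amplitude and enhancing
    fraction (negative day-4-to-7 perfusion change).  The manifest lists
    every phantom with its ground truth and is byte-identical when
    regenerated with the same seed.
    """
    design = design or StudyDesign()
    ss = np.random.SeedSequence(seed)
    eff = design.effect_sizes
    noise = design.noise_levels
    tumors: list[TumorPhantom] = []
    manifest: dict = {"seed": seed,
                      "design": {k: v for k, v in asdict(design).items()},
                      "tumors": []}

    groups = (["control"] * design.n_control
              + ["treated"] * design.n_treated)
    child_seeds = ss.generate_state(len(groups) * 8 + 1) % (2 ** 31)
    k = 0

    def next_seed() -> int:
        nonlocal k
        s = int(child_seeds[k])
        k += 1
        return s

    for i, group in enumerate(groups):
        tid = f"{group[0].upper()}{i + 1:02d}"
        treated = group == "treated"
        rng = np.random.default_rng(next_seed())

        # micro-CT: scale the expected tube count for the treated arm
        n_seg_mean = design.microct_n_segments * (eff["fbv"] if treated
                                                  else 1.0)
        n_seg = max(2, int(round(rng.normal(n_seg_mean, 1.5))))
        vol, vol_gt = generate_vascular_phantom(
            shape=design.microct_shape,
            n_segments=n_seg,
            radius_range_um=design.microct_radius_range_um,
            noise_sd=noise["microct"],
            seed=next_seed())

        # DCE-MRI: stable enhancement in controls; treated amplitude and
        # enhancing fraction drop at day 7
        dce, dce_gt = {}, {}
        for day in design.timepoints:
            peak = rng.normal(2.0, 0.08)
            frac = min(1.0, max(0.0,
                                rng.normal(design.dce_enhancing_fraction,
                                           0.03)))
            if treated and day == max(design.timepoints):
                peak = 1.0 + (peak - 1.0) * eff["delta_auc_day7"]
                frac = frac * eff["fev_day7"]
            series, gt = generate_dce_series(
                shape=design.dce_shape,
                enhancing_fraction=frac,
                peak_enhancement=max(1.6, peak),
                noise_sd=noise["dce"],
                seed=next_seed())
            dce[day], dce_gt[day] = series, gt

        # histology: Ki67 field (PECs) and α-SMA field (maturity)
        base_n_nuclei = 24
        frac_in = 0.25 * (eff["pec_density"] if treated else 1.0)
        ki67_field, ki67_gt = generate_histology_field(
            size_px=design.histology_size_px,
            um_per_px=design.histology_um_per_px,
            n_nuclei=base_n_nuclei,
            frac_in_vessel=frac_in,
            with_sma=False,
            seed=next_seed())
        target = 0.30 * (eff["immature_fraction"] if treated else 1.0)
        frac_unrimmed = float(np.clip(rng.normal(target, 0.02), 0.0, 1.0))
        sma_field, sma_gt = generate_histology_field(
            size_px=design.histology_size_px,
            um_per_px=design.histology_um_per_px,
            n_nuclei=0,
            frac_in_vessel=0.0,
            with_sma=True,
            n_vessels=12,
            frac_unrimmed=frac_unrimmed,
            seed=next_seed())

        tumors.append(TumorPhantom(tid, group, vol, vol_gt, dce, dce_gt,
                                   ki67_field, ki67_gt, sma_field, sma_gt))
        manifest["tumors"].append({
            "tumor_id": tid, "group": group,
            "microct": vol_gt.to_json_dict(),
            "dce": {str(d): g.to_json_dict() for d, g in dce_gt.items()},
            "ki67": ki67_gt.to_json_dict(),
            "sma": sma_gt.to_json_dict(),
        })

    spectra = generate_spectra_cohort(
        n_per_class=design.n_spectra_per_class,
        class_effects={m: eff[m] for m in ("PCho", "GPC") if m in eff},
        noise_sd=noise["spectra"],
        seed=next_seed()) if include_spectra else None

    manifest_json = json.dumps(manifest, sort_keys=True, default=float)
    return StudyBundle(design, seed, tumors, spectra, manifest_json)
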