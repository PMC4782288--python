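"""Shared in-memory carriers for the imaging and spectroscopy data.

Each container is a thin dataclass around numpy arrays plus the physical
metadata (voxel size, frame timing, pixel scale, ppm axis) that every
downstream computation needs.  Validation happens at construction so that
the analysis stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeImage",
    "DynamicSeries",
    "StainField",
    "SpectrumSet",
]


@dataclass
class VolumeImage:
    """3D scalar field with isotropic physical voxel size (μm).

    Carrier for micro-CT volumes and their tumor masks.  Anisotropic
    voxels are not supported; pass a single scalar ``voxel_size``.
    """

    voxels: np.ndarray
    voxel_size: float
    tumor_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.ndim(self.voxel_size) != 0:
            raise ValueError("anisotropic voxels are not supported; "
                             "voxel_size must be a scalar (μm)")
        self.voxel_size = float(self.voxel_size)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive (μm)")
        if self.tumor_mask is None:
            self.tumor_mask = np.ones(self.voxels.shape, dtype=bool)
        else:
            self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
            if self.tumor_mask.shape != self.voxels.shape:
                raise ValueError("tumor_mask shape must match voxels")


@dataclass
class DynamicSeries:
    """4D dynamic MRI series: spatial dims + a trailing frame axis.

    ``injection_frame`` is the 0-based index of the first post-injection
    frame; frames ``0 .. injection_frame-1`` are pre-contrast baseline.
    """

    signal: np.ndarray
    frame_interval: float
    injection_frame: int
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, slice, frame)")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        self.frame_interval = float(self.frame_interval)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive (s)")
        self.injection_frame = int(self.injection_frame)
        if self.injection_frame < 1:
            raise ValueError("need at least one baseline frame "
                             "(injection_frame >= 1)")
        if self.injection_frame >= self.n_frames:
            raise ValueError("injection_frame must precede the last frame")
        spatial = self.signal.shape[:3]
        if self.roi is None:
            self.roi = np.ones(spatial, dtype=bool)
        else:
            self.roi = np.asarray(self.roi, dtype=bool)
            if self.roi.shape != spatial:
                raise ValueError("roi shape must match spatial dims")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[3]


@dataclass
class StainField:
    """2D RGB stained-section field with its pixel scale in μm/px."""

    rgb: np.ndarray
    um_per_px: float
    magnification_tag: str = "40x"

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.rgb.dtype != np.uint8:
            raise ValueError("rgb must be 8-bit (uint8)")
        self.um_per_px = float(self.um_per_px)
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")


@dataclass
class SpectrumSet:
    """Matrix of 1D spectra on a shared, strictly monotone ppm axis."""

    intensities: np.ndarray
    ppm: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities,
                                                    dtype=float))
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be 1D")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError("intensities columns must match ppm axis length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.size != self.intensities.shape[0]:
                raise ValueError("one label per spectrum required")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    def select_region(self, ppm_lo: float, ppm_hi: float) -> "SpectrumSet":
        """Restrict to ppm in [ppm_lo, ppm_hi], preserving axis direction."""
        keep = (self.ppm >= ppm_lo) & (self.ppm <= ppm_hi)
        if not keep.any():
            raise ValueError("selected ppm region is empty")
        return SpectrumSet(self.intensities[:, keep], self.ppm[keep],
                           None if self.labels is None else self.labels)
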