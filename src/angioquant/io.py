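"""File-format interfaces for volumes, dynamic series, fields and spectra.

Volumes and 4D series go through NIfTI (nibabel) or multi-page TIFF
(tifffile); histology fields through PNG/TIFF (imageio/tifffile); spectra
and tabular outputs through CSV (pandas).  Physical metadata (voxel size
in μm, frame interval in s) is carried in the NIfTI header zooms.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .containers import DynamicSeries, SpectrumSet, StainField, VolumeImage

__all__ = [
    "save_volume", "load_volume",
    "save_series", "load_series",
    "save_field", "load_field",
    "save_spectra", "load_spectra",
]


def save_volume(volume: VolumeImage, path) -> None:
    """Write a 3D volume as NIfTI (.nii/.nii.gz) or multi-page TIFF."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        affine = np.diag([volume.voxel_size] * 3 + [1.0])
        nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine),
                 str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, volume.voxels.astype(np.float32),
                         resolution=(1e4 / volume.voxel_size,) * 2)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def load_volume(path, voxel_size: float | None = None,
                tumor_mask=None) -> VolumeImage:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()[:3]
        if voxel_size is None:
            if not np.allclose(zooms, zooms[0]):
                raise ValueError("anisotropic voxels are not supported")
            voxel_size = float(zooms[0])
    elif path.suffix in (".tif", ".tiff"):
        data = tifffile.imread(path).astype(float)
        if voxel_size is None:
            raise ValueError("voxel_size (μm) required for TIFF input")
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    return VolumeImage(data, voxel_size, tumor_mask)


def save_series(series: DynamicSeries, path) -> None:
    """Write a 4D dynamic series as NIfTI with time as the 4th dimension."""
    path = Path(path)
    affine = np.eye(4)
    img = nib.Nifti1Image(series.signal.astype(np.float32), affine)
    img.header.set_zooms((1.0, 1.0, 1.0, series.frame_interval))
    nib.save(img, str(path))


def load_series(path, injection_frame: int, roi=None) -> DynamicSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    dt = float(img.header.get_zooms()[3])
    return DynamicSeries(data, dt, injection_frame, roi)


def save_field(fld: StainField, path) -> None:
    """Write an RGB histology field as PNG or TIFF."""
    path = Path(path)
    if path.suffix == ".png":
        iio.imwrite(path, fld.rgb)
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, fld.rgb)
    else:
        raise ValueError(f"unsupported field format: {path.suffix}")


def load_field(path, um_per_px: float,
               magnification_tag: str = "40x") -> StainField:
    rgb = iio.imread(Path(path))
    return StainField(np.asarray(rgb[..., :3], dtype=np.uint8), um_per_px,
                      magnification_tag)


def save_spectra(spectra: SpectrumSet, path, labels_path=None) -> None:
    """Write spectra as CSV: first column ppm, one column per sample."""
    cols = {"ppm": spectra.ppm}
    for i in range(spectra.n_samples):
        cols[f"s{i:03d}"] = spectra.intensities[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    if labels_path is not None and spectra.labels is not None:
        pd.DataFrame({"sample": [f"s{i:03d}" for i
                                 in range(spectra.n_samples)],
                      "label": spectra.labels}).to_csv(labels_path,
                                                       index=False)


def load_spectra(path, labels_path=None) -> SpectrumSet:
    df = pd.read_csv(path)
    ppm = df["ppm"].to_numpy(float)
    intensities = df.drop(columns="ppm").to_numpy(float).T
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path)["label"].to_numpy()
    return SpectrumSet(intensities, ppm, labels)
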