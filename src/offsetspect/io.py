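"""Reading and writing volumes, sinograms and angle tables.

Volumes go to NIfTI through nibabel with the pixel size in the affine;
sinograms are stored as a ``.npy`` array plus a JSON sidecar header carrying
the geometry (angles, radius, bin size, seed, target counts per view); angle
tables export to CSV.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import nibabel as nib

from .acquisition import AcquisitionGeometry, Sinogram
from .grids import ImageGrid, SegmentMap

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_segmap_nifti",
    "save_sinogram",
    "load_sinogram",
    "save_angles_csv",
    "save_png",
]


def _affine(pixel_mm: float, slice_mm: float) -> np.ndarray:
    return np.diag([pixel_mm, pixel_mm, slice_mm, 1.0])


def save_nifti(image: ImageGrid, path: str | pathlib.Path):
    data = image.values if image.is_3d else image.values[None, :, :]
    # store as (x, y, z): transpose (slice, row, col) -> (col, row, slice)
    nib.save(
        nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(image.pixel_size_mm, image.slice_thickness_mm)),
        str(path),
    )


def load_nifti(path: str | pathlib.Path) -> ImageGrid:
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    zooms = img.header.get_zooms()
    if data.shape[0] == 1:
        return ImageGrid(data[0], float(zooms[0]))
    return ImageGrid(data, float(zooms[0]), float(zooms[2]))


def save_segmap_nifti(segmap: SegmentMap, path: str | pathlib.Path):
    """Write the label volume with the same geometry as its image."""
    data = segmap.labels if segmap.labels.ndim == 3 else segmap.labels[None, :, :]
    nib.save(
        nib.Nifti1Image(
            np.transpose(data.astype(np.int16), (2, 1, 0)),
            _affine(segmap.pixel_size_mm, segmap.slice_thickness_mm),
        ),
        str(path),
    )


def save_sinogram(sino: Sinogram, path_prefix: str | pathlib.Path):
    prefix = pathlib.Path(path_prefix)
    np.save(prefix.with_suffix(".npy"), sino.counts)
    header = {
        "angles_deg": sino.geometry.angles_deg.tolist(),
        "mode": sino.geometry.mode,
        "rotation_radius_mm": sino.geometry.rotation_radius_mm,
        "detector_bin_mm": sino.geometry.detector_bin_mm,
        "n_bins": sino.geometry.n_bins,
        "noise_seed": sino.noise_seed,
        "counts_per_view_target": sino.counts_per_view_target,
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_sinogram(path_prefix: str | pathlib.Path) -> Sinogram:
    prefix = pathlib.Path(path_prefix)
    counts = np.load(prefix.with_suffix(".npy"))
    header = json.loads(prefix.with_suffix(".json").read_text())
    geom = AcquisitionGeometry(
        np.asarray(header["angles_deg"]),
        header["mode"],
        header["rotation_radius_mm"],
        header["detector_bin_mm"],
        header["n_bins"],
    )
    return Sinogram(counts, geom, header.get("noise_seed"), header.get("counts_per_view_target"))


def save_angles_csv(geometry: AcquisitionGeometry, path: str | pathlib.Path):
    lines = ["index,angle_deg"] + [
        f"{i},{a:.6f}" for i, a in enumerate(geometry.angles_deg)
    ]
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def save_png(image: ImageGrid, path: str | pathlib.Path, normalize: bool = True):
    """Grayscale preview of a slice, normalized to its own maximum."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = image.slice2d().values
    vmax = values.max() if normalize and values.max() > 0 else None
    plt.imsave(str(path), values, cmap="gray", vmin=0, vmax=vmax)
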