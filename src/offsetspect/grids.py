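"""Image containers, the physical coordinate convention, and pixel-mask helpers.

All images live on a square, center-anchored grid: the physical coordinate of
pixel (row r, column c) is

    x = (c - (cols - 1) / 2) * pixel_size_mm
    y = ((rows - 1) / 2 - r) * pixel_size_mm

i.e. x grows with column index, y grows *upward* (decreasing row index), and
the grid center is physical (0, 0) mm.  3D stacks are indexed
(slice, row, col) and every transverse slice shares the same in-plane
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "SegmentMap",
    "pixel_coords_mm",
    "mm_to_pixel",
    "nearest_pixel",
    "disc_mask",
    "ellipse_mask",
    "nearest_area_mask",
]


def pixel_coords_mm(shape: tuple[int, int], pixel_size_mm: float):
    """Return (X, Y) arrays of pixel-center coordinates in mm for a 2D shape."""
    rows, cols = shape
    c_col = (cols - 1) / 2.0
    c_row = (rows - 1) / 2.0
    x = (np.arange(cols) - c_col) * pixel_size_mm
    y = (c_row - np.arange(rows)) * pixel_size_mm
    return np.meshgrid(x, y)  # X[r, c], Y[r, c]


def mm_to_pixel(x_mm: float, y_mm: float, shape: tuple[int, int], pixel_size_mm: float):
    """Fractional (row, col) of a physical point."""
    rows, cols = shape
    col = x_mm / pixel_size_mm + (cols - 1) / 2.0
    row = (rows - 1) / 2.0 - y_mm / pixel_size_mm
    return row, col


def nearest_pixel(x_mm: float, y_mm: float, shape: tuple[int, int], pixel_size_mm: float):
    """Integer (row, col) of the pixel whose center is nearest a physical point.

    Exact half-way ties are broken toward the larger index (round half up),
    so the mapping is deterministic.
    """
    row, col = mm_to_pixel(x_mm, y_mm, shape, pixel_size_mm)
    return int(np.floor(row + 0.5)), int(np.floor(col + 0.5))


@dataclass
class ImageGrid:
    """A 2D transverse slice or 3D stack of count densities on a physical grid.

    Parameters
    ----------
    values
        Array of shape (rows, cols) or (slices, rows, cols).  Phantom ground
        truth is nonnegative; reconstructed images (notably ramp-filtered
        backprojection) may carry small negative excursions, which callers
        clip only where a metric requires counts.
    pixel_size_mm
        Square in-plane pixel edge length, > 0.
    slice_thickness_mm
        Spacing between transverse slices for 3D stacks; defaults to the
        pixel size.
    """

    values: np.ndarray
    pixel_size_mm: float
    slice_thickness_mm: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("ImageGrid requires a 2D or 3D array")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        if self.slice_thickness_mm is None:
            self.slice_thickness_mm = self.pixel_size_mm

    @property
    def is_3d(self) -> bool:
        return self.values.ndim == 3

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    def slice2d(self, index: int | None = None) -> "ImageGrid":
        """Central transverse slice (or the given one) as a 2D ImageGrid."""
        if not self.is_3d:
            return self
        if index is None:
            index = self.values.shape[0] // 2
        return ImageGrid(self.values[index], self.pixel_size_mm)

    def mm_to_pixel(self, x_mm: float, y_mm: float):
        return mm_to_pixel(x_mm, y_mm, self.plane_shape, self.pixel_size_mm)

    def pixel_to_mm(self, row: int, col: int):
        rows, cols = self.plane_shape
        x = (col - (cols - 1) / 2.0) * self.pixel_size_mm
        y = ((rows - 1) / 2.0 - row) * self.pixel_size_mm
        return x, y

    def nearest_pixel(self, x_mm: float, y_mm: float):
        return nearest_pixel(x_mm, y_mm, self.plane_shape, self.pixel_size_mm)


@dataclass
class SegmentMap:
    """Ground-truth segment labels with assigned count densities.

    Every pixel carries exactly one integer label; ``legend`` maps label ids
    to segment names and ``assigned_counts`` to the count density (counts per
    pixel) rendered into the matching :class:`ImageGrid`.  Masks are hard
    (no anti-aliasing) so linearity references and ratio ground truths are
    exact.
    """

    labels: np.ndarray
    legend: dict[int, str]
    assigned_counts: dict[int, float]
    pixel_size_mm: float
    slice_thickness_mm: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from legend")
        if self.slice_thickness_mm is None:
            self.slice_thickness_mm = self.pixel_size_mm

    def id_of(self, name: str) -> int:
        for k, v in self.legend.items():
            if v == name:
                return k
        raise KeyError(name)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.id_of(name)

    def to_image(self) -> ImageGrid:
        """Render the assigned counts into an ImageGrid (exact equality)."""
        values = np.zeros(self.labels.shape, dtype=float)
        for label_id, counts in self.assigned_counts.items():
            values[self.labels == label_id] = counts
        return ImageGrid(values, self.pixel_size_mm, self.slice_thickness_mm)


def disc_mask(shape, pixel_size_mm, center_mm, radius_mm) -> np.ndarray:
    """Pixels whose centers lie inside a disc."""
    X, Y = pixel_coords_mm(shape, pixel_size_mm)
    return (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2 <= radius_mm**2


def ellipse_mask(shape, pixel_size_mm, center_mm, semi_axes_mm) -> np.ndarray:
    """Pixels whose centers lie inside an axis-aligned ellipse."""
    X, Y = pixel_coords_mm(shape, pixel_size_mm)
    a, b = semi_axes_mm
    return ((X - center_mm[0]) / a) ** 2 + ((Y - center_mm[1]) / b) ** 2 <= 1.0


def nearest_area_mask(shape, pixel_size_mm, center_mm, area_mm2, semi_axis_ratio=1.0):
    """Mask of the N pixels nearest ``center_mm`` realizing a target area.

    N = round(area / pixel_area), so the realized area is always within one
    pixel-area of the target — tighter than thresholding a disc boundary.
    ``semi_axis_ratio`` = a/b stretches the distance metric to select an
    elliptical region (a along x, b along y) of the same area.  Ties in the
    metric are broken by (row, col) for determinism.
    """
    px_area = pixel_size_mm**2
    n_pix = int(round(area_mm2 / px_area))
    if n_pix < 1:
        raise ValueError("target area smaller than one pixel")
    X, Y = pixel_coords_mm(shape, pixel_size_mm)
    # same-area ellipse: a = sqrt(area*ratio/pi), b = a/ratio
    a = np.sqrt(area_mm2 * semi_axis_ratio / np.pi)
    b = a / semi_axis_ratio
    metric = ((X - center_mm[0]) / a) ** 2 + ((Y - center_mm[1]) / b) ** 2
    rows, cols = np.indices(shape)
    order = np.lexsort((cols.ravel(), rows.ravel(), metric.ravel()))
    mask = np.zeros(shape, dtype=bool)
    flat = mask.ravel()
    flat[order[:n_pix]] = True
    return mask
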