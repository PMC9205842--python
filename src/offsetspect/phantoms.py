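"""Numerical phantoms for the sparse-view SPECT simulation study.

Three phantoms, rendered as hard-mask count-density grids together with their
ground-truth segment maps:

* a **resolution phantom** — a uniform cylinder cross-section with three
  point sources 10 and 100 mm off center, for FWHM / aspect-ratio analysis;
* a **multi-cylinder phantom** — six 40 mm cylinders with graded count
  densities inside a 160 mm cylinder, for count-density linearity;
* a **striatal digital brain phantom** — a parametric anthropomorphic
  stand-in with parenchyma, skull bone, ventricle and bilateral comma-shaped
  striata at a striatum-to-parenchyma count ratio of exactly 8, for
  uniformity (%CV) and specific-binding-ratio analysis.

Ground truth uses hard (non-antialiased) masks so that per-segment count
assignments, linearity references and the ground-truth SBR are exact.
Generation is deterministic: identical arguments give bit-identical grids.
"""

from __future__ import annotations

import numpy as np

from .grids import (
    ImageGrid,
    SegmentMap,
    disc_mask,
    ellipse_mask,
    nearest_area_mask,
    nearest_pixel,
    pixel_coords_mm,
)

__all__ = [
    "make_resolution_phantom",
    "make_multicylinder_phantom",
    "make_sdb_phantom",
    "RESOLUTION_POINT_POSITIONS_MM",
    "MULTICYLINDER_COUNTS",
    "SDB_COUNTS",
]

#: Default point-source positions (x, y) in mm.  The three sources sit 10 mm
#: above, 100 mm above and 100 mm right of the cylinder center, so both a
#: "10 mm" and a "100 mm" position exist and the 100 mm positions admit
#: radial/tangential FWHM measurement.  Config-exposed: alternatives testable.
RESOLUTION_POINT_POSITIONS_MM = ((0.0, 10.0), (0.0, 100.0), (100.0, 0.0))

#: Count densities of the six 40 mm cylinders (counts/pixel).
MULTICYLINDER_COUNTS = (0.0, 200.0, 300.0, 400.0, 600.0, 800.0)

#: Count densities of the striatal brain phantom segments (counts/pixel).
SDB_COUNTS = {"striatum": 800.0, "parenchyma": 100.0, "bone": 20.0, "ventricle": 0.0}


def make_resolution_phantom(
    matrix_size: int = 128,
    pixel_size_mm: float = 3.2,
    *,
    cylinder_radius_mm: float = 150.0,
    point_positions_mm=RESOLUTION_POINT_POSITIONS_MM,
    point_counts: float = 800.0,
    background_counts: float = 10.0,
    point_diameter_mm: float | None = None,
):
    """Resolution phantom: uniform disc background with point sources.

    Point sources are single pixels (delta-like) at ``point_counts``
    counts/pixel unless ``point_diameter_mm`` requests finite discs; the
    background cylinder cross-section is at ``background_counts``.

    Returns
    -------
    (ImageGrid, SegmentMap)
        Segment ids: 0 air, 1 cylinder background, 2.. point_k.
    """
    if matrix_size < 64:
        raise ValueError("matrix_size must be at least 64")
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    shape = (matrix_size, matrix_size)
    labels = np.zeros(shape, dtype=np.int32)
    labels[disc_mask(shape, pixel_size_mm, (0.0, 0.0), cylinder_radius_mm)] = 1
    legend = {0: "background", 1: "cylinder"}
    assigned = {0: 0.0, 1: float(background_counts)}
    half = (matrix_size - 1) / 2.0 * pixel_size_mm
    for k, (x, y) in enumerate(point_positions_mm):
        if abs(x) > half or abs(y) > half:
            raise ValueError(
                f"point source {k} at ({x}, {y}) mm lies outside the "
                f"{matrix_size}x{matrix_size} grid (half-width {half} mm)"
            )
        label_id = 2 + k
        if point_diameter_mm is None:
            r, c = nearest_pixel(x, y, shape, pixel_size_mm)
            labels[r, c] = label_id
        else:
            labels[disc_mask(shape, pixel_size_mm, (x, y), point_diameter_mm / 2)] = label_id
        legend[label_id] = f"point_{k}"
        assigned[label_id] = float(point_counts)
    seg = SegmentMap(labels, legend, assigned, pixel_size_mm)
    return seg.to_image(), seg


def _hex_ring_centers(ring_radius_mm: float):
    # clockwise from 12 o'clock: 90, 30, -30, -90, -150, 150 degrees
    angles = np.deg2rad([90.0, 30.0, -30.0, -90.0, -150.0, 150.0])
    return [(ring_radius_mm * np.cos(a), ring_radius_mm * np.sin(a)) for a in angles]


def make_multicylinder_phantom(
    matrix_size: int = 128,
    pixel_size_mm: float = 3.2,
    *,
    outer_diameter_mm: float = 160.0,
    cylinder_diameter_mm: float = 40.0,
    ring_radius_mm: float = 50.0,
    cylinder_counts=MULTICYLINDER_COUNTS,
    background_counts: float = 100.0,
):
    """Multi-cylinder linearity phantom.

    Six 40 mm cylinders with count densities ``cylinder_counts`` sit on a
    hexagonal ring (clockwise from 12 o'clock, ascending count) inside a
    160 mm cylinder at ``background_counts``.  Cylinder discs are realized
    by nearest-pixel-count area matching, so each labeled area is within one
    pixel-area of pi*r^2.

    Returns
    -------
    (ImageGrid, SegmentMap)
        Segment ids: 0 air, 1 background cylinder, 2..7 cylinder_k.
    """
    shape = (matrix_size, matrix_size)
    outer_r = outer_diameter_mm / 2.0
    cyl_r = cylinder_diameter_mm / 2.0
    half = (matrix_size - 1) / 2.0 * pixel_size_mm
    if outer_r > half:
        raise ValueError("outer cylinder does not fit in the grid")
    if ring_radius_mm + cyl_r > outer_r:
        raise ValueError("cylinders do not fit inside the outer cylinder")
    centers = _hex_ring_centers(ring_radius_mm)
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            d = np.hypot(centers[i][0] - centers[j][0], centers[i][1] - centers[j][1])
            if d < cylinder_diameter_mm:
                raise ValueError(f"cylinders {i} and {j} overlap (center distance {d:.1f} mm)")
    labels = np.zeros(shape, dtype=np.int32)
    labels[disc_mask(shape, pixel_size_mm, (0.0, 0.0), outer_r)] = 1
    legend = {0: "background", 1: "cylinder_background"}
    assigned = {0: 0.0, 1: float(background_counts)}
    area = np.pi * cyl_r**2
    for k, (center, counts) in enumerate(zip(centers, cylinder_counts)):
        mask = nearest_area_mask(shape, pixel_size_mm, center, area)
        if np.any(labels[mask] >= 2):
            raise ValueError(f"cylinder {k} overlaps a previously placed cylinder")
        labels[mask] = 2 + k
        legend[2 + k] = f"cylinder_{k}"
        assigned[2 + k] = float(counts)
    seg = SegmentMap(labels, legend, assigned, pixel_size_mm)
    return seg.to_image(), seg


# Parametric striatal-brain geometry (mm).  The anatomy is illustrative: only
# the four count levels and the striatum/parenchyma ratio of 8 are fixed by
# the study conditions.
_SDB_PARENCHYMA_SEMI = (85.0, 65.0)
_SDB_BONE_THICKNESS = 6.0
_SDB_VENTRICLE_SEMI = (15.0, 10.0)
_SDB_STRIATUM_BODY_SEMI = (6.0, 14.0)
_SDB_STRIATUM_BODY_CENTER = (22.0, -2.0)  # (|x|, y)
_SDB_STRIATUM_HEAD_RADIUS = 6.0
_SDB_STRIATUM_HEAD_CENTER = (20.0, 8.0)  # (|x|, y)


def _sdb_slice(shape, pixel_size_mm):
    labels = np.zeros(shape, dtype=np.int32)
    a, b = _SDB_PARENCHYMA_SEMI
    t = _SDB_BONE_THICKNESS
    bone = ellipse_mask(shape, pixel_size_mm, (0, 0), (a + t, b + t))
    par = ellipse_mask(shape, pixel_size_mm, (0, 0), (a, b))
    labels[bone] = 1
    labels[par] = 2
    labels[ellipse_mask(shape, pixel_size_mm, (0, 0), _SDB_VENTRICLE_SEMI)] = 3
    bx, by = _SDB_STRIATUM_BODY_CENTER
    hx, hy = _SDB_STRIATUM_HEAD_CENTER
    striatum = np.zeros(shape, dtype=bool)
    for sign in (-1.0, 1.0):
        striatum |= ellipse_mask(shape, pixel_size_mm, (sign * bx, by), _SDB_STRIATUM_BODY_SEMI)
        striatum |= disc_mask(shape, pixel_size_mm, (sign * hx, hy), _SDB_STRIATUM_HEAD_RADIUS)
    if np.any(~par[striatum]):
        raise ValueError("striatum extends outside the brain parenchyma")
    labels[striatum] = 4
    return labels


def make_sdb_phantom(matrix_size: int = 128, pixel_size_mm: float = 3.2, n_slices: int = 1):
    """Striatal digital brain phantom (parametric stand-in).

    Elliptical brain parenchyma at 100 counts/pixel inside a 6 mm skull-bone
    shell at 20, a central ventricle at 0, and bilateral comma-shaped striata
    (elliptical body plus anterior head) at 800 counts/pixel — a
    striatum-to-parenchyma count ratio of exactly 8.  ``n_slices`` > 1
    extrudes the cross-section into a 3D stack (slice thickness = pixel
    size); ``n_slices = 1`` returns the 2D special case.

    Returns
    -------
    (ImageGrid, SegmentMap)
        Segment ids: 0 air, 1 bone, 2 parenchyma, 3 ventricle, 4 striatum.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be at least 1")
    shape = (matrix_size, matrix_size)
    plane = _sdb_slice(shape, pixel_size_mm)
    labels = plane if n_slices == 1 else np.repeat(plane[None, :, :], n_slices, axis=0)
    legend = {0: "background", 1: "bone", 2: "parenchyma", 3: "ventricle", 4: "striatum"}
    assigned = {
        0: 0.0,
        1: SDB_COUNTS["bone"],
        2: SDB_COUNTS["parenchyma"],
        3: SDB_COUNTS["ventricle"],
        4: SDB_COUNTS["striatum"],
    }
    seg = SegmentMap(labels, legend, assigned, pixel_size_mm)
    return seg.to_image(), seg
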