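"""Particle analysis of the binarized crumb: cleaning, labeling, measuring.

A pore ("cell") is a connected foreground region of the binary mask.
The chain is: one pass of a 3x3 binary median filter to despeckle, connected
component labeling (8-connected by default), per-particle geometry in
physical units, then an aggregate summary shaped like the standard crumb
grain report (cell count, total area, average cell size, % area, min/max
cell area, mean cell periphery, and the two fractal descriptors).

Perimeter convention
--------------------
The perimeter is the length of the crack boundary (pixel edges exposed to
background), which is exact for axis-aligned rectangles: a 4x4-pixel square
at 1 mm/px has perimeter 16 mm and an L-tromino 8 mm. At junctions where two
pixels of the same particle touch only diagonally, the four unit cracks that
meet at the shared corner are replaced by two sqrt(2) diagonal segments, so
8-connected particles have a single finite boundary length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .thresholding import BinaryMask

__all__ = [
    "Particle",
    "PoreSummary",
    "DEFAULT_MIN_AREA_MM2",
    "remove_noise",
    "label_particles",
    "measure_particles",
    "summarize_pores",
]

#: smallest reportable cell area (mm^2); pores below this are treated as noise
DEFAULT_MIN_AREA_MM2 = 0.002

_STRUCTURE_8 = np.ones((3, 3), dtype=int)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class Particle:
    """One connected pore with pixel-level and physical geometry."""

    id: int
    pixel_count: int
    centroid: tuple[float, float]  # (row, col), pixel coordinates
    touches_border: bool
    slice_: tuple | None = None
    submask: np.ndarray | None = None  # particle's own pixels inside slice_
    area_mm2: float = float("nan")
    perimeter_mm: float = float("nan")
    dfp: float | None = None


@dataclass
class PoreSummary:
    """Aggregate crumb-grain report over the retained particles.

    ``None`` marks statistics that are undefined for an empty particle list
    (reported as not-available, never as zero).
    """

    cell_count: int
    total_area_mm2: float
    average_cell_size_mm2: float | None
    pct_area: float
    min_cell_area_mm2: float | None
    max_cell_area_mm2: float | None
    mean_cell_periphery_mm: float | None
    dfp_mean: float | None
    dft: float | None


def remove_noise(mask: BinaryMask) -> BinaryMask:
    """One pass of a 3x3 binary median filter (replicate-padded borders).

    Isolated foreground or background pixels vanish; solid regions and their
    interiors are preserved.
    """
    filtered = ndimage.median_filter(mask.bits, size=3, mode="nearest")
    return BinaryMask(bits=filtered, scale_mm_per_px=mask.scale_mm_per_px)


def label_particles(mask: BinaryMask, connectivity: int = 8) -> list[Particle]:
    """Label connected foreground components.

    Components are numbered in raster-scan order of their first pixel;
    ``connectivity`` is 8 (default: diagonal neighbors connect) or 4.
    """
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labels, n = ndimage.label(mask.bits, structure=structure)
    if n == 0:
        return []
    slices = ndimage.find_objects(labels)
    nrows, ncols = mask.bits.shape
    particles: list[Particle] = []
    order = _raster_order(labels, n)
    for new_id, lab in enumerate(order, start=1):
        sl = slices[lab - 1]
        sub = (labels[sl] == lab)
        count = int(sub.sum())
        rows, cols = np.nonzero(sub)
        centroid = (
            float(rows.mean() + sl[0].start),
            float(cols.mean() + sl[1].start),
        )
        touches = (
            sl[0].start == 0
            or sl[1].start == 0
            or sl[0].stop == nrows
            or sl[1].stop == ncols
        )
        particles.append(
            Particle(
                id=new_id,
                pixel_count=count,
                centroid=centroid,
                touches_border=touches,
                slice_=sl,
                submask=sub,
            )
        )
    return particles


def _raster_order(labels: np.ndarray, n: int) -> list[int]:
    """Labels sorted by flat index of each component's first pixel."""
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    first = np.full(n + 1, np.iinfo(np.int64).max, dtype=np.int64)
    # reversed so earlier flat indices overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    return sorted(range(1, n + 1), key=lambda lab: first[lab])


def _crack_perimeter_px(sub: np.ndarray) -> float:
    """Crack-boundary length in pixel units with diagonal corner cuts."""
    padded = np.pad(sub.astype(bool), 1, mode="constant", constant_values=False)
    fg = padded
    # exposed 4-neighbor edges
    exposed = (
        np.count_nonzero(fg[1:-1, 1:-1] & ~fg[:-2, 1:-1])
        + np.count_nonzero(fg[1:-1, 1:-1] & ~fg[2:, 1:-1])
        + np.count_nonzero(fg[1:-1, 1:-1] & ~fg[1:-1, :-2])
        + np.count_nonzero(fg[1:-1, 1:-1] & ~fg[1:-1, 2:])
    )
    # diagonal-only junctions: both diagonal pixels set, both shared
    # orthogonal neighbors clear
    a = padded
    d1 = a[:-1, :-1] & a[1:, 1:] & ~a[:-1, 1:] & ~a[1:, :-1]  # "\" pairs
    d2 = a[:-1, 1:] & a[1:, :-1] & ~a[:-1, :-1] & ~a[1:, 1:]  # "/" pairs
    n_diag = int(np.count_nonzero(d1) + np.count_nonzero(d2))
    return float(exposed) - 4.0 * n_diag + 2.0 * math.sqrt(2.0) * n_diag


def measure_particles(
    particles: list[Particle],
    scale_mm_per_px: float,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> list[Particle]:
    """Attach physical area/perimeter and drop particles below ``min_area_mm2``.

    ``area = pixel_count * scale^2``; the perimeter follows the crack-boundary
    convention in the module docstring. The default minimum (0.002 mm^2) is
    the smallest cell a crumb analysis typically reports.
    """
    if not scale_mm_per_px > 0:
        raise ParameterError("scale_mm_per_px must be positive")
    if min_area_mm2 < 0:
        raise ParameterError("min_area_mm2 must be non-negative")
    kept: list[Particle] = []
    for p in particles:
        area = p.pixel_count * scale_mm_per_px**2
        if area < min_area_mm2:
            continue
        p.area_mm2 = area
        p.perimeter_mm = _crack_perimeter_px(p.submask) * scale_mm_per_px
        kept.append(p)
    return kept


def summarize_pores(
    particles: list[Particle],
    field_area_mm2: float,
    dft: float | None = None,
) -> PoreSummary:
    """Aggregate measured particles into the crumb-grain summary.

    ``pct_area`` is relative to the analyzed field area. ``dft`` (texture
    fractal dimension) is computed by :mod:`crumbscan.fractal` and passed in;
    per-cell DFp values must already be attached (see
    :func:`crumbscan.fractal.attach_dfp`).
    """
    if not field_area_mm2 > 0:
        raise ParameterError("field_area_mm2 must be positive")
    if not particles:
        return PoreSummary(
            cell_count=0,
            total_area_mm2=0.0,
            average_cell_size_mm2=None,
            pct_area=0.0,
            min_cell_area_mm2=None,
            max_cell_area_mm2=None,
            mean_cell_periphery_mm=None,
            dfp_mean=None,
            dft=dft,
        )
    areas = np.array([p.area_mm2 for p in particles])
    perims = np.array([p.perimeter_mm for p in particles])
    dfps = [p.dfp for p in particles if p.dfp is not None]
    total = float(areas.sum())
    return PoreSummary(
        cell_count=len(particles),
        total_area_mm2=total,
        average_cell_size_mm2=total / len(particles),
        pct_area=total / field_area_mm2 * 100.0,
        min_cell_area_mm2=float(areas.min()),
        max_cell_area_mm2=float(areas.max()),
        mean_cell_periphery_mm=float(perims.mean()),
        dfp_mean=float(np.mean(dfps)) if dfps else None,
        dft=dft,
    )
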