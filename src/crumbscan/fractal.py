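"""Fractal descriptors of the pore structure.

Two quantities characterize boundary roughness and the size texture of the
crumb:

* per-cell perimeter-area fractal dimension
  ``DFp = 2 * log10(P / 4) / log10(A)`` with perimeter ``P`` in mm and area
  ``A`` in mm^2 (the formula is not unit-invariant, so the millimetre
  convention is frozen). Any axis-aligned square of side ``s != 1`` mm gives
  exactly 1; areas within 1e-6 of 1 mm^2 hit the ``log10(A) = 0`` singularity
  and are reported as undefined and excluded from means.

* texture fractal dimension ``DFt``, the least-squares slope of
  ``log10 N`` versus ``log10(1 / r)`` over multiple scales ``r``. Two
  variants: ``size_distribution`` (default) counts cells with area >= r over
  the grid of observed cell areas; ``box_counting`` counts occupied boxes of
  dyadic edge length r (in mm) over the mask. With exactly two scales the
  slope reduces to the closed-form two-point ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientScalesError, ParameterError
from .particles import Particle
from .thresholding import BinaryMask

__all__ = [
    "FractalResult",
    "cell_fractal_dimension",
    "attach_dfp",
    "texture_fractal_dimension",
]

#: |log10(area)| below which DFp is undefined (area ~ 1 mm^2 singularity)
_LOG_AREA_EPS = 1e-6


@dataclass(frozen=True)
class FractalResult:
    """Texture fractal dimension with its log-log fit diagnostics."""

    dfp_values: list[float | None]
    dfp_mean: float | None
    dft: float
    dft_method: str
    fit_points: list[tuple[float, float]]  # (r, N)


def cell_fractal_dimension(perimeter_mm: float, area_mm2: float) -> float | None:
    """Perimeter-area fractal dimension of a single cell, or None if undefined."""
    if not perimeter_mm > 0 or not area_mm2 > 0:
        raise ParameterError("perimeter and area must be positive")
    log_a = math.log10(area_mm2)
    if abs(log_a) < _LOG_AREA_EPS:
        return None
    return 2.0 * math.log10(perimeter_mm / 4.0) / log_a


def attach_dfp(particles: list[Particle]) -> list[Particle]:
    """Compute and store DFp on each measured particle (in place)."""
    for p in particles:
        p.dfp = cell_fractal_dimension(p.perimeter_mm, p.area_mm2)
    return particles


def _loglog_slope(r: np.ndarray, N: np.ndarray) -> float:
    """Least-squares slope of log10(N) against log10(1/r)."""
    x = np.log10(1.0 / r)
    y = np.log10(N)
    x = x - x.mean()
    return float(np.dot(x, y - y.mean()) / np.dot(x, x))


def _size_distribution_points(areas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    r = np.unique(areas)  # logarithmically spread in practice; observed grid
    N = np.array([(areas >= ri).sum() for ri in r], dtype=float)
    return r, N


def _box_counting_points(mask: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    bits = mask.bits.astype(bool)
    if not bits.any():
        raise InsufficientScalesError("empty mask has no boxes to count")
    nrows, ncols = bits.shape
    max_box = max(1, min(nrows, ncols) // 2)
    sizes = []
    b = 1
    while b <= max_box:
        sizes.append(b)
        b *= 2
    rs, Ns = [], []
    for b in sizes:
        pr = (-nrows) % b
        pc = (-ncols) % b
        padded = np.pad(bits, ((0, pr), (0, pc)))
        blocks = padded.reshape(padded.shape[0] // b, b, padded.shape[1] // b, b)
        occupied = int(blocks.any(axis=(1, 3)).sum())
        rs.append(b * mask.scale_mm_per_px)
        Ns.append(float(occupied))
    return np.asarray(rs, dtype=float), np.asarray(Ns, dtype=float)


def texture_fractal_dimension(
    source: list[Particle] | BinaryMask,
    method: str = "size_distribution",
) -> FractalResult:
    """Texture fractal dimension DFt across size scales.

    Parameters
    ----------
    source
        Measured particles (for ``size_distribution``) or a binary mask (for
        ``box_counting``).
    method : {"size_distribution", "box_counting"}

    Raises
    ------
    InsufficientScalesError
        Fewer than two usable (r, N) points, e.g. all cells the same size.
    """
    if method == "size_distribution":
        if isinstance(source, BinaryMask):
            raise ParameterError("size_distribution requires measured particles")
        areas = np.array([p.area_mm2 for p in source], dtype=float)
        if areas.size == 0:
            raise InsufficientScalesError("no particles")
        r, N = _size_distribution_points(areas)
        dfp_values = [p.dfp for p in source]
    elif method == "box_counting":
        if not isinstance(source, BinaryMask):
            raise ParameterError("box_counting requires a BinaryMask")
        r, N = _box_counting_points(source)
        dfp_values = []
    else:
        raise ParameterError("method must be 'size_distribution' or 'box_counting'")

    usable = N > 0
    r, N = r[usable], N[usable]
    if len(np.unique(r)) < 2:
        raise InsufficientScalesError(
            f"only {len(np.unique(r))} usable scale(s); need at least 2"
        )
    dft = _loglog_slope(r, N)
    defined = [v for v in dfp_values if v is not None]
    return FractalResult(
        dfp_values=dfp_values,
        dfp_mean=float(np.mean(defined)) if defined else None,
        dft=dft,
        dft_method=method,
        fit_points=list(zip(r.tolist(), N.tolist())),
    )
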