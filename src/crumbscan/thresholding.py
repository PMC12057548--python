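"""Global histogram thresholding of 8-bit crumb images.

A crumb photograph is reduced to its 256-bin intensity histogram and a single
gray-level cutoff ``T`` is chosen by one of five classical criteria:

``otsu``
    maximize the between-class variance ``P(T)(1-P(T))(mu_f - mu_b)^2``;
``isodata``
    fixed point of ``T -> round((mean_below(T) + mean_above(T)) / 2)``
    (Ridler-Calvard iterative selection);
``maxentropy``
    maximize the sum of Shannon entropies of the two normalized class
    distributions (Kapur);
``huang``
    minimize the histogram-weighted fuzzy Shannon entropy with membership
    ``1 / (1 + |g - class_mean| / C)`` (Huang-Wang);
``intermodes``
    smooth the histogram with a 3-point running mean until exactly two local
    maxima ``j < k`` remain, then ``T = floor((j + k) / 2)``
    (Prewitt-Mendelsohn).

Pixels with intensity ``<= T`` form the below class; ties in any objective are
broken toward the lowest qualifying ``T`` so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoSeparationError, NotBimodalError, ParameterError

__all__ = [
    "GrayImage",
    "BinaryMask",
    "IntensityHistogram",
    "ThresholdResult",
    "THRESHOLD_METHODS",
    "build_histogram",
    "compute_threshold",
    "binarize",
]

THRESHOLD_METHODS = ("huang", "maxentropy", "intermodes", "isodata", "otsu")

#: maximum 3-point smoothing passes before Intermodes gives up
_INTERMODES_MAX_PASSES = 10_000


@dataclass(frozen=True)
class GrayImage:
    """2-D grid of 8-bit intensities with a physical scale.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (rows, cols)
        Gray levels in [0, 255].
    scale_mm_per_px : float
        Physical edge length of one pixel in millimetres.
    """

    pixels: np.ndarray
    scale_mm_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError("pixels must be a non-empty 2-D array")
        if px.dtype != np.uint8:
            if np.any((px < 0) | (px > 255)):
                raise ParameterError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.scale_mm_per_px > 0:
            raise ParameterError("scale_mm_per_px must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_area_mm2(self) -> float:
        """Physical area of the full raster in mm^2."""
        return self.pixels.size * self.scale_mm_per_px**2


@dataclass(frozen=True)
class BinaryMask:
    """0/1 foreground mask sharing the image's physical scale."""

    bits: np.ndarray
    scale_mm_per_px: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bits)
        if b.ndim != 2 or b.size == 0:
            raise ParameterError("bits must be a non-empty 2-D array")
        if not np.isin(b, (0, 1)).all():
            raise ParameterError("mask values must be strictly 0/1")
        if not self.scale_mm_per_px > 0:
            raise ParameterError("scale_mm_per_px must be positive")
        object.__setattr__(self, "bits", b.astype(np.uint8))

    @property
    def foreground_count(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class IntensityHistogram:
    """256-bin count histogram of an 8-bit image."""

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (256,) or np.any(c < 0):
            raise ParameterError("counts must be 256 non-negative integers")
        if int(c.sum()) != self.total or self.total <= 0:
            raise ParameterError("total must equal the sum of counts and be positive")
        object.__setattr__(self, "counts", c)

    @property
    def occupied(self) -> np.ndarray:
        """Sorted gray levels with non-zero count."""
        return np.flatnonzero(self.counts)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.total


@dataclass(frozen=True)
class ThresholdResult:
    """Chosen threshold plus per-method diagnostics.

    ``objective[t]`` is the criterion value at candidate ``t`` for the scan
    methods (NaN where the candidate is infeasible); ``iterations`` counts
    IsoData fixed-point steps; ``smoothing_passes`` counts Intermodes
    smoothing iterations.
    """

    method: str
    T: int
    objective: np.ndarray | None = None
    iterations: int = 0
    smoothing_passes: int = 0
    diagnostics: dict = field(default_factory=dict)


def build_histogram(image: GrayImage) -> IntensityHistogram:
    """Count pixels per gray level g in [0, 255]."""
    counts = np.bincount(image.pixels.ravel(), minlength=256)
    return IntensityHistogram(counts=counts, total=int(image.pixels.size))


def _class_stats(counts: np.ndarray):
    """Cumulative pixel count and intensity mass of the class g <= T, for all T.

    Returns (n_below[T], s_below[T], n_total, s_total); class g > T follows by
    complement.
    """
    g = np.arange(256, dtype=np.float64)
    n_below = np.cumsum(counts).astype(np.float64)
    s_below = np.cumsum(counts * g)
    return n_below, s_below, n_below[-1], s_below[-1]


def _otsu(hist: IntensityHistogram) -> ThresholdResult:
    counts = hist.counts.astype(np.float64)
    n_below, s_below, n, s = _class_stats(counts)
    # candidates T where both classes are non-empty
    P = n_below / n
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_below = s_below / n_below
        mu_above = (s - s_below) / (n - n_below)
        sigma_b2 = P * (1.0 - P) * (mu_below - mu_above) ** 2
    sigma_b2[(n_below == 0) | (n_below == n)] = np.nan
    T = int(np.nanargmax(sigma_b2))  # argmax returns first (lowest) maximizer
    return ThresholdResult(method="otsu", T=T, objective=sigma_b2)


def _isodata(hist: IntensityHistogram) -> ThresholdResult:
    counts = hist.counts.astype(np.float64)
    n_below, s_below, n, s = _class_stats(counts)
    lo, hi = int(hist.occupied[0]), int(hist.occupied[-1])
    T = int(round(s / n))  # start at the rounded global mean
    # keep both classes non-empty: clamp into [lo, hi)
    T = min(max(T, lo), hi - 1)
    iterations = 0
    while True:
        iterations += 1
        nb = n_below[T]
        mu_below = s_below[T] / nb if nb > 0 else float(lo)
        na = n - nb
        mu_above = (s - s_below[T]) / na if na > 0 else float(hi)
        T_next = int(round((mu_below + mu_above) / 2.0))
        T_next = min(max(T_next, lo), hi - 1)
        if T_next == T or iterations > 256:
            break
        T = T_next
    return ThresholdResult(method="isodata", T=T, iterations=iterations)


def _maxentropy(hist: IntensityHistogram) -> ThresholdResult:
    p = hist.probabilities
    P_below = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H_below_raw = np.cumsum(plogp)  # sum p log p over g <= T
    H_total = H_below_raw[-1]
    obj = np.full(256, np.nan)
    for T in range(256):
        pb = P_below[T]
        pa = 1.0 - pb
        if pb <= 0 or pa <= 0:
            continue  # a class with zero probability is skipped
        # entropy of normalized class distributions
        H_b = np.log(pb) - H_below_raw[T] / pb
        H_a = np.log(pa) - (H_total - H_below_raw[T]) / pa
        obj[T] = H_b + H_a
    T = int(np.nanargmax(obj))
    return ThresholdResult(method="maxentropy", T=T, objective=obj)


def _huang(hist: IntensityHistogram) -> ThresholdResult:
    counts = hist.counts.astype(np.float64)
    n_below, s_below, n, s = _class_stats(counts)
    lo, hi = int(hist.occupied[0]), int(hist.occupied[-1])
    C = float(hi - lo)  # occupied intensity range; padding empty bins is inert
    g = np.arange(256, dtype=np.float64)
    obj = np.full(256, np.nan)
    for T in range(lo, hi):
        nb = n_below[T]
        na = n - nb
        if nb == 0 or na == 0:
            continue
        mu_b = s_below[T] / nb
        mu_a = (s - s_below[T]) / na
        mu_class = np.where(g <= T, mu_b, mu_a)
        membership = 1.0 / (1.0 + np.abs(g - mu_class) / C)
        m = np.clip(membership, 1e-12, 1.0 - 1e-12)
        S = -m * np.log(m) - (1.0 - m) * np.log(1.0 - m)
        S[membership >= 1.0 - 1e-12] = 0.0  # S(1) = 0 by convention
        obj[T] = float(np.dot(S, counts))
    T = int(np.nanargmin(obj))
    return ThresholdResult(method="huang", T=T, objective=obj)


def _local_maxima(h: np.ndarray) -> np.ndarray:
    """Indices i with h[i-1] < h[i] >= h[i+1] and h[i] > next distinct right value.

    Plateaus count once (at their left edge); the array is conceptually padded
    with -inf on both sides.
    """
    maxima = []
    i = 0
    n = len(h)
    while i < n:
        j = i
        while j + 1 < n and h[j + 1] == h[i]:
            j += 1
        left = h[i - 1] if i > 0 else -np.inf
        right = h[j + 1] if j + 1 < n else -np.inf
        if h[i] > left and h[i] > right and h[i] > 0:
            maxima.append(i)
        i = j + 1
    return np.asarray(maxima, dtype=int)


def _intermodes(hist: IntensityHistogram) -> ThresholdResult:
    occupied = hist.occupied
    if len(occupied) == 2:
        # two occupied levels are themselves the modes; smoothing adjacent
        # spikes could never separate them
        j, k = int(occupied[0]), int(occupied[1])
        return ThresholdResult(
            method="intermodes", T=(j + k) // 2, diagnostics={"modes": (j, k)}
        )
    h = hist.counts.astype(np.float64)
    passes = 0
    while True:
        maxima = _local_maxima(h)
        if len(maxima) == 2:
            break
        if len(maxima) < 2 or passes >= _INTERMODES_MAX_PASSES:
            raise NotBimodalError(
                f"histogram did not become bimodal after {passes} smoothing passes"
            )
        # 3-point running mean, edges replicate
        padded = np.pad(h, 1, mode="edge")
        h = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
        passes += 1
    j, k = int(maxima[0]), int(maxima[1])
    T = (j + k) // 2
    return ThresholdResult(
        method="intermodes", T=T, smoothing_passes=passes, diagnostics={"modes": (j, k)}
    )


_DISPATCH = {
    "otsu": _otsu,
    "isodata": _isodata,
    "maxentropy": _maxentropy,
    "huang": _huang,
    "intermodes": _intermodes,
}


def compute_threshold(hist: IntensityHistogram, method: str) -> ThresholdResult:
    """Choose a global threshold from a 256-bin histogram.

    Parameters
    ----------
    hist : IntensityHistogram
    method : {"huang", "maxentropy", "intermodes", "isodata", "otsu"}

    Returns
    -------
    ThresholdResult
        ``T`` always lies in ``[lowest occupied bin, highest occupied bin)``.

    Raises
    ------
    NoSeparationError
        If fewer than two gray levels are occupied.
    NotBimodalError
        If Intermodes smoothing cannot reach a two-mode histogram.
    """
    if method not in _DISPATCH:
        raise ParameterError(
            f"unknown method {method!r}; expected one of {THRESHOLD_METHODS}"
        )
    occupied = hist.occupied
    if len(occupied) < 2:
        raise NoSeparationError(
            "histogram has a single occupied gray level; no threshold separates it"
        )
    result = _DISPATCH[method](hist)
    lo, hi = int(occupied[0]), int(occupied[-1])
    # clamp pathological iterative exits into the valid half-open range
    T = min(max(result.T, lo), hi - 1)
    if T != result.T:
        result = ThresholdResult(
            method=result.method,
            T=T,
            objective=result.objective,
            iterations=result.iterations,
            smoothing_passes=result.smoothing_passes,
            diagnostics=result.diagnostics,
        )
    return result


def binarize(image: GrayImage, T: int, polarity: str = "dark") -> BinaryMask:
    """Split pixels at threshold ``T``.

    ``polarity="dark"`` (default) marks intensity <= T as foreground — pores
    are the dark class in crumb photographs; ``"bright"`` marks intensity > T.
    """
    if not 0 <= T <= 255:
        raise ParameterError("T must lie in [0, 255]")
    if polarity == "dark":
        bits = (image.pixels <= T).astype(np.uint8)
    elif polarity == "bright":
        bits = (image.pixels > T).astype(np.uint8)
    else:
        raise ParameterError("polarity must be 'dark' or 'bright'")
    return BinaryMask(bits=bits, scale_mm_per_px=image.scale_mm_per_px)
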