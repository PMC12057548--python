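"""Synthetic crumb images and digestion profiles with known ground truth.

Real crumb photographs show dark pores in a brighter matrix, giving a
bimodal gray-level histogram. The image generator emulates exactly that:
rasterized disks with lognormal radii at uniform random centers form the
pore mask, each pixel then receives Gaussian gray noise around its class
mean, optionally followed by Gaussian blur and salt-and-pepper speckle. The
ground-truth mask is captured *before* any noise, so recovery of pore count
and area by the thresholding + particle-analysis chain can be scored
exactly.

The digestion generator emulates an in-vitro glucose-release time course
with first-order kinetics,

    glucose(t) = FG + C_inf * (1 - exp(-k t)) + noise,

sampled at 20 and 120 min plus a 30-min grid to 180 min; the noise-free
ground-truth starch fractions are returned alongside the (possibly noisy)
profile.

``load_reference_tables`` packages the published quality measurements for
gluten-free cakes made with maize, rice, potato and horse-chestnut
(alkaline / ultrasound-assisted) starches — CIELAB crumb/crust triplets,
baked weights and volumes, storage hardness, and starch fractions — used as
worked-value fixtures throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .nutrition import DigestionProfile, StarchFractions, starch_fractions
from .thresholding import BinaryMask, GrayImage

__all__ = [
    "CrumbSynthParams",
    "GroundTruth",
    "DigestionSynthParams",
    "generate_crumb_image",
    "generate_digestion_profile",
    "load_reference_tables",
    "SAMPLES",
]

#: default pixel scale: a 30 mm field of view at ~667 px across
DEFAULT_SCALE_MM_PER_PX = 0.045

#: sampling grid for digestion: 30-min grid to 180 plus the 20/120 min draws
DEFAULT_DIGESTION_TIMES = (0.0, 20.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)

SAMPLES = ("maize", "rice", "potato", "a_hcs", "u_hcs")


@dataclass(frozen=True)
class CrumbSynthParams:
    """Parameters of the synthetic crumb image.

    Radii are lognormal in millimetres (``exp(pore_radius_log_mean)`` is the
    median radius); gray levels are 8-bit. Defaults emulate a 30 mm x 30 mm
    crumb field with a few hundred pores covering roughly a fifth of the
    area, the regime reported for starch-based cakes.
    """

    image_size_px: tuple[int, int] = (667, 667)
    scale_mm_per_px: float = DEFAULT_SCALE_MM_PER_PX
    n_pores: int = 400
    pore_radius_log_mean: float = -0.8  # median radius ~0.45 mm
    pore_radius_log_sd: float = 0.4
    matrix_gray_mean: float = 170.0
    pore_gray_mean: float = 80.0
    gray_sd: float = 10.0
    blur_sigma_px: float = 0.0
    speckle_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ParameterError("image_size_px must be positive")
        if not self.scale_mm_per_px > 0:
            raise ParameterError("scale_mm_per_px must be positive")
        if self.n_pores < 0:
            raise ParameterError("n_pores must be non-negative")
        if not self.pore_gray_mean < self.matrix_gray_mean:
            raise ParameterError("pores must be darker than the matrix")
        for name in ("matrix_gray_mean", "pore_gray_mean"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ParameterError(f"{name} must lie in [0, 255]")
        if self.gray_sd < 0 or self.blur_sigma_px < 0:
            raise ParameterError("gray_sd and blur_sigma_px must be non-negative")
        if not 0 <= self.speckle_fraction <= 1:
            raise ParameterError("speckle_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Pre-noise pore mask and its exact component statistics."""

    pore_mask: BinaryMask
    true_count: int
    true_total_area_mm2: float
    true_mean_area_mm2: float


def generate_crumb_image(params: CrumbSynthParams) -> tuple[GrayImage, GroundTruth]:
    """Draw a synthetic crumb photograph and its ground truth.

    Overlapping disks merge; the ground truth counts 8-connected components
    of the final mask, which is what particle analysis can observe.
    Identical seeds and parameters give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    scale = params.scale_mm_per_px

    # Pores thinner than ~3 px and walls thinner than ~2 px are below the
    # imaging resolution and cannot be represented faithfully; radii are
    # floored at 3 px, and a disk that would leave a sub-resolution wall to
    # an earlier pore is redrawn so pores either overlap by >= 3 px depth or
    # keep a >= 3 px wall (ground truth stays exact either way).
    min_radius_px = 3.0
    mask = np.zeros((h, w), dtype=np.uint8)
    if params.n_pores > 0:
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        placed_r: list[float] = []
        placed_c: list[float] = []
        placed_rad: list[float] = []
        placed = 0
        attempts = 0
        max_attempts = max(100, 50 * params.n_pores)
        while placed < params.n_pores and attempts < max_attempts:
            attempts += 1
            cr = rng.uniform(0, h)
            cc = rng.uniform(0, w)
            r_px = max(
                rng.lognormal(params.pore_radius_log_mean, params.pore_radius_log_sd)
                / scale,
                min_radius_px,
            )
            if placed_rad:
                d = np.hypot(np.array(placed_r) - cr, np.array(placed_c) - cc)
                sep = d - (np.array(placed_rad) + r_px)
                if np.any((-3.0 < sep) & (sep < 3.0)):
                    continue  # sub-resolution wall or grazing contact: redraw
            placed_r.append(cr)
            placed_c.append(cc)
            placed_rad.append(r_px)
            placed += 1
            r0 = max(0, int(np.floor(cr - r_px)) - 1)
            r1 = min(h, int(np.ceil(cr + r_px)) + 2)
            c0 = max(0, int(np.floor(cc - r_px)) - 1)
            c1 = min(w, int(np.ceil(cc + r_px)) + 2)
            rr = rows[r0:r1] - cr
            cc_ = cols[:, c0:c1] - cc
            inside = rr * rr + cc_ * cc_ <= r_px * r_px  # center-in-circle test
            mask[r0:r1, c0:c1] |= inside.astype(np.uint8)

    pore_mask = BinaryMask(bits=mask, scale_mm_per_px=scale)
    n_components = int(ndimage.label(mask, structure=np.ones((3, 3)))[1])
    total_area = float(mask.sum()) * scale**2
    truth = GroundTruth(
        pore_mask=pore_mask,
        true_count=n_components,
        true_total_area_mm2=total_area,
        true_mean_area_mm2=total_area / n_components if n_components else 0.0,
    )

    img = np.where(mask == 1, params.pore_gray_mean, params.matrix_gray_mean).astype(
        float
    )
    if params.gray_sd > 0:
        img += rng.normal(0.0, params.gray_sd, size=img.shape)
    if params.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, sigma=params.blur_sigma_px)
    if params.speckle_fraction > 0:
        hit = rng.random(img.shape) < params.speckle_fraction
        img[hit] = np.where(rng.random(img.shape) < 0.5, 0.0, 255.0)[hit]
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(pixels=img, scale_mm_per_px=scale), truth


@dataclass(frozen=True)
class DigestionSynthParams:
    """First-order glucose-release kinetics (g/100 g; k per minute).

    ``C_inf`` is the asymptotic digested glucose above the free glucose FG;
    total glucose is ``FG + C_inf``. Defaults give fractions in the range
    reported for starch-based gluten-free cakes (RAG ~ 42, SDS ~ 9).
    """

    FG: float = 0.65
    C_inf: float = 55.0
    k: float = 0.07
    times: tuple[float, ...] = DEFAULT_DIGESTION_TIMES
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.FG < 0:
            raise ParameterError("FG must be non-negative")
        if not self.C_inf > 0:
            raise ParameterError("C_inf must be positive")
        if not self.k > 0:
            raise ParameterError("rate k must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        t = np.asarray(self.times, dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing")
        if t[0] != 0 or t[-1] != 180:
            raise ParameterError("times must start at 0 and end at 180")
        for required in (20.0, 120.0):
            if required not in t:
                raise ParameterError(f"times must include {required:g} min")


def generate_digestion_profile(
    params: DigestionSynthParams,
) -> tuple[DigestionProfile, StarchFractions]:
    """Simulate one digestion time course.

    Returns the (possibly noisy) measured profile and the *noise-free*
    ground-truth starch fractions computed by the same formulas the analysis
    applies, so a noise-free round trip is an exact identity.
    """
    rng = np.random.default_rng(params.seed)
    t = np.asarray(params.times, dtype=float)
    glucose_true = params.FG + params.C_inf * (1.0 - np.exp(-params.k * t))
    TG = params.FG + params.C_inf

    def at(time: float, series: np.ndarray) -> float:
        return float(series[np.where(t == time)[0][0]])

    truth_profile = DigestionProfile(
        FG=params.FG, TG=TG, G20=at(20.0, glucose_true), G120=at(120.0, glucose_true)
    )
    truth = starch_fractions(truth_profile)

    glucose = glucose_true.copy()
    if params.noise_sd > 0:
        glucose = glucose + rng.normal(0.0, params.noise_sd, size=glucose.shape)
        glucose = np.clip(glucose, params.FG, TG)
        glucose = np.maximum.accumulate(glucose)  # keep the release monotone

    # percent of total starch digested, the curve used for HI
    pct = (glucose - params.FG) / (TG - params.FG) * 100.0
    pct = np.clip(pct, 0.0, 100.0)
    if params.noise_sd == 0:
        pct[0] = 0.0  # exp(0) term: exact zero at t=0
    profile = DigestionProfile(
        FG=params.FG,
        TG=TG,
        G20=at(20.0, glucose),
        G120=at(120.0, glucose),
        curve=list(zip(t.tolist(), pct.tolist())),
    )
    return profile, truth


# --------------------------------------------------------------------------
# Published worked-value tables (gluten-free cakes from five starches)
# --------------------------------------------------------------------------

_REFERENCE_TABLES: dict[str, dict] = {
    # CIELAB (L*, a*, b*); the rice-starch cake is the dE reference sample
    "crumb_color": {
        "maize": (74.5, -3.9, 22.9),
        "rice": (68.8, -3.7, 24.8),
        "potato": (70.0, -4.0, 21.6),
        "a_hcs": (71.1, -3.5, 23.6),
        "u_hcs": (70.7, -3.5, 24.1),
    },
    "crust_color": {
        "maize": (55.7, 13.0, 38.6),
        "rice": (56.7, 13.5, 40.7),
        "potato": (66.2, 9.7, 45.9),
        "a_hcs": (61.2, 13.9, 38.1),
        "u_hcs": (60.3, 13.7, 37.8),
    },
    "delta_e_crumb": {"maize": 6.01, "potato": 3.43, "a_hcs": 2.60, "u_hcs": 2.03},
    "delta_e_crust": {"maize": 2.38, "potato": 11.48, "a_hcs": 5.21, "u_hcs": 4.63},
    "browning_index": {
        "maize": 130.5,
        "rice": 138.1,
        "potato": 124.86,
        "a_hcs": 134.2,
        "u_hcs": 132.1,
    },
    "batter_weight_g": 150.0,
    "baked_weight_g": {
        "maize": 134.0,
        "rice": 136.0,
        "potato": 131.2,
        "a_hcs": 132.7,
        "u_hcs": 133.5,
    },
    "volume_cm3": {
        "maize": 340.5,
        "rice": 309.6,
        "potato": 284.5,
        "a_hcs": 317.8,
        "u_hcs": 321.6,
    },
    "specific_volume": {
        "maize": 2.55,
        "rice": 2.29,
        "potato": 2.18,
        "a_hcs": 2.40,
        "u_hcs": 2.42,
    },
    "weight_loss_pct": {
        "maize": 11.0,
        "rice": 9.7,
        "potato": 12.5,
        "a_hcs": 11.8,
        "u_hcs": 11.5,
    },
    # day-0 hardness is published for the extremes of the range
    "hardness_day0": {"maize": 57.11, "a_hcs": 38.12},
    "hardness_day28": {
        "maize": 68.41,
        "rice": 53.36,
        "potato": 54.60,
        "a_hcs": 50.13,
        "u_hcs": 61.22,
    },
    "hardness_rate_N_per_day": {
        "maize": 0.40,
        "rice": 0.47,
        "potato": 0.54,
        "a_hcs": 0.43,
        "u_hcs": 0.77,
    },
    "starch_fractions": {
        "maize": {"RAG": 41.89, "RDS": 37.12, "SDS": 8.80, "SHI": 82.13, "pGI": 79.88},
        "rice": {"RAG": 46.98, "RDS": 41.57, "SDS": 7.85, "SHI": 83.14, "pGI": 80.46},
        "potato": {"RAG": 38.12, "RDS": 35.23, "SDS": 7.12, "SHI": 80.16, "pGI": 78.48},
        "a_hcs": {"RAG": 42.13, "RDS": 37.71, "SDS": 8.65, "SHI": 82.31, "pGI": 79.41},
        "u_hcs": {"RAG": 40.24, "RDS": 32.76, "SDS": 8.12, "SHI": 81.49, "pGI": 78.95},
    },
}


def load_reference_tables() -> dict[str, dict]:
    """Bundled published quality measurements for the five cake samples.

    Keys: ``crumb_color``/``crust_color`` (CIELAB triplets), printed
    ``delta_e_crumb``/``delta_e_crust``/``browning_index``, batter and baked
    weights, volumes, specific volumes, weight-loss percentages, day-0/28
    hardness, hardness-increase rates, and the starch-fraction table. Sample
    keys are ``maize, rice, potato, a_hcs, u_hcs`` (a/u = alkaline /
    ultrasound-assisted horse-chestnut starch).
    """
    import copy

    return copy.deepcopy(_REFERENCE_TABLES)
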