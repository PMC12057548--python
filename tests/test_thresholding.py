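"""Histogram construction and the five global thresholding criteria."""

import numpy as np
import pytest

import crumbscan as cs
from crumbscan.thresholding import build_histogram, compute_threshold

from conftest import bimodal_histogram


def hist_from_counts(spec: dict) -> cs.IntensityHistogram:
    counts = np.zeros(256, dtype=int)
    for level, n in spec.items():
        counts[level] = n
    return cs.IntensityHistogram(counts=counts, total=int(counts.sum()))


def brute_force_otsu(counts: np.ndarray) -> int:
    """Independent oracle: exhaustive between-class variance maximization."""
    g = np.arange(256)
    best_T, best_val = None, -1.0
    total = counts.sum()
    for T in range(255):
        below = counts[: T + 1]
        above = counts[T + 1 :]
        nb, na = below.sum(), above.sum()
        if nb == 0 or na == 0:
            continue
        P = nb / total
        mu_b = (below * g[: T + 1]).sum() / nb
        mu_a = (above * g[T + 1 :]).sum() / na
        val = P * (1 - P) * (mu_b - mu_a) ** 2
        if val > best_val + 1e-12:
            best_val, best_T = val, T
    return best_T


class TestBuildHistogram:
    def test_constant_image(self):
        img = cs.GrayImage(np.full((2, 2), 7, dtype=np.uint8), 1.0)
        h = build_histogram(img)
        assert h.counts[7] == 4 and h.counts.sum() == 4

    def test_two_level_image(self):
        px = np.concatenate([np.full(100, 50), np.full(100, 200)]).reshape(20, 10)
        h = build_histogram(cs.GrayImage(px.astype(np.uint8), 1.0))
        assert h.counts[50] == 100 and h.counts[200] == 100

    def test_counts_conserve_pixels(self):
        rng = np.random.default_rng(0)
        px = rng.integers(0, 256, size=(37, 53), dtype=np.uint8)
        h = build_histogram(cs.GrayImage(px, 1.0))
        assert h.total == 37 * 53 == h.counts.sum()


class TestWorkedThresholds:
    def test_isodata_two_spikes(self, two_spike_hist):
        assert compute_threshold(two_spike_hist, "isodata").T == 125

    def test_otsu_two_spikes_lowest_tie(self, two_spike_hist):
        # all T in [50,199] tie at maximal variance; lowest wins
        assert compute_threshold(two_spike_hist, "otsu").T == 50

    def test_huang_two_spikes_zero_entropy_tie(self, two_spike_hist):
        # perfect separation: all memberships 1, fuzzy entropy 0; lowest tie
        r = compute_threshold(two_spike_hist, "huang")
        assert r.T == 50
        assert r.objective[50] == pytest.approx(0.0, abs=1e-9)

    def test_intermodes_two_spikes_midpoint(self, two_spike_hist):
        assert compute_threshold(two_spike_hist, "intermodes").T == 125

    def test_maxentropy_uniform(self):
        h = cs.IntensityHistogram(counts=np.full(256, 10), total=2560)
        # maximize ln(T+1) + ln(255-T) over integers -> 127
        assert compute_threshold(h, "maxentropy").T == 127

    def test_single_spike_raises_for_every_method(self):
        h = hist_from_counts({128: 500})
        for method in cs.THRESHOLD_METHODS:
            with pytest.raises(cs.NoSeparationError):
                compute_threshold(h, method)

    def test_unknown_method_rejected(self, two_spike_hist):
        with pytest.raises(cs.ParameterError):
            compute_threshold(two_spike_hist, "magic")


class TestProperties:
    def test_otsu_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1234)
        for _ in range(120):
            counts = rng.integers(0, 50, size=256)
            if (counts > 0).sum() < 2:
                counts[[10, 200]] = 5
            h = cs.IntensityHistogram(counts=counts, total=int(counts.sum()))
            assert compute_threshold(h, "otsu").T == brute_force_otsu(counts)

    @pytest.mark.parametrize("method", cs.THRESHOLD_METHODS)
    def test_two_level_perfect_separation(self, method):
        rng = np.random.default_rng(99)
        for _ in range(25):
            a, b = sorted(rng.choice(256, size=2, replace=False))
            if b - a < 2:
                continue
            h = hist_from_counts({int(a): int(rng.integers(1, 500)),
                                  int(b): int(rng.integers(1, 500))})
            T = compute_threshold(h, method).T
            assert a <= T < b

    @pytest.mark.parametrize("method", cs.THRESHOLD_METHODS)
    def test_threshold_in_occupied_range(self, method):
        rng = np.random.default_rng(5)
        for _ in range(20):
            h = bimodal_histogram(rng)
            lo, hi = h.occupied[0], h.occupied[-1]
            T = compute_threshold(h, method).T
            assert lo <= T < hi

    @pytest.mark.parametrize("method", cs.THRESHOLD_METHODS)
    @pytest.mark.parametrize("shift", [-15, 23])
    def test_shift_equivariance(self, method, shift):
        rng = np.random.default_rng(17)
        h = bimodal_histogram(rng, lo_mean=80, hi_mean=170)
        counts = np.zeros(256, dtype=int)
        occ = np.flatnonzero(h.counts)
        counts[occ + shift] = h.counts[occ]
        shifted = cs.IntensityHistogram(counts=counts, total=h.total)
        T0 = compute_threshold(h, method).T
        T1 = compute_threshold(shifted, method).T
        assert T1 == T0 + shift

    def test_isodata_fixed_point_is_self_consistent(self):
        rng = np.random.default_rng(3)
        h = bimodal_histogram(rng)
        T = compute_threshold(h, "isodata").T
        g = np.arange(256)
        c = h.counts
        mu_b = (c[: T + 1] * g[: T + 1]).sum() / c[: T + 1].sum()
        mu_a = (c[T + 1 :] * g[T + 1 :]).sum() / c[T + 1 :].sum()
        assert int(round((mu_b + mu_a) / 2)) == T


class TestBinarize:
    def test_dark_marks_low_levels(self):
        px = np.array([[50, 200], [200, 50]], dtype=np.uint8)
        img = cs.GrayImage(px, 1.0)
        mask = cs.binarize(img, 125, polarity="dark")
        assert np.array_equal(mask.bits, (px == 50).astype(np.uint8))

    def test_polarities_partition_the_image(self):
        rng = np.random.default_rng(11)
        px = rng.integers(0, 256, size=(30, 30), dtype=np.uint8)
        img = cs.GrayImage(px, 1.0)
        for T in (0, 77, 255):
            dark = cs.binarize(img, T, "dark")
            bright = cs.binarize(img, T, "bright")
            assert dark.foreground_count + bright.foreground_count == px.size
        assert cs.binarize(img, 255, "dark").foreground_count == px.size

    def test_bad_threshold_rejected(self):
        img = cs.GrayImage(np.zeros((2, 2), dtype=np.uint8), 1.0)
        with pytest.raises(cs.ParameterError):
            cs.binarize(img, 300)
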