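"""Starch fractions, glycemic-index prediction, color and texture indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import crumbscan as cs
from crumbscan.nutrition import GLUCOSE_TO_STARCH


def valid_profile(FG, d20, d120, dTG):
    """Build a valid profile from non-negative increments."""
    return cs.DigestionProfile(FG=FG, G20=FG + d20, G120=FG + d20 + d120,
                               TG=FG + d20 + d120 + dTG)


class TestStarchFractions:
    def test_worked_arithmetic(self):
        p = cs.DigestionProfile(FG=1.0, TG=51.0, G20=41.0, G120=50.0)
        f = cs.starch_fractions(p)
        assert f.TS == pytest.approx(45.0)
        assert f.RAG == pytest.approx(41.0)
        assert f.RDS == pytest.approx(36.0)
        assert f.SDS == pytest.approx(8.1)
        assert f.SHI == pytest.approx(80.0)

    def test_published_maize_row_implies_valid_free_glucose(self, tables):
        row = tables["starch_fractions"]["maize"]
        fg = cs.implied_free_glucose(row["RAG"], row["RDS"])
        assert fg == pytest.approx(0.646, abs=0.01)
        assert fg >= 0

    def test_published_potato_row_flags_negative_free_glucose(self, tables):
        row = tables["starch_fractions"]["potato"]
        fg = cs.implied_free_glucose(row["RAG"], row["RDS"])
        assert fg < 0
        with pytest.raises(cs.ProfileValidationError, match="FG"):
            cs.DigestionProfile(FG=fg, G20=row["RAG"], G120=50.0, TG=60.0)

    def test_degenerate_profile_rejected(self):
        p = cs.DigestionProfile(FG=5.0, G20=5.0, G120=5.0, TG=5.0)
        with pytest.raises(cs.DegenerateProfileError):
            cs.starch_fractions(p)

    def test_invalid_ordering_names_the_inequality(self):
        with pytest.raises(cs.ProfileValidationError, match="G20 <= G120"):
            cs.DigestionProfile(FG=1.0, G20=30.0, G120=20.0, TG=40.0)

    @given(
        FG=st.floats(0, 5),
        d20=st.floats(0.1, 50),
        d120=st.floats(0, 20),
        dTG=st.floats(0.1, 20),
    )
    @settings(max_examples=200, deadline=None)
    def test_rds_plus_sds_identity(self, FG, d20, d120, dTG):
        f = cs.starch_fractions(valid_profile(FG, d20, d120, dTG))
        p120 = FG + d20 + d120
        assert f.RDS + f.SDS == pytest.approx(
            GLUCOSE_TO_STARCH * (p120 - FG), rel=1e-12, abs=1e-12
        )


class TestHydrolysisIndex:
    reference = [(0.0, 0.0), (30.0, 40.0), (90.0, 70.0), (180.0, 90.0)]

    def test_identical_curve_gives_100(self):
        assert cs.hydrolysis_index(self.reference, self.reference) == pytest.approx(100)

    def test_scale_equivariance(self):
        half = [(t, 0.5 * y) for t, y in self.reference]
        assert cs.hydrolysis_index(half, self.reference) == pytest.approx(50.0)

    def test_zero_curve(self):
        zero = [(t, 0.0) for t, y in self.reference]
        assert cs.hydrolysis_index(zero, self.reference) == 0.0

    def test_zero_reference_rejected(self):
        zero = [(t, 0.0) for t, y in self.reference]
        with pytest.raises(cs.ParameterError):
            cs.hydrolysis_index(self.reference, zero)


class TestPredictedGI:
    def test_intercept_and_worked_values(self):
        assert cs.predicted_gi(0.0) == pytest.approx(39.71)
        assert cs.predicted_gi(100.0) == pytest.approx(94.61)
        # published maize pGI back-computes to HI = (79.88-39.71)/0.549
        assert cs.predicted_gi(73.17) == pytest.approx(79.88, abs=0.01)

    def test_affine_and_strictly_increasing(self):
        hi = np.linspace(0, 120, 13)
        pgi = np.array([cs.predicted_gi(h) for h in hi])
        assert np.all(np.diff(pgi) > 0)
        assert np.allclose(np.diff(pgi, 2), 0.0, atol=1e-12)

    def test_negative_hi_rejected(self):
        with pytest.raises(cs.ParameterError):
            cs.predicted_gi(-1.0)


class TestColor:
    def test_identical_triplets_give_zero(self):
        c = cs.ColorTriplet(50.0, 1.0, 2.0)
        assert cs.delta_e(c, c) == 0.0

    @given(
        st.tuples(st.floats(0, 100), st.floats(-40, 40), st.floats(-40, 40)),
        st.tuples(st.floats(0, 100), st.floats(-40, 40), st.floats(-40, 40)),
    )
    @settings(max_examples=100, deadline=None)
    def test_delta_e_is_symmetric_and_nonnegative(self, t1, t2):
        c1, c2 = cs.ColorTriplet(*t1), cs.ColorTriplet(*t2)
        d = cs.delta_e(c1, c2)
        assert d >= 0
        assert d == pytest.approx(cs.delta_e(c2, c1))
        if max(abs(a - b) for a, b in zip(t1, t2)) > 1e-6:
            assert d > 0

    def test_browning_index_worked_values(self, tables):
        rice_crust = cs.ColorTriplet(*tables["crust_color"]["rice"])
        # printed value 138.1 from 1-dp inputs; direct evaluation gives 138.26
        assert cs.browning_index(rice_crust) == pytest.approx(138.26, abs=0.01)
        assert cs.browning_index(cs.ColorTriplet(100, 0, 0)) == pytest.approx(
            100 * ((179 / 564.5) - 0.31) / 0.17, abs=1e-9
        )

    def test_browning_index_zero_denominator(self):
        # 5.645 L + a - 3.012 b == 0
        c = cs.ColorTriplet(L=3.012, a=0.0, b=5.645)
        with pytest.raises(cs.DegenerateColorError):
            cs.browning_index(c)

    def test_l_out_of_range_rejected(self):
        with pytest.raises(cs.ParameterError):
            cs.ColorTriplet(120.0, 0.0, 0.0)


class TestPhysical:
    def test_specific_volume(self, tables):
        assert cs.specific_volume(300.0, 150.0) == 2.0
        v = cs.specific_volume(tables["volume_cm3"]["a_hcs"],
                               tables["baked_weight_g"]["a_hcs"])
        assert v == pytest.approx(2.3949, abs=1e-4)
        with pytest.raises(cs.ParameterError):
            cs.specific_volume(300.0, 0.0)

    def test_weight_loss(self, tables):
        loss = cs.weight_loss(tables["batter_weight_g"],
                              tables["baked_weight_g"]["maize"])
        assert loss == pytest.approx(10.67, abs=0.01)
        assert cs.weight_loss(100.0, 100.0) == 0.0
        assert cs.weight_loss(100.0, 110.0) == -10.0  # negative loss as-is

    def test_hardness_rate(self, tables):
        series = cs.TextureSeries(
            day=[0, 28],
            hardness_N=[tables["hardness_day0"]["a_hcs"],
                        tables["hardness_day28"]["a_hcs"]],
        )
        assert cs.hardness_rate(series) == pytest.approx(0.43, abs=0.005)
        flat = cs.TextureSeries(day=[0, 7, 14], hardness_N=[40.0, 40.0, 40.0])
        assert cs.hardness_rate(flat) == 0.0
        with pytest.raises(cs.ParameterError):
            cs.hardness_rate(cs.TextureSeries(day=[0], hardness_N=[40.0]))
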