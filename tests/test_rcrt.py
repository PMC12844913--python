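import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from striplight import rcrt
from striplight.geometry import StripGeometry
from striplight.validation import seasonal_states

GEOM = StripGeometry(Wa=1.0, Wb=1.2, Ha=2.6, Hb=0.8)


class TestLayerLai:
    def test_worked_example(self):
        upper, lower = rcrt.layer_lai(2.6, 0.8, 3.0)
        assert upper == pytest.approx(2.0769, abs=1e-4)
        assert lower == pytest.approx(0.9231, abs=1e-4)

    @pytest.mark.parametrize("ha,hb,lai,expected", [
        (1.7, 1.7, 2.5, (0.0, 2.5)),   # equal heights: all maize in the shared layer
        (1.7, 0.0, 2.5, (2.5, 0.0)),   # no soybean: all maize above it
    ])
    def test_degenerate_heights(self, ha, hb, lai, expected):
        assert rcrt.layer_lai(ha, hb, lai) == pytest.approx(expected)

    def test_rejects_overtopping(self):
        with pytest.raises(ValueError):
            rcrt.layer_lai(0.8, 2.6, 3.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(ha=st.floats(0.1, 4.0), frac=st.floats(0.0, 1.0), lai=st.floats(0.0, 8.0))
    def test_conserves_total_lai(self, ha, frac, lai):
        upper, lower = rcrt.layer_lai(ha, frac * ha, lai)
        assert upper + lower == pytest.approx(lai, abs=1e-12)
        assert upper >= 0 and lower >= 0


class TestBlackViewFactor:
    @pytest.mark.parametrize("h,w,expected", [
        (0.0, 1.0, 1.0),
        (1.0, 1.0, math.sqrt(2) - 1),
        (1.8, 1.0, 0.25913),
        (1.8, 1.2, 0.30278),
    ])
    def test_values(self, h, w, expected):
        assert rcrt.black_view_factor(h, w) == pytest.approx(expected, abs=1e-5)

    def test_limits(self):
        assert rcrt.black_view_factor(100.0, 1.0) == pytest.approx(0.0, abs=1e-2)
        assert rcrt.black_view_factor(1.0, 100.0) == pytest.approx(1.0, abs=1e-2)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            rcrt.black_view_factor(1.0, 0.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(h=st.floats(0.0, 10.0), w=st.floats(0.05, 10.0), dh=st.floats(0.01, 2.0),
           dw=st.floats(0.01, 2.0))
    def test_bounds_and_monotonicity(self, h, w, dh, dw):
        v = rcrt.black_view_factor(h, w)
        assert 0.0 < v <= 1.0
        assert rcrt.black_view_factor(h + dh, w) <= v       # taller wall passes less
        assert rcrt.black_view_factor(h, w + dw) >= v       # wider gap passes more

    def test_strict_monotonicity_away_from_limits(self):
        assert rcrt.black_view_factor(1.5, 1.0) < rcrt.black_view_factor(1.0, 1.0)
        assert rcrt.black_view_factor(1.0, 1.5) > rcrt.black_view_factor(1.0, 1.0)


def test_view_factors_mapping():
    vf = rcrt.view_factors(GEOM)
    assert vf.Fia_black == pytest.approx(0.25913, abs=1e-5)
    assert vf.Fib_black == pytest.approx(0.30278, abs=1e-5)
    assert vf.Fiia_black == pytest.approx(rcrt.black_view_factor(0.8, 1.0))
    assert vf.Fiib_black == pytest.approx(rcrt.black_view_factor(0.8, 1.2))
    equal = rcrt.view_factors(StripGeometry(Wa=1.0, Wb=1.2, Ha=0.8, Hb=0.8))
    assert equal.Fia_black == equal.Fib_black == 1.0
    flat = rcrt.view_factors(StripGeometry(Wa=1.0, Wb=1.2, Ha=2.6, Hb=0.0))
    assert flat.Fiia_black == flat.Fiib_black == 1.0


class TestPartition:
    @pytest.mark.parametrize("variant", ["literal", "consistent"])
    def test_empty_canopy_intercepts_nothing(self, variant):
        p = rcrt.partition(GEOM, rcrt.CanopyState(0.0, 0.0), variant)
        assert all(v == 0.0 for v in p.fractions().values())
        assert p.Fa == 0.0 and p.Fb == 0.0

    def test_homogeneous_limit_matches_beer(self):
        # equal heights, equal k, uniform strip-local leaf area
        geom = StripGeometry(Wa=1.0, Wb=1.2, Ha=0.8, Hb=0.8)
        for lai_total in (0.5, 2.0, 5.0):
            canopy = rcrt.CanopyState(LAIa=lai_total * geom.fa, LAIb=lai_total * geom.fb,
                                      ka=0.5, kb=0.5)
            p = rcrt.partition(geom, canopy, "consistent")
            assert p.Fa + p.Fb == pytest.approx(1 - math.exp(-0.5 * lai_total), abs=0.05)

    def test_fb_nondecreasing_in_soy_lai(self):
        fbs = [rcrt.partition(GEOM, rcrt.CanopyState(2.0, lai)).Fb
               for lai in np.linspace(0.0, 2.5, 26)]
        assert all(b >= a - 1e-12 for a, b in zip(fbs, fbs[1:]))

    def test_species_totals_bounded_on_random_grid(self):
        for geom, canopy in seasonal_states(1000, seed=2):
            p = rcrt.partition(geom, canopy, "consistent")
            total = p.Fa + p.Fb
            assert 0.0 <= total <= 1.0
            assert all(0.0 <= v <= 1.0 for v in p.fractions().values())

    def test_totals_follow_printed_pathway_assignment(self):
        p = rcrt.partition(GEOM, rcrt.CanopyState(2.0, 1.5))
        assert p.Fa == pytest.approx(p.F1 + p.F2 + p.F3 + p.F4 + p.F5 + p.F9)
        assert p.Fb == pytest.approx(p.F6 + p.F7 + p.F8)

    def test_literal_variant_flags_clamped_values(self):
        # verbatim equations keep the printed LAIa/LAIb mix-up; with a large
        # maize LAI the literal shared terms are driven out of range or differ
        # from the corrected variant
        canopy = rcrt.CanopyState(2.5, 1.5)
        lit = rcrt.partition(GEOM, canopy, "literal")
        con = rcrt.partition(GEOM, canopy, "consistent")
        assert lit.variant == "literal" and con.variant == "consistent"
        assert lit.Fb != pytest.approx(con.Fb)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            rcrt.partition(GEOM, rcrt.CanopyState(1.0, 1.0), "bogus")


class TestMonoFraction:
    @pytest.mark.parametrize("lai,k,expected", [
        (0.0, 0.34, 0.0),
        (math.log(2) / 0.34, 0.34, 0.5),
        (3.0, 0.34, 0.63941),
    ])
    def test_values(self, lai, k, expected):
        assert rcrt.mono_fraction(lai, k) == pytest.approx(expected, abs=1e-5)

    def test_rejects_negative_lai(self):
        with pytest.raises(ValueError):
            rcrt.mono_fraction(-0.1)
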