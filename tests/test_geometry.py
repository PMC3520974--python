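"""Projection geometry, metric consistency and Monte-Carlo error propagation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colinshift import (
    DegenerateLineError,
    Peak2D,
    ShiftUncertainty,
    ccsp_matrix,
    combined_shift_delta,
    project_onto_line,
    project_onto_line_vector,
    propagate_ccsp_error,
)
from colinshift.peaks import Nucleus, ResonanceSeries

FREE = Peak2D(8.0, 120.0)
REF = Peak2D(8.5, 120.0)
OBS = Peak2D(8.2, 121.0)


class TestCombinedShiftDelta:
    def test_identity_is_zero(self):
        assert combined_shift_delta(FREE, FREE) == 0.0

    @pytest.mark.parametrize(
        "b, expected",
        [(Peak2D(8.3, 124.0), 0.5),   # dH=0.3, dN=4.0 -> sqrt(0.09+0.16)
         (Peak2D(8.0, 121.0), 0.1)],  # dH=0, dN=1.0 -> 0.1
    )
    def test_scaled_euclidean_examples(self, b, expected):
        assert combined_shift_delta(FREE, b) == pytest.approx(expected)

    def test_symmetric(self):
        assert combined_shift_delta(FREE, OBS) == combined_shift_delta(OBS, FREE)

    def test_nucleus_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            combined_shift_delta(FREE, Peak2D(8.2, 121.0, Nucleus.C13))


class TestProjection:
    def test_free_endpoint_gives_zero_percent(self):
        r = project_onto_line(FREE, REF, FREE)
        assert r.s == 0.0 and r.p == 0.0 and r.ccsp_percent == 0.0

    def test_reference_endpoint_gives_hundred_percent(self):
        r = project_onto_line(FREE, REF, REF)
        assert r.s == pytest.approx(r.z) and r.p == pytest.approx(0.0)
        assert r.ccsp_percent == pytest.approx(100.0)

    def test_worked_example(self):
        r = project_onto_line(FREE, REF, OBS)
        assert r.z == pytest.approx(0.5)
        assert r.x == pytest.approx(np.sqrt(0.05))
        assert r.y == pytest.approx(np.sqrt(0.10))
        assert r.s == pytest.approx(0.2)
        assert r.p == pytest.approx(0.1)
        assert r.ccsp_percent == pytest.approx(40.0)

    def test_midpoint_gives_fifty_percent_on_line(self):
        mid = Peak2D(8.25, 120.0)
        r = project_onto_line(FREE, REF, mid)
        assert r.ccsp_percent == pytest.approx(50.0) and r.p == pytest.approx(0.0)

    def test_beyond_endpoint_reported_not_clipped(self):
        beyond = Peak2D(8.7, 120.0)
        assert project_onto_line(FREE, REF, beyond).ccsp_percent == pytest.approx(140.0)
        before = Peak2D(7.9, 120.0)
        assert project_onto_line(FREE, REF, before).ccsp_percent == pytest.approx(-20.0)

    def test_degenerate_line_raises(self):
        with pytest.raises(DegenerateLineError):
            project_onto_line(FREE, FREE, OBS)

    def test_translation_invariance(self):
        def shift(p, dh, dn):
            return Peak2D(p.h_shift + dh, p.x_shift + dn)

        a = project_onto_line(FREE, REF, OBS)
        b = project_onto_line(shift(FREE, 0.7, -3.0), shift(REF, 0.7, -3.0),
                              shift(OBS, 0.7, -3.0))
        assert a.ccsp_percent == pytest.approx(b.ccsp_percent)
        assert a.p == pytest.approx(b.p)

    def test_reflection_invariance(self):
        def mirror(p):
            return Peak2D(-p.h_shift + 17.0, p.x_shift)

        a = project_onto_line(FREE, REF, OBS)
        b = project_onto_line(mirror(FREE), mirror(REF), mirror(OBS))
        assert a.ccsp_percent == pytest.approx(b.ccsp_percent)

    def test_nitrogen_scale_factor_config(self):
        # with x_scale 0.2 the dN=1.0 example doubles its contribution
        assert combined_shift_delta(FREE, Peak2D(8.0, 121.0), x_scale=0.2) \
            == pytest.approx(0.2)
        r = project_onto_line(FREE, REF, OBS, x_scale=0.2)
        s_vec = project_onto_line_vector(FREE, REF, OBS, x_scale=0.2)
        assert r.s == pytest.approx(s_vec[0], abs=1e-12)


coord = st.floats(min_value=-5.0, max_value=5.0, allow_nan=False)


@settings(max_examples=300, derandomize=True)
@given(fh=coord, fn=coord, rh=coord, rn=coord, oh=coord, on=coord)
def test_law_of_cosines_matches_vector_projection(fh, fn, rh, rn, oh, on):
    """The triangle-side formulas and the coordinate dot product agree."""
    free = Peak2D(8.0 + fh, 120.0 + fn)
    ref = Peak2D(8.0 + rh, 120.0 + rn)
    obs = Peak2D(8.0 + oh, 120.0 + on)
    # below ~1e-3 ppm the subtraction x^2 - s^2 cancels catastrophically;
    # such lines are far below the 0.03 ppm screening floor anyway
    if combined_shift_delta(free, ref) < 1e-3:
        return
    r = project_onto_line(free, ref, obs)
    s_vec, p_vec = project_onto_line_vector(free, ref, obs)
    assert abs(r.s - s_vec) < 1e-9
    # p = sqrt(x^2 - s^2) cancels to ~sqrt(eps)*x when the three peaks are
    # exactly collinear, so p gets a correspondingly looser tolerance
    assert abs(r.p - p_vec) < max(1e-9, 1e-7 * r.x)
    assert r.s ** 2 + r.p ** 2 == pytest.approx(r.x ** 2, abs=1e-9)


class TestErrorPropagation:
    def test_noise_free_limit(self):
        err = propagate_ccsp_error(FREE, REF, OBS, ShiftUncertainty(1e-9),
                                   seed=1)
        assert err < 1e-4

    def test_reproducible_under_seed(self):
        a = propagate_ccsp_error(FREE, REF, OBS, seed=42)
        b = propagate_ccsp_error(FREE, REF, OBS, seed=42)
        assert a == b
        assert a > 0

    def test_first_order_linearity_in_sigma(self):
        on_line = Peak2D(8.2, 120.0)  # 40% along a 0.5 ppm line
        e1 = propagate_ccsp_error(FREE, REF, on_line, ShiftUncertainty(0.0051),
                                  seed=7)
        e2 = propagate_ccsp_error(FREE, REF, on_line, ShiftUncertainty(0.0102),
                                  seed=7)
        assert 1.8 <= e2 / e1 <= 2.2

    def test_too_many_degenerate_draws_raises(self):
        tiny = Peak2D(8.0 + 1e-5, 120.0)
        with pytest.raises(ValueError, match="degenerate"):
            propagate_ccsp_error(FREE, tiny, OBS, ShiftUncertainty(0.01),
                                 seed=3)

    def test_minimum_draws_enforced(self):
        with pytest.raises(ValueError, match="1000"):
            propagate_ccsp_error(FREE, REF, OBS, n_draws=10)


class TestCcspMatrix:
    def _series(self):
        mk = lambda h, n: Peak2D(h, n)
        return [
            ResonanceSeries(9, "bb", mk(8.0, 120.0), mk(8.5, 120.0),
                            {"c1": mk(8.2, 120.0), "c2": mk(8.4, 120.0)}),
            ResonanceSeries(36, "bb", mk(7.5, 115.0), mk(7.9, 115.0),
                            {"c1": mk(7.7, 115.0), "c2": mk(7.8, 115.0)}),
            ResonanceSeries(36, "s", mk(6.8, 112.0), mk(7.0, 112.0),
                            {"c1": mk(6.9, 112.0)}),
        ]

    def test_full_table(self):
        m = ccsp_matrix(self._series())
        assert m.shape == (3, 2)
        assert m.loc["9", "c1"] == pytest.approx(40.0)

    def test_missing_peak_is_nan_not_error(self):
        m = ccsp_matrix(self._series())
        assert np.isnan(m.loc["36s", "c2"])

    def test_sidechain_selection_resolves_to_sidechain_series(self):
        m = ccsp_matrix(self._series(), selection={(36, "s")})
        assert list(m.index) == ["36s"]
        assert m.loc["36s", "c1"] == pytest.approx(50.0)

    def test_unknown_selection_raises(self):
        with pytest.raises(KeyError):
            ccsp_matrix(self._series(), selection={(99, "bb")})
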