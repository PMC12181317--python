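import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irclass.core import GridError, WavenumberGrid
from irclass.preprocessing import (
    PreprocessSpec,
    absorbance_from_single_beam,
    area_normalize,
    atmospheric_compensation,
    baseline_correct_two_point,
    minmax_normalize,
    preprocess_spectrum,
    restrict_range,
)
from irclass import synthetic as syn

from conftest import make_spectrum


class TestAbsorbanceConversion:
    def test_identity_and_log_point(self, grid):
        n = len(grid)
        ref = make_spectrum(grid, np.ones(n))
        sample = make_spectrum(grid, np.ones(n))
        a = absorbance_from_single_beam(sample, ref)
        np.testing.assert_allclose(a.absorbance, 0.0, atol=1e-15)
        vals = np.ones(n)
        vals[0] = 0.1
        a = absorbance_from_single_beam(make_spectrum(grid, vals), ref)
        assert a.absorbance[0] == pytest.approx(1.0)

    def test_algebraic_roundtrip(self, grid):
        rng = np.random.default_rng(1)
        s = make_spectrum(grid, rng.uniform(0.1, 2.0, len(grid)))
        r = make_spectrum(grid, rng.uniform(0.1, 2.0, len(grid)))
        a = absorbance_from_single_beam(s, r)
        recovered = 10.0 ** (-a.absorbance) * r.absorbance
        np.testing.assert_allclose(recovered, s.absorbance, rtol=1e-12)

    def test_nonpositive_reference_rejected(self, grid):
        vals = np.ones(len(grid))
        bad = vals.copy()
        bad[3] = 0.0
        with pytest.raises(ValueError):
            absorbance_from_single_beam(make_spectrum(grid, vals),
                                        make_spectrum(grid, bad))

    def test_nonpositive_sample_capped_with_warning(self, grid):
        vals = np.ones(len(grid))
        vals[5] = -0.2
        ref = make_spectrum(grid, np.ones(len(grid)))
        with pytest.warns(UserWarning, match="capped"):
            a = absorbance_from_single_beam(make_spectrum(grid, vals), ref)
        assert a.absorbance[5] == 10.0


class TestRestrictRange:
    def test_full_span_unchanged(self, grid):
        s = make_spectrum(grid, np.arange(len(grid), dtype=float))
        r = restrict_range(s, 950, 1800)
        np.testing.assert_array_equal(r.absorbance, s.absorbance)

    def test_classification_range_point_count(self, grid):
        s = make_spectrum(grid, np.zeros(len(grid)))
        r = restrict_range(s, 950, 1480)
        assert len(r.grid) == 266  # (1480-950)/2 + 1
        assert r.meta.preprocessing_state[-1] == "range_restricted"

    def test_idempotent(self, grid):
        s = make_spectrum(grid, np.random.default_rng(0).random(len(grid)))
        once = restrict_range(s, 950, 1480)
        twice = restrict_range(once, 950, 1480)
        np.testing.assert_array_equal(once.absorbance, twice.absorbance)
        assert once.meta.preprocessing_state == twice.meta.preprocessing_state

    def test_empty_result_errors(self, grid):
        s = make_spectrum(grid, np.zeros(len(grid)))
        with pytest.raises(GridError):
            restrict_range(s, 100, 200)


class TestBaseline:
    def test_anchors_exactly_zero(self, grid):
        rng = np.random.default_rng(2)
        s = make_spectrum(grid, rng.random(len(grid)))
        c = baseline_correct_two_point(s, (950, 1800))
        assert c.absorbance[0] == 0.0
        assert c.absorbance[-1] == 0.0

    def test_linear_spectrum_goes_to_zero(self, grid):
        s = make_spectrum(grid, 0.3 + 0.001 * grid.values)
        c = baseline_correct_two_point(s, (950, 1800))
        np.testing.assert_allclose(c.absorbance, 0.0, atol=1e-12)

    def test_hand_worked_three_points(self):
        g = WavenumberGrid(np.array([950.0, 1375.0, 1800.0]))
        s = make_spectrum(g, [2.0, 5.0, 4.0])
        c = baseline_correct_two_point(s, (950, 1800))
        np.testing.assert_allclose(c.absorbance, [0.0, 2.0, 0.0], atol=1e-12)

    def test_equal_anchors_rejected(self, grid):
        s = make_spectrum(grid, np.zeros(len(grid)))
        with pytest.raises(ValueError):
            baseline_correct_two_point(s, (1000, 1000))


class TestAreaNormalize:
    def test_constant_spectrum(self, grid):
        s = make_spectrum(grid, np.full(len(grid), 3.7))
        n = area_normalize(s, (950, 1480))
        k = len(grid.window_indices(950, 1480))
        np.testing.assert_allclose(n.absorbance[grid.window_indices(950, 1480)],
                                   1.0 / k)

    def test_unit_sum_over_range(self, grid):
        rng = np.random.default_rng(3)
        s = make_spectrum(grid, 0.1 + rng.random(len(grid)))
        n = area_normalize(s, (950, 1480))
        assert n.absorbance[grid.window_indices(950, 1480)].sum() == pytest.approx(
            1.0, abs=1e-12
        )

    @settings(derandomize=True, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        g = WavenumberGrid.regular(950, 1480, 2.0)
        rng = np.random.default_rng(4)
        vals = 0.1 + rng.random(len(g))
        a = area_normalize(make_spectrum(g, vals), (950, 1480))
        b = area_normalize(make_spectrum(g, k * vals), (950, 1480))
        np.testing.assert_allclose(a.absorbance, b.absorbance, rtol=1e-10)

    def test_nonpositive_area_rejected(self, grid):
        s = make_spectrum(grid, -np.ones(len(grid)))
        with pytest.raises(ValueError):
            area_normalize(s, (950, 1480))


class TestMinMax:
    def test_hand_example(self):
        g = WavenumberGrid(np.array([950.0, 952.0, 954.0]))
        n = minmax_normalize(make_spectrum(g, [2.0, 5.0, 4.0]))
        np.testing.assert_allclose(n.absorbance, [0.0, 1.0, 2.0 / 3.0])

    def test_idempotent_and_attains_bounds(self, grid):
        rng = np.random.default_rng(5)
        n = minmax_normalize(make_spectrum(grid, rng.random(len(grid))))
        assert n.absorbance.min() == 0.0
        assert n.absorbance.max() == 1.0
        again = minmax_normalize(n)
        np.testing.assert_allclose(again.absorbance, n.absorbance, atol=1e-15)

    @settings(derandomize=True, max_examples=25)
    @given(a=st.floats(min_value=1e-3, max_value=1e3),
           b=st.floats(min_value=-10, max_value=10))
    def test_affine_invariance(self, a, b):
        g = WavenumberGrid.regular(950, 1000, 2.0)
        rng = np.random.default_rng(6)
        vals = rng.random(len(g))
        x = minmax_normalize(make_spectrum(g, vals))
        y = minmax_normalize(make_spectrum(g, a * vals + b))
        np.testing.assert_allclose(x.absorbance, y.absorbance, atol=1e-9)

    def test_constant_rejected(self, grid):
        with pytest.raises(ValueError):
            minmax_normalize(make_spectrum(grid, np.ones(len(grid))))


class TestAtmosphericCompensation:
    def test_planted_lines_removed(self, grid):
        ref = syn.water_vapor_reference(grid)
        background = syn.default_class_models()["normal"].noise_free(grid)
        s = make_spectrum(grid, background + 0.3 * ref)
        c = atmospheric_compensation(s, ref)
        residual = np.abs(c.absorbance - background)
        line_height = 0.3 * ref.max()
        assert residual.max() < 0.01 * line_height

    def test_zero_reference_is_noop(self, grid):
        s = make_spectrum(grid, np.random.default_rng(7).random(len(grid)))
        c = atmospheric_compensation(s, np.zeros(len(grid)))
        np.testing.assert_array_equal(c.absorbance, s.absorbance)

    def test_clean_spectrum_nearly_unchanged(self, grid):
        """A spectrum without water lines changes by less than its own noise."""
        noise_sd = 0.003
        rng = np.random.default_rng(8)
        model = syn.default_class_models()["normal"]
        vals = model.noise_free(grid) + noise_sd * rng.standard_normal(len(grid))
        s = make_spectrum(grid, vals)
        c = atmospheric_compensation(s, syn.water_vapor_reference(grid))
        assert np.abs(c.absorbance - s.absorbance).max() < noise_sd


class TestChain:
    def test_chain_order_and_states(self, grid):
        model = syn.default_class_models()["normal"]
        s = make_spectrum(grid, model.noise_free(grid) + 0.05)
        out = preprocess_spectrum(s, PreprocessSpec())
        assert out.meta.preprocessing_state == [
            "raw", "range_restricted", "baseline_corrected", "area_normalized",
        ]
        assert len(out.grid) == 266
        assert out.absorbance.sum() == pytest.approx(1.0, abs=1e-12)

    def test_chain_idempotent_after_first_pass(self, grid):
        """Re-running the chain on preprocessed output reproduces it (the
        area re-normalization divides by 1)."""
        model = syn.default_class_models()["normal"]
        s = make_spectrum(grid, model.noise_free(grid) + 0.05)
        spec = PreprocessSpec(range_full=(950, 1480), baseline_anchors=(950, 1480))
        once = preprocess_spectrum(s, spec)
        twice = preprocess_spectrum(once, spec)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)
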