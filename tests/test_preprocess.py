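import numpy as np
import pytest

from soyspec.containers import SpectraTable, WavelengthGrid
from soyspec.preprocess import PreprocessSpec, apply_preprocess, make_chain


def table_from(X, centers=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if centers is None:
        centers = 400.0 + 10.0 * np.arange(X.shape[1])
    return SpectraTable(X, WavelengthGrid(np.asarray(centers, dtype=float)),
                        np.array(["a"] * X.shape[0]))


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"method": "XX"},
        {"method": "MA", "window": 4},
        {"method": "SGD", "window": 3, "polyorder": 3},
        {"method": "SGD", "polyorder": 2, "deriv_order": 3},
        {"method": "BC", "baseline": "spline"},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PreprocessSpec(**kwargs)


class TestTransforms:
    def test_snv_standardizes_each_row(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.random((4, 20)))
        out = apply_preprocess(t, PreprocessSpec("SNV")).reflectance
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_snv_constant_spectrum_rejected(self):
        t = table_from([[0.5] * 6, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]])
        with pytest.raises(ValueError, match="row 0"):
            apply_preprocess(t, PreprocessSpec("SNV"))

    def test_msc_inverts_affine_scatter(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0.2, 0.8, 15)
        t = table_from(2.0 * ref + 0.3)
        out = apply_preprocess(t, PreprocessSpec("MSC", reference=ref)).reflectance
        np.testing.assert_allclose(out[0], ref, atol=1e-10)

    def test_msc_idempotent(self):
        rng = np.random.default_rng(2)
        t = table_from(rng.random((5, 12)))
        ref = t.reflectance.mean(axis=0)
        spec = PreprocessSpec("MSC", reference=ref)
        once = apply_preprocess(t, spec).reflectance
        twice = apply_preprocess(apply_preprocess(t, spec), spec).reflectance
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_sgs_reproduces_quadratic(self):
        i = np.arange(30, dtype=float)
        x = 0.3 + 0.02 * i - 0.001 * i**2
        t = table_from(x)
        out = apply_preprocess(t, PreprocessSpec("SGS", window=11, polyorder=2))
        np.testing.assert_allclose(out.reflectance[0], x, atol=1e-9)

    def test_bc_zeroes_linear_spectrum(self):
        t = table_from(np.linspace(0.1, 0.9, 17))
        out = apply_preprocess(t, PreprocessSpec("BC"))
        np.testing.assert_allclose(out.reflectance, 0, atol=1e-12)

    def test_bc_offset_variant_subtracts_minimum(self):
        t = table_from([[0.3, 0.5, 0.4]])
        out = apply_preprocess(t, PreprocessSpec("BC", baseline="offset"))
        np.testing.assert_allclose(out.reflectance[0], [0.0, 0.2, 0.1], atol=1e-12)

    def test_ds_hand_finite_difference(self):
        t = table_from([[0.2, 0.4, 0.8]], centers=[400.0, 402.0, 404.0])
        out = apply_preprocess(t, PreprocessSpec("DS"))
        np.testing.assert_allclose(out.reflectance[0], [0.1, 0.2], atol=1e-12)
        np.testing.assert_allclose(out.wavelengths, [401.0, 403.0])

    def test_ma_hand_average_with_shrunken_edges(self):
        t = table_from([[1.0, 2.0, 3.0, 4.0]])
        out = apply_preprocess(t, PreprocessSpec("MA", window=3))
        np.testing.assert_allclose(out.reflectance[0], [1.5, 2.0, 3.0, 3.5],
                                   atol=1e-12)

    def test_norm_scales_to_unit_interval(self):
        rng = np.random.default_rng(3)
        out = apply_preprocess(table_from(rng.random((6, 9))),
                               PreprocessSpec("NORM")).reflectance
        np.testing.assert_allclose(out.min(axis=1), 0, atol=0)
        np.testing.assert_allclose(out.max(axis=1), 1, atol=0)

    def test_sgd_matches_analytic_cubic_derivative(self):
        lam = 400.0 + 2.0 * np.arange(40)
        u = (lam - lam[0]) / 10.0
        x = 0.1 + 0.05 * u - 0.002 * u**2 + 0.0001 * u**3
        dx = (0.05 - 0.004 * u + 0.0003 * u**2) / 10.0  # d/d lambda
        t = table_from(x, centers=lam)
        out = apply_preprocess(t, PreprocessSpec("SGD", window=9, polyorder=3))
        np.testing.assert_allclose(out.reflectance[0][5:-5], dx[5:-5], atol=1e-8)

    def test_window_exceeding_band_count_rejected(self):
        t = table_from([[0.1, 0.2, 0.3, 0.4, 0.5]])
        with pytest.raises(ValueError, match="window"):
            apply_preprocess(t, PreprocessSpec("SGS", window=7))

    def test_row_permutation_commutes(self):
        rng = np.random.default_rng(4)
        t = table_from(rng.random((7, 11)))
        perm = rng.permutation(7)
        spec = PreprocessSpec("SNV")
        a = apply_preprocess(t, spec).reflectance[perm]
        b = apply_preprocess(t.take_rows(perm), spec).reflectance
        np.testing.assert_allclose(a, b, atol=0)


class TestChain:
    def test_empty_chain_is_identity(self, small_table):
        out = make_chain([])(small_table)
        np.testing.assert_array_equal(out.reflectance, small_table.reflectance)

    def test_singleton_chain_equals_apply(self, small_table):
        spec = PreprocessSpec("SNV")
        a = make_chain([spec])(small_table).reflectance
        b = apply_preprocess(small_table, spec).reflectance
        np.testing.assert_array_equal(a, b)

    def test_bc_then_norm_yields_unit_rows(self):
        rng = np.random.default_rng(5)
        t = table_from(rng.random((8, 14)))
        out = make_chain([PreprocessSpec("BC"), PreprocessSpec("NORM")])(t)
        np.testing.assert_allclose(out.reflectance.min(axis=1), 0, atol=0)
        np.testing.assert_allclose(out.reflectance.max(axis=1), 1, atol=0)

    def test_ds_must_be_last(self):
        with pytest.raises(ValueError, match="last"):
            make_chain([PreprocessSpec("DS"), PreprocessSpec("SNV")])

    def test_msc_reference_frozen_on_calibration(self):
        rng = np.random.default_rng(6)
        cal = table_from(rng.random((6, 10)))
        pred = table_from(rng.random((3, 10)))
        chain = make_chain([PreprocessSpec("MSC")]).fit(cal)
        out1 = chain.transform(pred).reflectance
        # perturbing prediction rows must not change the fitted transform
        pred2 = table_from(pred.reflectance + rng.normal(0, 0.1, pred.reflectance.shape))
        chain2 = make_chain([PreprocessSpec("MSC")]).fit(cal)
        np.testing.assert_array_equal(chain2._fitted[0].reference,
                                      chain._fitted[0].reference)
        out1b = chain2.transform(pred).reflectance
        np.testing.assert_array_equal(out1, out1b)
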