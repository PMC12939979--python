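"""Scatter correction and Savitzky-Golay identities, plus the bake-off."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from specswarm import (
    PreprocessMethod,
    bake_off,
    msc_apply,
    msc_fit,
    savitzky_golay,
    snv,
    spxy_split,
)
from specswarm.preprocess import fit_preprocessor, apply_preprocessor
from specswarm.synthetic import SyntheticSpec, generate, make_grid


class TestSnv:
    def test_simple_row(self):
        assert np.allclose(snv(np.array([[1.0, 2.0, 3.0]])), [[-1, 0, 1]])

    def test_constant_row_named(self):
        with pytest.raises(ValueError, match="row 1"):
            snv(np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))

    def test_idempotent(self, rng):
        X = rng.normal(size=(5, 30))
        once = snv(X)
        assert np.max(np.abs(snv(once) - once)) <= 1e-12

    @given(
        X=arrays(
            float, (4, 12),
            elements=st.floats(-50, 50, allow_nan=False),
        ).filter(lambda a: (a.std(axis=1) > 1e-3).all())
    )
    def test_rows_standardised(self, X):
        out = snv(X)
        assert np.max(np.abs(out.mean(axis=1))) <= 1e-12
        assert np.max(np.abs(out.std(axis=1, ddof=1) - 1)) <= 1e-12


class TestMsc:
    def test_reference_is_mean(self, rng):
        r = rng.random(10) + 0.5
        fp = msc_fit(np.vstack([r, 3 * r]))
        assert np.allclose(fp.reference_spectrum, 2 * r)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            msc_fit(np.ones((1, 5)))

    def test_affine_row_maps_to_reference(self, rng):
        cal = rng.random((4, 20)) + 0.5
        fp = msc_fit(cal)
        ref = fp.reference_spectrum
        out = msc_apply(fp, np.vstack([ref, 2 * ref + 5]))
        assert np.allclose(out[0], ref)
        assert np.allclose(out[1], ref)

    def test_orthogonal_row_degenerate(self, rng):
        # Gram-Schmidt a row against the centred reference: OLS slope is then
        # exactly zero, which MSC must reject as a degenerate regression.
        cal = rng.random((4, 20)) + 0.5
        fp = msc_fit(cal)
        ref_c = fp.reference_spectrum - fp.reference_spectrum.mean()
        w = rng.normal(size=20)
        w = w - (w @ ref_c) / (ref_c @ ref_c) * ref_c
        slope = ((w - w.mean()) @ ref_c) / (ref_c @ ref_c)
        assert abs(slope) < 1e-12  # closed-form OLS slope vanishes
        with pytest.raises(ValueError, match="degenerate"):
            msc_apply(fp, w[None, :])


class TestSavitzkyGolay:
    def test_reproduces_polynomial_rows(self, rng):
        lam = np.arange(400, 400 + 4 * 51, 4, dtype=float)
        rows = np.vstack([
            0.3 + 0.001 * lam,
            5 - 0.002 * lam + 1e-6 * lam**2,
        ])
        out = savitzky_golay(rows, window=11, polyorder=2, deriv=0, step_nm=4)
        assert np.max(np.abs(out - rows)) <= 1e-9

    def test_first_derivative_of_linear_row(self):
        lam = np.arange(400, 400 + 4 * 51, 4, dtype=float)
        out = savitzky_golay(0.5 * lam[None, :], 11, 2, deriv=1, step_nm=4)
        assert np.allclose(out[0, 5:-5], 0.5, atol=1e-9)

    def test_second_derivative_of_quadratic_row(self):
        lam = np.arange(400, 400 + 4 * 51, 4, dtype=float)
        out = savitzky_golay((lam**2)[None, :], 11, 2, deriv=2, step_nm=4)
        assert np.allclose(out[0, 5:-5], 2.0, atol=1e-6)

    def test_shape_preserved(self, rng):
        X = rng.normal(size=(3, 40))
        for deriv in (0, 1, 2):
            assert savitzky_golay(X, 11, 2, deriv, 4).shape == X.shape

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            savitzky_golay(np.ones((1, 20)), window=10, polyorder=2)

    def test_window_longer_than_row_rejected(self):
        with pytest.raises(ValueError, match="length"):
            savitzky_golay(np.ones((1, 5)), window=11, polyorder=2)


class TestMethodValidation:
    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown"):
            PreprocessMethod("OSC")

    def test_sg2d_requires_polyorder(self):
        with pytest.raises(ValueError):
            PreprocessMethod("SG2D", window=11, polyorder=1)


class TestBakeOff:
    @pytest.fixture(scope="class")
    def scattered(self):
        # heavy multiplicative/additive scatter, no other noise: scatter
        # correction provably beats raw spectra
        spec = SyntheticSpec(
            n_samples=60,
            grid=make_grid(400, 400 + 4 * 23, 4),
            bands=((420.0, 8.0, 0.15), (460.0, 8.0, 0.2), (480.0, 6.0, 0.15)),
            informative_idx=(0, 1, 2),
            noise_sd=0.0,
            scatter_slope_sd=0.3,
            scatter_offset_sd=0.2,
            target_noise_frac=0.0,
            seed=5,
        )
        ds, _ = generate(spec)
        y = ds.indicator_values("tvbn")
        split = spxy_split(ds.reflectance, y)
        return ds, split

    def test_scatter_correction_beats_raw(self, scattered):
        ds, split = scattered
        methods = [PreprocessMethod(n) for n in ("RAW", "SNV", "MSC")]
        table = bake_off(ds, "tvbn", methods, split,
                        model_cfg={"n_estimators": 60, "max_bin": 32})
        assert table.iloc[0]["method"] in ("SNV", "MSC")
        raw_rmsep = float(table.set_index("method").loc["RAW", "rmse_pred"])
        assert float(table.iloc[0]["rmse_pred"]) < raw_rmsep

    def test_exact_tie_breaks_by_method_order(self, scattered):
        # SG smoothing reproduces quadratic rows exactly, so RAW and SG give
        # byte-identical matrices and exactly tied metrics: RAW must rank
        # first by the declared order.
        ds, split = scattered
        lam = ds.grid.values
        quad = 0.8 - 1e-4 * (lam - 440) ** 2 / 100
        ds2 = ds.subset(range(ds.n_samples))
        ds2.reflectance = np.vstack(
            [quad * (1 + 0.01 * i) for i in range(ds.n_samples)]
        )
        table = bake_off(
            ds2, "tvbn", [PreprocessMethod("SG"), PreprocessMethod("RAW")],
            split, model_cfg={"n_estimators": 20, "max_bin": 16},
        )
        assert table["rmse_pred"].nunique() == 1
        assert list(table["method"]) == ["RAW", "SG"]

    def test_missing_indicator_rejected(self, scattered):
        ds, split = scattered
        with pytest.raises(KeyError, match="'x'"):
            bake_off(ds, "x", [PreprocessMethod("RAW")], split)


def test_apply_preprocessor_shapes(rng):
    X = rng.random((6, 30)) + 0.2
    for name in ("RAW", "SNV", "MSC", "SG", "SG1D", "SG2D"):
        fp = fit_preprocessor(PreprocessMethod(name), X)
        assert apply_preprocessor(fp, X, step_nm=4).shape == X.shape
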