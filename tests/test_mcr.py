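"""MCR-ALS decomposition: oracles, fixed points, invariants, labelling."""

import numpy as np
import pytest
from sklearn.base import clone

from phycoscope import COMPONENTS, MCRALS, SpectralCube, background_mask, mcr_als
from phycoscope.mcr import (
    AmbiguityError,
    SpectralModel,
    identify_components,
    pin_offset,
    variance_explained,
)


def _two_gaussians(ch=48):
    x = np.linspace(0, 1, ch)
    S = np.vstack(
        [np.exp(-0.5 * ((x - 0.3) / 0.07) ** 2), np.exp(-0.5 * ((x - 0.7) / 0.07) ** 2)]
    )
    return S / np.linalg.norm(S, axis=1, keepdims=True)


class TestVarianceExplained:
    def test_exact_reconstruction_is_one(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(size=(20, 3))
        S = rng.uniform(size=(3, 10))
        assert variance_explained(C @ S, C, S) == 1.0

    def test_zero_model_is_zero(self):
        D = np.ones((5, 4))
        assert variance_explained(D, np.zeros((5, 2)), np.zeros((2, 4))) == 0.0

    def test_matches_brute_force_sum_of_squares(self):
        """Element-wise Python-loop oracle for the variance fraction."""
        rng = np.random.default_rng(1)
        D = rng.uniform(size=(6, 5))
        C = rng.uniform(size=(6, 2))
        S = rng.uniform(size=(2, 5))
        fit = C @ S
        num = sum(
            (D[i, j] - fit[i, j]) ** 2 for i in range(6) for j in range(5)
        )
        den = sum(D[i, j] ** 2 for i in range(6) for j in range(5))
        assert variance_explained(D, C, S) == pytest.approx(1 - num / den, abs=1e-12)

    def test_zero_data_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            variance_explained(np.zeros((3, 3)), np.zeros((3, 1)), np.zeros((1, 3)))


class TestMcrAls:
    def test_truth_init_is_fixed_point(self):
        """Noiseless two-component mixture initialised at the truth stays at
        the truth with (near-)zero residual."""
        S = _two_gaussians()
        rng = np.random.default_rng(2)
        C = rng.uniform(0.5, 2.0, size=(200, 2))
        X = C @ S
        est = MCRALS(n_components=2, max_iter=50, tol=1e-12).fit(X, S_init=S)
        assert est.residuals_[-1] < 1e-8 * np.linalg.norm(X)
        cos = np.abs(est.components_ @ S.T)
        assert np.allclose(np.diag(cos), 1.0, atol=1e-8)

    def test_permuting_init_permutes_output(self):
        S = _two_gaussians()
        rng = np.random.default_rng(3)
        X = rng.uniform(0.5, 2.0, size=(150, 2)) @ S + 0.01 * rng.uniform(
            size=(150, 48)
        )
        a = MCRALS(n_components=2, max_iter=40).fit(X, S_init=S)
        b = MCRALS(n_components=2, max_iter=40).fit(X, S_init=S[::-1])
        assert np.allclose(a.components_, b.components_[::-1], atol=1e-8)
        assert a.residuals_[-1] == pytest.approx(b.residuals_[-1], rel=1e-9)

    def test_residual_monotone_noisy(self):
        rng = np.random.default_rng(4)
        S = _two_gaussians()
        X = rng.poisson(200 * rng.uniform(0.2, 1.0, size=(300, 2)) @ S).astype(float)
        est = MCRALS(n_components=2, max_iter=200).fit(X)
        assert np.all(np.diff(est.residuals_) <= 1e-9 * est.residuals_[0])

    def test_noiseless_recovery_with_pure_rows(self):
        """Non-overlapping spatial supports: each component has pure pixels,
        so the spectra come back with cosine ≥ 0.99 (up to permutation)."""
        x = np.linspace(0, 1, 64)
        S = np.vstack(
            [
                np.exp(-0.5 * ((x - m) / 0.06) ** 2)
                for m in (0.25, 0.55, 0.85)
            ]
        )
        S /= np.linalg.norm(S, axis=1, keepdims=True)
        rng = np.random.default_rng(5)
        C = np.zeros((300, 3))
        for j in range(3):  # disjoint supports
            C[j * 100 : (j + 1) * 100, j] = rng.uniform(0.5, 2.0, 100)
        est = MCRALS(n_components=3, max_iter=300).fit(C @ S)
        cos = est.components_ @ S.T
        matched = cos.max(axis=0)
        assert np.all(matched >= 0.99)

    def test_nested_models_explain_no_less_variance(self):
        rng = np.random.default_rng(6)
        x = np.linspace(0, 1, 40)
        S = np.vstack([np.exp(-0.5 * ((x - m) / 0.1) ** 2) for m in (0.2, 0.5, 0.8)])
        C = rng.uniform(size=(250, 3))
        X = rng.poisson(500 * C @ S).astype(float)
        prev = 0.0
        for k in (1, 2, 3):
            est = MCRALS(n_components=k, max_iter=150).fit(X)
            assert est.variance_explained_ >= prev - 1e-9
            prev = est.variance_explained_

    def test_transform_concentrations_nonnegative(self):
        S = _two_gaussians()
        rng = np.random.default_rng(7)
        X = rng.uniform(0.5, 2.0, size=(100, 2)) @ S
        est = MCRALS(n_components=2, max_iter=30).fit(X)
        assert np.all(est.transform(X[:10]) >= 0)

    def test_k_exceeding_channels_rejected(self):
        with pytest.raises(ValueError):
            MCRALS(n_components=10).fit(np.ones((5, 8)))

    def test_sklearn_clone_roundtrip(self):
        est = MCRALS(n_components=3, tol=1e-5)
        assert clone(est).get_params() == est.get_params()

    def test_functional_wrapper_diagnostics(self):
        S = _two_gaussians()
        rng = np.random.default_rng(8)
        X = rng.uniform(0.5, 2.0, size=(80, 2)) @ S
        spectra, conc, diag = mcr_als(X, k=2, max_iter=30)
        assert spectra.shape == (2, 48) and conc.shape == (80, 2)
        assert 0.99 < diag["variance_explained"] <= 1.0
        assert diag["n_pixels_used"] == 80


class TestBackgroundMask:
    def test_bright_cell_on_zero_background(self):
        data = np.zeros((20, 20, 8))
        data[5:9, 5:9, :] = 50.0
        cube = SpectralCube(data, np.linspace(500, 800, 8))
        mask = background_mask(cube)
        assert np.array_equal(mask, data[:, :, 0] > 0)

    def test_absolute_zero_threshold_all_true(self):
        cube = SpectralCube(
            np.ones((5, 5, 4)), np.linspace(500, 800, 4)
        )
        assert background_mask(cube, method="absolute", threshold=0).all()

    def test_flat_image_warns_empty(self):
        cube = SpectralCube(np.ones((5, 5, 4)), np.linspace(500, 800, 4))
        with pytest.warns(UserWarning, match="no contrast"):
            mask = background_mask(cube)
        assert not mask.any()

    def test_default_threshold_covers_cells(self, control_scene):
        """Otsu-style default covers ≥ 95 % of true cell pixels."""
        cube, truth = control_scene
        mask = background_mask(cube)
        cells = truth.labels > 0
        assert (mask & cells).sum() / cells.sum() >= 0.95

    def test_background_statistics_method_is_permissive(self, control_scene):
        cube, truth = control_scene
        otsu = background_mask(cube)
        bg = background_mask(cube, method="background")
        assert bg.sum() >= otsu.sum()
        cells = truth.labels > 0
        assert (bg & cells).sum() / cells.sum() >= 0.95


class TestIdentifyComponents:
    def test_generator_reference_labelled_correctly(self, ref):
        """Shuffled generator spectra get their own labels back."""
        order = [3, 5, 0, 4, 1, 2]
        model = SpectralModel(ref.wavelengths, ref.spectra[order])
        labelled = identify_components(model)
        assert labelled.labels == COMPONENTS
        for name in COMPONENTS:
            row = labelled.spectra[labelled.labels.index(name)]
            assert row @ ref[name] > 0.999

    def test_constant_row_is_offset(self, ref):
        model = SpectralModel(ref.wavelengths, ref.spectra)
        labelled = identify_components(model)
        offset = labelled.spectra[labelled.labels.index("offset")]
        assert np.ptp(offset) == 0.0

    def test_requires_six_components(self, ref):
        model = SpectralModel(ref.wavelengths, ref.spectra[:4])
        with pytest.raises(ValueError, match="six-component"):
            identify_components(model)

    def test_duplicate_flat_rows_ambiguous(self, ref):
        spectra = ref.spectra.copy()
        spectra[4] = spectra[5]  # two flat rows
        with pytest.raises(AmbiguityError):
            identify_components(SpectralModel(ref.wavelengths, spectra))

    def test_pin_offset_restores_flat_shape(self, ref):
        spectra = ref.spectra.copy()
        spectra[5] = np.clip(spectra[5] - 0.1 * spectra[0], 0, None)
        spectra[5] /= np.linalg.norm(spectra[5])
        model = SpectralModel(ref.wavelengths, spectra, COMPONENTS)
        pinned = pin_offset(model)
        flat = pinned.spectra[pinned.labels.index("offset")]
        assert np.ptp(flat) == 0.0
        assert np.linalg.norm(flat) == pytest.approx(1.0)

    def test_model_csv_round_trip(self, ref, tmp_path):
        model = SpectralModel(
            ref.wavelengths, ref.spectra, COMPONENTS, {"init": "purest"}
        )
        model.save(tmp_path / "model.csv")
        back = SpectralModel.load(tmp_path / "model.csv")
        assert back.labels == COMPONENTS
        assert np.allclose(back.spectra, model.spectra)
        assert back.provenance["init"] == "purest"
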