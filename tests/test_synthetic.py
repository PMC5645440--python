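"""Scene and bulk-spectrum generator: determinism, calibration, closure."""

import numpy as np
import pandas as pd
import pytest

from phycoscope import CONDITIONS, ConditionProfile, make_population, render_scene
from phycoscope.bulk import blank_correct, per_od_content, phycobilin_concentration
from phycoscope.synthetic import (
    BASE_ABUNDANCE,
    SceneGeometry,
    bulk_targets,
    make_bulk_spectrum,
    simulate_scene,
)


class TestPopulation:
    def test_same_seed_identical(self):
        a = make_population(CONDITIONS["T24-N"], 50, seed=3)
        b = make_population(CONDITIONS["T24-N"], 50, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_cv_and_dead_fraction(self):
        profile = ConditionProfile("x", {"PC": 1.0, "APC": 0.5}, cv=0.0, dead_fraction=0.0)
        pop = make_population(profile, 10, seed=0)
        assert pop["PC"].nunique() == 1
        assert pop["PC"].iloc[0] == BASE_ABUNDANCE["PC"]
        assert not pop["dead"].any()

    def test_large_sample_mean_matches_configured_multiplier(self):
        """Law of large numbers: alive-cell mean PC under T24−N defaults sits
        within 2 % of the configured 0.03 multiplier."""
        pop = make_population(CONDITIONS["T24-N"], 10_000, seed=1)
        alive = pop[~pop["dead"]]
        expected = 0.03 * BASE_ABUNDANCE["PC"]
        assert abs(alive["PC"].mean() / expected - 1.0) < 0.02

    def test_population_calibration_within_3_se(self):
        """Sample mean multipliers match the profile means within 3 SE for
        every pigment (n = 2000)."""
        profile = CONDITIONS["T24replete"]
        pop = make_population(profile, 2000, seed=4)
        alive = pop[~pop["dead"]]
        for name in ("PC", "APC", "Chl-PSII", "Chl-PSI"):
            mean = BASE_ABUNDANCE[name] * profile.multipliers[name]
            se = alive[name].std(ddof=1) / np.sqrt(len(alive))
            assert abs(alive[name].mean() - mean) < 3 * se

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ConditionProfile("bad", {"PC": -0.1})

    def test_dead_cells_at_stated_fraction(self):
        pop = make_population(CONDITIONS["T0+N"], 40, seed=2)
        assert pop["dead"].sum() == round(40 * CONDITIONS["T0+N"].dead_fraction)

    def test_bimodal_mode_creates_low_pc_subpopulation(self):
        profile = ConditionProfile(
            "replete2", dict(CONDITIONS["T24replete"].multipliers), bimodal_fraction=0.5
        )
        pop = make_population(profile, 4000, seed=9)
        unimodal = make_population(CONDITIONS["T24replete"], 4000, seed=9)
        assert pop["PC"].mean() < 0.85 * unimodal["PC"].mean()


class TestRenderScene:
    def test_default_frame_holds_44100_spectra(self, control_scene):
        cube, _ = control_scene
        assert cube.shape[:2] == (210, 210)
        assert cube.n_spectra == 44_100

    def test_same_seed_bit_identical(self, ref, small_geometry):
        a, _ = simulate_scene("T24-N", 6, seed=5, geometry=small_geometry, reference=ref)
        b, _ = simulate_scene("T24-N", 6, seed=5, geometry=small_geometry, reference=ref)
        assert np.array_equal(a.data, b.data)

    def test_linear_mixing_closure_noiseless(self, ref, small_geometry):
        """With noise off the cube equals truth concentrations × spectra."""
        truth_pop = make_population(CONDITIONS["T0+N"], 5, seed=1)
        cube, truth = render_scene(truth_pop, ref, small_geometry, noise=False, seed=1)
        expected = truth.concentrations.reshape(-1, 6) @ ref.spectra
        assert np.allclose(cube.pixel_matrix(), expected, rtol=0, atol=1e-9)

    def test_single_component_pixels_are_scalar_multiples(self, ref, small_geometry):
        """One emitter, no offset: every in-cell spectrum is a non-negative
        multiple of that emitter's spectrum."""
        profile = ConditionProfile(
            "pc_only",
            {"PC": 1.0, "APC": 0.0, "Chl-PSII": 0.0, "Chl-PSI": 0.0, "autofluorescence": 0.0},
            dead_fraction=0.0,
        )
        pop = make_population(profile, 4, seed=2)
        pop["offset"] = 0.0
        cube, truth = render_scene(pop, ref, small_geometry, noise=False, seed=2)
        pixels = cube.pixel_matrix()[truth.labels.ravel() > 0]
        coeff = pixels @ ref["PC"]
        assert np.all(coeff >= 0)
        assert np.allclose(pixels, np.outer(coeff, ref["PC"]), atol=1e-9)

    def test_per_cell_truth_mean_is_exact(self, ref, small_geometry):
        """The rendered per-pixel concentrations average back to the truth
        table's per-cell abundances."""
        pop = make_population(CONDITIONS["T0+N"], 4, seed=3)
        cube, truth = render_scene(pop, ref, small_geometry, noise=False, seed=3)
        pc_map = truth.concentrations[:, :, 0]
        for _, rec in truth.table.iterrows():
            cell = truth.labels == rec["cell_id"]
            assert pc_map[cell].mean() == pytest.approx(rec["PC"], rel=1e-9)

    def test_poisson_noise_unbiased(self, ref, small_geometry):
        """Monte-Carlo mean of a noisy pixel over 100 renders stays within
        3 SE of its noiseless value."""
        pop = make_population(CONDITIONS["T0+N"], 3, seed=4)
        clean, truth = render_scene(pop, ref, small_geometry, noise=False, seed=4)
        r, c = np.argwhere(truth.labels > 0)[0]
        draws = []
        for i in range(100):
            noisy, _ = render_scene(
                pop, ref, small_geometry, noise=True, seed=4, noise_seed=1000 + i
            )
            draws.append(noisy.data[r, c].sum())
        draws = np.asarray(draws)
        expected = clean.data[r, c].sum()
        se = np.sqrt(expected / len(draws))  # Poisson variance = mean
        assert abs(draws.mean() - expected) < 3 * se

    def test_overcrowded_frame_rejected(self, ref):
        geometry = SceneGeometry(shape=(40, 40))
        pop = make_population(CONDITIONS["T0+N"], 30, seed=0)
        with pytest.raises(RuntimeError, match="non-overlapping"):
            render_scene(pop, ref, geometry, noise=False, seed=0)


class TestBulkSpectra:
    def test_positive_bands_and_od(self):
        spec = make_bulk_spectrum("T0+N", seed=0)
        blank = make_bulk_spectrum("blank", seed=1)
        corr = blank_correct(spec, blank)
        assert corr.at(625.0) > 0 and corr.at(730.0) > 0

    def test_blank_is_flat(self):
        blank = make_bulk_spectrum("blank", seed=0, noise_sd=0.0)
        assert np.ptp(blank.absorbance) == 0.0

    def test_depletion_ratio_6p5(self):
        """Phycobilin per OD730 falls 6.5-fold over 24 h of nitrogen
        depletion on noiseless generator spectra."""
        blank = make_bulk_spectrum("blank", noise_sd=0.0)
        per_od = {}
        for cond in ("T0-N", "T24-N"):
            corr = blank_correct(make_bulk_spectrum(cond, noise_sd=0.0), blank)
            conc = phycobilin_concentration(
                corr.at(620.0), corr.at(678.0), corr.at(730.0)
            )
            per_od[cond] = per_od_content(conc, corr.at(730.0))
        assert per_od["T0-N"] / per_od["T24-N"] == pytest.approx(6.5, rel=0.02)

    def test_injected_concentrations_recovered(self):
        """Round trip: concentrations injected into the generator come back
        through the concentration equations within 3 % (noiseless)."""
        blank = make_bulk_spectrum("blank", noise_sd=0.0)
        for cond in ("T0+N", "T24-N", "T24replete"):
            phyc_per_od, _, od = bulk_targets(cond)
            corr = blank_correct(make_bulk_spectrum(cond, noise_sd=0.0), blank)
            conc = phycobilin_concentration(
                corr.at(620.0), corr.at(678.0), corr.at(730.0)
            )
            assert conc == pytest.approx(phyc_per_od * od, rel=0.03)

    def test_seeded_noise_reproducible(self):
        a = make_bulk_spectrum("T0+N", seed=5)
        b = make_bulk_spectrum("T0+N", seed=5)
        assert np.array_equal(a.absorbance, b.absorbance)
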