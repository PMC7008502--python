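"""Photon transport engine: step operations, full simulations, statistics."""

import numpy as np
import pytest

from polarmc.engine import (
    INPUT_STATES,
    ModelConfig,
    PhotonState,
    apply_birefringence,
    choose_scatterer,
    free_path,
    mc_standard_error,
    run_simulation,
    scatter,
    spatial_average,
)
from polarmc.invariants import invariant_set
from polarmc.mueller import make_retarder

WAVELENGTH = 0.533


def base_config(**kw):
    defaults = dict(thickness_um=10.0, n_photons=2000, n_batches=10, seed=5)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestFreePath:
    def test_mean_matches_inverse_coefficient(self, rng):
        mu = 1500.0  # cm^-1 -> mean free path 6.667 um
        draws = np.array([free_path(rng, mu) for _ in range(200_000)])
        assert draws.mean() == pytest.approx(1e4 / mu, rel=5e-3)

    def test_zero_coefficient_is_ballistic(self, rng):
        assert free_path(rng, 0.0) == np.inf

    def test_closed_form_quantile(self, rng):
        # median of the exponential is ln(2)/mu
        mu = 1000.0
        draws = np.array([free_path(rng, mu) for _ in range(100_000)])
        assert np.median(draws) == pytest.approx(np.log(2.0) * 1e4 / mu, rel=1e-2)


class TestChooseScatterer:
    def test_single_species_limits(self, rng):
        assert all(choose_scatterer(rng, 1.0, 0.0) == "sphere" for _ in range(100))
        assert all(choose_scatterer(rng, 0.0, 1.0) == "cylinder" for _ in range(100))

    @pytest.mark.parametrize("mu_s,mu_c,p", [(1.0, 1.0, 0.5), (1500.0, 500.0, 0.75)])
    def test_binomial_fraction(self, rng, mu_s, mu_c, p):
        n = 100_000
        hits = sum(choose_scatterer(rng, mu_s, mu_c) == "sphere" for _ in range(n))
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3.0 * sigma

    def test_both_zero_rejected(self, rng):
        with pytest.raises(ValueError):
            choose_scatterer(rng, 0.0, 0.0)


class TestBirefringence:
    def test_propagation_along_optic_axis_unaffected(self):
        cfg = base_config(delta_n=0.009, optic_axis=(1, 0, 0))
        p = PhotonState.launch(INPUT_STATES["P"])
        p.direction = np.array([1.0, 0.0, 0.0])
        p.frame_v = np.array([0.0, 1.0, 0.0])
        before = p.stokes.copy()
        apply_birefringence(p, 10.0, cfg)
        np.testing.assert_allclose(p.stokes, before)

    def test_ballistic_retardance_closed_form(self):
        cfg = base_config(delta_n=0.009)
        p = PhotonState.launch(INPUT_STATES["P"])
        apply_birefringence(p, 10.0, cfg)
        delta = 2.0 * np.pi * 0.009 * 10.0 / WAVELENGTH
        expected = make_retarder(delta, 0.0) @ INPUT_STATES["P"]
        np.testing.assert_allclose(p.stokes, expected, atol=1e-12)
        assert delta == pytest.approx(1.0609, abs=2e-4)

    def test_isotropic_host_is_identity(self):
        cfg = base_config(delta_n=0.0)
        p = PhotonState.launch(INPUT_STATES["R"])
        before = p.stokes.copy()
        apply_birefringence(p, 25.0, cfg)
        np.testing.assert_allclose(p.stokes, before)


class TestScatterStep:
    def test_sphere_event_preserves_intensity_and_frames(self, rng):
        cfg = base_config(mu_s_cm=1500.0)
        p = PhotonState.launch(INPUT_STATES["H"])
        scatter(p, "sphere", rng, cfg)
        assert p.stokes[0] == pytest.approx(1.0)
        assert np.linalg.norm(p.direction) == pytest.approx(1.0)
        assert abs(np.dot(p.direction, p.frame_v)) < 1e-12

    def test_cylinder_event_stays_on_cone(self, rng):
        cfg = base_config(mu_c_cm=1500.0)
        axis = np.array([1.0, 0.0, 0.0])
        for _ in range(200):
            p = PhotonState.launch(INPUT_STATES["H"])
            ca_in = abs(np.dot(p.direction, axis))
            scatter(p, "cylinder", rng, cfg)
            assert abs(abs(np.dot(p.direction, axis)) - ca_in) < 1e-9

    def test_unknown_scatterer(self, rng):
        with pytest.raises(ValueError):
            scatter(PhotonState.launch(INPUT_STATES["H"]), "cube", rng, base_config())


class TestRunSimulation:
    def test_empty_slab_is_identity(self):
        cfg = base_config(thickness_um=0.01, n_photons=500)
        res = run_simulation(cfg)
        np.testing.assert_allclose(res.matrix, np.eye(4), atol=1e-6)

    def test_ballistic_birefringent_slab_exact(self):
        cfg = base_config(delta_n=0.009, n_photons=500)
        res = run_simulation(cfg)
        delta = 2.0 * np.pi * 0.009 * 10.0 / WAVELENGTH
        np.testing.assert_allclose(res.matrix, make_retarder(delta, 0.0), atol=1e-12)

    def test_determinism(self):
        cfg = base_config(mu_s_cm=1500.0, delta_n=0.009, n_photons=5000)
        r1 = run_simulation(cfg)
        r2 = run_simulation(cfg)
        np.testing.assert_array_equal(r1.image.elements, r2.image.elements)
        np.testing.assert_array_equal(r1.batch_matrices, r2.batch_matrices)
        assert r1.tallies == r2.tallies

    def test_energy_bookkeeping(self):
        cfg = base_config(mu_s_cm=3000.0, mu_c_cm=1000.0, delta_n=0.009,
                          thickness_um=20.0, n_photons=20_000)
        res = run_simulation(cfg)
        for state, t in res.tallies.items():
            assert (
                t["detected"] + t["undetected"] + t["reflected"] + t["lost"]
                == t["launched"]
            )

    def test_angular_acceptance_reduces_detection(self):
        cfg = base_config(mu_s_cm=3000.0, thickness_um=20.0, n_photons=20_000)
        res_all = run_simulation(cfg)
        res_na = run_simulation(cfg.with_(accept_half_angle_deg=10.0))
        for s in INPUT_STATES:
            assert res_na.tallies[s]["detected"] < res_all.tallies[s]["detected"]

    def test_rayleigh_circular_depolarization_dominates_linear(self):
        # subwavelength spheres: |a44| > |aL| on the detected matrix
        cfg = base_config(mu_s_cm=1500.0, thickness_um=10.0, n_photons=50_000,
                          accept_half_angle_deg=20.0)
        inv = invariant_set(run_simulation(cfg).matrix)
        assert abs(inv.a44) > abs(inv.aL)
        assert inv.aL < 0 and inv.a44 < 0


class TestSpatialAverage:
    def test_uniform_image_gives_pixel_matrix(self):
        cfg = base_config(thickness_um=0.01, n_photons=500)
        img = run_simulation(cfg).image
        M = spatial_average(img, 600.0)
        np.testing.assert_allclose(M, np.eye(4), atol=1e-9)

    def test_zero_diameter_rounds_to_central_pixel(self):
        cfg = base_config(thickness_um=0.01, n_photons=500)
        img = run_simulation(cfg).image
        np.testing.assert_allclose(spatial_average(img, 0.0), np.eye(4), atol=1e-9)

    def test_scaling_invariance(self):
        cfg = base_config(thickness_um=0.01, n_photons=500)
        img = run_simulation(cfg).image
        ref = spatial_average(img, 600.0)
        img.elements *= 7.5
        np.testing.assert_allclose(spatial_average(img, 600.0), ref, atol=1e-12)

    def test_region_must_fit(self):
        cfg = base_config(thickness_um=0.01, n_photons=500)
        img = run_simulation(cfg).image
        with pytest.raises(ValueError):
            spatial_average(img, 1e5)


class TestStandardErrors:
    def test_identical_batches_zero_se(self):
        M = make_retarder(0.4, 0.1) * 123.0
        ses = mc_standard_error(np.array([M] * 10))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in ses.values())

    def test_requires_ten_batches(self):
        M = np.eye(4)
        with pytest.raises(ValueError):
            mc_standard_error(np.array([M] * 9))

    def test_se_scales_with_batch_count(self):
        # synthetic jitter: independent perturbations of a base matrix
        rng = np.random.default_rng(0)
        base = make_retarder(0.5, 0.0) * 100.0

        def batches(n):
            return np.array([base + rng.normal(scale=0.5, size=(4, 4)) for _ in range(n)])

        se_small = np.median([mc_standard_error(batches(10))["RT"] for _ in range(20)])
        se_large = np.median([mc_standard_error(batches(40))["RT"] for _ in range(20)])
        # total photons grow 4x -> SE of the pooled estimate halves
        assert se_large == pytest.approx(se_small / 2.0, rel=0.35)

    def test_seeded_run_reproduces_ses(self):
        cfg = base_config(mu_s_cm=1500.0, delta_n=0.009, n_photons=5000)
        s1 = run_simulation(cfg).standard_errors()
        s2 = run_simulation(cfg).standard_errors()
        assert s1 == s2
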