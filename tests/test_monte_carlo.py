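import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drsvessel.monte_carlo import (
    fresnel_reflectance,
    sample_henyey_greenstein,
    simulate,
    sweep_spectrum,
)
from drsvessel.tissue_model import (
    BeamSpec,
    CylindricalVessel,
    InvalidModelError,
    MCConfig,
    OpticalProperties,
    PhantomModel,
    PropertyTable,
    flip_model,
)


class TestFresnel:
    def test_matched_indices_no_reflection(self):
        assert fresnel_reflectance(1.0, 1.0, 0.7) == 0.0

    def test_normal_incidence_closed_form(self):
        # ((n-1)/(n+1))^2 at normal incidence
        assert fresnel_reflectance(1.0, 1.5, 1.0) == pytest.approx(0.04)

    def test_total_internal_reflection(self):
        # critical angle arcsin(1/1.5) ~ 41.8 deg < 60 deg
        assert fresnel_reflectance(1.5, 1.0, np.cos(np.radians(60.0))) == 1.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fresnel_reflectance(1.0, 1.5, 1.2)

    @settings(max_examples=100, deadline=None)
    @given(
        n_i=st.floats(1.0, 2.0),
        n_t=st.floats(1.0, 2.0),
        c=st.floats(0.0, 1.0),
    )
    def test_is_probability(self, n_i, n_t, c):
        r = fresnel_reflectance(n_i, n_t, c)
        assert 0.0 <= r <= 1.0


class TestHenyeyGreenstein:
    def test_isotropic_midpoint(self):
        assert sample_henyey_greenstein(0.0, 0.5) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(u=st.floats(0.0, 0.999999))
    def test_isotropic_limit_is_linear(self, u):
        assert sample_henyey_greenstein(0.0, u) == pytest.approx(2 * u - 1)

    @pytest.mark.parametrize("g", [0.5, 0.9, -0.3])
    def test_mean_cosine_equals_g(self, g):
        u = np.random.default_rng(2024).random(10**6)
        cos = sample_henyey_greenstein(g, u)
        assert np.all((cos >= -1) & (cos <= 1))
        se = cos.std() / 1000.0
        assert abs(cos.mean() - g) < 3 * se


class TestSimulate:
    def test_ballistic_transmission(self, wide_slab, pencil_beam, fast_mc):
        b = simulate(wide_slab, pencil_beam, OpticalProperties(0.0, 0.0, 0.0, 1.0), fast_mc)
        assert b.T == 1.0
        assert b.total == pytest.approx(1.0, abs=1e-12)

    def test_energy_budget_sums_to_one(self, wide_slab, pencil_beam, fast_mc):
        b = simulate(wide_slab, pencil_beam, OpticalProperties(0.05, 5.0, 0.5, 1.4), fast_mc)
        assert abs(b.total - 1.0) < 1e-9

    def test_determinism_bit_identical(self, wide_slab, pencil_beam):
        mc = MCConfig(photons=20_000, seed=77)
        p = OpticalProperties(0.02, 3.0, 0.0, 1.5)
        assert simulate(wide_slab, pencil_beam, p, mc) == simulate(
            wide_slab, pencil_beam, p, mc
        )

    def test_specular_entry_reflection(self, wide_slab, pencil_beam, fast_mc):
        b = simulate(wide_slab, pencil_beam, OpticalProperties(1.0, 0.0, 0.0, 1.5), fast_mc)
        assert b.R_specular == pytest.approx(0.04, abs=1e-12)

    def test_missing_blood_properties_is_config_error(self, fast_mc):
        model = PhantomModel(vessel=CylindricalVessel(300.0, 0.65))
        beam = BeamSpec(0.5, (500.0,))
        with pytest.raises(InvalidModelError, match="blood"):
            simulate(model, beam, OpticalProperties(0.01, 2.0, 0.0, 1.5), fast_mc)

    def test_absorption_grid_consistent_with_budget(self, pencil_beam):
        model = PhantomModel(thickness_mm=2.0, lateral_mm=5.0)
        mc = MCConfig(photons=5_000, seed=3, tally_fluence=True, fluence_pitch_mm=0.25)
        b, grid = simulate(model, pencil_beam, OpticalProperties(0.5, 2.0, 0.0, 1.5), mc)
        assert grid.total == pytest.approx(b.Abs, abs=1e-9)

    def test_side_escape_tallied_for_narrow_slab(self, pencil_beam):
        model = PhantomModel(thickness_mm=2.0, lateral_mm=1.0)
        mc = MCConfig(photons=20_000, seed=9)
        b = simulate(model, pencil_beam, OpticalProperties(0.001, 5.0, 0.0, 1.0), mc)
        assert b.E_side > 0.05
        assert abs(b.total - 1.0) < 1e-9


def _band_mean(spec):
    return spec.values.mean()


class TestSweep:
    def test_sweep_deterministic(self, vessel_model):
        beam = BeamSpec(0.5, tuple(np.linspace(400.0, 600.0, 5)))
        mc = MCConfig(photons=10_000, seed=21)
        r1, t1 = sweep_spectrum(vessel_model, beam, mc)
        r2, t2 = sweep_spectrum(vessel_model, beam, mc)
        np.testing.assert_array_equal(r1.values, r2.values)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_deeper_vessel_reflects_more(self, vessel_model):
        """R rises with vessel depth at every band wavelength (CRN)."""
        beam = BeamSpec(0.5, tuple(np.linspace(400.0, 600.0, 5)))
        mc = MCConfig(photons=30_000, seed=31)
        r_shallow, _ = sweep_spectrum(vessel_model.with_vessel_depth(0.35), beam, mc)
        r_deep, _ = sweep_spectrum(vessel_model.with_vessel_depth(1.35), beam, mc)
        assert np.all(r_deep.values > r_shallow.values)

    def test_larger_vessel_reflects_less(self, vessel_model):
        from dataclasses import replace

        beam = BeamSpec(0.5, tuple(np.linspace(400.0, 600.0, 5)))
        mc = MCConfig(photons=30_000, seed=41)
        small = replace(
            vessel_model, vessel=replace(vessel_model.vessel, diameter_um=100.0)
        )
        r_small, _ = sweep_spectrum(small, beam, mc)
        r_big, _ = sweep_spectrum(vessel_model, beam, mc)
        assert _band_mean(r_big) < _band_mean(r_small)

    def test_flip_preserves_transmittance(self, vessel_model):
        """T is invariant under flipping the slab (vessel at d vs 2-d) in the
        wide-beam limit, where the problem becomes plane-parallel."""
        beam = BeamSpec(6.0, tuple(np.linspace(400.0, 600.0, 5)))
        mc = MCConfig(photons=30_000, seed=51)
        _, t_orig = sweep_spectrum(vessel_model, beam, mc)
        _, t_flip = sweep_spectrum(flip_model(vessel_model), beam, mc)
        n = mc.photons
        for a, b in zip(t_orig.values, t_flip.values):
            se = np.sqrt((a * (1 - a) + b * (1 - b)) / n)
            assert abs(a - b) <= 3 * max(se, 1e-4)
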