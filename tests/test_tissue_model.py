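import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drsvessel.tissue_model import (
    BeamSpec,
    CylindricalVessel,
    InvalidModelError,
    MCConfig,
    OpticalProperties,
    PhantomModel,
    PropertyTable,
    REGIONS,
    flip_model,
    load_config,
    model_from_config,
    model_to_config,
    region_at,
    save_config,
)


def make_model(d=0.65, D=300.0):
    return PhantomModel(
        thickness_mm=2.0, lateral_mm=15.0, vessel=CylindricalVessel(D, d)
    )


class TestOpticalProperties:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mu_a=-0.1, mu_s=1.0),
            dict(mu_a=0.1, mu_s=-1.0),
            dict(mu_a=0.1, mu_s=1.0, g=1.0),
            dict(mu_a=0.1, mu_s=1.0, n=0.9),
        ],
    )
    def test_invariants_enforced(self, kwargs):
        with pytest.raises(InvalidModelError):
            OpticalProperties(**kwargs)

    def test_albedo_and_mu_t(self):
        p = OpticalProperties(1.0, 3.0)
        assert p.mu_t == 4.0
        assert p.albedo == 0.75


class TestVesselContainment:
    def test_vessel_breaking_top_surface_rejected(self):
        with pytest.raises(InvalidModelError):
            CylindricalVessel(300.0, 0.1)  # radius 0.15 mm > depth

    def test_vessel_breaking_bottom_surface_rejected(self):
        with pytest.raises(InvalidModelError):
            make_model(d=1.95, D=300.0)

    def test_diameter_unit_conversion(self):
        assert CylindricalVessel(300.0, 1.0).radius_mm == pytest.approx(0.15)


class TestRegionAt:
    def test_axis_point_is_vessel(self):
        m = make_model(d=0.65)
        assert region_at((0.0, 0.3, 0.65), m) == "vessel"

    def test_point_just_below_vessel_is_background(self):
        m = make_model(d=0.65, D=300.0)
        assert region_at((0.0, 0.0, 0.65 + 0.15 + 1e-6), m) == "background"

    def test_above_surface_is_ambient(self):
        assert region_at((0.0, 0.0, -1e-9), make_model()) == "ambient_above"

    def test_below_slab_and_lateral(self):
        m = make_model()
        assert region_at((0.0, 0.0, 2.5), m) == "ambient_below"
        assert region_at((20.0, 0.0, 1.0), m) == "lateral_exit"

    @settings(max_examples=200, deadline=None)
    @given(
        x=st.floats(-30, 30),
        y=st.floats(-30, 30),
        z=st.floats(-1, 3),
        d=st.floats(0.2, 1.8),
    )
    def test_partition_exactly_one_label(self, x, y, z, d):
        m = make_model(d=d, D=100.0)
        label = region_at((x, y, z), m)
        assert label in REGIONS

    @settings(max_examples=100, deadline=None)
    @given(
        x=st.floats(-5, 5),
        y=st.floats(-5, 5),
        z=st.floats(0.0, 2.0),
        d=st.floats(0.2, 1.8),
    )
    def test_region_commutes_with_flip(self, x, y, z, d):
        """Turning the slab upside down relabels positions consistently."""
        m = make_model(d=d, D=100.0)
        flipped = flip_model(m)
        direct = region_at((x, y, z), m)
        mirrored = region_at((x, y, m.thickness_mm - z), flipped)
        assert direct == mirrored


class TestFlip:
    def test_flip_depth_arithmetic(self):
        m = make_model(d=0.65)
        assert flip_model(m).vessel.axis_depth_mm == pytest.approx(1.35)

    def test_flip_is_involution(self):
        m = make_model(d=0.2)
        assert flip_model(flip_model(m)).vessel.axis_depth_mm == pytest.approx(0.2)

    def test_flip_swaps_ambient_indices(self):
        m = PhantomModel(n_above=1.0, n_below=1.33)
        f = flip_model(m)
        assert (f.n_above, f.n_below) == (1.33, 1.0)


class TestBeamAndConfig:
    def test_beam_wavelength_window(self):
        with pytest.raises(InvalidModelError):
            BeamSpec(0.5, (250.0, 500.0))
        with pytest.raises(InvalidModelError):
            BeamSpec(0.5, (500.0, 400.0))

    def test_mc_config_invariants(self):
        with pytest.raises(InvalidModelError):
            MCConfig(photons=0)
        with pytest.raises(InvalidModelError):
            MCConfig(roulette_threshold=2.0)

    def test_config_round_trip(self, tmp_path, vessel_model):
        beam = BeamSpec(0.5, (400.0, 500.0, 600.0))
        mc = MCConfig(photons=5000, seed=7)
        path = tmp_path / "model.json"
        save_config(path, vessel_model, beam, mc)
        m2, b2, mc2 = load_config(path)
        assert m2.thickness_mm == vessel_model.thickness_mm
        assert m2.vessel.diameter_um == vessel_model.vessel.diameter_um
        np.testing.assert_allclose(
            m2.background.mu_s, vessel_model.background.mu_s
        )
        assert b2.wavelengths_nm == beam.wavelengths_nm
        assert mc2.seed == 7

    def test_missing_config_key_named(self):
        cfg = {"geometry": {"thickness_mm": 2.0, "lateral_mm": 15.0}, "mc": {}}
        with pytest.raises(InvalidModelError, match="beam"):
            model_from_config(cfg)


class TestPropertyTable:
    def test_interpolation_and_range(self):
        t = PropertyTable([400.0, 600.0], [0.1, 0.3], [2.0, 1.0])
        p = t.at(500.0)
        assert p.mu_a == pytest.approx(0.2)
        assert p.mu_s == pytest.approx(1.5)
        with pytest.raises(InvalidModelError):
            t.at(700.0)
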