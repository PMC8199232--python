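import numpy as np
import pytest

from drsvessel.depth_inversion import (
    BracketError,
    DepthBracket,
    DepthEstimate,
    extract_depth,
    reflectance_depth_curve,
)
from drsvessel.monte_carlo import Spectrum, sweep_spectrum
from drsvessel.synthetic import ScenarioSpec, generate_scenario
from drsvessel.tissue_model import InvalidModelError, MCConfig

WAVELENGTHS = tuple(np.linspace(400.0, 600.0, 5))
FAST = dict(photons=20_000, wavelengths_nm=WAVELENGTHS)


class TestDepthCurve:
    def test_curve_increasing_in_depth(self, vessel_model):
        from drsvessel.tissue_model import BeamSpec

        beam = BeamSpec(0.5, WAVELENGTHS)
        mc = MCConfig(photons=20_000, seed=13)
        curve = reflectance_depth_curve(vessel_model, [0.3, 0.65, 1.0, 1.35, 1.7], beam, mc)
        vals = [c for _, c in curve]
        assert vals == sorted(vals)

    def test_no_vessel_bounds_curve_from_above(self, vessel_model):
        from dataclasses import replace
        from drsvessel.tissue_model import BeamSpec

        beam = BeamSpec(0.5, WAVELENGTHS)
        mc = MCConfig(photons=20_000, seed=13)
        (_, deepest), = reflectance_depth_curve(vessel_model, [1.8], beam, mc)
        clean = replace(vessel_model, vessel=None)
        r_clean, _ = sweep_spectrum(clean, beam, mc)
        assert r_clean.values.mean() >= deepest

    def test_curve_deterministic(self, vessel_model):
        from drsvessel.tissue_model import BeamSpec

        beam = BeamSpec(0.5, WAVELENGTHS)
        mc = MCConfig(photons=10_000, seed=17)
        c1 = reflectance_depth_curve(vessel_model, [0.5, 1.5], beam, mc)
        c2 = reflectance_depth_curve(vessel_model, [0.5, 1.5], beam, mc)
        assert c1 == c2

    def test_containment_violation_raises(self, vessel_model):
        from drsvessel.tissue_model import BeamSpec

        beam = BeamSpec(0.5, WAVELENGTHS)
        with pytest.raises(InvalidModelError):
            reflectance_depth_curve(
                vessel_model, [0.05], beam, MCConfig(photons=1000, seed=1)
            )


class TestExtractDepth:
    def test_endpoint_fixed_point(self):
        """Measurement generated at d1 with the solver's own seed returns d1."""
        spec = ScenarioSpec(vessel_depth_mm=0.65, noise=0.0, seed=19, **FAST)
        model = spec.model()
        beam = spec.beam()
        mc = spec.measurement_mc()  # same seed for "measurement" and solver
        r_meas, _ = sweep_spectrum(model, beam, mc)
        est = extract_depth(
            r_meas, model, beam, mc,
            bracket=DepthBracket(0.65, 1.5), mismatch_tol=1e-9,
        )
        assert est.d_hat_mm == pytest.approx(0.65, abs=1e-9)
        assert est.iterations <= 1

    def test_recovery_with_independent_seeds(self):
        spec = ScenarioSpec(
            vessel_depth_mm=1.0, vessel_diameter_um=300.0, noise=0.0, seed=23,
            photons=40_000, wavelengths_nm=WAVELENGTHS,
        )
        model, r_meas, _, truth = generate_scenario(spec)
        est = extract_depth(
            r_meas, model, spec.beam(), MCConfig(photons=40_000, seed=777),
            bracket=DepthBracket(0.3, 1.8), depth_tol_mm=0.02,
        )
        assert est.d_hat_mm == pytest.approx(1.0, rel=0.07)

    def test_iteration_bound(self):
        """Bisection halves the bracket: iterations <= ceil(log2(range/tol))."""
        spec = ScenarioSpec(vessel_depth_mm=1.0, noise=0.0, seed=29, **FAST)
        model, r_meas, _, _ = generate_scenario(spec)
        est = extract_depth(
            r_meas, model, spec.beam(), MCConfig(photons=20_000, seed=31),
            bracket=DepthBracket(0.3, 1.8), depth_tol_mm=0.05,
        )
        assert est.iterations <= int(np.ceil(np.log2(1.5 / 0.05)))

    def test_estimate_stays_in_bracket(self):
        spec = ScenarioSpec(vessel_depth_mm=0.65, noise=0.01, seed=37, **FAST)
        model, r_meas, _, _ = generate_scenario(spec)
        est = extract_depth(
            r_meas, model, spec.beam(), MCConfig(photons=20_000, seed=41),
            bracket=DepthBracket(0.4, 1.2), depth_tol_mm=0.05,
        )
        assert 0.4 <= est.d_hat_mm <= 1.2

    def test_unreachable_measurement_raises_bracket_error(self):
        spec = ScenarioSpec(vessel_depth_mm=1.0, noise=0.0, seed=43, **FAST)
        model, r_meas, _, _ = generate_scenario(spec)
        fake = Spectrum(r_meas.wavelengths_nm, np.full_like(r_meas.values, 0.95))
        with pytest.raises(BracketError):
            extract_depth(
                fake, model, spec.beam(), MCConfig(photons=20_000, seed=47),
                bracket=DepthBracket(0.3, 1.8),
            )

    def test_noisy_scenario_suite_median_error(self):
        """Median relative depth error over noisy scenarios stays small.

        Scaled-down variant of the multi-scenario recovery property: three
        1%-noise scenarios at 40k photons."""
        errs = []
        for seed, d in [(101, 0.65), (102, 1.0), (103, 1.35)]:
            spec = ScenarioSpec(
                vessel_depth_mm=d, vessel_diameter_um=300.0, noise=0.01,
                seed=seed, photons=40_000, wavelengths_nm=WAVELENGTHS,
            )
            model, r_meas, _, _ = generate_scenario(spec)
            est = extract_depth(
                r_meas, model, spec.beam(), MCConfig(photons=40_000, seed=7 * seed),
                bracket=DepthBracket(0.3, 1.8), depth_tol_mm=0.02,
            )
            errs.append(abs(est.d_hat_mm - d) / d)
        assert np.median(errs) <= 0.05
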