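"""Synthetic forcing: hydrograph, river inputs, initial ocean, case grid."""

import numpy as np
import pytest
from scipy.integrate import quad

from floodplume.grid import Grid
from floodplume.physics import PhysParams, equation_of_state
from floodplume.scenario import (CaseSpec, FloodPulse, InitialOceanParams,
                                 StdInputs, build_initial_ocean, case_grid,
                                 hyperpycnal_preset, hypopycnal_preset,
                                 riverine_concentrations,
                                 synthetic_flood_hydrograph)

BASE = 62.46


class TestHydrograph:
    def test_flat_pulse_returns_base_flow_everywhere(self):
        h = synthetic_flood_hydrograph(BASE, BASE, t_peak=3600.0, rise=1800.0,
                                       fall=1800.0, duration=86400.0)
        assert np.all(h.Q == BASE)

    def test_peak_value_exact_at_peak_time(self):
        h = synthetic_flood_hydrograph(BASE, 3000.0, t_peak=5000.0,
                                       rise=36000.0, fall=50400.0,
                                       duration=432000.0)
        assert h.Q.max() == 3000.0
        assert h.Q[np.argmax(h.Q)] == 3000.0
        assert h.times[np.argmax(h.Q)] == 5000.0

    def test_exact_base_flow_outside_pulse(self):
        p = FloodPulse(BASE, 3000.0, 86400.0, 36000.0, 50400.0, 432000.0)
        assert p.discharge(86400.0 - 36001.0) == BASE
        assert p.discharge(86400.0 + 50401.0) == BASE
        assert p.discharge(0.0) == BASE

    def test_flood_volume_matches_quadrature_oracle(self):
        p = FloodPulse(BASE, 3000.0, 86400.0, 36000.0, 50400.0, 432000.0)
        num, _ = quad(lambda t: p.discharge(t) - BASE, 0.0, 432000.0,
                      limit=400)
        assert num == pytest.approx(p.flood_volume(), rel=1e-8)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValueError):
            FloodPulse(BASE, 30.0, 0.0, 3600.0, 3600.0, 86400.0)  # peak < base
        with pytest.raises(ValueError):
            FloodPulse(BASE, 3000.0, 1e6, 3600.0, 3600.0, 86400.0)

    def test_bitwise_determinism(self):
        a = synthetic_flood_hydrograph(BASE, 3000.0, 86400.0, 36000.0,
                                       50400.0, 432000.0)
        b = synthetic_flood_hydrograph(BASE, 3000.0, 86400.0, 36000.0,
                                       50400.0, 432000.0)
        assert np.array_equal(a.times, b.times) and np.array_equal(a.Q, b.Q)


class TestRiverInputs:
    def test_standard_nutrient_concentration(self):
        std = StdInputs()
        _, N = riverine_concentrations(100.0, CaseSpec(1.0, 5e-5, 1.0), std)
        assert N == pytest.approx(0.046)

    def test_wos_carries_no_sediment(self):
        std = StdInputs()
        C, _ = riverine_concentrations(3000.0, CaseSpec(0.0, None, 1.0), std)
        assert C == 0.0

    def test_rating_curve_power_scaling(self):
        std = StdInputs(rating_a=1e-3, rating_b=1.3)
        case = CaseSpec(2.0, 5e-5, 1.0)
        C1, _ = riverine_concentrations(500.0, case, std)
        C2, _ = riverine_concentrations(1000.0, case, std)
        assert C2 / C1 == pytest.approx(2.0 ** 1.3, rel=1e-12)

    def test_calibrated_rating_is_density_neutral_at_crossing(self):
        """The calibration pins crossing_mult x STD at peak flow to the
        river-sea density crossing."""
        phys = PhysParams()
        std = StdInputs.calibrated(phys, T_river=20.0, T_ambient=24.0,
                                   S_ambient=32.0, peak_Q=3000.0,
                                   crossing_mult=5.0)
        C = 5.0 * std.c_std(3000.0)
        rho_riv = equation_of_state(20.0, 0.0, C, phys)
        rho_amb = equation_of_state(24.0, 32.0, 0.0, phys)
        assert rho_riv == pytest.approx(rho_amb, abs=1e-9)


class TestInitialOcean:
    def grid(self):
        return Grid.uniform(nx=8, dx=250.0,
                            dz=np.array([1.0, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0,
                                         5.0, 6.0, 7.0, 7.0]))

    def test_zero_halocline_gives_uniform_salinity(self, phys):
        prm = InitialOceanParams(S_surface=33.0, S_deep=33.0)
        init = build_initial_ocean(self.grid(), prm, phys)
        assert np.allclose(init.S, 33.0)

    def test_density_non_decreasing_downward(self, phys):
        init = build_initial_ocean(self.grid(), InitialOceanParams(), phys)
        rho = init.density(phys)
        assert np.all(np.diff(rho) >= -1e-12)

    def test_scm_sits_at_configured_depth_cell(self, phys):
        grid = self.grid()
        prm = InitialOceanParams(scm_depth=10.0)
        init = build_initial_ocean(grid, prm, phys)
        k_expect = int(np.argmin(np.abs(grid.z_c - 10.0)))
        assert int(np.argmax(init.P)) == k_expect
        assert init.P[k_expect] > init.P[0]      # maximum below the surface

    def test_surface_nutrient_depleted(self, phys):
        init = build_initial_ocean(self.grid(), InitialOceanParams(), phys)
        assert init.N[0] < init.N[-1]

    def test_unstable_request_rejected(self, phys):
        prm = InitialOceanParams(S_surface=35.0, S_deep=30.0)
        with pytest.raises(ValueError):
            build_initial_ocean(self.grid(), prm, phys)


class TestCaseGrid:
    def test_full_campaign_grid_has_155_cases(self):
        """Six nonzero SSM multipliers x five diameters x five nutrient
        levels, plus one WOS per nutrient level."""
        cases = case_grid(ssm_mults=[0, 0.1, 1, 2, 4, 6, 10],
                          diameters=[5e-6, 1e-5, 2e-5, 5e-5, 1e-4],
                          nutrient_mults=[0, 0.01, 0.1, 1, 10])
        assert len(cases) == 155
        assert sum(c.is_wos for c in cases) == 5

    def test_wos_only_grid(self):
        cases = case_grid([0], [], [1.0])
        assert len(cases) == 1 and cases[0].is_wos

    def test_duplicates_deduplicated(self):
        cases = case_grid([0, 1, 1, 2], [1e-5, 1e-5], [1.0, 1.0])
        # unique nonzero product 2*1*1 = 2, plus one WOS
        assert len(cases) == 3

    def test_out_of_range_multiplier_rejected(self):
        with pytest.raises(ValueError):
            case_grid([0, 12], [1e-5], [1.0])
        with pytest.raises(ValueError):
            CaseSpec(11.0, 1e-5, 1.0)

    def test_presets_match_typical_cases(self):
        hypo = hypopycnal_preset()
        assert (hypo.ssm_mult, hypo.diameter, hypo.nutrient_mult) == (4.0, 5e-5, 1.0)
        hyper = hyperpycnal_preset()
        assert (hyper.ssm_mult, hyper.diameter, hyper.nutrient_mult) == (10.0, 1e-5, 1.0)
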