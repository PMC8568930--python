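"""Full model step: conservation, equilibrium, adjustment, stable_dt."""

import numpy as np
import pytest

from floodplume.grid import Grid
from floodplume.model import (OceanState, PlumeModel, convective_adjust,
                              stable_dt)
from floodplume.physics import PhysParams, equation_of_state
from floodplume.scenario import InitialOceanParams, build_initial_ocean


def closed_model(grid, phys, biology=False):
    return PlumeModel(grid, phys, forcing=None, sponge=None,
                      biology_on=biology)


def rest_state(grid, phys):
    init = build_initial_ocean(grid, InitialOceanParams(), phys)
    return OceanState.rest(grid, init)


class TestConvectiveAdjustment:
    def test_stable_column_unchanged(self, grid_small, phys):
        st = rest_state(grid_small, phys)
        out = convective_adjust(st, phys, grid_small)
        for name in ("T", "S", "N", "P"):
            assert np.array_equal(getattr(out, name), getattr(st, name))

    def test_two_cell_inversion_mixes_to_average(self, phys):
        grid = Grid.uniform(nx=3, dx=100.0, dz=np.array([1.0, 1.0, 1.0, 1.0]))
        st = rest_state(grid, phys)
        st.S[:, :] = 33.0
        st.S[0, 1] = 35.0
        st.S[1, 1] = 33.0
        st.T[:, :] = 20.0
        out = convective_adjust(st, phys, grid)
        col = out.S[:, 1]
        # equal-thickness pair(s) mix to averages and the column is stable
        rho = equation_of_state(out.T[:, 1], col, out.C[:, 1], phys)
        assert np.all(np.diff(rho) >= -1e-12)
        assert col.sum() == pytest.approx(st.S[:, 1].sum() + 0.0, rel=1e-14)
        assert col[0] < 35.0                      # actually mixed

    def test_random_columns_stable_and_conservative(self, phys):
        """Property check against the brute-force notion of adjustment:
        any result must be statically stable and conserve every tracer
        column integral exactly."""
        grid = Grid.uniform(nx=10, dx=100.0,
                            dz=np.array([1.0, 1.5, 2.0, 2.5, 3.0]))
        rng = np.random.default_rng(11)
        st = rest_state(grid, phys)
        st.S = np.where(grid.mask, 30.0 + 5.0 * rng.random(st.S.shape), 0.0)
        st.T = np.where(grid.mask, 15.0 + 10.0 * rng.random(st.S.shape), 0.0)
        st.N = np.where(grid.mask, rng.random(st.S.shape), 0.0)
        before = {n: (getattr(st, n) * grid.cell_volume).sum(axis=0)
                  for n in ("T", "S", "N")}
        out = convective_adjust(st, phys, grid)
        rho = equation_of_state(out.T, out.S, out.C, phys)
        for i in range(grid.nx):
            col = rho[grid.mask[:, i], i]
            assert np.all(np.diff(col) >= -1e-10)
        for n, b in before.items():
            after = (getattr(out, n) * grid.cell_volume).sum(axis=0)
            assert np.allclose(after, b, rtol=1e-12)


class TestClosedBudgets:
    def test_zero_forcing_resting_state_is_fixed_point(self):
        """A stably stratified resting state with negligible mixing is a
        fixed point of the step (no spurious currents or drift)."""
        phys = PhysParams(Kh=1e-12, Kv=1e-14, Ah=1e-12, Av=1e-14)
        grid = Grid.uniform(nx=10, dx=250.0,
                            dz=np.array([1.0, 1.0, 2.0, 3.0, 4.0]))
        st = rest_state(grid, phys)
        model = closed_model(grid, phys)
        s0 = st.copy()
        for _ in range(100):
            st = model.step(st, 60.0)
        assert np.abs(st.u).max() <= 1e-9
        assert np.abs(st.S - s0.S).max() <= 1e-9
        assert np.abs(st.T - s0.T).max() <= 1e-9

    def test_closed_run_conserves_salt_and_nitrogen(self, phys):
        """1000 steps with stirred initial flow: salt and total nitrogen
        drift stay at round-off (<= 1e-10 relative per run)."""
        grid = Grid.uniform(nx=12, dx=250.0,
                            dz=np.array([1.0, 1.0, 2.0, 3.0, 4.0]))
        st = rest_state(grid, phys)
        rng = np.random.default_rng(5)
        st.S += np.where(grid.mask, 0.5 * rng.random(st.S.shape), 0.0)
        model = closed_model(grid, phys, biology=True)
        vol = grid.cell_volume
        salt0 = float((st.S * vol).sum())
        nit0 = float(((st.N + st.P + st.Z + st.Dt) * vol).sum())
        for _ in range(1000):
            st = model.step(st, 45.0)
        salt1 = float((st.S * vol).sum())
        nit1 = float(((st.N + st.P + st.Z + st.Dt) * vol).sum())
        assert abs(salt1 - salt0) <= 1e-10 * salt0
        assert abs(nit1 - nit0) <= 1e-8 * nit0
        assert model.clipped <= 1e-12 * nit0 or model.clipped == 0.0
        st.validate(grid)

    def test_max_divergence_stays_healthy(self, phys):
        grid = Grid.uniform(nx=12, dx=250.0,
                            dz=np.array([1.0, 1.0, 2.0, 3.0, 4.0]))
        st = rest_state(grid, phys)
        rng = np.random.default_rng(9)
        st.S += np.where(grid.mask, 0.5 * rng.random(st.S.shape), 0.0)
        model = closed_model(grid, phys)
        for _ in range(50):
            st = model.step(st, 60.0)
        assert model.max_div <= 1e-8


class TestStableDt:
    def grid(self):
        return Grid.uniform(nx=12, dx=250.0,
                            dz=np.array([1.0, 1.0, 2.0, 3.0, 4.0]))

    def test_quiescent_state_bounded_by_diffusion_and_waves(self, phys):
        grid = self.grid()
        st = rest_state(grid, phys)
        model = closed_model(grid, phys)
        b = model.stable_dt_bounds(st)
        # no velocities, no settling: the advective bound is effectively
        # unbounded and dt is set by the other two
        assert b["advective"] > 1e6
        assert model.stable_dt(st) <= model.safety * min(
            b["diffusive"], b["internal_wave"])

    def test_doubling_velocity_halves_dt_at_advective_limit(self, phys):
        grid = self.grid()
        st = rest_state(grid, phys)
        st.u[:, :] = 2.0              # strongly advective regime
        model = closed_model(grid, phys)
        dt1 = model.stable_dt(st)
        st.u[:, :] = 4.0
        dt2 = model.stable_dt(st)
        assert dt2 == pytest.approx(dt1 / 2.0, rel=1e-9)

    def test_equals_min_of_three_independent_bounds(self, phys):
        grid = self.grid()
        st = rest_state(grid, phys)
        rng = np.random.default_rng(3)
        st.u = 0.5 * rng.random(st.u.shape)
        st.w[1:-1, :] = 0.01 * rng.random((grid.nz - 1, grid.nx))
        model = closed_model(grid, phys)
        # independent recomputation of the three closed-form bounds
        adv = min(grid.dx / np.abs(st.u).max(),
                  grid.dz.min() / np.abs(st.w).max())
        diff = 0.5 * min(grid.dx**2 / (2 * max(phys.Kh, phys.Ah)),
                         grid.dz.min()**2 / (2 * max(phys.Kv, phys.Av)))
        rho = equation_of_state(st.T, st.S, st.C, phys)
        drho = rho[grid.mask].max() - rho[grid.mask].min()
        c = np.sqrt(phys.g * max(drho, 1e-6) / phys.rho0 * grid.H.max() / 4)
        expected = model.safety * min(adv, diff, grid.dx / c, model.max_dt / model.safety)
        assert model.stable_dt(st) == pytest.approx(expected, rel=1e-12)

    def test_functional_wrapper_matches_model(self, phys):
        grid = self.grid()
        st = rest_state(grid, phys)
        model = closed_model(grid, phys)
        assert stable_dt(st, phys, grid) == pytest.approx(model.stable_dt(st))
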