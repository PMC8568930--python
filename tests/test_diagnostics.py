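"""Plume masking, means, difference series, regime maps."""

import numpy as np
import pandas as pd
import pytest

from floodplume.diagnostics import (EmptyMaskError, PlumeParams, PlumeSeries,
                                    SurfaceSeries, build_regime_map,
                                    difference_series, plume_mask, plume_mean,
                                    regime_classify, river_density_difference)
from floodplume.grid import Grid
from floodplume.physics import PhysParams, ssm_density_crossing
from floodplume.scenario import CaseSpec, StdInputs


class FakeState:
    def __init__(self, S):
        self.S = np.asarray(S)


def grid4():
    return Grid.uniform(nx=6, dx=100.0, dz=np.array([1.0, 1.0, 2.0, 3.0]))


def make_series(case, times, S, N=None, P=None, grid=None):
    S = np.asarray(S, dtype=float)
    if N is None:
        N = np.zeros_like(S)
    if P is None:
        P = np.zeros_like(S)
    return SurfaceSeries(case=case, times=np.asarray(times, float),
                         S=S, N=np.asarray(N, float), P=np.asarray(P, float),
                         grid=grid or grid4())


class TestMask:
    def test_salty_everywhere_gives_empty_mask(self):
        st = FakeState(np.full((4, 6), 35.0))
        assert not plume_mask(st, PlumeParams(mask_source="per-case")).any()

    def test_fresh_surface_slab_masks_exactly_top_two_layers(self):
        S = np.full((4, 6), 35.0)
        S[:2, :] = 20.0
        m = plume_mask(FakeState(S), PlumeParams(mask_source="per-case"))
        assert m.shape == (2, 6) and m.all()

    def test_threshold_boundary_included(self):
        S = np.full((4, 6), 35.0)
        S[0, 2] = 28.0
        m = plume_mask(FakeState(S), PlumeParams(mask_source="per-case"))
        assert m[0, 2]

    def test_reference_mask_requires_reference(self):
        st = FakeState(np.full((4, 6), 20.0))
        with pytest.raises(ValueError):
            plume_mask(st, PlumeParams(mask_source="reference"))

    def test_lowering_threshold_never_grows_mask(self):
        rng = np.random.default_rng(0)
        S = 20.0 + 15.0 * rng.random((4, 6))
        st = FakeState(S)
        m28 = plume_mask(st, PlumeParams(salinity_threshold=28.0,
                                         mask_source="per-case"))
        m25 = plume_mask(st, PlumeParams(salinity_threshold=25.0,
                                         mask_source="per-case"))
        assert not np.any(m25 & ~m28)


class TestPlumeMean:
    def test_uniform_field_returns_value(self):
        g = grid4()
        mask = np.ones((2, g.nx), dtype=bool)
        assert plume_mean(np.full((4, g.nx), 7.5), mask, g) == 7.5

    def test_two_equal_volume_cells_average(self):
        g = grid4()     # top two layers have equal dz
        mask = np.zeros((2, g.nx), dtype=bool)
        mask[0, 0] = mask[1, 0] = True
        f = np.zeros((4, g.nx))
        f[0, 0], f[1, 0] = 0.0, 2.0
        assert plume_mean(f, mask, g) == pytest.approx(1.0)

    def test_matches_brute_force_weighted_sum(self):
        g = grid4()
        rng = np.random.default_rng(3)
        f = rng.random((4, g.nx))
        mask = rng.random((2, g.nx)) > 0.4
        if not mask.any():
            mask[0, 0] = True
        num = den = 0.0
        for k in range(2):
            for i in range(g.nx):
                if mask[k, i]:
                    wv = g.dz[k] * g.dx
                    num += f[k, i] * wv
                    den += wv
        assert plume_mean(f, mask, g) == pytest.approx(num / den, rel=1e-12)

    def test_empty_mask_signals_missing(self):
        g = grid4()
        with pytest.raises(EmptyMaskError):
            plume_mean(np.ones((4, g.nx)), np.zeros((2, g.nx), bool), g)


class TestDifferenceSeries:
    def pp(self):
        return PlumeParams(mask_source="per-case")

    def test_identical_runs_difference_zero(self):
        S = 20.0 + np.random.default_rng(1).random((5, 2, 6))
        a = make_series(CaseSpec(1.0, 1e-5, 1.0), np.arange(5.0), S)
        b = make_series(CaseSpec(0.0, None, 1.0), np.arange(5.0), S.copy())
        ps = difference_series(a, b, self.pp())
        assert np.allclose(ps.table["dS"], 0.0)

    def test_constant_offset_recovered(self):
        rng = np.random.default_rng(2)
        S = 20.0 + rng.random((5, 2, 6))
        a = make_series(CaseSpec(1.0, 1e-5, 1.0), np.arange(5.0), S + 0.5)
        b = make_series(CaseSpec(0.0, None, 1.0), np.arange(5.0), S)
        ps = difference_series(a, b, self.pp())
        assert np.allclose(ps.table["dS"], 0.5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        Sa = 20.0 + rng.random((6, 2, 6))
        Sb = 20.0 + rng.random((6, 2, 6))
        a = make_series(CaseSpec(2.0, 1e-5, 1.0), np.arange(6.0), Sa)
        b = make_series(CaseSpec(4.0, 1e-5, 1.0), np.arange(6.0), Sb)
        dab = difference_series(a, b, self.pp()).table["dS"].to_numpy()
        dba = difference_series(b, a, self.pp()).table["dS"].to_numpy()
        assert np.allclose(dab, -dba)

    def test_time_grid_mismatch_rejected(self):
        S = np.full((5, 2, 6), 20.0)
        a = make_series(CaseSpec(1.0, 1e-5, 1.0), np.arange(5.0), S)
        b = make_series(CaseSpec(0.0, None, 1.0), np.arange(5.0) + 0.5, S)
        with pytest.raises(ValueError):
            difference_series(a, b, self.pp())

    def test_empty_mask_times_recorded_missing(self):
        S = np.full((4, 2, 6), 35.0)     # always salty -> empty mask
        S[2] = 20.0                       # except one time
        Sa = S.copy()
        Sa[2] += 0.5
        a = make_series(CaseSpec(1.0, 1e-5, 1.0), np.arange(4.0), Sa)
        b = make_series(CaseSpec(0.0, None, 1.0), np.arange(4.0), S)
        ps = difference_series(a, b, self.pp())
        assert ps.table["S"].isna().sum() == 3
        assert ps.extrema["S"]["time"] == 2.0
        assert ps.extrema["S"]["value"] == pytest.approx(0.5)


class TestRegimeClassification:
    @pytest.mark.parametrize("value,label", [
        (-0.3, "hypopycnal"),
        (+1.0, "hyperpycnal"),
        (0.0, "neutral"),
        (0.005, "neutral"),
    ])
    def test_sign_convention(self, value, label):
        assert regime_classify(value, tol=0.01) == label

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            regime_classify(float("nan"))


class TestRiverDensityDifference:
    def setup_method(self):
        self.phys = PhysParams()
        self.std = StdInputs.calibrated(self.phys, T_river=20.0,
                                        T_ambient=24.0, S_ambient=32.0,
                                        peak_Q=3000.0, crossing_mult=5.0)

    def test_no_sediment_river_water_is_lighter(self):
        d = river_density_difference(CaseSpec(0.0, None, 1.0), self.std,
                                     3000.0, 20.0, 24.0, 32.0, self.phys)
        assert d < 0.0

    def test_crossing_concentration_is_neutral(self):
        d = river_density_difference(CaseSpec(5.0, 1e-5, 1.0), self.std,
                                     3000.0, 20.0, 24.0, 32.0, self.phys)
        assert abs(d) <= 1e-9

    def test_diameter_independent(self):
        args = (self.std, 3000.0, 20.0, 24.0, 32.0, self.phys)
        d1 = river_density_difference(CaseSpec(6.0, 1e-5, 1.0), *args)
        d2 = river_density_difference(CaseSpec(6.0, 5e-5, 1.0), *args)
        assert d1 == d2


def synthetic_plume_series(case, ds_value, t_ext=10.0):
    times = np.arange(0.0, 21.0)
    d = ds_value * np.exp(-0.5 * ((times - t_ext) / 3.0) ** 2)
    tab = pd.DataFrame({"time": times, "area": 100.0, "S": 25.0, "N": 0.0,
                        "P": 0.0, "S_ref": 25.0, "N_ref": 0.0, "P_ref": 0.0,
                        "dS": d, "dN": 0.0 * d, "dP": 0.0 * d})
    i = int(np.argmax(np.abs(d)))
    ext = {"S": {"time": float(times[i]), "value": float(d[i])},
           "N": {"time": float(times[i]), "value": 0.0},
           "P": {"time": float(times[i]), "value": 0.0}}
    return PlumeSeries(case=case, table=tab, extrema=ext)


class TestRegimeMap:
    def pp(self):
        return PlumeParams(mask_source="per-case", neutral_tol=0.01)

    def test_all_wos_grid_is_neutral_zero(self):
        runs = [(CaseSpec(0.0, None, 1.0),
                 synthetic_plume_series(CaseSpec(0.0, None, 1.0), 0.0))]
        rm = build_regime_map(runs, self.pp())
        assert np.allclose(rm.value, 0.0)
        assert (rm.label == "neutral").all()

    def test_cells_hold_constructed_extrema(self):
        vals = {(1.0, 1e-5): -0.4, (1.0, 5e-5): -0.2,
                (4.0, 1e-5): 0.8, (4.0, 5e-5): -0.6}
        runs = []
        for (m, d), v in vals.items():
            c = CaseSpec(m, d, 1.0)
            runs.append((c, synthetic_plume_series(c, v)))
        rm = build_regime_map(runs, self.pp())
        for (m, d), v in vals.items():
            j = list(rm.diameters).index(d)
            i = list(rm.ssm_mults).index(m)
            assert rm.value[j, i] == pytest.approx(v)
            assert rm.label[j, i] == regime_classify(v, 0.01)

    def test_transition_interval_bracketing(self):
        """Monotone dS crossing zero between multipliers 4 and 6."""
        runs = []
        for m, v in [(1.0, -0.5), (2.0, -0.7), (4.0, -0.9), (6.0, 0.6),
                     (8.0, 1.4)]:
            c = CaseSpec(m, 2e-5, 1.0)
            runs.append((c, synthetic_plume_series(c, v)))
        rm = build_regime_map(runs, self.pp())
        assert rm.transition[2e-5] == (4.0, 6.0)

    def test_incomplete_grid_lists_missing_cells(self):
        runs = []
        for m, d in [(1.0, 1e-5), (2.0, 1e-5), (1.0, 5e-5)]:
            c = CaseSpec(m, d, 1.0)
            runs.append((c, synthetic_plume_series(c, -0.1)))
        with pytest.raises(ValueError, match="missing"):
            build_regime_map(runs, self.pp())
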