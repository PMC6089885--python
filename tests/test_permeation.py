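"""Permeation event counting and collective-diffusion permeability."""

import numpy as np
import pytest

from chanflux.errors import InsufficientDataError
from chanflux.permeation import (
    Region,
    V_W_CM3,
    collective_coordinate,
    count_permeation_events,
    extract_axial_traces,
    osmotic_permeability,
)
from chanflux.synthetic import gen_planted_crossings, gen_single_file_channel
from chanflux.trajectory_model import ChannelGeometry


class TestTraces:
    def test_linear_crosser_state_sequence(self, geom, water_view):
        view = water_view(np.linspace(-20, 20, 41)[:, None])
        (trace,) = extract_axial_traces(view, geom, "all")
        states = trace.region_state
        assert states[0] == Region.BELOW
        assert states[-1] == Region.ABOVE
        assert np.any(states == Region.INSIDE)
        # monotone path: below block, inside block, above block
        changes = np.nonzero(np.diff(states))[0]
        assert len(changes) == 2

    def test_stationary_water_always_inside(self, geom, water_view):
        view = water_view(np.zeros((10, 1)))
        (trace,) = extract_axial_traces(view, geom, "all")
        assert np.all(trace.region_state == Region.INSIDE)

    def test_random_walks_match_brute_force_classification(self, geom, water_view):
        rng = np.random.default_rng(12)
        z = np.cumsum(rng.normal(0, 3, size=(200, 50)), axis=0)
        lat = rng.uniform(0, 12)
        view = water_view(z, lateral=lat)
        traces = extract_axial_traces(view, geom, "all")
        for w, tr in enumerate(traces):
            for f in range(200):
                zz = z[f, w]
                if zz < geom.z_lower:
                    exp = Region.BELOW
                elif zz > geom.z_upper:
                    exp = Region.ABOVE
                elif lat <= geom.lateral_cutoff:
                    exp = Region.INSIDE
                else:
                    exp = Region.OUTSIDE_LATERAL
                assert tr.region_state[f] == exp


class TestEventCounting:
    def test_single_up_crossing(self, geom, water_view):
        view = water_view(np.linspace(-20, 20, 21)[:, None])
        traces = extract_axial_traces(view, geom, "all")
        records, total, up, down = count_permeation_events(traces)
        assert (total, up, down) == (1, 1, 0)
        assert records[0].direction == "up"
        assert records[0].entry_time < records[0].exit_time

    def test_retreating_water_records_nothing(self, geom, water_view):
        z = np.concatenate([np.linspace(-20, 0, 11), np.linspace(0, -20, 11)[1:]])
        view = water_view(z[:, None])
        _, total, _, _ = count_permeation_events(
            extract_axial_traces(view, geom, "all")
        )
        assert total == 0

    def test_planted_mixture_counts_exactly(self):
        traj, geom, truth = gen_planted_crossings(n_up=5, n_down=3, n_retreat=4)
        _, total, up, down = count_permeation_events(
            extract_axial_traces(traj, geom, "all")
        )
        assert (total, up, down) == (8, 5, 3)

    def test_lateral_exit_resets_state_machine(self, geom, water_view):
        # enters from below, drifts laterally out mid-channel at z > 0,
        # then reaches above: no complete pore passage
        z = np.linspace(-20, 20, 41)
        view = water_view(z[:, None])
        mid = (z > 2) & (z < 10)
        view.coords[mid, 0, 0] = 10.0  # outside lateral cutoff
        _, total, _, _ = count_permeation_events(
            extract_axial_traces(view, geom, "all")
        )
        assert total == 0

    def test_time_reversal_swaps_directions(self):
        traj, geom, _ = gen_single_file_channel(
            n_waters=40, n_frames=3000, seed=21, dt_ps=10.0
        )
        traces = extract_axial_traces(traj, geom, "all")
        _, total, up, down = count_permeation_events(traces)
        rev = traj.with_coords(traj.coords[::-1])
        rtraces = extract_axial_traces(rev, geom, "all")
        _, rtotal, rup, rdown = count_permeation_events(rtraces)
        assert rtotal == total
        assert (rup, rdown) == (down, up)

    def test_frame_rate_doubling_preserves_counts(self, geom, water_view):
        z = np.linspace(-20, 20, 21)
        coarse = water_view(z[:, None], dt=2.0)
        fine = water_view(np.linspace(-20, 20, 41)[:, None], dt=1.0)
        _, t1, _, _ = count_permeation_events(extract_axial_traces(coarse, geom, "all"))
        _, t2, _, _ = count_permeation_events(extract_axial_traces(fine, geom, "all"))
        assert t1 == t2 == 1


class TestCollectiveCoordinate:
    def test_no_inside_waters_gives_zero(self, geom, water_view):
        view = water_view(np.full((20, 3), -25.0))
        series = collective_coordinate(extract_axial_traces(view, geom, "all"), geom)
        assert np.all(series.n == 0)

    def test_near_full_crossing_increments_by_dz_over_L(self, geom, water_view):
        # one inside water displaced +29.8 Å of L = 30 Å in one step
        view = water_view(np.array([[-14.9], [-14.9], [14.9]]))
        series = collective_coordinate(extract_axial_traces(view, geom, "all"), geom)
        assert series.n[-1] == pytest.approx(29.8 / 30.0)

    def test_brownian_variance_grows_with_2Dn(self):
        # Var[n(t)] ~ 2 D_n t for the generator's collective coordinate
        traj, geom, truth = gen_single_file_channel(
            D_n_true=1.0, n_waters=100, n_frames=100_000 // 10, dt_ps=10.0, seed=2
        )
        series = collective_coordinate(extract_axial_traces(traj, geom, "all"), geom)
        # slope of Var over disjoint increments
        lag = 50  # frames -> 500 ps
        d = series.n[lag:] - series.n[:-lag]
        var = d.var()
        D_est = var / (2 * lag * 10.0) * 1000.0  # 1/ns
        assert D_est == pytest.approx(1.0, rel=0.15)


class TestPermeability:
    def test_constant_series_gives_zero(self, geom):
        from chanflux.permeation import CollectiveCoordinateSeries

        s = CollectiveCoordinateSeries(
            times=np.arange(2000) * 10.0, n=np.zeros(2000), pore_length_L=30.0
        )
        res = osmotic_permeability(s)
        assert res.D_n == 0.0
        assert res.p_f == 0.0

    def test_single_water_molar_volume(self):
        v = 18.015 / (0.997 * 6.022e23)
        assert V_W_CM3 == pytest.approx(v, rel=0.002)

    def test_too_few_windows_raises(self):
        from chanflux.permeation import CollectiveCoordinateSeries

        s = CollectiveCoordinateSeries(
            times=np.arange(50) * 10.0, n=np.zeros(50), pore_length_L=30.0
        )
        with pytest.raises(InsufficientDataError):
            osmotic_permeability(s)

    def test_brownian_path_recovers_known_Dn(self):
        # direct Brownian n(t): increments N(0, 2 D dt), D = 1/ns
        rng = np.random.default_rng(5)
        D, dt = 1.0 / 1000.0, 10.0  # 1/ps, ps
        estimates = []
        for _ in range(5):
            n = np.concatenate(
                [[0.0], np.cumsum(rng.normal(0, np.sqrt(2 * D * dt), 5000))]
            )
            from chanflux.permeation import CollectiveCoordinateSeries

            s = CollectiveCoordinateSeries(
                times=np.arange(5001) * dt, n=n, pore_length_L=30.0
            )
            estimates.append(osmotic_permeability(s).D_n)
        assert np.mean(estimates) == pytest.approx(1.0, rel=0.1)

    def test_pf_unit_conversion(self):
        from chanflux.permeation import CollectiveCoordinateSeries

        rng = np.random.default_rng(8)
        n = np.concatenate([[0.0], np.cumsum(rng.normal(0, 0.14, 3000))])
        s = CollectiveCoordinateSeries(times=np.arange(3001) * 10.0, n=n, pore_length_L=30.0)
        res = osmotic_permeability(s)
        assert res.p_f == pytest.approx(res.v_w * res.D_n * 1e9 / 1e-14)
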