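"""MD trajectory statistics: occupancy, exchange time, permeation, density."""

import numpy as np
import pytest

from chw import mdstats
from chw.mdstats import Site, Trajectory
from chw.synth import TrajectorySpec, make_count_trajectory, make_two_state_trajectory


def constant_site_traj(n_frames=100, occupied=True, dt=0.1):
    coords = np.zeros((n_frames, 2, 3))
    coords[:, 1] = [50.0, 50.0, 50.0]
    if not occupied:
        coords[:, 0] = [40.0, 40.0, 40.0]
    return Trajectory(coords, dt)


# ------------------------------------------------------------------ occupancy

def test_always_occupied_site():
    stats = mdstats.site_occupancy(constant_site_traj(), Site((0, 0, 0), 1.4))
    assert stats.occupancy == 1.0
    tau, n_ep = mdstats.exchange_time(stats, 0.1)
    assert tau == pytest.approx(10.0) and n_ep == 1


def test_never_occupied_site():
    stats = mdstats.site_occupancy(constant_site_traj(occupied=False), Site((0, 0, 0), 1.4))
    assert stats.occupancy == 0.0
    with pytest.raises(ValueError):
        mdstats.exchange_time(stats, 0.1)


def test_empty_trajectory_is_error():
    traj = Trajectory(np.zeros((0, 2, 3)), 0.1)
    with pytest.raises(ValueError):
        mdstats.site_occupancy(traj, Site((0, 0, 0), 1.4))


@pytest.mark.parametrize("p_true,dwell", [(0.44, 3.0), (0.60, 3.0), (0.94, 15.0)])
def test_two_state_occupancy_within_3se(p_true, dwell):
    """Estimator agrees with the chain's stationary truth within 3 SE.

    The effective sample size is the number of occupancy cycles, not frames
    (consecutive frames are strongly correlated).
    """
    spec = TrajectorySpec(n_frames=6000, seed=17, p_occupied=p_true,
                          mean_dwell_frames=dwell)
    traj = make_two_state_trajectory(spec)
    stats = mdstats.site_occupancy(traj, Site(spec.site_center, spec.site_radius))
    n_cycles = max(stats.n_exchanges, 1)
    se = np.sqrt(spec.achieved_p * (1 - spec.achieved_p) / n_cycles)
    assert abs(stats.occupancy - spec.achieved_p) <= 3 * se + 1e-9


def test_occupancy_estimator_consistency():
    """|estimate − truth| shrinks from 500 to 5000 frames (seed-averaged)."""
    errs = {}
    for n in (500, 5000):
        errs[n] = np.mean([
            abs(
                mdstats.site_occupancy(
                    make_two_state_trajectory(
                        TrajectorySpec(n_frames=n, seed=s, p_occupied=0.6,
                                       mean_dwell_frames=3)
                    ),
                    Site((0, 0, 0), 1.4),
                ).occupancy
                - 0.6
            )
            for s in range(8)
        ])
    assert errs[5000] < errs[500]


# ------------------------------------------------------------------ exchange time

def test_exchange_time_geometric_dwell_recovery():
    """Mean episode length recovers the geometric dwell within 2 SE."""
    spec = TrajectorySpec(n_frames=20000, seed=5, p_occupied=0.94,
                          mean_dwell_frames=15, dt=0.1)
    traj = make_two_state_trajectory(spec)
    stats = mdstats.site_occupancy(traj, Site((0, 0, 0), 1.4))
    tau, n_ep = mdstats.exchange_time(stats, traj.dt, gap_tolerance=0)
    assert n_ep >= 200
    se = 1.5 / np.sqrt(n_ep)  # geometric dwell: sd ≈ mean
    assert abs(tau - 1.5) <= 2 * se


def test_exchange_time_alternating_occupants():
    history = np.array([0, 1, 0, 1, 0, 1])
    stats = mdstats.OccupancyStats(1.0, None, 0, history, 0.1)
    tau, n_ep = mdstats.exchange_time(stats, 0.1, gap_tolerance=0)
    assert tau == pytest.approx(0.1) and n_ep == 6


def test_exchange_time_gap_merging():
    """A one-frame vacancy inside a same-occupant run merges at tolerance 1."""
    history = np.array([7, 7, -1, 7, 7])
    stats = mdstats.OccupancyStats(0.8, None, 0, history, 0.1)
    tau1, n1 = mdstats.exchange_time(stats, 0.1, gap_tolerance=1)
    assert n1 == 1 and tau1 == pytest.approx(0.5)
    tau0, n0 = mdstats.exchange_time(stats, 0.1, gap_tolerance=0)
    assert n0 == 2 and tau0 == pytest.approx(0.2)


# ------------------------------------------------------------------ counts

def test_channel_counts_constant():
    coords = np.zeros((50, 7, 3))
    coords[:, 5:] = [0.0, 0.0, 40.0]  # two atoms outside the region
    traj = Trajectory(coords, 0.1)
    res = mdstats.channel_counts(traj, (-15, 15), 5.0, selection="water_O")
    assert res["mean"] == 5.0 and res["sd"] == 0.0


def test_channel_counts_poisson_scenario():
    traj, scripted = make_count_trajectory(2000, 11.6, seed=2)
    res = mdstats.channel_counts(traj, (-15, 15), 5.0, selection="water_O")
    assert np.array_equal(res["counts"], scripted)  # exact per-frame recount
    se = np.sqrt(11.6 / 2000)
    assert res["mean"] == pytest.approx(11.6, abs=3 * se)


def test_channel_counts_bruteforce_recount():
    traj, _ = make_count_trajectory(80, 5.0, seed=3)
    res = mdstats.channel_counts(traj, (-15, 15), 5.0, selection="water_O")
    for f in range(traj.n_frames):
        z = traj.coords[f, :, 2]
        lat = np.linalg.norm(traj.coords[f, :, :2], axis=1)
        brute = int(np.sum((z >= -15) & (z <= 15) & (lat <= 5.0)))
        assert res["counts"][f] == brute


def test_channel_counts_region_outside_everything():
    coords = np.zeros((10, 3, 3))
    traj = Trajectory(coords, 0.1)
    res = mdstats.channel_counts(traj, (100, 120), 5.0, selection="water_O")
    assert res["mean"] == 0.0


def test_channel_counts_empty_selection():
    traj = Trajectory(np.zeros((5, 2, 3)), 0.1, resnames=["SIH", "SIH"])
    with pytest.raises(ValueError):
        mdstats.channel_counts(traj, (-15, 15), 5.0, selection="water_O")


# ------------------------------------------------------------------ permeation

def _path_traj(paths, n_frames=200):
    coords = np.zeros((n_frames, len(paths), 3))
    for j, wp in enumerate(paths):
        t_wp = np.linspace(0, n_frames - 1, len(wp))
        coords[:, j, 2] = np.interp(np.arange(n_frames), t_wp, wp)
    return Trajectory(coords, 0.1, names=["Si"] * len(paths),
                      resnames=["SIH"] * len(paths))


def test_single_full_crossing():
    traj = _path_traj([[20, -20]])
    events = mdstats.count_permeations(traj, 15, -15)
    assert len(events) == 1 and events[0].direction == "in"
    assert events[0].entry_frame < events[0].exit_frame


def test_partial_entry_is_discarded():
    traj = _path_traj([[20, 5, 20], [-20, -2, -20]])
    assert mdstats.count_permeations(traj, 15, -15) == []


def test_scripted_two_full_three_partial():
    traj = _path_traj([
        [20, -20, 20, -20],      # two full crossings by one molecule
        [20, 5, 20],
        [-20, -5, -20],
        [20, 10, 18, 20],
    ])
    events = mdstats.count_permeations(traj, 15, -15)
    assert len(events) == 3  # in, out, in for molecule 0
    assert [e.direction for e in events if e.molecule == 0] == ["in", "out", "in"]
    assert all(e.molecule == 0 for e in events)


def test_permeation_time_reversal_swaps_direction():
    traj = _path_traj([[20, -20], [-20, 20]])
    fwd = mdstats.count_permeations(traj, 15, -15)
    rev = Trajectory(traj.coords[::-1].copy(), traj.dt, names=traj.names,
                     resnames=traj.resnames)
    bwd = mdstats.count_permeations(rev, 15, -15)
    assert sorted(e.direction for e in fwd) == sorted(
        {"in": "out", "out": "in"}[e.direction] for e in bwd
    )


def test_permeation_boundary_validation():
    traj = _path_traj([[20, -20]])
    with pytest.raises(ValueError):
        mdstats.count_permeations(traj, -15, 15)


# ------------------------------------------------------------------ density

def _density_traj(zs):
    coords = np.zeros((len(zs), len(zs[0]), 3))
    for f, row in enumerate(zs):
        coords[f, :, 2] = row
    return Trajectory(coords, 0.1, names=["Si"] * len(zs[0]),
                      resnames=["SIH"] * len(zs[0]))


def test_uniform_density_no_bottlenecks():
    rng = np.random.default_rng(6)
    zs = rng.uniform(-19.9, 19.9, (500, 30))
    res = mdstats.axial_density(_density_traj(zs), bin_width=2.0)
    assert res["bottlenecks"] == []


def test_three_scripted_gaps_three_bottlenecks():
    rng = np.random.default_rng(7)
    zs = rng.uniform(-19.9, 19.9, (800, 40))
    for lo, hi in [(-13, -11), (-1, 1), (9, 11)]:
        mask = (zs > lo) & (zs < hi)
        zs[mask] = -19.5  # evacuate the gap
    res = mdstats.axial_density(_density_traj(zs), bin_width=1.0)
    got = res["bottlenecks"]
    assert len(got) == 3
    for (lo, hi), (glo, ghi) in zip([(-13, -11), (-1, 1), (9, 11)], got):
        assert glo == pytest.approx(lo, abs=1.0) and ghi == pytest.approx(hi, abs=1.0)


def test_zero_threshold_no_bottlenecks():
    rng = np.random.default_rng(8)
    zs = rng.uniform(-19.9, 19.9, (200, 10))
    zs[(zs > -1) & (zs < 1)] = -19.5
    res = mdstats.axial_density(_density_traj(zs), bin_width=1.0,
                                bottleneck_fraction=0.0)
    assert res["bottlenecks"] == []


def test_density_bin_validation():
    with pytest.raises(ValueError):
        mdstats.axial_density(_density_traj(np.zeros((2, 3))), bin_width=0.0)


# ------------------------------------------------------------------ invariance

def test_statistics_invariant_under_uniform_rigid_transform():
    from chw._geom import random_rotation

    spec = TrajectorySpec(n_frames=1500, seed=9, p_occupied=0.6, mean_dwell_frames=4)
    traj = make_two_state_trajectory(spec)
    R = random_rotation(np.random.default_rng(10))
    t = np.array([11.0, -3.0, 6.0])
    moved = Trajectory(traj.coords @ R.T + t, traj.dt, names=traj.names,
                       resnames=traj.resnames)
    s1 = mdstats.site_occupancy(traj, Site((0, 0, 0), 1.4))
    s2 = mdstats.site_occupancy(moved, Site(R @ np.zeros(3) + t, 1.4))
    assert s1.occupancy == s2.occupancy
    assert np.array_equal(s1.occupant_history, s2.occupant_history)
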