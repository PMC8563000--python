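"""Track-statistics pipeline: velocities, profiles, segmentation, fits."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from bandwave import synthetic_tracks as st
from bandwave import trackstats as ts
from bandwave.io_config import TrackTable


def make_tracks(rows, dt=1.0 / 540.0, frame="lab"):
    df = pd.DataFrame(rows, columns=["cell_id", "t_min", "x_mm", "y_mm"])
    return TrackTable(data=df, frame_interval=dt, frame=frame, validate=False)


# --- group velocity ---------------------------------------------------------


def test_group_velocity_stationary_and_constant():
    t = np.arange(5) * 0.1
    still = make_tracks([("a", ti, 1.0, 0.0) for ti in t], dt=0.1)
    assert ts.estimate_group_velocity(still)[0] == 0.0
    mover = make_tracks([("a", ti, 0.18 * ti, 0.0) for ti in t], dt=0.1)
    v, _ = ts.estimate_group_velocity(mover)
    assert np.isclose(v, 0.18)


def test_group_velocity_recovered_from_band(stationary_band):
    # quasi-stationary band generated with V_G = 0.18 mm/min (3.0 um/s)
    v, sem = ts.estimate_group_velocity(stationary_band.tracks)
    assert abs(v - 0.18) < 2 * sem + 1e-3


def test_group_velocity_needs_pairs():
    single = make_tracks([("a", 0.0, 0.0, 0.0)])
    with pytest.raises(ValueError):
        ts.estimate_group_velocity(single)


# --- moving frame -----------------------------------------------------------


def test_moving_frame_zero_vg_is_peak_shift():
    rows = [("a", 0.0, 1.0, 0.0), ("a", 0.1, 1.2, 0.0),
            ("b", 0.0, 1.01, 0.0), ("b", 0.1, 0.9, 0.0)]
    tracks = make_tracks(rows, dt=0.1)
    mv = ts.to_moving_frame(tracks, 0.0)
    ref = mv.meta["reference"]
    np.testing.assert_allclose(mv.data["z_mm"], mv.data["x_mm"] - ref)


def test_comoving_cell_has_constant_z():
    t = np.arange(20) * 0.01
    tracks = make_tracks([("a", ti, 0.5 + 0.18 * ti, 0.0) for ti in t], dt=0.01)
    mv = ts.to_moving_frame(tracks, 0.18, reference=0.5)
    np.testing.assert_allclose(mv.data["z_mm"], 0.0, atol=1e-12)


def test_moving_frame_round_trip(stationary_moving, stationary_band):
    back = ts.to_lab_frame(stationary_moving)
    np.testing.assert_allclose(back.data["x_mm"],
                               stationary_band.tracks.data["x_mm"])


def test_moving_frame_requires_t0_or_reference():
    tracks = make_tracks([("a", 0.5, 0.0, 0.0), ("a", 0.6, 0.1, 0.0)], dt=0.1)
    with pytest.raises(ValueError, match="reference"):
        ts.to_moving_frame(tracks, 0.1)
    mv = ts.to_moving_frame(tracks, 0.1, reference=0.0)
    assert "z_mm" in mv.data


# --- density ----------------------------------------------------------------


def test_density_single_bin_formula_and_conservation():
    # N cells in one bin, a = 0.012 mm^2, dz = 0.24 mm -> rho = N / 0.00288
    z = np.full(30, 0.1)
    prof = ts.density_profile(z, bin_width=0.24, section_area=0.012,
                              edges=np.array([0.0, 0.24]))
    assert np.isclose(prof.value[0], 30 / 0.00288)
    total = (prof.value * 0.012 * 0.24).sum()
    assert np.isclose(total, 30.0)


def test_density_conservation_random():
    rng = np.random.default_rng(0)
    z = rng.normal(0, 0.4, size=1234)
    prof = ts.density_profile(z, bin_width=0.24)
    assert np.isclose((prof.value * ts.SECTION_AREA_MM2 * 0.24).sum(), 1234.0)


def test_density_matches_gaussian_pdf():
    rng = np.random.default_rng(1)
    n = 200_000
    z = rng.normal(0.0, 0.5, size=n)
    prof = ts.density_profile(z, bin_width=0.1, section_area=1.0)
    pdf = scipy.stats.norm.pdf(prof.centers, 0.0, 0.5) * n
    # sup-norm within binomial error (4 sigma per bin)
    err = 4 * np.sqrt(np.clip(pdf * 0.1, 1, None)) / 0.1
    assert np.all(np.abs(prof.value - pdf) < err)


def test_density_empty_warns():
    with pytest.warns(UserWarning, match="empty"):
        prof = ts.density_profile(np.array([]), bin_width=0.24)
    assert prof.value.sum() == 0


# --- instantaneous velocity -------------------------------------------------


def test_instantaneous_velocity_comoving():
    t = np.arange(50) * 0.01
    rows = [(c, ti, x0 + 0.18 * ti, 0.0) for c, x0 in [("a", 0.0), ("b", 0.3)]
            for ti in t]
    tracks = make_tracks(rows, dt=0.01)
    mv = ts.to_moving_frame(tracks, 0.18, reference=0.0)
    prof = ts.instantaneous_velocity_profile(mv, bin_width=0.24)
    occupied = prof.n > 0
    np.testing.assert_allclose(prof.value[occupied], 0.18, atol=1e-9)


def test_instantaneous_velocity_hand_computed():
    rows = [("a", 0.0, 0.0, 0.0), ("a", 0.1, 0.2, 0.0),
            ("a", 0.2, 0.1, 0.0), ("a", 0.3, 0.4, 0.0)]
    tracks = make_tracks(rows, dt=0.1)
    mv = ts.to_moving_frame(tracks, 0.0, reference=0.0)
    prof = ts.instantaneous_velocity_profile(mv, bin_width=0.15)
    # pairs: z0=0.0 v=2.0; z0=0.2 v=-1.0; z0=0.1 v=3.0
    # bins [0,0.15): {2.0, 3.0} -> 2.5 ; [0.15,0.3): {-1.0}
    lookup = dict(zip(np.round(prof.centers, 3), prof.value))
    assert np.isclose(lookup[0.075], 2.5)
    assert np.isclose(lookup[0.225], -1.0)


def test_instantaneous_velocity_flat_in_stationary_band(stationary_moving):
    """In a coherently migrating band the instantaneous velocity is uniform
    and equals the group velocity, unlike the structured drift velocity."""
    v_g = stationary_moving.meta["v_g"]
    prof = ts.instantaneous_velocity_profile(stationary_moving, bin_width=0.24)
    ok = prof.n > 5000
    assert ok.sum() >= 4
    dev = np.abs(prof.value[ok] - v_g)
    assert np.all(dev < 4 * prof.sem[ok] + 0.002)


# --- segmentation -----------------------------------------------------------


def test_straight_track_is_one_run():
    t = np.arange(30) / 540.0
    tracks = make_tracks([("a", ti, 1.2 * ti, 0.0) for ti in t])
    mv = ts.to_moving_frame(tracks, 0.0, reference=0.0)
    events, info = ts.segment_runs_tumbles(mv)
    assert len(events) == 0            # no tumble -> no tumble-run pair
    labels = info["frame_labels"]
    assert (labels["state"] == "run").all()


def test_three_frame_dwell_is_one_tumble():
    dt = 1.0 / 540.0
    v = 1.2
    rows = []
    t = 0.0
    x = 0.0
    for _ in range(15):                 # run
        rows.append(("a", t, x, 0.0)); t += dt; x += v * dt
    for _ in range(3):                  # near-zero-speed dwell
        rows.append(("a", t, x, 0.0)); t += dt
    for _ in range(15):                 # run (reversed direction)
        rows.append(("a", t, x, 0.0)); t += dt; x -= v * dt
    tracks = make_tracks(rows)
    mv = ts.to_moving_frame(tracks, 0.0, reference=0.0)
    events, _ = ts.segment_runs_tumbles(mv)
    assert len(events) == 1
    assert np.isclose(events["tau_T_min"].iloc[0], 3 * dt)
    assert np.isclose(events["theta_R_rad"].iloc[0], np.pi)


def test_segmentation_frame_agreement(stationary_band, stationary_moving):
    """Frame-level run/tumble agreement with generator ground truth >= 90%
    at the default thresholds."""
    events, info = ts.segment_runs_tumbles(stationary_moving)
    gt = st.ground_truth_frame_states(stationary_band)
    merged = gt.merge(info["frame_labels"], on=["cell_id", "t_min"],
                      suffixes=("_gt", "_seg"))
    assert len(merged) > 100_000
    agreement = (merged["state_gt"] == merged["state_seg"]).mean()
    assert agreement >= 0.90


def test_short_tracks_skipped():
    rows = [("a", 0.0, 0.0, 0.0), ("a", 1 / 540, 0.01, 0.0)]
    rows += [("b", i / 540, 1.2 * i / 540, 0.0) for i in range(30)]
    tracks = make_tracks(rows)
    mv = ts.to_moving_frame(tracks, 0.0, reference=0.0)
    _, info = ts.segment_runs_tumbles(mv)
    assert info["n_skipped_short"] == 1


# --- drift velocity and fit -------------------------------------------------


def test_drift_single_event_formula():
    ev = pd.DataFrame({
        "cell_id": ["a"], "t_tumble_min": [0.0], "z_tumble_mm": [0.1],
        "tau_T_min": [0.04], "tau_R_min": [0.06], "l_R_mm": [0.02],
        "theta_R_rad": [0.0]})
    prof = ts.drift_velocity_profile(ev, bin_width=0.24)
    assert np.isclose(prof.value[~np.isnan(prof.value)][0], 0.2)


def test_drift_mirror_symmetry_is_zero():
    theta = np.array([0.3, np.pi - 0.3, 1.0, np.pi - 1.0])
    ev = pd.DataFrame({
        "cell_id": ["a"] * 4, "t_tumble_min": np.zeros(4),
        "z_tumble_mm": np.full(4, 0.05), "tau_T_min": np.full(4, 0.01),
        "tau_R_min": np.full(4, 0.02), "l_R_mm": np.full(4, 0.03),
        "theta_R_rad": theta})
    prof = ts.drift_velocity_profile(ev, bin_width=0.24)
    val = prof.value[~np.isnan(prof.value)]
    np.testing.assert_allclose(val, 0.0, atol=1e-14)


def test_segmented_drift_recovers_profile(recovery):
    """Binned V_D from segmented tracks agrees with the generating linear
    drift profile bin by bin."""
    prof = recovery["v_d"]
    truth = recovery["truth"]
    expected = -truth["r"] * prof.abscissa() + truth["v_d0"]
    ok = prof.n > 2000
    assert ok.sum() >= 4
    dev = np.abs(prof.value[ok] - expected[ok])
    # 3 bootstrap SEMs plus the small frame-origin uncertainty
    slack = 3 * prof.sem[ok] + 0.05 * recovery["reference_se"]
    assert np.all(dev < slack)


def test_drift_and_instantaneous_velocity_differ(stationary_moving):
    """V_D(z) is spatially structured while V_I(z) is flat: the two
    statistics must disagree on a biased-run ensemble."""
    events, _ = ts.segment_runs_tumbles(stationary_moving)
    v_d = ts.drift_velocity_profile(events, bin_width=0.24, seed=0)
    fit = ts.fit_linear_drift(v_d, z_range=(-0.6, 0.6))
    assert fit.r > 3 * fit.r_se          # V_D slope clearly negative
    v_i = ts.instantaneous_velocity_profile(stationary_moving, bin_width=0.24)
    okd = (v_d.n > 2000) & (v_i.n > 2000)
    assert np.nanmax(np.abs(v_d.value[okd] - v_i.value[okd])) > 0.01


def test_fit_exact_on_noiseless_profile():
    centers = np.arange(-0.5, 0.51, 0.24)
    edges = np.concatenate([centers - 0.12, [centers[-1] + 0.12]])
    from bandwave.io_config import SpatialProfile
    vals = -0.05 * centers + 0.17
    prof = SpatialProfile(edges, vals, np.full_like(vals, 0.01),
                          np.full(len(vals), 100), "drift_velocity")
    fit = ts.fit_linear_drift(prof)
    assert np.isclose(fit.r, 0.05) and np.isclose(fit.v_d0, 0.17)
    const = SpatialProfile(edges, np.full_like(vals, 0.1),
                           np.full_like(vals, 0.01),
                           np.full(len(vals), 100), "drift_velocity")
    assert np.isclose(ts.fit_linear_drift(const).r, 0.0)


def test_fit_matches_normal_equation_oracle():
    rng = np.random.default_rng(3)
    centers = np.arange(-0.6, 0.61, 0.24)
    edges = np.concatenate([centers - 0.12, [centers[-1] + 0.12]])
    sem = rng.uniform(0.005, 0.02, len(centers))
    vals = -0.05 * centers + 0.17 + rng.normal(0, sem)
    from bandwave.io_config import SpatialProfile
    prof = SpatialProfile(edges, vals, sem, np.full(len(vals), 50),
                          "drift_velocity")
    fit = ts.fit_linear_drift(prof)
    w = 1 / sem**2
    X = np.column_stack([centers, np.ones_like(centers)])
    beta = np.linalg.solve(X.T * w @ X, X.T * w @ vals)
    assert np.isclose(fit.r, -beta[0]) and np.isclose(fit.v_d0, beta[1])


def test_fit_requires_enough_bins():
    from bandwave.io_config import SpatialProfile
    edges = np.array([0.0, 0.24, 0.48])
    prof = SpatialProfile(edges, np.array([0.1, 0.2]),
                          np.array([0.01, 0.01]), np.array([5, 5]), "d")
    with pytest.raises(ValueError):
        ts.fit_linear_drift(prof)


# --- run statistics, width, MSD ---------------------------------------------


def test_run_statistics_direction_asymmetry(stationary_moving):
    """Forward runs are longer than backward runs behind the band center
    and the exponential rate is the reciprocal mean."""
    events, _ = ts.segment_runs_tumbles(stationary_moving)
    stats = ts.run_statistics(events, bin_width=0.48)
    fwd = stats["by_direction"]["forward"]
    bwd = stats["by_direction"]["backward"]
    f = fwd[(fwd.quantity == "tau_R_min") & (fwd.n > 500)]
    b = bwd[(bwd.quantity == "tau_R_min") & (bwd.n > 500)]
    joined = f.merge(b, on="z_mm", suffixes=("_f", "_b"))
    behind = joined[joined.z_mm < 0]
    assert (behind["mean_f"] > behind["mean_b"]).all()
    np.testing.assert_allclose(f["exp_rate"], 1.0 / f["mean"])


def test_exponential_mle_closed_form():
    rng = np.random.default_rng(0)
    tau = rng.exponential(0.013, size=2000)
    ev = pd.DataFrame({
        "cell_id": "a", "t_tumble_min": 0.0, "z_tumble_mm": 0.0,
        "tau_T_min": 0.003, "tau_R_min": tau, "l_R_mm": tau * 1.2,
        "theta_R_rad": rng.uniform(0, np.pi, 2000)})
    stats = ts.run_statistics(ev, bin_width=0.24, direction_split=False)
    tab = stats["by_direction"]["all"]
    row = tab[(tab.quantity == "tau_R_min") & (tab.n == 2000)]
    assert np.isclose(row["exp_rate"].iloc[0], 1.0 / tau.mean())


def test_width_two_points_and_degenerate():
    assert np.isclose(ts.width(np.array([-1.0, 1.0])), 2 * np.sqrt(2))
    assert ts.width(np.array([0.3, 0.3, 0.3])) == 0.0
    with pytest.raises(ValueError):
        ts.width(np.array([1.0]))


def test_width_gaussian_sample():
    rng = np.random.default_rng(5)
    z = rng.normal(0, 0.5, size=50_000)
    assert abs(ts.width(z) - 1.0) < 0.02


def test_msd_stationary_particle_and_diffusion():
    t = np.arange(200) * 0.01
    df = pd.DataFrame({"cell_id": "a", "t_min": t, "z_mm": 0.0})
    still = TrackTable(data=df, frame_interval=0.01, frame="moving",
                       validate=False)
    msd = ts.msd_moving_frame(still)
    np.testing.assert_allclose(msd["msd_mm2"], 0.0, atol=1e-15)

    # pure diffusion: MSD = 2 D t
    D = 0.01
    p = st.OUParams(r=0.0, epsilon=np.sqrt(2 * D))
    tracks = st.generate_ou_particles(p, 600, dt=0.01, T=3.0, seed=4,
                                      initial_z=0.0)
    msd = ts.msd_moving_frame(tracks, lags=[0.25, 0.5, 1.0])
    expected = 2 * D * msd["lag_min"]
    np.testing.assert_allclose(msd["msd_mm2"], expected, rtol=0.12)


def test_msd_drops_long_lags():
    t = np.arange(50) * 0.01
    df = pd.DataFrame({"cell_id": "a", "t_min": t, "z_mm": np.sin(t)})
    tr = TrackTable(data=df, frame_interval=0.01, frame="moving", validate=False)
    with pytest.warns(UserWarning, match="lags"):
        msd = ts.msd_moving_frame(tr, lags=[0.1, 5.0])
    assert (msd["lag_min"] < 0.5).all()
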