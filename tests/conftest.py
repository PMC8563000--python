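"""Shared fixtures: expensive simulation runs are session-scoped so the
recovery ensemble and the agent ladder are simulated once."""

from dataclasses import replace

import numpy as np
import pytest

from bandwave import agent_sim, pipeline, synthetic_tracks, trackstats

try:
    from hypothesis import settings

    settings.register_profile("deterministic", deadline=None, derandomize=True)
    settings.load_profile("deterministic")
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


@pytest.fixture(scope="session")
def recovery():
    """The standard parameter-recovery condition: 500 run-and-tumble cells
    tracked 10 min at 9 fps with the reference linear drift profile,
    analyzed by the full pipeline."""
    cfg = pipeline.default_config(seed=2024)
    return pipeline.recovery_analysis(cfg)


@pytest.fixture(scope="session")
def stationary_band():
    """A quasi-stationary band: drift crossing at the band center
    (V_D0 = V_G), 300 cells for 8 min; used for V_G / V_I statistics."""
    params = synthetic_tracks.RunTumbleGenParams(
        drift_profile=synthetic_tracks.linear_drift(0.05, 0.18),
    )
    run = synthetic_tracks.generate_run_tumble_tracks(params, 300, 8.0, seed=7)
    return run


@pytest.fixture(scope="session")
def stationary_moving(stationary_band):
    v_g, _ = trackstats.estimate_group_velocity(stationary_band.tracks)
    return trackstats.to_moving_frame(stationary_band.tracks, v_g)


@pytest.fixture(scope="session")
def agent_ladder():
    """A four-point receptor-gain ladder (chi ~ 0.2-0.35 mm^2/min) chasing
    a rigid moving profile with a linearly decreasing perceived gradient."""
    base = agent_sim.PathwayParams()
    ladder = [replace(base, N=N) for N in (3.7, 4.6, 5.5, 6.4)]
    v_g = 0.15
    env = agent_sim.quadratic_log_profile(g0=0.9, g1=-0.45, v_g=v_g, x0=5.0)
    # recorded at 3 fps: enough for event statistics over 45 min while
    # keeping the 800-agent ensemble's memory footprint modest
    tracks, phenotypes, info = agent_sim.simulate_agents(
        ladder, env, n_cells=200, T=45.0, seed=11, initial_x=(5.9, 0.4),
        frame_rate=3.0 * 60.0)
    moving = trackstats.to_moving_frame(tracks, v_g, reference=5.0)
    df = moving.data.merge(phenotypes[["cell_id", "phenotype"]], on="cell_id")
    seg = trackstats.SegmentationParams(min_tumble_frames=1, min_run_frames=1)
    return {
        "ladder": ladder, "v_g": v_g, "g1": -0.45, "tracks": tracks,
        "moving": moving, "tagged": df, "phenotypes": phenotypes,
        "info": info, "burn_in": 20.0, "seg_params": seg,
    }
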