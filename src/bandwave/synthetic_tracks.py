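"""Synthetic run-and-tumble and Ornstein-Uhlenbeck trajectory ensembles.

The run-and-tumble generator emulates particle tracking of fluorescent
cells inside a band migrating at constant group speed ``V_G``: minutes-long
2D tracks sampled at the camera frame rate, built from alternating tumbles
(zero displacement, exponential duration) and straight runs (constant
speed, exponential duration).  The spatial bias that lets a band hold
together is imposed through a direction-dependent mean run duration: runs
headed along the migration axis last longer when the event starts behind
the band center.  The modulation is calibrated so that the event-level
drift statistic

    V_D(z) = <l_R cos(theta_R)> / <tau_R + tau_T>

evaluated at the tumble position ``z`` equals the requested drift profile
exactly in expectation.  With a reorientation angle theta drawn uniformly
on the circle and run duration mean ``tau_R0 * (1 + b(z) cos theta)``:

    <l_R cos theta>   = v * tau_R0 * b(z) / 2      (since <cos^2> = 1/2)
    <tau_R + tau_T>   = tau_R0 + tau_T0

so ``b(z) = 2 V_D(z) (tau_R0 + tau_T0) / (v tau_R0)``; |b| < 1 is required
for run durations to stay positive, which bounds the attainable drift.

Ground truth (the exact event list) can be logged for segmentation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io_config import EVENT_COLUMNS, TrackTable

__all__ = [
    "RunTumbleGenParams",
    "OUParams",
    "GeneratorRun",
    "InfeasibleDriftError",
    "linear_drift",
    "generate_run_tumble_tracks",
    "generate_ou_particles",
    "emit_ground_truth",
    "ground_truth_frame_states",
]

#: camera frame rate of the tracking experiments, frames per minute (9 fps)
DEFAULT_FRAME_RATE = 9.0 * 60.0


class InfeasibleDriftError(ValueError):
    """The requested drift profile exceeds what run modulation can deliver."""


def linear_drift(r: float, v_d0: float) -> Callable[[np.ndarray], np.ndarray]:
    """Linear drift-velocity profile ``V_D(z) = -r z + V_D0`` (mm/min)."""

    def profile(z):
        return -r * np.asarray(z, dtype=float) + v_d0

    return profile


@dataclass
class RunTumbleGenParams:
    """Ground-truth parameters of the run-and-tumble band generator.

    Defaults describe a migrating E. coli band: swimming speed 20 um/s,
    mean run 0.8 s, mean tumble 0.2 s, group speed 0.18 mm/min (3 um/s),
    camera at 9 fps.  The initial moving-frame positions are Gaussian with
    the band peak at the origin; the band half-width matches the
    quasi-stationary spread of the mean-reverting run-and-tumble process.
    """

    mean_run_speed: float = 1.2                    # mm/min
    base_mean_run_duration: float = 0.8 / 60.0     # min
    mean_tumble_duration: float = 0.2 / 60.0       # min
    v_g: float = 0.18                              # mm/min
    drift_profile: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: linear_drift(0.05, 0.17)
    )
    frame_rate: float = DEFAULT_FRAME_RATE         # frames/min
    initial_z_mean: float = 0.0                    # mm
    initial_z_sd: float = 0.39                     # mm
    tumble_angle_distribution: str = "uniform"
    persistence: float = 0.0   # wrapped-normal heading memory, 0 = uniform

    def __post_init__(self) -> None:
        if min(self.mean_run_speed, self.base_mean_run_duration,
               self.mean_tumble_duration, self.frame_rate) <= 0:
            raise ValueError("speeds, durations and frame rate must be positive")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def max_attainable_drift(self) -> float:
        """|V_D| bound implied by |b| < 1 (run durations must stay > 0)."""
        tau_r, tau_t = self.base_mean_run_duration, self.mean_tumble_duration
        return self.mean_run_speed * tau_r / (2.0 * (tau_r + tau_t))

    def bias(self, z: float | np.ndarray) -> np.ndarray:
        """Duration-asymmetry coefficient b(z) realizing the drift profile."""
        tau_r, tau_t = self.base_mean_run_duration, self.mean_tumble_duration
        return 2.0 * np.asarray(self.drift_profile(z)) * (tau_r + tau_t) / (
            self.mean_run_speed * tau_r
        )


@dataclass
class OUParams:
    """Mean-reverting (OU) particle parameters in the moving frame.

    ``dz = -r (z - z_star) dt + epsilon dW``; ``epsilon = sqrt(2 D)`` with
    ``D`` the motility diffusivity, so the stationary SD is
    ``epsilon / sqrt(2 r)``.
    """

    r: float                      # reversion rate, 1/min
    z_star: float = 0.0           # balanced position, mm
    epsilon: float = 0.124        # noise strength, mm/min^0.5
    v_g: float = 0.18             # group speed (for lab-frame conversion)

    def __post_init__(self) -> None:
        if self.r < 0 or self.epsilon < 0:
            raise ValueError("r and epsilon must be nonnegative")


@dataclass
class GeneratorRun:
    """A generator invocation: tracks plus (optionally) exact ground truth."""

    tracks: TrackTable
    events: pd.DataFrame | None
    params: RunTumbleGenParams
    seed: int
    duration: float


def generate_run_tumble_tracks(
    params: RunTumbleGenParams,
    n_cells: int,
    duration: float,
    seed: int,
    log_events: bool = True,
) -> GeneratorRun:
    """Simulate ``n_cells`` run-and-tumble tracks of ``duration`` minutes.

    Cells are generated in the moving frame (z) and reported in the lab
    frame ``x = z + V_G t``; sampling happens at the camera frame grid.
    """
    if n_cells <= 0 or duration <= 0:
        raise ValueError("n_cells and duration must be positive")
    rng = np.random.default_rng(seed)
    dt_frame = params.frame_interval
    frame_t = np.arange(0.0, duration + 0.5 * dt_frame, dt_frame)
    v = params.mean_run_speed
    tau_r0 = params.base_mean_run_duration
    tau_t0 = params.mean_tumble_duration

    all_rows = []
    event_rows = []
    z0s = rng.normal(params.initial_z_mean, params.initial_z_sd, size=n_cells)
    n_draw = int(duration / (tau_r0 + tau_t0) * 1.6) + 32

    for ci in range(n_cells):
        cell_id = f"cell{ci:04d}"
        # pre-drawn randomness; topped up in the rare long-duration tail
        exp_t = rng.exponential(tau_t0, size=n_draw)
        exp_r = rng.exponential(1.0, size=n_draw)       # unit-mean, scaled per event
        thetas = rng.uniform(-np.pi, np.pi, size=n_draw)
        if params.persistence > 0.0:
            # heading memory: new angle = previous + wrapped-normal kick
            kicks = rng.normal(0.0, np.pi * (1.0 - params.persistence), size=n_draw)
            thetas = np.mod(np.cumsum(np.concatenate([[thetas[0]], kicks[1:]])) + np.pi,
                            2 * np.pi) - np.pi

        t = 0.0
        z = float(z0s[ci])
        y = 0.0
        # piecewise-linear breakpoints in the moving frame
        bp_t = [t]
        bp_z = [z]
        bp_y = [y]
        k = 0
        while t < duration:
            if k >= n_draw:
                exp_t = np.concatenate([exp_t, rng.exponential(tau_t0, size=n_draw)])
                exp_r = np.concatenate([exp_r, rng.exponential(1.0, size=n_draw)])
                thetas = np.concatenate([thetas, rng.uniform(-np.pi, np.pi, size=n_draw)])
                n_draw *= 2
            # tumble: stationary in the lab frame, so z slides back at -V_G
            tau_t = exp_t[k]
            z_tumble = z
            t_tumble = t
            t += tau_t
            z -= params.v_g * tau_t
            bp_t.append(t)
            bp_z.append(z)
            bp_y.append(y)
            # run: straight at constant speed; duration mean modulated by the
            # heading relative to the migration axis, evaluated at the tumble
            # position (the tumble barely moves the cell in the lab frame)
            theta = thetas[k]
            b = float(params.bias(z_tumble))
            if abs(b) >= 1.0:
                raise InfeasibleDriftError(
                    f"drift profile at z={z_tumble:.3f} mm needs |b|={abs(b):.2f} >= 1;"
                    f" max attainable |V_D| is {params.max_attainable_drift:.3f} mm/min"
                )
            tau_r = exp_r[k] * tau_r0 * (1.0 + b * np.cos(theta))
            t += tau_r
            z += (v * np.cos(theta) - params.v_g) * tau_r
            y += v * np.sin(theta) * tau_r
            bp_t.append(t)
            bp_z.append(z)
            bp_y.append(y)
            if log_events:
                event_rows.append(
                    (cell_id, t_tumble, z_tumble, tau_t, tau_r,
                     v * tau_r, abs(theta))
                )
            k += 1

        bp_t = np.asarray(bp_t)
        bp_z = np.asarray(bp_z)
        bp_y = np.asarray(bp_y)
        ft = frame_t[frame_t <= bp_t[-1]]
        fz = np.interp(ft, bp_t, bp_z)
        fy = np.interp(ft, bp_t, bp_y)
        fx = fz + params.v_g * ft
        all_rows.append(
            pd.DataFrame({"cell_id": cell_id, "t_min": ft, "x_mm": fx, "y_mm": fy})
        )

    data = pd.concat(all_rows, ignore_index=True)
    tracks = TrackTable(
        data=data,
        frame_interval=dt_frame,
        frame="lab",
        meta={"seed": seed, "generator": "run_tumble"},
        validate=False,
    )
    events = None
    if log_events:
        events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    return GeneratorRun(tracks=tracks, events=events, params=params,
                        seed=seed, duration=duration)


def emit_ground_truth(run: GeneratorRun) -> tuple[pd.DataFrame, dict]:
    """Exact per-event ground truth plus the generating parameter record."""
    if run.events is None:
        raise ValueError("generator was run with log_events=False")
    record = {
        "seed": run.seed,
        "duration_min": run.duration,
        "mean_run_speed_mm_min": run.params.mean_run_speed,
        "base_mean_run_duration_min": run.params.base_mean_run_duration,
        "mean_tumble_duration_min": run.params.mean_tumble_duration,
        "v_g_mm_min": run.params.v_g,
        "frame_rate_per_min": run.params.frame_rate,
    }
    return run.events.copy(), record


def ground_truth_frame_states(run: GeneratorRun) -> pd.DataFrame:
    """Majority-state label ('run'/'tumble') for every sampled frame interval.

    A frame interval is labeled by the state occupying the larger share of
    [t_k, t_{k+1}); used to score segmentation against ground truth.
    """
    if run.events is None:
        raise ValueError("generator was run with log_events=False")
    dt = run.tracks.frame_interval
    out = []
    for cell_id, ev in run.events.groupby("cell_id", sort=False):
        # tumble intervals of this cell
        starts = ev["t_tumble_min"].to_numpy()
        ends = starts + ev["tau_T_min"].to_numpy()
        cell_t = run.tracks.data.loc[run.tracks.data["cell_id"] == cell_id,
                                     "t_min"].to_numpy()
        if len(cell_t) < 2:
            continue
        frame_starts = cell_t[:-1]
        # tumble time overlapping each frame interval
        overlap = np.zeros_like(frame_starts)
        for s, e in zip(starts, ends):
            overlap += np.clip(
                np.minimum(e, frame_starts + dt) - np.maximum(s, frame_starts),
                0.0, None,
            )
        state = np.where(overlap > 0.5 * dt, "tumble", "run")
        out.append(pd.DataFrame({"cell_id": cell_id, "t_min": frame_starts,
                                 "state": state}))
    return pd.concat(out, ignore_index=True)


def generate_ou_particles(
    params: OUParams,
    n: int,
    dt: float,
    T: float,
    seed: int,
    initial_z: np.ndarray | float | str = "stationary",
    record_every: int = 1,
) -> TrackTable:
    """Euler-Maruyama paths of ``dz = -r (z - z*) dt + eps dW``.

    Returns a moving-frame TrackTable (``z_mm`` column, ``frame='moving'``,
    integer cell ids).  ``initial_z`` may be a scalar, an array of length
    ``n``, or ``'stationary'`` to draw from the stationary Gaussian
    (requires r > 0).  ``record_every`` thins the stored samples (the
    integration step stays ``dt``), which keeps big ensembles affordable.
    """
    if dt <= 0 or T < dt:
        raise ValueError("need dt > 0 and T >= dt")
    if params.r * dt > 1.0:
        raise ValueError(f"dt*r = {params.r * dt:.2f} > 1: integrator unstable")
    if params.r * dt > 0.1:
        warnings.warn(f"dt*r = {params.r * dt:.2f} > 0.1: coarse OU integration",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n_steps = int(round(T / dt))
    if isinstance(initial_z, str):
        if initial_z != "stationary":
            raise ValueError("initial_z must be scalar, array, or 'stationary'")
        if params.r <= 0:
            raise ValueError("stationary initial condition needs r > 0")
        sd = params.epsilon / np.sqrt(2.0 * params.r)
        z = rng.normal(params.z_star, sd, size=n)
    else:
        z = np.broadcast_to(np.asarray(initial_z, dtype=float), (n,)).copy()
    rec_idx = np.arange(0, n_steps + 1, record_every)
    zs = np.empty((len(rec_idx), n))
    zs[0] = z
    sq = params.epsilon * np.sqrt(dt)
    ptr = 1
    for k in range(1, n_steps + 1):
        z = z - params.r * (z - params.z_star) * dt + sq * rng.standard_normal(n)
        if ptr < len(rec_idx) and k == rec_idx[ptr]:
            zs[ptr] = z
            ptr += 1
    t = rec_idx * dt
    data = pd.DataFrame(
        {
            "cell_id": np.repeat(np.arange(n), len(rec_idx)),
            "t_min": np.tile(t, n),
            "z_mm": zs.T.ravel(),
        }
    )
    return TrackTable(data=data, frame_interval=dt * record_every,
                      frame="moving",
                      meta={"seed": seed, "generator": "ou"}, validate=False)
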