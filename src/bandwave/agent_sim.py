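"""Pathway-level 3D agent-based simulation of chemotactic bacteria.

Each agent carries the standard chemotaxis signalling cascade:

* MWC receptor cluster: free energy ``f = N [alpha (m0 - m) + ln(1+S/K_off)
  - ln(1+S/K_on)]`` with receptor gain ``N``; kinase activity
  ``a = 1/(1 + e^f)``.
* Linear adaptation: ``dm/dt = (a0 - a) / (tau N alpha a0 (1 - a0))``
  restores ``a`` to the adapted activity ``a0`` at any constant ligand
  level (perfect adaptation).  The slope normalization makes ``tau`` the
  relaxation time of the *activity* regardless of the receptor gain, so
  changing N changes only the amplification of the gradient signal.
* CheY-P proportional to activity: ``Yp = Yp0 a / a0``.
* Motors: each of ``n_flagella`` flagella is a two-state (CW/CCW) Markov
  process whose CW bias is a Hill function of Yp; the half-point is
  calibrated so the resting CW bias reproduces the basal tumble bias TB0
  through the voting rule (tumble iff >= ``voting_threshold`` flagella CW).

Agents swim at constant speed during runs (with optional rotational
diffusion), are stationary while tumbling, re-orient uniformly on the
sphere after a tumble, and reflect off the walls of the micro-channel box
(20 mm x 0.6 mm x 0.02 mm).  The environment is either a rigid attractant
profile translating at ``V_G`` or a 1D consumed field along the channel.

Raising the receptor gain N amplifies the gradient response (larger
chemotactic ability chi) without changing the run-tumble motility, which
is what makes N a clean chi ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .gradient_inference import DEFAULT_KOFF, DEFAULT_KON, mwc_log_occupancy
from .io_config import TrackTable
from .langevin_sim import _crank_nicolson_matrices, _diffuse_cn

__all__ = [
    "PathwayParams",
    "AgentState",
    "ChannelBox",
    "free_energy",
    "activity",
    "adapted_methylation",
    "cw_bias_half_point",
    "step_pathway",
    "simulate_agents",
    "effective_chi",
    "exponential_profile",
    "quadratic_log_profile",
]

SPHERE_EPS = 1e-12


@dataclass(frozen=True)
class PathwayParams:
    """Chemotaxis-pathway constants (dimensionless unless noted)."""

    N: float = 6.0                      # receptor gain (cluster size)
    koff: float = DEFAULT_KOFF          # uM
    kon: float = DEFAULT_KON            # uM
    a0: float = 1.0 / 3.0               # adapted kinase activity
    tau: float = 10.0 / 60.0            # adaptation time, min
    alpha_m: float = 2.0                # methylation free-energy slope
    m0: float = 1.0                     # methylation offset
    yp0: float = 1.0                    # basal CheY-P (normalized)
    hill: float = 10.0                  # motor Hill coefficient
    n_flagella: int = 5
    voting_threshold: int = 2           # flagella CW needed to tumble
    tb0: float = 0.2                    # basal tumble bias
    motor_rate: float = 180.0           # flagellum switching scale, 1/min
    run_speed: float = 1.2              # mm/min
    rot_diffusion: float = 0.0          # rad^2/min during runs

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("receptor gain N must be >= 1")
        if not 0 < self.a0 < 1:
            raise ValueError("adapted activity must be in (0, 1)")
        if self.tau <= 0:
            raise ValueError("adaptation time must be positive")


@dataclass
class ChannelBox:
    """Reflective simulation box (channel geometry), mm."""

    lx: float = 20.0
    ly: float = 0.6
    lz: float = 0.02


@dataclass
class AgentState:
    """Vectorized state of all agents (arrays over the ensemble)."""

    pos: np.ndarray          # (n, 3) mm
    heading: np.ndarray      # (n, 3) unit vectors
    m: np.ndarray            # methylation
    flagella: np.ndarray     # (n, n_flagella) bool, True = CW
    tumbling: np.ndarray     # (n,) bool


def free_energy(S, m, params: PathwayParams):
    """Receptor free energy f(S, m); attractant raises f, lowering kinase
    activity."""
    S = np.asarray(S, dtype=float)
    return params.N * (params.alpha_m * (params.m0 - np.asarray(m))
                       + mwc_log_occupancy(S, params.koff, params.kon))


def activity(f):
    """Kinase activity a = 1 / (1 + e^f)."""
    return 1.0 / (1.0 + np.exp(np.asarray(f, dtype=float)))


def adapted_methylation(S, params: PathwayParams) -> np.ndarray:
    """Methylation level at which activity equals a0 for ligand level S."""
    f0 = np.log((1.0 - params.a0) / params.a0)
    return params.m0 + (mwc_log_occupancy(S, params.koff, params.kon)
                        - f0 / params.N) / params.alpha_m


def _basal_cw_bias(params: PathwayParams) -> float:
    """Per-flagellum CW bias whose voting rule yields the basal tumble bias."""

    def tb(b):
        return scipy.stats.binom.sf(params.voting_threshold - 1,
                                    params.n_flagella, b) - params.tb0

    return float(scipy.optimize.brentq(tb, 1e-9, 1.0 - 1e-9))


def cw_bias_half_point(params: PathwayParams) -> float:
    """Hill half-point calibrated so bias(Yp0) gives the basal tumble bias."""
    b0 = _basal_cw_bias(params)
    return params.yp0 * ((1.0 - b0) / b0) ** (1.0 / params.hill)


def _cw_bias(yp: np.ndarray, params: PathwayParams, y_half: float) -> np.ndarray:
    ratio = np.power(np.clip(yp, 0.0, None) / y_half, params.hill)
    return ratio / (1.0 + ratio)


def step_pathway(state: AgentState, S_local: np.ndarray, dt: float,
                 params: PathwayParams, y_half: float,
                 rng: np.random.Generator) -> AgentState:
    """Advance methylation, CheY-P, and flagellar states by ``dt``.

    ``dt`` must be well below the adaptation time; each flagellum flips
    CW<->CCW as a two-state Markov process whose stationary CW probability
    equals the Hill bias of the current CheY-P level.
    """
    if dt >= params.tau:
        raise ValueError("pathway step dt must be < adaptation time tau")
    a = activity(free_energy(S_local, state.m, params))
    slope_norm = params.N * params.alpha_m * params.a0 * (1.0 - params.a0)
    m = state.m + (params.a0 - a) / (params.tau * slope_norm) * dt
    yp = params.yp0 * a / params.a0
    bias = _cw_bias(yp, params, y_half)[:, None]
    # rate CCW->CW = omega * bias, CW->CCW = omega * (1 - bias):
    # stationary CW probability equals the bias
    p_to_cw = params.motor_rate * bias * dt
    p_to_ccw = params.motor_rate * (1.0 - bias) * dt
    u = rng.random(state.flagella.shape)
    flag = np.where(state.flagella, u >= p_to_ccw, u < p_to_cw)
    tumbling = flag.sum(axis=1) >= params.voting_threshold
    return AgentState(pos=state.pos, heading=state.heading, m=m,
                      flagella=flag, tumbling=tumbling)


def _random_headings(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / (np.linalg.norm(v, axis=1, keepdims=True) + SPHERE_EPS)


def _reflect(pos: np.ndarray, heading: np.ndarray, box: ChannelBox) -> int:
    """Reflect positions and headings at the box walls; returns the number
    of coordinates that needed clamping beyond one reflection (bug guard)."""
    clamped = 0
    for axis, size in enumerate((box.lx, box.ly, box.lz)):
        p = pos[:, axis]
        low = p < 0
        high = p > size
        pos[low, axis] = -p[low]
        pos[high, axis] = 2 * size - p[high]
        heading[low | high, axis] *= -1.0
        out = (pos[:, axis] < 0) | (pos[:, axis] > size)
        if out.any():
            clamped += int(out.sum())
            pos[:, axis] = np.clip(pos[:, axis], 0.0, size)
    return clamped


def exponential_profile(s_mid: float, slope: float,
                        x_mid: float) -> Callable[[np.ndarray, float], np.ndarray]:
    """Static exponential attractant ``S(x) = s_mid exp(slope (x - x_mid))``."""

    def S(x, t):
        return s_mid * np.exp(slope * (np.asarray(x) - x_mid))

    return S


def quadratic_log_profile(g0: float, g1: float, v_g: float, x0: float,
                          koff: float = DEFAULT_KOFF,
                          kon: float = DEFAULT_KON
                          ) -> Callable[[np.ndarray, float], np.ndarray]:
    """Moving profile whose perceived gradient is ~``g0 + g1 z`` near the
    band (z = x - x0 - V_G t), built as S = sqrt(K_off K_on) * exp(quadratic)
    so the receptors stay in their log-sensitive range there."""
    s_c = np.sqrt(koff * kon)

    def S(x, t):
        z = np.asarray(x) - x0 - v_g * t
        return s_c * np.exp(g0 * z + 0.5 * g1 * z**2)

    return S


def simulate_agents(
    params: PathwayParams | list[PathwayParams],
    environment: Callable[[np.ndarray, float], np.ndarray] | dict,
    n_cells: int,
    T: float,
    seed: int,
    dt: float = 0.02 / 60.0,
    box: ChannelBox | None = None,
    frame_rate: float = 9.0 * 60.0,
    initial_x: tuple[float, float] = (10.0, 0.3),
    record_field: bool = False,
) -> tuple[TrackTable, pd.DataFrame, dict]:
    """Run ``n_cells`` agents per parameter set for ``T`` minutes.

    ``environment`` is either a callable ``S(x, t)`` (rigid, possibly
    translating profile; x is the channel-axis coordinate) or a dict
    ``{"s0", "k", "d_s", "dx"}`` describing a consumed 1D field along the
    channel.  Positions are sampled at the camera frame rate into a 3D
    TrackTable (columns ``x_mm``, ``y_mm``, ``h_mm``); the returned
    phenotype table maps ``cell_id`` to its parameter-set index, and the
    info dict counts wall clamps and (for consumed fields) holds final
    field snapshots.
    """
    if box is None:
        box = ChannelBox()
    ladder = params if isinstance(params, list) else [params]
    rng = np.random.default_rng(seed)
    n_total = n_cells * len(ladder)
    pheno_idx = np.repeat(np.arange(len(ladder)), n_cells)

    pos = np.empty((n_total, 3))
    pos[:, 0] = np.clip(rng.normal(initial_x[0], initial_x[1], n_total), 0, box.lx)
    pos[:, 1] = rng.uniform(0, box.ly, n_total)
    pos[:, 2] = rng.uniform(0, box.lz, n_total)
    heading = _random_headings(n_total, rng)

    field_mode = isinstance(environment, dict)
    if field_mode:
        dx = environment.get("dx", 0.02)
        grid = np.arange(0.0, box.lx + 0.5 * dx, dx)
        S_field = np.full(len(grid), float(environment["s0"]))
        d_s = environment.get("d_s", 0.048)
        k_cons = environment["k"]
        ab, rhs_main, a_half = _crank_nicolson_matrices(len(grid), d_s * dt / dx**2)

        def S_at(x, t):
            return np.interp(x, grid, S_field)
    else:
        S_at = environment

    # per-phenotype constants
    y_half = np.array([cw_bias_half_point(p) for p in ladder])
    per = [ladder[i] for i in pheno_idx]
    N_arr = np.array([p.N for p in per])
    tau_arr = np.array([p.tau for p in per])
    a0_arr = np.array([p.a0 for p in per])
    alpha_arr = np.array([p.alpha_m for p in per])
    m0_arr = np.array([p.m0 for p in per])
    yp0_arr = np.array([p.yp0 for p in per])
    hill_arr = np.array([p.hill for p in per])
    yhalf_arr = y_half[pheno_idx]
    speed_arr = np.array([p.run_speed for p in per])
    rot_arr = np.array([p.rot_diffusion for p in per])
    omega_arr = np.array([p.motor_rate for p in per])
    n_flag = ladder[0].n_flagella
    vote = ladder[0].voting_threshold
    if any(p.n_flagella != n_flag or p.voting_threshold != vote for p in ladder):
        raise ValueError("flagella count and voting threshold must be shared")
    if dt >= min(p.tau for p in ladder):
        raise ValueError("dt must be < the smallest adaptation time")

    koff = ladder[0].koff
    kon = ladder[0].kon
    # start adapted to the local ligand level
    S_loc = np.asarray(S_at(pos[:, 0], 0.0), dtype=float)
    m = m0_arr + (mwc_log_occupancy(S_loc, koff, kon)
                  - np.log((1 - a0_arr) / a0_arr) / N_arr) / alpha_arr
    b0 = np.array([_basal_cw_bias(p) for p in ladder])[pheno_idx]
    flagella = rng.random((n_total, n_flag)) < b0[:, None]
    tumbling = flagella.sum(axis=1) >= vote

    n_steps = int(round(T / dt))
    frame_every = max(int(round(1.0 / (frame_rate * dt))), 1)
    rec_t = []
    rec_pos = []
    clamped = 0
    f0_arr = np.log((1 - a0_arr) / a0_arr)

    for step in range(n_steps + 1):
        t = step * dt
        if step % frame_every == 0:
            rec_t.append(t)
            rec_pos.append(pos.copy())
        if step == n_steps:
            break
        S_loc = np.asarray(S_at(pos[:, 0], t), dtype=float)
        # pathway
        f = N_arr * (alpha_arr * (m0_arr - m)
                     + mwc_log_occupancy(S_loc, koff, kon))
        a = 1.0 / (1.0 + np.exp(f))
        slope_norm = N_arr * alpha_arr * a0_arr * (1.0 - a0_arr)
        m = m + (a0_arr - a) / (tau_arr * slope_norm) * dt
        yp = yp0_arr * a / a0_arr
        ratio = np.power(yp / yhalf_arr, hill_arr)
        bias = ratio / (1.0 + ratio)
        p_to_cw = (omega_arr * bias * dt)[:, None]
        p_to_ccw = (omega_arr * (1.0 - bias) * dt)[:, None]
        u = rng.random((n_total, n_flag))
        flagella = np.where(flagella, u >= p_to_ccw, u < p_to_cw)
        was_tumbling = tumbling
        tumbling = flagella.sum(axis=1) >= vote
        # re-orient uniformly when a tumble ends
        ended = was_tumbling & ~tumbling
        if ended.any():
            heading[ended] = _random_headings(int(ended.sum()), rng)
        # motion
        running = ~tumbling
        if running.any():
            rot = rot_arr[running]
            if np.any(rot > 0):
                kick = np.sqrt(2.0 * rot * dt)[:, None] * \
                    rng.standard_normal((int(running.sum()), 3))
                h = heading[running] + kick
                heading[running] = h / (np.linalg.norm(h, axis=1, keepdims=True)
                                        + SPHERE_EPS)
            pos[running] += (speed_arr[running, None] * heading[running]) * dt
            clamped += _reflect(pos, heading, box)
        # field update
        if field_mode:
            idx = np.clip((pos[:, 0] / dx).astype(int), 0, len(grid) - 1)
            rho = np.bincount(idx, minlength=len(grid)) / dx
            S_field = np.clip(S_field - k_cons * rho * dt, 0.0, None)
            S_field = np.clip(_diffuse_cn(S_field, ab, rhs_main, a_half), 0.0, None)

    rec_t = np.asarray(rec_t)
    rec_pos = np.asarray(rec_pos)          # (n_frames, n_total, 3)
    n_frames = len(rec_t)
    cell_ids = np.array([f"agent{i:05d}" for i in range(n_total)])
    data = pd.DataFrame({
        "cell_id": np.repeat(cell_ids, n_frames),
        "t_min": np.tile(rec_t, n_total),
        "x_mm": rec_pos[:, :, 0].T.ravel(),
        "y_mm": rec_pos[:, :, 1].T.ravel(),
        "h_mm": rec_pos[:, :, 2].T.ravel(),
    })
    tracks = TrackTable(data=data, frame_interval=1.0 / frame_rate, frame="lab",
                        meta={"seed": seed, "generator": "agent"}, validate=False)
    phenotypes = pd.DataFrame({"cell_id": cell_ids, "phenotype": pheno_idx,
                               "N": N_arr, "tau_min": tau_arr, "yp0": yp0_arr})
    info = {"n_clamped": clamped}
    if field_mode:
        info["S_final"] = S_field
        info["S_grid"] = grid
    return tracks, phenotypes, info


def effective_chi(
    params: PathwayParams,
    probe_slope: float = 0.1,
    n_cells: int = 400,
    T: float = 10.0,
    seed: int = 0,
    burn_in: float = 1.0,
    dt: float = 0.02 / 60.0,
    check_linearity: bool = False,
) -> dict:
    """Measure chi and D of one parameter set.

    chi = (mean drift speed) / (perceived gradient) in a shallow static
    exponential profile held in the receptors' log-sensing range (there
    the perceived gradient equals the profile's log slope); D comes from
    the MSD slope of a zero-gradient run.  With ``check_linearity`` the
    probe is repeated at half the slope and a drift ratio far from the
    linear prediction raises an error.
    """
    box = ChannelBox()
    s_mid = np.sqrt(params.koff * params.kon)

    def drift_at(slope: float, seed_off: int) -> float:
        env = exponential_profile(s_mid, slope, box.lx / 2)
        tracks, _, _ = simulate_agents(params, env, n_cells, T,
                                       seed + seed_off, dt=dt, box=box)
        df = tracks.data
        keep = df["t_min"] >= burn_in
        per_cell = df[keep].groupby("cell_id", sort=False).agg(
            x0=("x_mm", "first"), x1=("x_mm", "last"),
            t0=("t_min", "first"), t1=("t_min", "last"))
        v = (per_cell["x1"] - per_cell["x0"]) / (per_cell["t1"] - per_cell["t0"])
        return float(v.mean())

    v_drift = drift_at(probe_slope, 0)
    chi = v_drift / probe_slope
    if check_linearity:
        v_half = drift_at(probe_slope / 2, 1)
        if v_half != 0 and not (1.4 < v_drift / v_half < 2.6):
            raise ValueError(
                "drift not proportional to the gradient: probe too steep, "
                "use a shallower slope"
            )
    # motility from a zero-gradient run
    env0 = exponential_profile(s_mid, 0.0, box.lx / 2)
    tracks0, _, _ = simulate_agents(params, env0, n_cells, T, seed + 17,
                                    dt=dt, box=box)
    df = tracks0.data
    piv = df.pivot_table(index="t_min", columns="cell_id", values="x_mm")
    lag = max(int(round(0.5 / (tracks0.frame_interval))), 1)   # 0.5 min lag
    lags_min = []
    msds = []
    arr = piv.to_numpy()
    for mult in (1, 2, 3):
        kk = lag * mult
        if kk < len(arr):
            d = arr[kk:] - arr[:-kk]
            lags_min.append(kk * tracks0.frame_interval)
            msds.append(float(np.nanmean(d * d)))
    slope = np.polyfit(lags_min, msds, 1)[0]
    return {"chi": chi, "D": float(slope / 2.0), "drift": v_drift,
            "probe_slope": probe_slope}
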