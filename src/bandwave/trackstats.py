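"""Single-cell statistics of tracks inside a migrating band.

Implements the measurement pipeline applied to particle-tracking output:
group velocity, transformation to the co-moving band coordinate, density /
instantaneous-velocity / drift-velocity profiles, run-tumble segmentation,
event statistics, band width, and moving-frame MSD.

Conventions: all positions mm, times min; the band coordinate is
``z = x - V_G t - x_peak(0)`` with the origin at the density peak of the
first frame; bins are uniform and half-open ``[left, right)``; ``z``
increases toward the migration direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_config import EVENT_COLUMNS, SpatialProfile, TrackTable

__all__ = [
    "SegmentationParams",
    "DriftFit",
    "estimate_group_velocity",
    "find_density_peak",
    "to_moving_frame",
    "to_lab_frame",
    "density_profile",
    "instantaneous_velocity_profile",
    "segment_runs_tumbles",
    "drift_velocity_profile",
    "fit_linear_drift",
    "run_statistics",
    "width",
    "msd_moving_frame",
]

#: experimental defaults: 240 um analysis bins, 60 um peak-finding bins,
#: 12,000 um^2 channel cross-section
DEFAULT_BIN_MM = 0.24
PEAK_BIN_MM = 0.06
SECTION_AREA_MM2 = 0.012


# ---------------------------------------------------------------------------
# helpers


def _frame_pairs(tracks: TrackTable) -> pd.DataFrame:
    """Consecutive-frame displacement pairs over all cells.

    Returns columns: x0 (and z0/y contributions if present), dx, dt.
    """
    df = tracks.data
    g = df.groupby("cell_id", sort=False)
    out = pd.DataFrame(index=df.index)
    out["dt"] = g["t_min"].diff().shift(-1)
    for col in ("x_mm", "z_mm", "y_mm"):
        if col in df.columns:
            out[col + "_0"] = df[col]
            out["d_" + col] = g[col].diff().shift(-1)
    out = out.dropna(subset=["dt"])
    return out


def _binned_mean(z: np.ndarray, values: np.ndarray, edges: np.ndarray,
                 quantity: str) -> SpatialProfile:
    idx = np.digitize(z, edges) - 1
    nb = len(edges) - 1
    ok = (idx >= 0) & (idx < nb)
    idx, values, z = idx[ok], values[ok], z[ok]
    n = np.bincount(idx, minlength=nb)
    s = np.bincount(idx, weights=values, minlength=nb)
    sz = np.bincount(idx, weights=z, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        ss = np.bincount(idx, weights=values**2, minlength=nb)
        var = np.where(n > 1, (ss - n * mean**2) / np.maximum(n - 1, 1), np.nan)
        sem = np.where(n > 1, np.sqrt(np.clip(var, 0, None) / np.maximum(n, 1)), np.nan)
        z_mean = np.where(n > 0, sz / np.maximum(n, 1), np.nan)
    return SpatialProfile(bin_edges=edges, value=mean, sem=sem, n=n,
                          quantity=quantity, z_mean=z_mean)


def _edges_covering(z: np.ndarray, bin_width: float) -> np.ndarray:
    """Uniform bin edges aligned to multiples of bin_width covering z."""
    lo = np.floor(z.min() / bin_width) * bin_width
    hi = np.ceil(z.max() / bin_width) * bin_width
    n = max(int(round((hi - lo) / bin_width)), 1)
    return lo + bin_width * np.arange(n + 1)


# ---------------------------------------------------------------------------
# group velocity and moving frame


def estimate_group_velocity(tracks: TrackTable) -> tuple[float, float]:
    """Mean frame-to-frame velocity <dx/dt> over all tracks and all time.

    Returns (V_G, SEM) in mm/min; SEM is over frame pairs.
    """
    pairs = _frame_pairs(tracks)
    if "d_x_mm" not in pairs or not len(pairs):
        raise ValueError("no displacement pairs: need >= 2 samples in >= 1 cell")
    v = (pairs["d_x_mm"] / pairs["dt"]).to_numpy()
    sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
    return float(v.mean()), float(sem)


def find_density_peak(tracks: TrackTable, bin_width: float = PEAK_BIN_MM,
                      smooth_bins: int = 5, t: float = 0.0) -> float:
    """Density-peak position of the frame at time ``t`` (default first frame).

    Histogram at ``bin_width`` (60 um default), boxcar-smoothed over
    ``smooth_bins`` bins, argmax refined by parabolic interpolation — the
    peak of a wide band is flat, so the raw argmax alone is noisy.
    """
    df = tracks.data
    sel = np.isclose(df["t_min"].to_numpy(), t)
    if not sel.any():
        raise ValueError(
            f"no frame at t={t}; pass the reference position explicitly"
        )
    x = df.loc[sel, "x_mm"].to_numpy()
    edges = _edges_covering(x, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        counts = np.convolve(counts, kernel, mode="same")
    i = int(np.argmax(counts))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if 0 < i < len(counts) - 1:
        denom = counts[i - 1] - 2 * counts[i] + counts[i + 1]
        if denom < 0:
            shift = 0.5 * (counts[i - 1] - counts[i + 1]) / denom
            return float(centers[i] + np.clip(shift, -0.5, 0.5) * bin_width)
    return float(centers[i])


def to_moving_frame(tracks: TrackTable, v_g: float,
                    reference: float | None = None) -> TrackTable:
    """Attach the band coordinate ``z = x - V_G t - x_peak(0)``.

    ``reference`` defaults to the t=0 density peak (60 um bins).  The lab
    coordinate is kept alongside ``z`` so lab-frame statistics (e.g. the
    instantaneous velocity) remain computable.
    """
    if not np.isfinite(v_g):
        raise ValueError("V_G must be finite")
    if reference is None:
        reference = find_density_peak(tracks)
    df = tracks.data.copy()
    df["z_mm"] = df["x_mm"] - v_g * df["t_min"] - reference
    meta = dict(tracks.meta)
    meta.update({"v_g": v_g, "reference": reference})
    return TrackTable(data=df, frame_interval=tracks.frame_interval,
                      frame="moving", meta=meta, validate=False)


def to_lab_frame(tracks: TrackTable) -> TrackTable:
    """Invert :func:`to_moving_frame` using the stored (V_G, reference)."""
    v_g = tracks.meta.get("v_g")
    ref = tracks.meta.get("reference")
    if v_g is None or ref is None:
        raise ValueError("tracks do not carry (v_g, reference) metadata")
    df = tracks.data.copy()
    df["x_mm"] = df["z_mm"] + v_g * df["t_min"] + ref
    df = df.drop(columns=["z_mm"])
    return TrackTable(data=df, frame_interval=tracks.frame_interval,
                      frame="lab", meta=dict(tracks.meta), validate=False)


# ---------------------------------------------------------------------------
# profiles


def density_profile(positions: TrackTable | np.ndarray,
                    bin_width: float = DEFAULT_BIN_MM,
                    section_area: float = SECTION_AREA_MM2,
                    edges: np.ndarray | None = None) -> SpatialProfile:
    """Number density per volume: per-bin count / (section_area * bin_width).

    ``positions`` may be a moving-frame TrackTable (all samples pooled) or a
    plain position array.  Conservation: sum(rho * a * dz) equals the number
    of counted positions exactly.  SEM is Poisson (sqrt(n) scaled).
    """
    if bin_width <= 0 or section_area <= 0:
        raise ValueError("bin_width and section_area must be positive")
    z = positions.positions("z_mm") if isinstance(positions, TrackTable) \
        else np.asarray(positions, dtype=float)
    if len(z) == 0:
        warnings.warn("empty input: all-zero density profile", stacklevel=2)
        e = edges if edges is not None else np.array([0.0, bin_width])
        nb = len(e) - 1
        return SpatialProfile(e, np.zeros(nb), np.full(nb, np.nan),
                              np.zeros(nb, dtype=int), "density")
    if edges is None:
        edges = _edges_covering(z, bin_width)
    counts, _ = np.histogram(z, bins=edges)
    vol = section_area * bin_width
    sem = np.where(counts > 1, np.sqrt(counts) / vol, np.nan)
    return SpatialProfile(bin_edges=edges, value=counts / vol, sem=sem,
                          n=counts, quantity="density")


def instantaneous_velocity_profile(tracks: TrackTable,
                                   bin_width: float = DEFAULT_BIN_MM,
                                   edges: np.ndarray | None = None) -> SpatialProfile:
    """Per-bin mean lab-frame frame-to-frame velocity, binned by the pair's
    starting band position z."""
    pairs = _frame_pairs(tracks)
    if "z_mm_0" not in pairs:
        raise ValueError("need a moving-frame table (z_mm column)")
    v = (pairs["d_x_mm"] / pairs["dt"]).to_numpy()
    z0 = pairs["z_mm_0"].to_numpy()
    if edges is None:
        edges = _edges_covering(z0, bin_width)
    return _binned_mean(z0, v, edges, "instantaneous_velocity")


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class SegmentationParams:
    """Two-state (run/tumble) classification thresholds.

    A frame step is called a tumble candidate when its speed falls below
    ``speed_fraction`` of the reference run speed (75th percentile of all
    step speeds), or when the turn angle between consecutive steps exceeds
    ``turn_angle_rad`` while the speed is below ``turn_speed_fraction`` of
    the reference.  Hysteresis then removes tumble segments shorter than
    ``min_tumble_frames`` and run segments shorter than ``min_run_frames``.
    """

    speed_fraction: float = 0.5
    turn_angle_rad: float = np.pi / 2
    turn_speed_fraction: float = 0.8
    min_tumble_frames: int = 2
    min_run_frames: int = 2
    min_frames: int = 10


def _enforce_min_length(labels: np.ndarray, state: bool, min_len: int) -> np.ndarray:
    """Flip segments of ``state`` shorter than ``min_len`` to the other state."""
    labels = labels.copy()
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] == state and (j - i) < min_len:
            labels[i:j] = not state
        i = j
    return labels


def segment_runs_tumbles(
    tracks: TrackTable,
    params: SegmentationParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Partition each track into alternating runs and tumbles.

    Steps are classified on lab-frame step speed and turn angle, with
    hysteresis on minimum segment lengths; events are assembled as
    tumble-then-run pairs with the tumble-start band position ``z_T`` as
    the event position.  Returns ``(events, info)`` where ``events`` has
    the canonical event columns and ``info`` counts skipped short tracks
    and per-frame labels for diagnostic use.

    Requires a moving-frame table (``z_mm``) sampled at ~uniform dt.
    """
    if params is None:
        params = SegmentationParams()
    df = tracks.data
    if "z_mm" not in df.columns:
        raise ValueError("need a moving-frame table (z_mm column)")
    dt = tracks.frame_interval
    has_y = "y_mm" in df.columns

    # global reference run speed from all step speeds
    g = df.groupby("cell_id", sort=False)
    dx_all = g["x_mm"].diff().to_numpy()
    dy_all = g["y_mm"].diff().to_numpy() if has_y else np.zeros_like(dx_all)
    step = np.hypot(dx_all, dy_all)
    speeds = step[np.isfinite(step)] / dt
    if len(speeds) == 0:
        raise ValueError("no displacement steps to segment")
    v_ref = np.percentile(speeds, 75)
    if v_ref <= 0:
        v_ref = max(speeds.max(), 1e-12)

    events = []
    labels_out = []
    n_skipped = 0
    for cell_id, cdf in g:
        n_f = len(cdf)
        if n_f < params.min_frames:
            n_skipped += 1
            continue
        x = cdf["x_mm"].to_numpy()
        y = cdf["y_mm"].to_numpy() if has_y else np.zeros(n_f)
        z = cdf["z_mm"].to_numpy()
        t = cdf["t_min"].to_numpy()
        dx = np.diff(x)
        dy = np.diff(y)
        sp = np.hypot(dx, dy) / dt
        # turn angle between consecutive steps (padded with 0 at the ends)
        dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
        nrm = np.hypot(dx[:-1], dy[:-1]) * np.hypot(dx[1:], dy[1:])
        with np.errstate(invalid="ignore", divide="ignore"):
            ang = np.arccos(np.clip(np.where(nrm > 0, dot / np.maximum(nrm, 1e-300), 1.0),
                                    -1.0, 1.0))
        turn = np.zeros(len(dx))
        turn[1:] = ang
        tumble = (sp < params.speed_fraction * v_ref) | (
            (turn > params.turn_angle_rad) & (sp < params.turn_speed_fraction * v_ref)
        )
        tumble = _enforce_min_length(tumble, True, params.min_tumble_frames)
        tumble = _enforce_min_length(tumble, False, params.min_run_frames)
        labels_out.append(pd.DataFrame(
            {"cell_id": cell_id, "t_min": t[:-1],
             "state": np.where(tumble, "tumble", "run")}))
        # tumble-then-run event assembly over step indices
        i = 0
        n_s = len(tumble)
        while i < n_s:
            j = i
            while j < n_s and tumble[j] == tumble[i]:
                j += 1
            if tumble[i] and j < n_s:           # tumble segment followed by a run
                k = j
                while k < n_s and not tumble[k]:
                    k += 1
                run_dx = x[k] - x[j]
                run_dy = y[k] - y[j]
                l_r = float(np.hypot(run_dx, run_dy))
                theta = float(np.arccos(np.clip(run_dx / l_r, -1.0, 1.0))) \
                    if l_r > 0 else np.pi / 2
                events.append((cell_id, t[i], z[i], (j - i) * dt, (k - j) * dt,
                               l_r, theta))
                i = k
            else:
                i = j
    events_df = pd.DataFrame(events, columns=EVENT_COLUMNS)
    info = {
        "n_skipped_short": n_skipped,
        "v_ref_mm_min": float(v_ref),
        "frame_labels": pd.concat(labels_out, ignore_index=True)
        if labels_out else pd.DataFrame(columns=["cell_id", "t_min", "state"]),
    }
    return events_df, info


# ---------------------------------------------------------------------------
# drift velocity and linear fit


def drift_velocity_profile(events: pd.DataFrame,
                           bin_width: float = DEFAULT_BIN_MM,
                           edges: np.ndarray | None = None,
                           sem_method: str = "bootstrap",
                           n_boot: int = 200,
                           seed: int = 0) -> SpatialProfile:
    """Expected drift velocity per bin of the tumble position:

        V_D = mean(l_R cos theta_R) / mean(tau_R + tau_T)

    Events are assigned to bins by ``z_T``.  SEM per bin by nonparametric
    bootstrap over events (default) or by delta-method propagation.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    z = events["z_tumble_mm"].to_numpy()
    num = (events["l_R_mm"] * np.cos(events["theta_R_rad"])).to_numpy()
    den = (events["tau_R_min"] + events["tau_T_min"]).to_numpy()
    if edges is None:
        edges = _edges_covering(z, bin_width)
    nb = len(edges) - 1
    idx = np.digitize(z, edges) - 1
    ok = (idx >= 0) & (idx < nb)
    idx, num, den, z = idx[ok], num[ok], den[ok], z[ok]
    n = np.bincount(idx, minlength=nb)
    s_num = np.bincount(idx, weights=num, minlength=nb)
    s_den = np.bincount(idx, weights=den, minlength=nb)
    s_z = np.bincount(idx, weights=z, minlength=nb)
    value = np.full(nb, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        flagged = s_den <= 0
        value = np.where((n > 0) & ~flagged, s_num / np.where(s_den > 0, s_den, 1.0),
                         np.nan)
        z_mean = np.where(n > 0, s_z / np.maximum(n, 1), np.nan)
    sem = np.full(nb, np.nan)
    if sem_method == "bootstrap":
        rng = np.random.default_rng(seed)
        for b in range(nb):
            m = idx == b
            nm = int(n[b])
            if nm < 2:
                continue
            bn, bd = num[m], den[m]
            picks = rng.integers(0, nm, size=(n_boot, nm))
            ratio = bn[picks].sum(axis=1) / bd[picks].sum(axis=1)
            sem[b] = ratio.std(ddof=1)
    elif sem_method == "delta":
        for b in range(nb):
            m = idx == b
            nm = int(n[b])
            if nm < 2:
                continue
            mn, md = num[m].mean(), den[m].mean()
            vn, vd = num[m].var(ddof=1), den[m].var(ddof=1)
            cov = np.cov(num[m], den[m], ddof=1)[0, 1]
            sem[b] = abs(mn / md) * np.sqrt(
                max(vn / mn**2 - 2 * cov / (mn * md) + vd / md**2, 0.0) / nm
            ) if mn != 0 else np.sqrt(vn / nm) / md
    else:
        raise ValueError("sem_method must be 'bootstrap' or 'delta'")
    return SpatialProfile(bin_edges=edges, value=value, sem=sem, n=n,
                          quantity="drift_velocity", z_mean=z_mean)


@dataclass
class DriftFit:
    """Weighted linear fit ``V_D(z) = -r z + V_D0``."""

    r: float
    v_d0: float
    r_se: float
    v_d0_se: float
    n_bins: int
    z_range: tuple[float, float]


def fit_linear_drift(profile: SpatialProfile,
                     z_range: tuple[float, float] | None = None) -> DriftFit:
    """Weighted least squares of the binned drift velocity on z.

    Weights are 1/sem^2 (unweighted if no bin has a finite SEM).  The
    abscissa is the per-bin mean tumble position when recorded, which
    avoids the slope attenuation of using bin centers under uneven
    occupancy.  ``z_range`` restricts the fit window; the band-analysis
    convention is the central +/-1.65 sigma of the density profile.
    """
    z = profile.abscissa()
    v = profile.value
    w = np.where(np.isfinite(profile.sem) & (profile.sem > 0),
                 1.0 / np.where(profile.sem > 0, profile.sem, 1.0) ** 2, np.nan)
    ok = np.isfinite(z) & np.isfinite(v)
    if z_range is not None:
        lo, hi = z_range
        ok &= (z >= lo) & (z <= hi)
    if ok.sum() < 3:
        raise ValueError("need >= 3 bins with defined values inside z_range")
    z, v = z[ok], v[ok]
    w = w[ok]
    if not np.isfinite(w).all():
        w = np.ones_like(v)
    X = np.column_stack([z, np.ones_like(z)])
    W = np.diag(w)
    XtW = X.T @ W
    A = XtW @ X
    if np.linalg.matrix_rank(A) < 2:
        raise ValueError("rank-deficient fit (degenerate abscissa)")
    beta = np.linalg.solve(A, XtW @ v)
    cov = np.linalg.inv(A)
    # scale by residual chi^2 per dof so the SEs are calibrated even if the
    # per-bin SEMs are off by a common factor
    resid = v - X @ beta
    dof = max(len(v) - 2, 1)
    chi2 = float(resid @ (w * resid)) / dof
    se = np.sqrt(np.diag(cov) * max(chi2, 1.0))
    slope, intercept = beta
    lo = float(z.min()) if z_range is None else float(z_range[0])
    hi = float(z.max()) if z_range is None else float(z_range[1])
    return DriftFit(r=float(-slope), v_d0=float(intercept),
                    r_se=float(se[0]), v_d0_se=float(se[1]),
                    n_bins=int(len(v)), z_range=(lo, hi))


# ---------------------------------------------------------------------------
# event statistics, width, MSD


def run_statistics(events: pd.DataFrame,
                   bin_width: float = DEFAULT_BIN_MM,
                   direction_split: bool = True,
                   n_angle_bins: int = 12) -> dict:
    """Per-bin run statistics, optionally split by run direction.

    Forward runs have cos(theta_R) > 0.  For each (bin, direction) cell the
    mean run length and duration are reported with SEM, plus the
    exponential-MLE rate (1/mean).  An angular histogram of theta_R over
    all events is included.
    """
    if not len(events):
        raise ValueError("empty event table")
    z = events["z_tumble_mm"].to_numpy()
    edges = _edges_covering(z, bin_width)
    groups: dict[str, pd.DataFrame] = {}
    masks = {"all": np.ones(len(events), dtype=bool)}
    if direction_split:
        fwd = np.cos(events["theta_R_rad"].to_numpy()) > 0
        masks = {"forward": fwd, "backward": ~fwd}
    for name, mask in masks.items():
        sub = events.loc[mask]
        rows = []
        for quantity, col in [("l_R_mm", "l_R_mm"), ("tau_R_min", "tau_R_min")]:
            prof = _binned_mean(sub["z_tumble_mm"].to_numpy(),
                                sub[col].to_numpy(), edges, quantity)
            with np.errstate(divide="ignore"):
                rate = np.where(prof.value > 0, 1.0 / prof.value, np.nan)
            rows.append(pd.DataFrame({
                "z_mm": prof.centers, "quantity": quantity,
                "mean": prof.value, "sem": prof.sem, "n": prof.n,
                "exp_rate": rate,
            }))
        groups[name] = pd.concat(rows, ignore_index=True)
    theta = events["theta_R_rad"].to_numpy()
    a_edges = np.linspace(0, np.pi, n_angle_bins + 1)
    counts, _ = np.histogram(theta, bins=a_edges)
    angular = pd.DataFrame({"theta_left_rad": a_edges[:-1],
                            "theta_right_rad": a_edges[1:], "n": counts})
    return {"by_direction": groups, "angular": angular, "bin_edges": edges}


def width(positions: TrackTable | np.ndarray) -> float:
    """Band width 2*sigma: twice the sample SD (n-1 denominator) of the
    relative positions."""
    z = positions.positions("z_mm") if isinstance(positions, TrackTable) \
        else np.asarray(positions, dtype=float)
    if len(z) < 2:
        raise ValueError("need at least 2 positions")
    return float(2.0 * z.std(ddof=1))


def msd_moving_frame(tracks: TrackTable,
                     lags: Sequence[float] | None = None) -> pd.DataFrame:
    """Ensemble- and time-averaged MSD of the band coordinate.

    ``lags`` in minutes are snapped to frame multiples; lags exceeding the
    longest track are dropped with a warning.  Returns columns
    ``lag_min``, ``msd_mm2``, ``n_pairs``.
    """
    dt = tracks.frame_interval
    cells = [cdf["z_mm"].to_numpy() for _, cdf in tracks.groupby_cell()]
    max_len = max(len(c) for c in cells)
    if lags is None:
        k_lags = np.unique(np.round(np.geomspace(1, max_len - 1, 30)).astype(int))
    else:
        k_lags = np.unique(np.maximum(np.round(np.asarray(lags) / dt), 1).astype(int))
        dropped = k_lags[k_lags >= max_len]
        if len(dropped):
            warnings.warn(f"dropping {len(dropped)} lags beyond track duration",
                          stacklevel=2)
        k_lags = k_lags[k_lags < max_len]
    rows = []
    for k in k_lags:
        s = 0.0
        n = 0
        for zc in cells:
            if len(zc) > k:
                d = zc[k:] - zc[:-k]
                s += float((d * d).sum())
                n += len(d)
        if n:
            rows.append((k * dt, s / n, n))
    return pd.DataFrame(rows, columns=["lag_min", "msd_mm2", "n_pairs"])
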