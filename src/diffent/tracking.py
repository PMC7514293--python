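"""Trajectory linking, mean-square-displacement curves, and power-law diffusion fits.

The anomalous-diffusion model throughout is

    MSD(Δt) = 2 n K_α Δt^α

with ``n`` the number of spatial dimensions, ``K_α`` the generalized
diffusion coefficient (µm²/s^α) and ``α`` the diffusion power (α < 1
sub-diffusion, α = 1 Brownian, α > 1 super-diffusion).  Detections are
linked frame-to-frame by a deterministic greedy nearest-neighbor rule,
per-trajectory MSDs are time-averaged over all overlapping index pairs,
averaged unweighted across trajectories, and fitted by nonlinear least
squares to the one-term power model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Time-stamped positions of one tracked object.

    Parameters
    ----------
    particle_id : int
        Identifier, unique within a cell.
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    xy : ndarray, shape (n, d)
        Positions in µm; ``d`` is usually 2.
    has_gaps : bool
        True if the time grid is not contiguous (gap-closing was applied).
    """

    particle_id: int
    t: np.ndarray
    xy: np.ndarray
    has_gaps: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.shape[0] != self.t.shape[0]:
            raise ValueError("t and xy must have the same length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def n_dims(self) -> int:
        return self.xy.shape[1]

    def to_frame(self, cell_id: str = "", dt_frame: float | None = None) -> pd.DataFrame:
        """Tabulate as (cell_id, particle_id, frame, t_s, x_um, y_um)."""
        dt = dt_frame if dt_frame is not None else _infer_dt(self.t)
        frames = np.rint((self.t - self.t[0]) / dt).astype(int)
        data = {
            "cell_id": cell_id,
            "particle_id": self.particle_id,
            "frame": frames,
            "t_s": self.t,
            "x_um": self.xy[:, 0],
        }
        if self.n_dims > 1:
            data["y_um"] = self.xy[:, 1]
        return pd.DataFrame(data)


def _infer_dt(t: np.ndarray) -> float:
    if t.size < 2:
        return 1.0
    return float(np.min(np.diff(t)))


def trajectories_to_csv(trajectories: list[Trajectory], path: str | Path,
                        cell_id: str = "") -> None:
    pd.concat([tr.to_frame(cell_id) for tr in trajectories],
              ignore_index=True).to_csv(path, index=False)


def trajectories_from_csv(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    cols = ["x_um"] + (["y_um"] if "y_um" in df.columns else [])
    out = []
    for pid, grp in df.groupby("particle_id"):
        grp = grp.sort_values("t_s")
        out.append(Trajectory(int(pid), grp["t_s"].to_numpy(),
                              grp[cols].to_numpy()))
    return out


@dataclass
class MSDCurve:
    """Per-cell ensemble MSD over a grid of time lags.

    ``msd[i]`` is the unweighted mean over trajectories of the time-averaged
    squared displacement at lag ``lags[i]``; ``n_obs[i]`` counts the
    displacement pairs contributing at that lag.
    """

    lags: np.ndarray          # s, strictly increasing
    msd: np.ndarray           # µm²
    n_obs: np.ndarray         # pairs per lag
    n_trajectories: int

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if self.lags.size and not np.all(np.diff(self.lags) > 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lags, "msd_um2": self.msd,
                             "n_obs": self.n_obs})


@dataclass
class DiffusionFit:
    """Fitted anomalous-diffusion parameters for one cell.

    ``k_alpha`` is in µm²/s^α; ``alpha`` is dimensionless.  ``fallback``
    marks fits where the nonlinear stage failed to converge and the log-log
    linear estimate was kept instead.
    """

    k_alpha: float
    alpha: float
    n_dims: int = 2
    k_alpha_stderr: float = float("nan")
    alpha_stderr: float = float("nan")
    residual_norm: float = float("nan")
    n_trajectories: int = 0
    fallback: bool = False

    def predict(self, lags: np.ndarray) -> np.ndarray:
        """Model MSD at the fitted parameters: 2 n K_α Δt^α."""
        return 2.0 * self.n_dims * self.k_alpha * np.asarray(lags, float) ** self.alpha

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "k_alpha": self.k_alpha, "alpha": self.alpha,
            "n_dims": self.n_dims, "k_alpha_stderr": self.k_alpha_stderr,
            "alpha_stderr": self.alpha_stderr,
            "residual_norm": self.residual_norm,
            "n_trajectories": self.n_trajectories, "fallback": self.fallback,
        }, indent=1))


# ---------------------------------------------------------------------------
# linking

def link(detections: pd.DataFrame, max_disp: float, min_len: int = 2,
         dt_frame: float = 1.0) -> list[Trajectory]:
    """Link per-frame detections into trajectories.

    Greedy global-distance-order assignment: within each consecutive frame
    pair every (open track, detection) candidate with distance ≤ ``max_disp``
    is considered in increasing distance order (ties broken by smaller
    particle id, then detection order) and accepted when both partners are
    still free.  Unmatched detections start new trajectories; tracks missing
    a detection are closed (no gap closing).  Trajectories shorter than
    ``min_len`` frames are dropped.

    Parameters
    ----------
    detections : DataFrame
        Columns ``frame``, ``x_um`` and (optionally) ``y_um``, sorted or
        sortable by frame.
    max_disp : float
        Maximum frame-to-frame displacement in µm.
    min_len : int
        Minimum trajectory length in frames.
    dt_frame : float
        Frame interval in seconds (converts frame index to time).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    cols = ["x_um"] + (["y_um"] if "y_um" in detections.columns else [])
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)

    open_tracks: dict[int, list[tuple[int, np.ndarray]]] = {}
    closed: list[list[tuple[int, np.ndarray]]] = []
    next_id = 0
    prev_frame = None

    for frame, grp in det.groupby("frame", sort=True):
        pts = grp[cols].to_numpy(dtype=float)
        if prev_frame is None or frame != prev_frame + 1 or not open_tracks:
            # non-contiguous frame: close everything, start fresh tracks
            closed.extend(open_tracks.values())
            open_tracks = {}
            matched_tracks: dict[int, int] = {}
        else:
            track_ids = sorted(open_tracks)
            last = np.array([open_tracks[tid][-1][1] for tid in track_ids])
            d = np.linalg.norm(last[:, None, :] - pts[None, :, :], axis=-1)
            cand = [(d[i, j], track_ids[i], j)
                    for i in range(len(track_ids)) for j in range(len(pts))
                    if d[i, j] <= max_disp]
            cand.sort()
            used_tracks: set[int] = set()
            used_dets: set[int] = set()
            matched_tracks = {}
            for dist, tid, j in cand:
                if tid in used_tracks or j in used_dets:
                    continue
                used_tracks.add(tid)
                used_dets.add(j)
                matched_tracks[tid] = j
            # close tracks that found no continuation
            for tid in list(open_tracks):
                if tid not in matched_tracks:
                    closed.append(open_tracks.pop(tid))
        for tid, j in matched_tracks.items():
            open_tracks[tid].append((int(frame), pts[j]))
        taken = set(matched_tracks.values())
        for j in range(len(pts)):
            if j not in taken:
                open_tracks[next_id] = [(int(frame), pts[j])]
                next_id += 1
        prev_frame = frame

    closed.extend(open_tracks.values())
    out = []
    for pid, samples in enumerate(sorted(closed, key=lambda s: (s[0][0], s[0][1][0]))):
        if len(samples) < min_len:
            continue
        frames = np.array([s[0] for s in samples], dtype=float)
        xy = np.array([s[1] for s in samples])
        out.append(Trajectory(pid, frames * dt_frame, xy))
    return out


# ---------------------------------------------------------------------------
# MSD

def compute_msd(trajectories: list[Trajectory], k_max: int = 10,
                dt_frame: float | None = None) -> MSDCurve:
    """Ensemble MSD curve over the lag grid k·dt_frame, k = 1..k_max.

    Each trajectory contributes its time-averaged squared displacement over
    all overlapping index pairs at lag k; the cell-level value is the
    unweighted mean across trajectories that reach that lag.  Lags with no
    observations are omitted.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    if max(len(tr) for tr in trajectories) < 2:
        raise ValueError("need at least one trajectory of length >= 2")
    if dt_frame is None:
        dt_frame = _infer_dt(trajectories[0].t)

    sums = np.zeros(k_max)
    traj_counts = np.zeros(k_max, dtype=int)
    pair_counts = np.zeros(k_max, dtype=int)
    for tr in trajectories:
        n = len(tr)
        for k in range(1, min(k_max, n - 1) + 1):
            disp = tr.xy[k:] - tr.xy[:-k]
            sq = np.einsum("ij,ij->i", disp, disp)
            sums[k - 1] += sq.mean()
            traj_counts[k - 1] += 1
            pair_counts[k - 1] += sq.size
    keep = traj_counts > 0
    if not np.all(keep):
        logger.info("omitting %d lag(s) with no observations", int((~keep).sum()))
    ks = np.arange(1, k_max + 1)[keep]
    return MSDCurve(lags=ks * dt_frame, msd=sums[keep] / traj_counts[keep],
                    n_obs=pair_counts[keep], n_trajectories=len(trajectories))


def msd_brute_force(trajectory: Trajectory, k_max: int = 10) -> np.ndarray:
    """Reference time-averaged MSD by an explicit double loop (oracle)."""
    n = len(trajectory)
    out = np.full(k_max, np.nan)
    for k in range(1, k_max + 1):
        acc, cnt = 0.0, 0
        for i in range(n):
            j = i + k
            if j < n:
                acc += float(np.sum((trajectory.xy[j] - trajectory.xy[i]) ** 2))
                cnt += 1
        if cnt:
            out[k - 1] = acc / cnt
    return out


# ---------------------------------------------------------------------------
# power-law fit

def _loglog_estimate(lags: np.ndarray, msd: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(np.log(lags), np.log(msd), 1)
    return float(np.exp(intercept)), float(slope)


def fit_power_law(curve: MSDCurve, n_dims: int = 2) -> DiffusionFit:
    """Fit MSD(Δt) = A·Δt^α by nonlinear least squares; K_α = A/(2 n_dims).

    The fit is initialized from a log-log linear regression and unweighted
    over lags.  If the nonlinear stage fails, the log-log estimate is
    returned with ``fallback=True``.
    """
    pos = curve.msd > 0
    lags, msd = curve.lags[pos], curve.msd[pos]
    if lags.size < 3:
        raise ValueError("need at least 3 lags with positive MSD")
    a0, alpha0 = _loglog_estimate(lags, msd)

    def model(t, amp, alpha):
        return amp * t ** alpha

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, lags, msd, p0=[a0, alpha0], maxfev=5000)
        amp, alpha = popt
        if amp <= 0 or not np.all(np.isfinite(popt)):
            raise RuntimeError("degenerate fit")
        perr = np.sqrt(np.diag(pcov))
        resid = msd - model(lags, *popt)
        return DiffusionFit(
            k_alpha=float(amp / (2 * n_dims)), alpha=float(alpha), n_dims=n_dims,
            k_alpha_stderr=float(perr[0] / (2 * n_dims)),
            alpha_stderr=float(perr[1]),
            residual_norm=float(np.linalg.norm(resid)),
            n_trajectories=curve.n_trajectories)
    except (RuntimeError, ValueError):
        logger.warning("power-law fit did not converge; using log-log estimate")
        resid = msd - a0 * lags ** alpha0
        return DiffusionFit(
            k_alpha=float(a0 / (2 * n_dims)), alpha=float(alpha0), n_dims=n_dims,
            residual_norm=float(np.linalg.norm(resid)),
            n_trajectories=curve.n_trajectories, fallback=True)
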