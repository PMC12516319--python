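"""Single-cell track statistics: speed, confinement, directional change,
and MSD with diffusion coefficient and exponent.

Tracks are 3-D positions in µm sampled at a (nominally uniform) interval in
minutes. Only tracks of 10-25 time points are retained by default, the
range used for manually curated light-sheet tracks. The MSD is the
time-averaged, all-pairs estimate MSD(τ) = <|r(t+τ) - r(t)|²>_t; fitting
log MSD = log(2·dims·D) + α·log τ over short lags yields the diffusion
coefficient D (µm²/min) and anomalous exponent α (1 = Brownian,
2 = ballistic, < 1 = confined).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import TrackTable


@dataclass(eq=False)
class CellTrack:
    """One cell's time-stamped 3-D trajectory (t in min, xyz in µm)."""

    track_id: int | str
    t_min: np.ndarray
    xyz: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (self.t_min.size, 3):
            raise ValueError("xyz must be (n, 3) matching t_min")
        if self.t_min.size < 2:
            raise ValueError("a track needs at least 2 points")
        dt = np.diff(self.t_min)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.max(np.abs(dt - dt.mean())) > 0.01 * dt.mean():
            self.flags.append("non-uniform sampling interval (> 1%)")

    @property
    def n_points(self) -> int:
        return self.t_min.size

    @property
    def duration_min(self) -> float:
        return float(self.t_min[-1] - self.t_min[0])

    @property
    def dt_min(self) -> float:
        return float(np.mean(np.diff(self.t_min)))


@dataclass
class TrackStats:
    """Motility statistics of one track (or of the track ensemble)."""

    track_id: int | str | None
    n_points: int
    duration_min: float
    mean_speed_um_per_min: float
    confinement_ratio: float
    directional_change_rate_rad_per_min: float
    D_um2_per_min: float
    alpha: float
    msd_lags_min: np.ndarray | None = None
    msd_um2: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def iter_tracks(table: TrackTable) -> list[CellTrack]:
    """Materialize CellTrack objects from a loaded TrackTable."""
    out = []
    for tid, grp in table.df.groupby("track_id", sort=True):
        out.append(
            CellTrack(
                track_id=tid,
                t_min=grp["t_min"].to_numpy(),
                xyz=grp[["x_um", "y_um", "z_um"]].to_numpy(),
            )
        )
    return out


def filter_tracks(
    tracks: list[CellTrack], min_points: int = 10, max_points: int = 25
) -> tuple[list[CellTrack], int]:
    """Keep tracks with min_points <= n <= max_points (inclusive bounds).

    Returns (kept tracks, number dropped).
    """
    kept = [tr for tr in tracks if min_points <= tr.n_points <= max_points]
    return kept, len(tracks) - len(kept)


def mean_speed(track: CellTrack) -> float:
    """Total 3-D path length divided by track duration (µm/min)."""
    if track.duration_min <= 0:
        raise ValueError("zero track duration")
    steps = np.linalg.norm(np.diff(track.xyz, axis=0), axis=1)
    return float(steps.sum() / track.duration_min)


def confinement_ratio(track: CellTrack) -> float:
    """Net displacement over total path length, in [0, 1]."""
    steps = np.linalg.norm(np.diff(track.xyz, axis=0), axis=1)
    path = steps.sum()
    if path <= 0:
        raise ValueError("zero path length")
    net = float(np.linalg.norm(track.xyz[-1] - track.xyz[0]))
    return net / float(path)


def directional_change_rate(track: CellTrack) -> float:
    """Mean unsigned turning angle between consecutive steps per minute.

    Zero-length steps make the angle undefined; those vertices are skipped
    and flagged on the track.
    """
    if track.n_points < 3:
        raise ValueError("directional change needs at least 3 points")
    steps = np.diff(track.xyz, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    angles = []
    skipped = 0
    for i in range(len(steps) - 1):
        if norms[i] == 0 or norms[i + 1] == 0:
            skipped += 1
            continue
        cosang = np.dot(steps[i], steps[i + 1]) / (norms[i] * norms[i + 1])
        angles.append(math.acos(float(np.clip(cosang, -1.0, 1.0))))
    if skipped:
        track.flags.append(f"{skipped} zero-length step(s) skipped in turning angles")
    if not angles:
        raise ValueError("no defined turning angles (all steps zero-length)")
    return float(np.mean(angles) / track.dt_min)


def msd(track: CellTrack, dims: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged all-pairs MSD: lags in minutes, MSD in µm².

    MSD(k·dt) averages |r(i+k) - r(i)|² over every ordered pair at lag k.
    ``dims=2`` projects onto xy before squaring displacements.
    """
    pos = track.xyz[:, :dims]
    n = track.n_points
    lags = np.arange(1, n) * track.dt_min
    out = np.empty(n - 1)
    for k in range(1, n):
        d = pos[k:] - pos[:-k]
        out[k - 1] = np.mean(np.sum(d * d, axis=1))
    return lags, out


def fit_msd(
    lags_min: np.ndarray,
    msd_um2: np.ndarray,
    *,
    dims: int = 3,
    max_lag_min: float | None = None,
) -> tuple[float, float]:
    """Least-squares power-law fit log MSD = log(2·dims·D) + α·log τ.

    Only lags <= max_lag_min with strictly positive MSD enter the fit;
    fewer than 3 usable lags raise ValueError.
    """
    lags_min = np.asarray(lags_min, dtype=float)
    msd_um2 = np.asarray(msd_um2, dtype=float)
    use = msd_um2 > 0
    if max_lag_min is not None:
        use &= lags_min <= max_lag_min
    if use.sum() < 3:
        raise ValueError("fewer than 3 usable lags for the MSD fit")
    alpha, intercept = np.polyfit(np.log(lags_min[use]), np.log(msd_um2[use]), 1)
    D = math.exp(intercept) / (2.0 * dims)
    return float(D), float(alpha)


def track_stats(
    track: CellTrack, *, dims: int = 3, max_lag_fraction: float = 0.25
) -> TrackStats:
    """All motility statistics of one track; degenerate fits are flagged."""
    lags, curve = msd(track, dims=dims)
    flags = list(track.flags)
    try:
        D, alpha = fit_msd(
            lags, curve, dims=dims, max_lag_min=max_lag_fraction * track.duration_min
        )
    except ValueError:
        D, alpha = math.nan, math.nan
        flags.append("degenerate MSD fit")
    try:
        conf = confinement_ratio(track)
    except ValueError:
        conf = math.nan
        flags.append("zero path length: confinement undefined")
    try:
        turn = directional_change_rate(track) if track.n_points >= 3 else math.nan
    except ValueError:
        turn = math.nan
        flags.append("turning angles undefined")
    return TrackStats(
        track_id=track.track_id,
        n_points=track.n_points,
        duration_min=track.duration_min,
        mean_speed_um_per_min=mean_speed(track),
        confinement_ratio=conf,
        directional_change_rate_rad_per_min=turn,
        D_um2_per_min=D,
        alpha=alpha,
        msd_lags_min=lags,
        msd_um2=curve,
        flags=flags,
    )


def msd_fit(
    tracks: list[CellTrack], *, max_lag_fraction: float = 0.25, dims: int = 3
) -> tuple[list[TrackStats], TrackStats]:
    """Per-track statistics plus the ensemble MSD and its fit.

    The ensemble MSD is the mean of the per-track curves at the lags every
    track shares; the ensemble D and α come from fitting that curve over
    lags up to ``max_lag_fraction`` of the shortest track duration.
    """
    if not tracks:
        raise ValueError("no tracks")
    per_track = [track_stats(tr, dims=dims, max_lag_fraction=max_lag_fraction) for tr in tracks]
    dts = {round(tr.dt_min, 9) for tr in tracks}
    if len(dts) > 1:
        warnings.warn("tracks have differing sampling intervals; ensemble lags are nominal")
    n_common = min(tr.n_points for tr in tracks) - 1
    lags = np.arange(1, n_common + 1) * tracks[0].dt_min
    stack = np.vstack([ts.msd_um2[:n_common] for ts in per_track])
    ensemble_curve = stack.mean(axis=0)
    min_duration = min(tr.duration_min for tr in tracks)
    flags: list[str] = []
    try:
        D, alpha = fit_msd(
            lags, ensemble_curve, dims=dims, max_lag_min=max_lag_fraction * min_duration
        )
    except ValueError:
        D, alpha = math.nan, math.nan
        flags.append("degenerate ensemble MSD fit")
    ensemble = TrackStats(
        track_id=None,
        n_points=int(np.mean([tr.n_points for tr in tracks])),
        duration_min=min_duration,
        mean_speed_um_per_min=float(np.mean([ts.mean_speed_um_per_min for ts in per_track])),
        confinement_ratio=float(np.mean([ts.confinement_ratio for ts in per_track])),
        directional_change_rate_rad_per_min=float(
            np.nanmean([ts.directional_change_rate_rad_per_min for ts in per_track])
        ),
        D_um2_per_min=D,
        alpha=alpha,
        msd_lags_min=lags,
        msd_um2=ensemble_curve,
        flags=flags,
    )
    return per_track, ensemble
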