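"""Image and track I/O plus the delimited-record output contract.

All quantities are converted to physical units (µm, minutes) at load time;
downstream modules never see pixels or frame indices. Calibration is always
caller-supplied: TIFF tags are not trusted for pixel sizes, since the study
data these routines emulate come from several different microscopes.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

#: canonical axis order of ImageStack.data
AXES = "tzcyx"

TRACKMATE_COLUMNS = (
    "TRACK_ID",
    "POSITION_T",
    "POSITION_X",
    "POSITION_Y",
    "POSITION_Z",
)


@dataclass
class ImageStack:
    """A calibrated image stack with axes normalized to (t, z, c, y, x).

    Missing axes are kept as singletons so every consumer can index the
    same five-dimensional layout.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float | None = None
    frame_interval_min: float | None = None
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError("ImageStack.data must be 5-D (t, z, c, y, x)")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.data.shape[1] > 1 and (self.z_step_um is None or not self.z_step_um > 0):
            raise ValueError("z_step_um must be positive for a z-stack")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[2]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def plane(self, t: int = 0, z: int = 0, c: int = 0) -> np.ndarray:
        """One (y, x) plane."""
        return self.data[t, z, c]

    def channel_index(self, name: str) -> int:
        if self.channel_names is None:
            raise ValueError("stack has no channel names")
        return self.channel_names.index(name)


def read_image(
    path: str | Path,
    axes: str = "",
    *,
    pixel_size_um: float,
    z_step_um: float | None = None,
    frame_interval_min: float | None = None,
    channel_names: list[str] | None = None,
    sizes: Mapping[str, int] | None = None,
) -> ImageStack:
    """Read a (multi-page) TIFF into a calibrated ImageStack.

    Parameters
    ----------
    axes:
        Page-dimension order, a subset of "tzc" from slowest to fastest
        (e.g. "z" for a plain z-stack, "tz" for a timelapse of z-stacks).
        Commas/spaces are ignored. Empty means a single page.
    sizes:
        Sizes of the declared page axes; at most one may be omitted and is
        then inferred from the page count. Inconsistent declarations (page
        count not divisible) raise ValueError.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim != 3:
        raise ValueError(f"expected single- or multi-page 2D TIFF, got shape {arr.shape}")
    axes = axes.replace(",", "").replace(" ", "").lower()
    if any(a not in "tzc" for a in axes) or len(set(axes)) != len(axes):
        raise ValueError(f"invalid axis spec {axes!r}: must be unique letters from 'tzc'")
    n_pages = arr.shape[0]
    sizes = dict(sizes or {})
    unknown = [a for a in axes if a not in sizes]
    if len(unknown) > 1:
        raise ValueError("at most one page axis may have an unspecified size")
    known = int(np.prod([sizes[a] for a in axes if a in sizes])) if axes else 1
    if n_pages % max(known, 1):
        raise ValueError(
            f"{n_pages} pages not divisible by declared axis sizes {sizes}"
        )
    if unknown:
        sizes[unknown[0]] = n_pages // known
    declared = int(np.prod([sizes[a] for a in axes])) if axes else 1
    if declared != n_pages:
        raise ValueError(
            f"axis spec {axes!r} with sizes {sizes} implies {declared} pages, file has {n_pages}"
        )
    shaped = arr.reshape(tuple(sizes[a] for a in axes) + arr.shape[1:])
    present = list(axes)
    if present:
        # put present page axes into canonical t, z, c relative order ...
        order = np.argsort(["tzc".index(a) for a in present], kind="stable")
        shaped = np.transpose(shaped, tuple(order) + (len(present), len(present) + 1))
    # ... then insert singleton axes for the absent ones
    for pos, a in enumerate("tzc"):
        if a not in present:
            shaped = np.expand_dims(shaped, pos)
    data = shaped.astype(np.float64, copy=False)
    return ImageStack(
        data=data,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        frame_interval_min=frame_interval_min,
        channel_names=channel_names,
    )


def write_image(path: str | Path, data: np.ndarray) -> None:
    """Write an array to TIFF (bool masks are stored as uint8)."""
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)


@dataclass
class TrackTable:
    """Calibrated single-cell tracks: one row per (track, time point).

    Columns: track_id, t_min, x_um, y_um, z_um — sorted by time within
    track, with strictly increasing timestamps and ≥ 2 points per track.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["track_id", "t_min", "x_um", "y_um", "z_um"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"TrackTable missing columns: {missing}")

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.df["track_id"]))


def read_tracks(
    path: str | Path,
    dialect: str = "trackmate-csv",
    *,
    spatial_scale_um: float = 1.0,
    time_scale_min: float = 1.0,
) -> TrackTable:
    """Load a delimited track export into physical units.

    The "trackmate-csv" dialect expects columns TRACK_ID, POSITION_T,
    POSITION_X/Y/Z. Extra non-numeric header rows (as written by TrackMate
    spot exports) are skipped. Positions are multiplied by
    ``spatial_scale_um`` and times by ``time_scale_min``; pass 1.0 when the
    file is already calibrated in µm / minutes.
    """
    if dialect != "trackmate-csv":
        raise ValueError(f"unknown track dialect {dialect!r}")
    raw = pd.read_csv(path)
    missing = [c for c in TRACKMATE_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"track file missing required column(s): {missing}")
    numeric = raw[list(TRACKMATE_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    # TrackMate exports carry up to three repeated/unit header rows
    header_rows = numeric[list(TRACKMATE_COLUMNS)[1:]].isna().all(axis=1)
    numeric = numeric[~header_rows]
    if numeric.isna().any().any():
        raise ValueError("non-numeric values in required track columns")
    df = pd.DataFrame(
        {
            "track_id": numeric["TRACK_ID"].astype(int),
            "t_min": numeric["POSITION_T"] * time_scale_min,
            "x_um": numeric["POSITION_X"] * spatial_scale_um,
            "y_um": numeric["POSITION_Y"] * spatial_scale_um,
            "z_um": numeric["POSITION_Z"] * spatial_scale_um,
        }
    )
    df = df.sort_values(["track_id", "t_min"], kind="mergesort").reset_index(drop=True)
    for tid, grp in df.groupby("track_id"):
        dt = np.diff(grp["t_min"].to_numpy())
        if np.any(dt <= 0):
            raise ValueError(f"track {tid}: duplicate or non-increasing timestamps")
    sizes = df.groupby("track_id").size()
    singletons = sizes[sizes < 2].index
    if len(singletons):
        warnings.warn(f"dropping {len(singletons)} track(s) with < 2 points")
        df = df[~df["track_id"].isin(singletons)].reset_index(drop=True)
    return TrackTable(df)


def _record_to_dict(record) -> dict:
    if isinstance(record, Mapping):
        d = dict(record)
    elif dataclasses.is_dataclass(record):
        d = dataclasses.asdict(record)
    else:
        raise TypeError(f"cannot serialize record of type {type(record)!r}")
    out = {}
    for k, v in d.items():
        if isinstance(v, (str, bool, int, float, np.integer, np.floating)) or v is None:
            out[k] = v
    return out


def write_records(
    records: Sequence | pd.DataFrame,
    path: str | Path,
    *,
    units: Mapping[str, str] | None = None,
    meta: Mapping[str, str] | None = None,
) -> None:
    """Write records as comma-separated text with '#'-prefixed comments.

    Scalars only; array-valued fields of dataclass records are dropped.
    Floats round-trip through read_records to better than 1e-9 relative.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([_record_to_dict(r) for r in records])
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        if df.empty and not len(df.columns):
            fh.write("\n")
        else:
            df.to_csv(fh, index=False, float_format="%.17g")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read back a write_records file (comments skipped)."""
    return pd.read_csv(path, comment="#")
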