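"""Data containers and file readers/writers.

Unit conventions: SMLM localizations and AFM maps are held in nanometres;
trajectories are held in micrometres and seconds. Readers convert at the
boundary according to the declared units of the file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
import shapely
import tifffile

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular schema."""


class ParameterError(ValueError):
    """Raised when a parameter is outside its documented domain."""


# Header-name registry for localization tables: canonical field -> accepted
# column names (case-insensitive). Tolerates common exporter variants.
_LOC_HEADER_REGISTRY: dict[str, tuple[str, ...]] = {
    "x": ("x", "x_nm", "x [nm]", "x[nm]", "xw", "position_x"),
    "y": ("y", "y_nm", "y [nm]", "y[nm]", "yw", "position_y"),
    "z": ("z", "z_nm", "z [nm]", "z[nm]"),
    "precision": (
        "precision", "precision_nm", "uncertainty", "uncertainty_nm",
        "uncertainty [nm]", "uncertainty[nm]", "uncertainty_xy [nm]",
        "loc_precision",
    ),
    "frame": ("frame", "frame_id", "t_frame"),
    "channel": ("channel", "ch", "channel_id"),
}


@dataclass
class LocalizationTable:
    """One SMLM channel's point set with per-point localization precision.

    Coordinates and precisions are in nanometres. ``roi``, when present, is a
    closed polygon in nm; :meth:`points_in_roi` uses the even-odd rule with
    boundary points counted inside.
    """

    xy: np.ndarray                      # (n, 2) nm
    precision: np.ndarray               # (n,) nm, > 0
    z: np.ndarray | None = None         # (n,) nm
    frame: np.ndarray | None = None     # (n,) int
    channel: int = 0
    roi: Polygon | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.precision = np.asarray(self.precision, dtype=float).ravel()
        if self.precision.size != len(self.xy):
            raise ParameterError("precision length must match point count")
        if not np.all(np.isfinite(self.xy)):
            raise ParameterError("coordinates must be finite")
        if self.precision.size and not np.all(self.precision > 0):
            raise ParameterError("localization precision must be > 0")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float).ravel()
        if self.frame is not None:
            self.frame = np.asarray(self.frame).ravel().astype(int)

    def __len__(self) -> int:
        return len(self.xy)

    def points_in_roi(self) -> np.ndarray:
        """Boolean mask of points inside ``roi`` (boundary counts as inside)."""
        if self.roi is None:
            return np.ones(len(self), dtype=bool)
        inside = shapely.contains_xy(self.roi, self.xy[:, 0], self.xy[:, 1])
        on_edge = shapely.intersects_xy(
            self.roi.exterior, self.xy[:, 0], self.xy[:, 1]
        )
        return inside | on_edge

    def subset(self, mask: np.ndarray) -> "LocalizationTable":
        return LocalizationTable(
            xy=self.xy[mask],
            precision=self.precision[mask],
            z=None if self.z is None else self.z[mask],
            frame=None if self.frame is None else self.frame[mask],
            channel=self.channel,
            roi=self.roi,
        )


@dataclass
class TrackSet:
    """3D+t trajectories with a common frame interval ``dt`` (seconds).

    Each track is an (n_i, 4) array of columns (t, x, y, z) with time strictly
    increasing at uniform spacing ``dt``; coordinates in micrometres.
    """

    tracks: list[np.ndarray]
    dt: float
    track_ids: list[int] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if not self.track_ids:
            self.track_ids = list(range(len(self.tracks)))
        for tr in self.tracks:
            if tr.ndim != 2 or tr.shape[1] != 4:
                raise ParameterError("each track must be an (n, 4) array of (t, x, y, z)")
            if not np.all(np.isfinite(tr)):
                raise ParameterError("track coordinates must be finite")
            dts = np.diff(tr[:, 0])
            if len(dts) and (np.any(dts <= 0) or not np.allclose(dts, self.dt, rtol=1e-6, atol=1e-9)):
                raise ParameterError("track times must increase uniformly by dt")

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class HeightMap:
    """AFM topograph: a rectangular grid of heights (nm) at ``pixel_size`` nm/px."""

    heights: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ParameterError("heights must be a 2D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ParameterError("heights must be finite")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")


def _resolve_columns(
    columns: Iterable[str], dialect: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical localization fields to actual file columns.

    An explicit ``dialect`` entry wins; otherwise the header registry is
    searched case-insensitively. Unknown file columns are ignored.
    """
    lower = {c.lower().strip(): c for c in columns}
    resolved: dict[str, str] = {}
    for canon, aliases in _LOC_HEADER_REGISTRY.items():
        if dialect and canon in dialect:
            if dialect[canon] in lower.values() or dialect[canon] in lower:
                resolved[canon] = lower.get(dialect[canon].lower(), dialect[canon])
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def read_localizations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    units: str = "nm",
    channel: int = 0,
    roi: Polygon | None = None,
) -> LocalizationTable:
    """Read a localization table from CSV/TSV.

    Parameters
    ----------
    path
        Delimited text file with a header row; delimiter is sniffed.
    dialect
        Optional explicit mapping from canonical field names
        (``x, y, z, precision, frame, channel``) to file column names;
        unmapped fields fall back to the built-in header registry.
    units
        ``"nm"`` (default) or ``"um"``; µm coordinates/precisions are
        converted to nm.

    Raises
    ------
    FormatError
        If a mandatory column (x, y, precision) is missing, naming the
        column, or a cell fails to parse, naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = _resolve_columns(df.columns, dialect)
    for required in ("x", "y", "precision"):
        if required not in cols:
            raise FormatError(
                f"{path.name}: missing mandatory column for '{required}'"
            )
    if units not in ("nm", "um"):
        raise ParameterError("units must be 'nm' or 'um'")
    scale = 1.0 if units == "nm" else 1000.0

    def _numeric(name: str) -> np.ndarray:
        series = pd.to_numeric(df[cols[name]], errors="coerce")
        bad = series.index[series.isna() & df[cols[name]].notna()]
        if len(bad):
            raise FormatError(
                f"{path.name}: non-numeric value in column '{cols[name]}' "
                f"at row(s) {list(bad[:5])}"
            )
        if series.isna().any():
            raise FormatError(
                f"{path.name}: empty cell in column '{cols[name]}' at row(s) "
                f"{list(series.index[series.isna()][:5])}"
            )
        return series.to_numpy(dtype=float)

    xy = np.column_stack([_numeric("x"), _numeric("y")]) * scale
    precision = _numeric("precision") * scale
    z = _numeric("z") * scale if "z" in cols else None
    frame = _numeric("frame").astype(int) if "frame" in cols else None
    return LocalizationTable(
        xy=xy, precision=precision, z=z, frame=frame, channel=channel, roi=roi
    )


def read_tracks(
    path: str | Path,
    dt: float | None = None,
    min_length: int = 10,
) -> TrackSet:
    """Read 3D trajectories from CSV/TSV into a :class:`TrackSet`.

    Expects columns ``track_id``, ``x``, ``y``, ``z`` and either ``t``
    (seconds) or ``frame`` plus an explicit ``dt``. Tracks are grouped by id
    and sorted by time; tracks shorter than ``min_length`` are dropped and
    counted in ``TrackSet.n_dropped``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("%s: empty track file", path.name)
        return TrackSet(tracks=[], dt=dt or 1.0)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty track file", path.name)
        return TrackSet(tracks=[], dt=dt or 1.0)
    cols = {c.lower().strip(): c for c in df.columns}
    for required in ("track_id", "x", "y", "z"):
        if required not in cols:
            raise FormatError(f"{path.name}: missing column '{required}'")
    if "t" in cols:
        t = df[cols["t"]].to_numpy(dtype=float)
        if dt is None:
            all_dt = np.concatenate(
                [np.diff(np.sort(g[cols["t"]].to_numpy(dtype=float)))
                 for _, g in df.groupby(cols["track_id"]) if len(g) > 1]
            )
            if not len(all_dt):
                raise FormatError(f"{path.name}: cannot infer dt from single-point tracks")
            dt = float(np.median(all_dt))
    elif "frame" in cols:
        if dt is None:
            raise FormatError(f"{path.name}: frame column requires an explicit dt")
        t = df[cols["frame"]].to_numpy(dtype=float) * dt
    else:
        raise FormatError(f"{path.name}: needs a 't' or 'frame' column")
    df = df.assign(_t=t)

    tracks: list[np.ndarray] = []
    ids: list[int] = []
    n_dropped = 0
    for tid, g in df.groupby(cols["track_id"], sort=True):
        g = g.sort_values("_t")
        tt = g["_t"].to_numpy(dtype=float)
        if len(np.unique(tt)) != len(tt):
            raise FormatError(f"{path.name}: duplicate (track_id, t) in track {tid}")
        dts = np.diff(tt)
        if len(dts) and not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
            raise FormatError(f"{path.name}: non-uniform dt within track {tid}")
        if len(g) < min_length:
            n_dropped += 1
            continue
        arr = np.column_stack([
            tt,
            g[cols["x"]].to_numpy(dtype=float),
            g[cols["y"]].to_numpy(dtype=float),
            g[cols["z"]].to_numpy(dtype=float),
        ])
        tracks.append(arr)
        ids.append(int(tid))
    if n_dropped:
        logger.info("%s: dropped %d track(s) shorter than %d frames",
                    path.name, n_dropped, min_length)
    return TrackSet(tracks=tracks, dt=float(dt), track_ids=ids, n_dropped=n_dropped)


def read_height_map(path: str | Path, pixel_size: float) -> HeightMap:
    """Read an AFM height map (nm) from a plain-text matrix or TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = tifffile.imread(path).astype(float)
    else:
        heights = np.loadtxt(path)
    return HeightMap(heights=heights, pixel_size=pixel_size)


def write_height_map(hmap: HeightMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, hmap.heights.astype(np.float32))
    else:
        np.savetxt(path, hmap.heights)


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a localization table as CSV with registry-canonical headers."""
    data = {"x_nm": table.xy[:, 0], "y_nm": table.xy[:, 1],
            "precision_nm": table.precision}
    if table.z is not None:
        data["z_nm"] = table.z
    if table.frame is not None:
        data["frame"] = table.frame
    data["channel"] = np.full(len(table), table.channel, dtype=int)
    pd.DataFrame(data).to_csv(path, index=False)


def write_tracks(ts: TrackSet, path: str | Path) -> None:
    rows = []
    for tid, tr in zip(ts.track_ids, ts.tracks):
        for t, x, y, z in tr:
            rows.append((tid, t, x, y, z))
    pd.DataFrame(rows, columns=["track_id", "t", "x", "y", "z"]).to_csv(
        path, index=False
    )


def write_report(
    results: Sequence[Mapping] | Mapping,
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write analysis output as flat records.

    CSV columns follow the key order of the first record (deterministic);
    floats are written at full precision. JSON round-trips bit-for-bit.
    """
    path = Path(path)
    if isinstance(results, Mapping):
        results = [results]
    results = list(results)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=1, default=_json_default)
    elif format == "csv":
        if not results:
            path.write_text("")
            return
        columns = list(results[0].keys())
        df = pd.DataFrame(results, columns=columns)
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ParameterError(f"unknown report format: {format!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
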