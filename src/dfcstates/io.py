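"""On-disk formats: plain TSV and JSON throughout.

The package's boundary is extracted ROI time series, so no imaging formats
are read or written.  All indices on disk are 0-based; edge vectors follow
the row-major strict-upper-triangle order declared in :mod:`dfcstates.dfc`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dfc import RoiTimeSeries, WindowedFc
from .metrics import Parcellation
from .qc import MotionTrace

__all__ = [
    "read_time_series",
    "write_time_series",
    "read_motion_trace",
    "read_parcellation",
    "write_parcellation",
    "read_manifest",
    "write_windowed_fc",
    "read_windowed_fc",
    "config_hash",
    "write_json",
]

GROUPS = ("NC", "SCD", "AD")


def read_time_series(
    path: str | Path,
    tr_seconds: float = 2.0,
    parcellation: Parcellation | None = None,
) -> RoiTimeSeries:
    """Read a T x R time-series TSV (header row of ROI ids, numeric body).

    Values are parsed with round-trip float precision so write-then-read
    reproduces a matrix bit-exactly.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(
            f"{path.name}: connectivity needs at least 2 ROI columns, "
            f"found {df.shape[1]}"
        )
    bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise ValueError(f"{path.name}: non-numeric column(s) {bad}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df[df[col].isna()].index[0])
        raise ValueError(f"{path.name}: missing value at row {row}, column {col!r}")
    roi_ids = list(df.columns)
    if parcellation is not None and roi_ids != parcellation.roi_ids:
        raise ValueError(
            f"{path.name}: ROI header does not match the parcellation"
        )
    return RoiTimeSeries(
        subject_id=path.stem,
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        roi_ids=roi_ids,
    )


def write_time_series(ts: RoiTimeSeries, path: str | Path) -> None:
    roi_ids = ts.roi_ids or [f"roi_{i:03d}" for i in range(ts.n_rois)]
    pd.DataFrame(ts.data, columns=roi_ids).to_csv(path, sep="\t", index=False)


def read_motion_trace(path: str | Path, sphere_radius: float = 50.0) -> MotionTrace:
    """Read a 6-column realignment-parameter TSV (3 trans mm, 3 rot rad)."""
    arr = np.loadtxt(path, ndmin=2)
    return MotionTrace(params=arr, sphere_radius=sphere_radius)


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation TSV with columns roi_id, network[, x, y, z]."""
    df = pd.read_csv(path, sep="\t")
    for col in ("roi_id", "network"):
        if col not in df.columns:
            raise ValueError(f"parcellation file lacks a {col!r} column")
    coords = None
    if {"x", "y", "z"} <= set(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    return Parcellation(
        roi_ids=df["roi_id"].astype(str).tolist(),
        networks=df["network"].astype(str).tolist(),
        coordinates=coords,
    )


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    df = pd.DataFrame(
        {"roi_id": parcellation.roi_ids, "network": parcellation.networks}
    )
    if parcellation.coordinates is not None:
        df[["x", "y", "z"]] = parcellation.coordinates
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read the cohort manifest and validate ids, groups and completeness."""
    df = pd.read_csv(path, sep="\t")
    if "subject_id" not in df.columns or "group" not in df.columns:
        raise ValueError("manifest needs subject_id and group columns")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject id {dup!r} in manifest")
    unknown = set(df["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group label(s) {sorted(unknown)}")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
        if df[col].isna().any():
            raise ValueError(f"missing values in manifest column {col!r}")
    return df


def write_windowed_fc(fc: WindowedFc, path: str | Path) -> None:
    """Windowed-FC TSV: window_start column then one column per edge."""
    df = pd.DataFrame(fc.data, columns=[f"e{i}" for i in range(fc.n_edges)])
    df.insert(0, "window_start", fc.window_starts)
    df.to_csv(path, sep="\t", index=False)


def read_windowed_fc(path: str | Path, n_rois: int) -> WindowedFc:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    starts = df.pop("window_start").to_numpy(dtype=int)
    return WindowedFc(
        subject_id=Path(path).stem,
        data=df.to_numpy(dtype=float),
        window_starts=starts,
        n_rois=n_rois,
    )


def config_hash(config: dict) -> str:
    """Stable short hash identifying the configuration that produced a run."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
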