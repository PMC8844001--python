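"""Delimited-file adapters: one dialect everywhere.

Tab-separated values, ``NA`` as the missing token, and optional
provenance header lines starting with ``# `` (key: value) that every
pipeline output carries and every reader skips.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import RoiTimeSeries

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_roi_timeseries",
    "read_roi_timeseries",
    "write_motion",
    "read_motion",
    "write_centroids",
    "read_centroids",
]

NA_TOKEN = "NA"
MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_rad", "rot_y_rad", "rot_z_rad"]


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {key}: {value}\n" for key, value in provenance.items())


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.12g")


def read_tsv(path: str | Path, numeric_columns: list[str] | None = None) -> pd.DataFrame:
    """Read one of our TSVs, skipping provenance comments.

    Raises a parse error naming the offending row/column when a cell in
    a numeric column fails to parse.
    """
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN], keep_default_na=False)
    if numeric_columns:
        for col in numeric_columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as err:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                row = int(bad.index[0]) if len(bad) else -1
                raise ValueError(
                    f"{path}: non-numeric value in column '{col}' at data row {row}"
                ) from err
    return df


def write_roi_timeseries(ts: RoiTimeSeries, path: str | Path, provenance: dict | None = None) -> None:
    """ROI time series as TSV: header row of ROI names, T data rows."""
    meta = dict(provenance or {})
    meta.setdefault("tr_seconds", ts.tr_seconds)
    if ts.subject_id:
        meta.setdefault("subject_id", ts.subject_id)
    if ts.run_id:
        meta.setdefault("run_id", ts.run_id)
    write_tsv(pd.DataFrame(ts.values, columns=ts.roi_names), path, provenance=meta)


def _header_meta(path: Path) -> dict:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").rstrip("\n").partition(": ")
            meta[key] = value
    return meta


def read_roi_timeseries(path: str | Path, tr_seconds: float | None = None) -> RoiTimeSeries:
    path = Path(path)
    meta = _header_meta(path)
    df = read_tsv(path)
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: ROI time series contains missing or non-finite cells")
    return RoiTimeSeries(
        values=values,
        tr_seconds=tr_seconds if tr_seconds is not None else float(meta.get("tr_seconds", 2.0)),
        roi_names=list(df.columns),
        subject_id=meta.get("subject_id"),
        run_id=meta.get("run_id"),
    )


def write_motion(params: np.ndarray, path: str | Path, provenance: dict | None = None) -> None:
    write_tsv(pd.DataFrame(np.asarray(params), columns=MOTION_COLUMNS), path, provenance)


def read_motion(path: str | Path) -> np.ndarray:
    df = read_tsv(path, numeric_columns=MOTION_COLUMNS)
    return df[MOTION_COLUMNS].to_numpy(dtype=float)


def write_centroids(centroids: np.ndarray, path: str | Path, provenance: dict | None = None) -> None:
    """Centroid matrix as k rows x p coupling-value columns."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    cols = [f"c{j + 1}" for j in range(centroids.shape[1])]
    write_tsv(pd.DataFrame(centroids, columns=cols), path, provenance)


def read_centroids(path: str | Path) -> np.ndarray:
    return read_tsv(path).to_numpy(dtype=float)
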