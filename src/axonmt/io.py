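"""File I/O for every declared format.

Plain-text formats throughout: FDAP curves and manifests as CSV,
localization tables as CSV (with an optional HDF5 dialect), rendered volumes
as TIFF stacks with a JSON metadata sidecar, detection/track tables as CSV,
phosphosite tables and term maps as TSV, and filament polylines as JSON.
Readers validate field presence and types and report malformed rows with
their line number and column; write/read round-trips preserve fields and
ordering.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .fdap import FDAPCurve
from .filaments import Filament
from .smlm import LocalizationTable, RenderedVolume
from .transport import DetectionTable, Track

__all__ = [
    "read_fdap_csv",
    "write_fdap_csv",
    "read_manifest",
    "read_localizations_csv",
    "write_localizations_csv",
    "read_localizations_hdf5",
    "write_localizations_hdf5",
    "read_volume_tiff",
    "write_volume_tiff",
    "read_detections_csv",
    "write_detections_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_term_map_tsv",
    "read_gene_list",
    "read_polylines_json",
    "write_polylines_json",
]

LOC_COLUMNS = ("frame", "x_nm", "y_nm", "z_nm", "photons", "precision_xy_nm", "precision_z_nm")
SITE_COLUMNS = ("gene", "residue", "position", "log2_fold_change", "p_value", "condition")


def _validated_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    """Coerce columns to numeric, naming the first malformed row and column."""
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: malformed value {df[col].iloc[row]!r} in column {col!r} at line {row + 2}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(f"{path}: missing value in column {col!r} at line {row + 2}")
        df[col] = coerced
    return df


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


# --- FDAP curves -----------------------------------------------------------


def read_fdap_csv(path, window_length_um: float = 6.0, frame_interval_s: float = 1.0) -> FDAPCurve:
    """Read a two-column ``time_s,intensity`` curve file (one cell)."""
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "intensity"), path)
    df = _validated_numeric(df, ("time_s", "intensity"), path)
    return FDAPCurve(
        df["time_s"].to_numpy(),
        df["intensity"].to_numpy(),
        window_length_um=window_length_um,
        frame_interval_s=frame_interval_s,
        meta={"path": str(path)},
    )


def write_fdap_csv(curve: FDAPCurve, path) -> None:
    pd.DataFrame({"time_s": curve.time_s, "intensity": curve.intensity}).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    """Batch manifest: ``file,condition,cell_id`` rows."""
    df = pd.read_csv(path)
    _require_columns(df, ("file", "condition", "cell_id"), path)
    return df


# --- localization tables ---------------------------------------------------


def read_localizations_csv(path) -> LocalizationTable:
    df = pd.read_csv(path)
    _require_columns(df, LOC_COLUMNS, path)
    df = _validated_numeric(df, LOC_COLUMNS, path)
    df["frame"] = df["frame"].astype(int)
    return LocalizationTable(df[list(LOC_COLUMNS)])


def write_localizations_csv(locs: LocalizationTable, path) -> None:
    locs.data.to_csv(path, index=False)


def read_localizations_hdf5(path, dataset: str = "locs") -> LocalizationTable:
    """HDF5 localization dialect: one dataset per column under a group."""
    with h5py.File(path, "r") as fh:
        group = fh[dataset]
        df = pd.DataFrame({col: np.asarray(group[col]) for col in LOC_COLUMNS})
    df["frame"] = df["frame"].astype(int)
    return LocalizationTable(df)


def write_localizations_hdf5(locs: LocalizationTable, path, dataset: str = "locs") -> None:
    with h5py.File(path, "w") as fh:
        group = fh.create_group(dataset)
        for col in LOC_COLUMNS:
            group.create_dataset(col, data=locs.data[col].to_numpy())


# --- rendered volumes ------------------------------------------------------


def write_volume_tiff(volume: RenderedVolume, path) -> None:
    """TIFF stack of z-planes plus a JSON sidecar with the voxel geometry."""
    path = Path(path)
    # axes (z, row=x, col=y) for plane-wise viewing
    tifffile.imwrite(
        path, np.moveaxis(volume.intensity, 2, 0).astype(np.float32), photometric="minisblack"
    )
    sidecar = {
        "voxel_size_nm": list(volume.voxel_size_nm),
        "origin_nm": list(volume.origin_nm),
        "n_out_of_bounds": volume.n_out_of_bounds,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_volume_tiff(path) -> RenderedVolume:
    path = Path(path)
    stack = np.moveaxis(tifffile.imread(path), 0, 2).astype(float)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return RenderedVolume(
        stack,
        voxel_size_nm=tuple(sidecar["voxel_size_nm"]),
        origin_nm=tuple(sidecar["origin_nm"]),
        n_out_of_bounds=int(sidecar.get("n_out_of_bounds", 0)),
    )


# --- detections and tracks -------------------------------------------------


def read_detections_csv(path, frame_rate_hz: float = 5.0) -> DetectionTable:
    df = pd.read_csv(path)
    _require_columns(df, ("frame", "x_nm", "y_nm", "intensity"), path)
    df = _validated_numeric(df, ("frame", "x_nm", "y_nm", "intensity"), path)
    df["frame"] = df["frame"].astype(int)
    return DetectionTable(df, frame_rate_hz=frame_rate_hz)


def write_detections_csv(dets: DetectionTable, path) -> None:
    dets.data.to_csv(path, index=False)


def write_tracks_csv(tracks: list[Track], path) -> None:
    """Long-format ``track_id,frame,x_nm,y_nm`` table."""
    rows = []
    for track in tracks:
        for frame, (x, y) in zip(track.frames, track.xy_nm):
            rows.append({"track_id": track.id, "frame": int(frame), "x_nm": x, "y_nm": y})
    pd.DataFrame(rows, columns=["track_id", "frame", "x_nm", "y_nm"]).to_csv(path, index=False)


def read_tracks_csv(path, frame_rate_hz: float = 5.0) -> list[Track]:
    df = pd.read_csv(path)
    _require_columns(df, ("track_id", "frame", "x_nm", "y_nm"), path)
    df = _validated_numeric(df, ("track_id", "frame", "x_nm", "y_nm"), path)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(
            Track(
                id=int(tid),
                frames=sub["frame"].to_numpy(dtype=int),
                xy_nm=sub[["x_nm", "y_nm"]].to_numpy(dtype=float),
                frame_rate_hz=frame_rate_hz,
            )
        )
    return tracks


# --- phosphosites ----------------------------------------------------------


def read_sites_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SITE_COLUMNS, path)
    df = _validated_numeric(df, ("position", "log2_fold_change", "p_value"), path)
    df["position"] = df["position"].astype(int)
    return df


def write_sites_tsv(df: pd.DataFrame, path) -> None:
    df[list(SITE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_term_map_tsv(path) -> dict[str, set]:
    """Term -> substrate gene sets from a two-column ``term<TAB>gene`` file."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ("term", "gene"), path)
    terms: dict[str, set] = {}
    for term, gene in zip(df["term"], df["gene"]):
        terms.setdefault(str(term), set()).add(str(gene))
    return terms


def read_gene_list(path) -> list[str]:
    text = Path(path).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


# --- filament polylines ----------------------------------------------------


def write_polylines_json(filaments: list[Filament], path) -> None:
    """JSON array of filament polylines in nm coordinates."""
    payload = [
        {
            "points_nm": f.points_nm.tolist(),
            "composite": bool(f.composite),
            "n_fragments": int(f.n_fragments),
        }
        for f in filaments
    ]
    Path(path).write_text(json.dumps(payload))


def read_polylines_json(path) -> list[Filament]:
    payload = json.loads(Path(path).read_text())
    return [
        Filament(
            points_nm=np.asarray(item["points_nm"], dtype=float),
            composite=bool(item["composite"]),
            n_fragments=int(item["n_fragments"]),
        )
        for item in payload
    ]
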