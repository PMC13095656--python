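"""File formats: MRC volumes (via gemmi), trace files, result tables.

Volumes are exchanged as CCP4/MRC mode-2 (float32) maps with the voxel
size in the header; arrays are canonical (z, y, x) in memory regardless
of the axis order recorded in the file.  Traces use a small CSV dialect
(``mt_id,x,y,z``; pixels; one point per row; header required); the ASCII
"point listing" dialect produced by IMOD's model tools (``object contour
x y z`` per line) is also accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .segments import FilamentTrace
from .stats import GroupComparison, GroupStats, SpacingMeasurement
from .volume import DensityVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_trace",
    "write_trace_csv",
    "read_trace_imod",
    "measurements_to_frame",
    "write_measurements",
    "read_measurements",
    "write_stats_json",
]


def read_volume(path: str | Path, voxel_size: float | None = None) -> DensityVolume:
    """Read an MRC/CCP4 map into canonical (z, y, x) order.

    The header's axis-order fields are honored (gemmi reorders on setup).
    A missing or zero header voxel size is an error unless ``voxel_size``
    overrides it.
    """
    m = gemmi.read_ccp4_map(str(path))
    m.setup(0.0)
    data = np.array(m.grid, copy=True)  # gemmi exposes (x, y, z)
    data = np.ascontiguousarray(data.transpose(2, 1, 0))
    spac = m.grid.spacing
    vx = float(np.mean(spac))
    if voxel_size is not None:
        vx = float(voxel_size)
    elif not vx > 1e-6:  # catches zero, negative and NaN
        raise ValueError(
            f"{path}: header voxel size is zero/missing; pass voxel_size explicitly"
        )
    else:
        if max(spac) - min(spac) > 1e-3 * vx:
            raise ValueError(f"{path}: anisotropic voxel size {spac} not supported")
    return DensityVolume(data, vx)


def write_volume(volume: DensityVolume, path: str | Path) -> None:
    """Write a volume as an MRC mode-2 map with voxel size in the header."""
    nz, ny, nx = volume.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.array(grid, copy=False)[:] = volume.data.transpose(2, 1, 0)
    vx = volume.voxel_size
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vx, nz * vx, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_trace(path: str | Path, volume_id: str | None = None) -> list[FilamentTrace]:
    """Read the native trace CSV: columns mt_id, x, y, z (pixels).

    Points of one mt_id must be listed in order along the filament;
    duplicate consecutive points are rejected with their row number.
    Interleaved mt_ids are allowed; within-filament order is preserved.
    """
    df = pd.read_csv(path)
    required = {"mt_id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: trace CSV needs columns {sorted(required)}")
    traces: list[FilamentTrace] = []
    for mt_id, grp in df.groupby("mt_id", sort=False):
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        rows = grp.index.to_numpy()
        dup = np.where(np.all(np.diff(pts, axis=0) == 0, axis=1))[0]
        if dup.size:
            raise ValueError(
                f"{path}: duplicate consecutive point at data row {int(rows[dup[0] + 1]) + 2}"
                f" (mt_id {mt_id})"
            )
        traces.append(FilamentTrace(mt_id=str(mt_id), points=pts, volume_id=volume_id))
    return traces


def write_trace_csv(traces: list[FilamentTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"mt_id": t.mt_id, "x": t.points[:, 0], "y": t.points[:, 1], "z": t.points[:, 2]}
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trace_imod(path: str | Path, volume_id: str | None = None) -> list[FilamentTrace]:
    """Parse IMOD's ASCII point listing: ``object contour x y z`` per line.

    Each (object, contour) pair becomes one trace with mt_id
    ``"<object>_<contour>"``.  Blank lines and ``#`` comments are skipped.
    """
    groups: dict[tuple[int, int], list[list[float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{ln}: expected 'object contour x y z', got {line!r}"
                )
            obj, cont = int(parts[0]), int(parts[1])
            groups.setdefault((obj, cont), []).append([float(p) for p in parts[2:5]])
    traces = []
    for (obj, cont), pts in groups.items():
        traces.append(
            FilamentTrace(
                mt_id=f"{obj}_{cont}", points=np.asarray(pts), volume_id=volume_id
            )
        )
    return traces


def measurements_to_frame(measurements: list[SpacingMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mt_id": m.mt_id,
                "condition": m.condition,
                "spacing_A": m.spacing,
                "n_segments": m.n_segments,
                "usable": m.usable,
                "peak_offset_px": m.meta.get("peak_offset_px"),
            }
            for m in measurements
        ]
    )


def write_measurements(measurements: list[SpacingMeasurement], path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def read_measurements(path: str | Path) -> list[SpacingMeasurement]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        spacing = row["spacing_A"]
        out.append(
            SpacingMeasurement(
                mt_id=str(row["mt_id"]),
                condition=str(row["condition"]),
                spacing=None if pd.isna(spacing) else float(spacing),
                n_segments=int(row.get("n_segments", 0)),
                usable=bool(row["usable"]),
            )
        )
    return out


def write_stats_json(
    path: str | Path,
    groups: list[GroupStats],
    comparison: GroupComparison | None = None,
) -> None:
    payload: dict = {
        "groups": [
            {
                "condition": g.condition,
                "n": g.n,
                "mean_A": g.mean,
                "sd_A": g.sd,
                "ci95_A": list(g.ci95),
            }
            for g in groups
        ]
    }
    if comparison is not None:
        payload["comparison"] = {
            "difference_A": comparison.difference,
            "ci95_A": list(comparison.ci95),
            "t": comparison.t,
            "df": comparison.df,
            "p": comparison.p,
            "test": comparison.test,
        }
    Path(path).write_text(json.dumps(payload, indent=2))
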