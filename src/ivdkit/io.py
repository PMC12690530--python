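"""On-disk formats for panels, volumes, traces, networks and results.

- Cytokine panels: wide CSV (``animal_id, group, replicate`` then one
  column per cytokine); out-of-range readings are the literal token
  ``OOR`` on disk and NaN in memory.
- Volumes and masks: multi-page TIFF, one page per transverse slice, with
  a JSON sidecar recording the voxel size in µm.
- Compression traces: 3-column CSV ``time_s, displacement_um, force_N``.
- GTT series: 2-column CSV ``time_h, glucose_mg_dl``.
- Networks: GraphML plus edge-list CSV ``source, target, r``.
- Contours: JSON mapping slice index to a list of (row, col) vertices.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .synthetic import META_COLS, DiscVolume, LoadingTrace

OOR_TOKEN = "OOR"

__all__ = [
    "OOR_TOKEN",
    "write_panel",
    "read_panel",
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_trace",
    "read_trace",
    "write_gtt",
    "read_gtt",
    "write_network",
    "read_network",
    "write_contours",
    "read_contours",
]


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.copy()
    cyts = [c for c in out.columns if c not in META_COLS]
    out[cyts] = out[cyts].astype(object).where(out[cyts].notna(), OOR_TOKEN)
    out.to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, na_values=[OOR_TOKEN], keep_default_na=True)
    missing = [c for c in META_COLS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel CSV lacks required columns {missing}")
    return panel


def write_volume(vol: DiscVolume, path: str | Path) -> None:
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"voxel_size_um": vol.voxel_size}))


def read_volume(path: str | Path) -> DiscVolume:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    voxel = 10.0
    if sidecar.exists():
        voxel = float(json.loads(sidecar.read_text())["voxel_size_um"])
    return DiscVolume(data, voxel)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_trace(trace: LoadingTrace, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time,
            "displacement_um": trace.displacement,
            "force_N": trace.force,
        }
    ).to_csv(path, index=False)


def read_trace(
    path: str | Path, frequency: float = 1.0, amplitude: float | None = None
) -> LoadingTrace:
    df = pd.read_csv(path)
    x = df["displacement_um"].to_numpy(dtype=float)
    if amplitude is None:
        amplitude = float((x.max() - x.min()) / 2)
    return LoadingTrace(
        time=df["time_s"].to_numpy(dtype=float),
        displacement=x,
        force=df["force_N"].to_numpy(dtype=float),
        frequency=frequency,
        amplitude=amplitude,
    )


def write_gtt(series: pd.DataFrame, path: str | Path) -> None:
    series[["time_h", "glucose_mg_dl"]].to_csv(path, index=False)


def read_gtt(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_network(net: nx.Graph, path: str | Path) -> None:
    """GraphML next to an edge-list CSV (same stem, ``.edges.csv``)."""
    path = Path(path)
    nx.write_graphml(net, path)
    edges = pd.DataFrame(
        [(u, v, d.get("r", np.nan)) for u, v, d in net.edges(data=True)],
        columns=["source", "target", "r"],
    )
    edges.to_csv(path.with_suffix(".edges.csv"), index=False)


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_contours(
    contours: dict[int, list[tuple[float, float]]], path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps({str(k): [list(v) for v in poly] for k, poly in contours.items()})
    )


def read_contours(path: str | Path) -> dict[int, list[tuple[float, float]]]:
    raw = json.loads(Path(path).read_text())
    return {int(k): [tuple(v) for v in poly] for k, poly in raw.items()}
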