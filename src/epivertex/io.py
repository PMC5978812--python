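"""Serialization: network JSON, polygon-table CSV import, per-cell CSV export.

Network JSON dialect::

    {"box_length": L or [Lx, Ly],
     "vertices": [[x, y], ...],
     "cells": [[[j, ox, oy], ...], ...],
     "periodic": true}

Vertex ids are 0-based; (ox, oy) are integer periodic image offsets so cell
polygons unwrap contiguously.  Coordinates are dimensionless model units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TissueNetwork, network_edges
from .mechanics import ModelParams, cell_stress

__all__ = [
    "read_network",
    "write_network",
    "network_from_polygon_table",
    "write_cell_table",
    "write_run_config",
]


class SchemaError(ValueError):
    """Raised when a network file violates the JSON dialect."""


def write_network(network: TissueNetwork, path) -> None:
    box = network.box
    box_out = box[0] if np.isclose(box[0], box[1]) else [box[0], box[1]]
    doc = {
        "box_length": box_out,
        "vertices": network.vertices.tolist(),
        "cells": [
            [[int(j), int(ox), int(oy)]
             for j, (ox, oy) in zip(cyc, off)]
            for cyc, off in zip(network.cell_vertices, network.cell_offsets)
        ],
        "periodic": bool(network.periodic),
    }
    if network.peripheral_vertices:
        doc["peripheral_vertices"] = sorted(int(j) for j
                                            in network.peripheral_vertices)
    if network.meta:
        doc["meta"] = _jsonable(network.meta)
    Path(path).write_text(json.dumps(doc))


def read_network(path) -> TissueNetwork:
    doc = json.loads(Path(path).read_text())
    for field in ("box_length", "vertices", "cells"):
        if field not in doc:
            raise SchemaError(f"network file missing required field {field!r}")
    cells = doc["cells"]
    cell_vertices = [np.array([c[0] for c in cyc], dtype=np.intp)
                     for cyc in cells]
    cell_offsets = [np.array([c[1:3] for c in cyc], dtype=np.intp)
                    for cyc in cells]
    return TissueNetwork(
        box=doc["box_length"],
        vertices=np.asarray(doc["vertices"], dtype=float),
        cell_vertices=cell_vertices,
        cell_offsets=cell_offsets,
        periodic=bool(doc.get("periodic", True)),
        peripheral_vertices=frozenset(doc.get("peripheral_vertices", ())),
        meta=doc.get("meta", {}),
    )


def network_from_polygon_table(path_or_df, scale: float = 1.0,
                               merge_tol: float | None = None,
                               ) -> TissueNetwork:
    """Build a finite-patch network from segmented cell polygons.

    Expects columns ``cell_id``, ``vertex_order``, ``x``, ``y`` (pixels or
    microns; multiplied by ``scale`` to reach dimensionless units).  Shared
    junction vertices are merged when closer than ``merge_tol`` (default
    1e-6 of the bounding extent); peripheral vertices (those on edges
    bounded by a single cell) are flagged.
    """
    df = (pd.read_csv(path_or_df) if not isinstance(path_or_df, pd.DataFrame)
          else path_or_df)
    for col in ("cell_id", "vertex_order", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"polygon table missing column {col!r}")
    df = df.sort_values(["cell_id", "vertex_order"])
    coords = df[["x", "y"]].to_numpy(dtype=float) * scale
    extent = float(np.ptp(coords, axis=0).max())
    if merge_tol is None:
        merge_tol = 1e-6 * extent
    from scipy.spatial import cKDTree
    tree = cKDTree(coords)
    parent = np.arange(coords.shape[0])

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, k in tree.query_pairs(merge_tol):
        ri, rk = find(i), find(k)
        if ri != rk:
            parent[max(ri, rk)] = min(ri, rk)
    roots = np.array([find(i) for i in range(coords.shape[0])])
    uniq, inv = np.unique(roots, return_inverse=True)
    vertices = coords[uniq]

    cell_vertices, cell_offsets = [], []
    pos = 0
    for _, group in df.groupby("cell_id", sort=True):
        z = len(group)
        ids = inv[pos:pos + z]
        cell_vertices.append(ids.astype(np.intp))
        cell_offsets.append(np.zeros((z, 2), dtype=np.intp))
        pos += z
    net = TissueNetwork(
        box=max(extent, merge_tol) * 1.0001,
        vertices=vertices, cell_vertices=cell_vertices,
        cell_offsets=cell_offsets, periodic=False,
    ).normalize_orientation()
    peripheral = set()
    for key, halves in network_edges(net).items():
        if len(halves) == 1:
            peripheral.update(key[:2])
    net.peripheral_vertices = frozenset(peripheral)
    return net


def write_cell_table(network: TissueNetwork, params: ModelParams,
                     path=None) -> pd.DataFrame:
    """Per-cell geometry + mechanics table (one row per cell)."""
    rows = []
    for a in range(network.n_cells):
        g = network.cell_geometry(a)
        m = cell_stress(g, params)
        rows.append({
            "cell_id": a, "Z": g.n_sides, "A": g.area, "L": g.perimeter,
            "C": g.circularity, "P": m.pressure, "T": m.tension,
            "P_eff": m.p_eff,
            "sigma_xx": m.stress[0, 0], "sigma_xy": m.stress[0, 1],
            "sigma_yy": m.stress[1, 1],
            "major_axis_angle": g.major_axis_angle,
            "stress_class": m.stress_class,
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def write_run_config(path, command: str, **settings) -> None:
    """Provenance sidecar: the command and every parameter of a run."""
    doc = {"command": command, **_jsonable(settings)}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
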