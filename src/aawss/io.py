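"""Readers, writers and the end-to-end pipeline.

Surface meshes are exchanged as STL (via trimesh) or legacy ASCII VTK
polydata; the VTK writer/reader here is a deliberately small text-format
implementation (POINTS / POLYGONS / POINT_DATA with SCALARS or VECTORS)
sufficient for surface fields.  WSS series travel as long-format CSV with
columns node_id, t, wss_x, wss_y, wss_z (Pa), mirroring a per-node
component export from a CFD post-processor.

Internally everything is meters / Pascals / seconds; millimeter mesh
files are converted on read via an explicit unit flag.  Node indices are
0-based.  All writers use fixed float formatting so identical inputs give
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import risk as _risk
from .mesh import VesselMesh, cylinder_profile, fusiform_profile, \
    make_vessel_mesh, saccular_bulge
from .metrics import CycleSpec, HemodynamicFields, WssSeries, \
    clamp_for_report, compute_fields
from .synth import LesionSpec, synth_wss_series
from .waveform import make_waveform

_FMT = "%.9e"


def _unit_scale(units: str) -> float:
    if units == "m":
        return 1.0
    if units == "mm":
        return 1e-3
    raise ValueError(f"unknown units {units!r}; expected 'm' or 'mm'")


def write_mesh(mesh: VesselMesh, path, units: str = "m") -> None:
    """Write STL (.stl) or legacy ASCII VTK polydata (.vtk)."""
    path = Path(path)
    scale = 1.0 / _unit_scale(units)
    if path.suffix.lower() == ".stl":
        tm = trimesh.Trimesh(vertices=mesh.vertices * scale,
                             faces=mesh.triangles, process=False)
        tm.export(path, file_type="stl_ascii")
    elif path.suffix.lower() == ".vtk":
        write_vtk_polydata(path, mesh, scale=scale)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")


def read_mesh(path, units: str = "m") -> VesselMesh:
    """Read a triangulated surface (STL or ASCII VTK polydata); ``units``
    names the file's length unit (CT exports are typically mm)."""
    path = Path(path)
    if path.suffix.lower() == ".stl":
        tm = trimesh.load(path, file_type="stl", process=False)
        verts, tris = np.asarray(tm.vertices, float), np.asarray(tm.faces)
        # STL stores loose triangles; merge coincident vertices
        verts, tris = _merge_vertices(verts, tris)
    elif path.suffix.lower() == ".vtk":
        verts, tris, _ = read_vtk_polydata(path)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    if tris.shape[1] != 3:
        raise ValueError("mesh is not purely triangular")
    return VesselMesh(vertices=verts * _unit_scale(units), triangles=tris)


def _merge_vertices(verts: np.ndarray, tris: np.ndarray):
    rounded = np.round(verts, 12)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    return uniq, inverse[tris]


def write_vtk_polydata(path, mesh: VesselMesh, point_data: dict | None = None,
                       scale: float = 1.0) -> None:
    """Legacy ASCII VTK polydata with optional per-node scalar/vector data."""
    lines = ["# vtk DataFile Version 3.0", "aawss surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {mesh.n_nodes} double"]
    for p in mesh.vertices * scale:
        lines.append(" ".join(_FMT % x for x in p))
    m = len(mesh.triangles)
    lines.append(f"POLYGONS {m} {4 * m}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(_FMT % v for v in arr.astype(float))
            elif arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(_FMT % x for x in row)
                             for row in arr.astype(float))
            else:
                raise ValueError(f"point data {name!r} must be (n,) or (n,3)")
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path):
    """Parse the subset of legacy ASCII VTK polydata written above.
    Returns (vertices, triangles, point_data)."""
    tokens = Path(path).read_text().split()
    tl = [t.upper() for t in tokens]

    def _find(kw, start=0):
        try:
            return tl.index(kw, start)
        except ValueError:
            raise ValueError(f"VTK file lacks a {kw} section") from None

    i = _find("POINTS")
    n = int(tokens[i + 1])
    verts = np.array(tokens[i + 3:i + 3 + 3 * n], float).reshape(n, 3)
    i = _find("POLYGONS")
    m = int(tokens[i + 1])
    raw = np.array(tokens[i + 3:i + 3 + int(tokens[i + 2])], dtype=np.int64)
    tris, k = [], 0
    for _ in range(m):
        c = int(raw[k])
        if c != 3:
            raise ValueError("non-triangular polygon in VTK file")
        tris.append(raw[k + 1:k + 4])
        k += c + 1
    point_data = {}
    if "POINT_DATA" in tl:
        i = tl.index("POINT_DATA") + 2
        while i < len(tokens):
            kind = tl[i]
            if kind == "SCALARS":
                name = tokens[i + 1]
                i += 6  # SCALARS name type 1 LOOKUP_TABLE default
                point_data[name] = np.array(tokens[i:i + n], float)
                i += n
            elif kind == "VECTORS":
                name = tokens[i + 1]
                i += 3
                point_data[name] = np.array(
                    tokens[i:i + 3 * n], float).reshape(n, 3)
                i += 3 * n
            else:
                break
    return verts, np.array(tris, dtype=np.int64), point_data


def write_fields_vtk(path, fields: HemodynamicFields) -> None:
    """Per-node index fields as VTK point data (display-clamped copy)."""
    disp = clamp_for_report(fields)
    write_vtk_polydata(path, fields.mesh, point_data={
        "TAWSS": disp.tawss, "OSI": disp.osi,
        "ECAP": disp.ecap, "RRT": disp.rrt})


def write_wss_series(series: WssSeries, path) -> None:
    """Long-format CSV: node_id, t, wss_x, wss_y, wss_z (Pa)."""
    nt, nn, _ = series.tau.shape
    node = np.repeat(np.arange(nn), nt)
    t = np.tile(series.times, nn)
    tau = series.tau.transpose(1, 0, 2).reshape(-1, 3)
    df = pd.DataFrame({"node_id": node, "t": t, "wss_x": tau[:, 0],
                       "wss_y": tau[:, 1], "wss_z": tau[:, 2]})
    df.to_csv(path, index=False, float_format="%.12g")


def read_wss_series(path, mesh: VesselMesh) -> WssSeries:
    """Assemble a WssSeries from a long-format CSV export; row order is
    immaterial (sorted by node_id, t), gaps and duplicates are rejected."""
    df = pd.read_csv(path)
    need = {"node_id", "t", "wss_x", "wss_y", "wss_z"}
    if not need <= set(df.columns):
        raise ValueError(f"series table missing columns {need - set(df.columns)}")
    df = df.sort_values(["node_id", "t"], kind="mergesort")
    times = np.unique(df["t"].to_numpy())
    nodes = np.unique(df["node_id"].to_numpy())
    if len(nodes) != mesh.n_nodes or nodes[0] != 0 or nodes[-1] != mesh.n_nodes - 1:
        raise ValueError(
            f"series has {len(nodes)} node ids; mesh has {mesh.n_nodes} nodes")
    if len(df) != len(times) * len(nodes):
        counts = df.groupby("t").size()
        bad = counts.index[counts != len(nodes)]
        raise ValueError(f"missing or duplicated samples at t = {list(bad)[:5]}")
    dt = np.diff(times)
    if np.any(np.abs(dt - dt[0]) > 1e-9):
        raise ValueError("non-uniform time grid in series table")
    tau = df[["wss_x", "wss_y", "wss_z"]].to_numpy().reshape(
        len(nodes), len(times), 3).transpose(1, 0, 2)
    return WssSeries(mesh=mesh, times=times, tau=tau)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end synthetic pipeline configuration."""
    out_dir: str = "aawss_out"
    shape: str = "fusiform"          # cylinder | fusiform | saccular
    radius: float = 0.01             # m
    length: float = 0.12             # m
    bulge_amplitude: float = 0.012   # m
    n_circ: int = 48
    n_axial: int = 72
    base_tawss: float = 1.5          # Pa, healthy background level
    n_lesions: int = 1
    lesion_radius: float = 0.012     # m, geodesic
    period: float = 1.0              # s
    dt: float = 0.01                 # s
    cycles: int = 3
    cycle_index: int = 3
    seed: int = 0
    min_area: float = 25e-6          # m^2
    thresholds: _risk.RiskThresholds = field(
        default_factory=_risk.RiskThresholds)


def build_mesh(config: RunConfig) -> VesselMesh:
    if config.shape == "cylinder":
        return make_vessel_mesh(cylinder_profile(config.radius),
                                config.length, config.n_circ, config.n_axial)
    if config.shape == "fusiform":
        prof = fusiform_profile(config.radius, config.bulge_amplitude,
                                config.length / 2, config.length / 8)
        return make_vessel_mesh(prof, config.length, config.n_circ,
                                config.n_axial)
    if config.shape == "saccular":
        bul = saccular_bulge(config.bulge_amplitude, config.length / 2,
                             config.length / 8)
        return make_vessel_mesh(cylinder_profile(config.radius),
                                config.length, config.n_circ, config.n_axial,
                                bulge=bul)
    raise ValueError(f"unknown shape {config.shape!r}")


def default_lesions(config: RunConfig, mesh: VesselMesh) -> list[LesionSpec]:
    """Evenly spaced criterion-satisfying lesions on the bulge equator."""
    lesions = []
    for k in range(config.n_lesions):
        theta = 2 * np.pi * k / max(config.n_lesions, 1)
        r_here = config.radius + (config.bulge_amplitude
                                  if config.shape != "cylinder" else 0.0)
        center = (r_here * np.cos(theta), r_here * np.sin(theta),
                  config.length / 2)
        lesions.append(LesionSpec(center=center,
                                  geodesic_radius=config.lesion_radius))
    return lesions


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> metrics -> classify -> report; deterministic for a fixed
    seed.  Returns a dict of written artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = []

    mesh = build_mesh(config)
    wave = make_waveform("generic_aortic", period=config.period,
                         cycles=config.cycles, dt=config.dt)
    lesions = default_lesions(config, mesh)
    series = synth_wss_series(mesh, wave, base_tawss=config.base_tawss,
                              lesions=lesions, seed=config.seed)
    log.append(f"simulate: shape={config.shape} nodes={mesh.n_nodes} "
               f"lesions={len(lesions)} seed={config.seed}")

    spec = CycleSpec(period=config.period, dt=config.dt,
                     cycle_index=config.cycle_index)
    fields = compute_fields(series, spec)
    log.append(f"metrics: cycle {spec.cycle_index}, "
               f"{spec.samples_per_cycle} samples/cycle")

    mask = _risk.joint_risk_mask(fields, config.thresholds)
    rmap = _risk.extract_patches(mask, mesh, fields, config.thresholds,
                                 min_area=config.min_area)
    log.append(f"classify: {int(mask.sum())} criterion nodes, "
               f"{len(rmap.patches)} patches")

    paths = {
        "mesh_stl": out / "mesh.stl",
        "series_csv": out / "wss_series.csv",
        "fields_vtk": out / "fields.vtk",
        "riskmap_vtk": out / "risk_map.vtk",
        "patches_csv": out / "patches.csv",
        "log": out / "pipeline.log",
    }
    write_mesh(mesh, paths["mesh_stl"])
    write_wss_series(series, paths["series_csv"])
    write_fields_vtk(paths["fields_vtk"], fields)
    write_vtk_polydata(paths["riskmap_vtk"], mesh, point_data={
        "criterion_mask": mask.astype(float),
        "patch_id": rmap.patch_id.astype(float)})
    rows = [{"patch": i, "n_nodes": len(p["nodes"]),
             "area_mm2": p["area_m2"] * 1e6,
             **{f"{par}_bin": p["modal_bins"][par]
                for par in ("tawss", "osi", "ecap", "rrt")}}
            for i, p in enumerate(rmap.patches)]
    pd.DataFrame(rows, columns=["patch", "n_nodes", "area_mm2", "tawss_bin",
                                "osi_bin", "ecap_bin", "rrt_bin"]
                 ).to_csv(paths["patches_csv"], index=False,
                          float_format="%.6f")
    paths["log"].write_text("\n".join(log) + "\n")
    return {k: str(v) for k, v in paths.items()} | {
        "n_patches": len(rmap.patches), "n_masked": int(mask.sum())}
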