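"""File formats: shape tables, transform files, LGE tables, meshes.

Shape tables are flat CSV (one row per nodal value) with a JSON sidecar
holding the shared coordinate-frame geometry:

    case_id,protocol,frame,surface,i,j,lambda

The sidecar (``<stem>_frame.json``) stores the prolate frame, mu_max, grid
dimensions and provenance.  Transforms are JSON with a parameter-count
manifest that is checked on application.  Meshes are ASCII PLY or legacy
ASCII VTK PolyData with optional per-vertex scalars.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd

from ._utils import config_hash
from .cohort import FRAMES, Cohort, PairedCohort
from .correction import ProtocolBiasCorrector
from .prolate import ProlateFrame

__all__ = [
    "write_shape_table", "read_shape_table",
    "write_transform", "read_transform",
    "write_lge_table", "read_lge_table",
    "write_ply", "write_vtk_polydata",
]

FORMAT_VERSION = 1


def _sidecar_path(path: pathlib.Path) -> pathlib.Path:
    return path.with_name(path.stem + "_frame.json")


def write_shape_table(cohort, path, provenance: dict | None = None) -> None:
    """Write a cohort (paired or single-protocol) to CSV + JSON sidecar."""
    path = pathlib.Path(path)
    nc, nl = cohort.grid_shape
    ii, jj = np.meshgrid(np.arange(nc), np.arange(nl), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    half = nc * nl
    rows = []

    def emit(case_id, protocol, frame, params):
        for surf, sl in (("endo", slice(0, half)), ("epi", slice(half, 2 * half))):
            vals = params[sl]
            rows.extend(zip([case_id] * half, [protocol] * half,
                            [frame] * half, [surf] * half, ii, jj, vals))

    if isinstance(cohort, PairedCohort):
        for idx, cid in enumerate(cohort.case_ids):
            for frame in cohort.frames:
                emit(cid, "GRE", frame, cohort.gre[frame][idx])
                emit(cid, "SSFP", frame, cohort.ssfp[frame][idx])
    else:
        for idx, cid in enumerate(cohort.case_ids):
            for frame in cohort.frames:
                emit(cid, cohort.protocol, frame, cohort.params[frame][idx])

    df = pd.DataFrame(rows, columns=["case_id", "protocol", "frame",
                                     "surface", "i", "j", "lambda"])
    meta = {
        "format_version": FORMAT_VERSION,
        "prolate": cohort.prolate.to_dict(),
        "mu_max": float(cohort.mu_max),
        "grid_shape": list(cohort.grid_shape),
        "provenance": provenance or dict(getattr(cohort, "provenance", {})),
    }
    meta["config_hash"] = config_hash(
        {k: v for k, v in meta.items() if k != "provenance"})
    with open(path, "w") as fh:
        fh.write(f"# lvatlas shape table v{FORMAT_VERSION} "
                 f"config={meta['config_hash']}\n")
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_shape_table(path):
    """Read a shape table; returns PairedCohort or single-protocol Cohort.

    Validates the schema (error messages carry the offending CSV row) and
    every shape's invariants (positive lambda, wall thickness), naming the
    case and node on failure.
    """
    path = pathlib.Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing frame sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    prolate = ProlateFrame.from_dict(meta["prolate"])
    grid_shape = tuple(meta["grid_shape"])
    mu_max = float(meta["mu_max"])
    nc, nl = grid_shape
    half = nc * nl

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["case_id", "protocol", "frame", "surface", "i", "j", "lambda"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"shape table missing columns {sorted(missing)}")
    bad = ~df["surface"].isin(["endo", "epi"])
    if bad.any():
        raise ValueError(f"invalid surface label at CSV row {bad.idxmax() + 2}")
    bad = ~df["frame"].isin(FRAMES)
    if bad.any():
        raise ValueError(f"invalid frame label at CSV row {bad.idxmax() + 2}")
    bad = (~np.isfinite(df["lambda"])) | (df["lambda"] <= 0.0)
    if bad.any():
        r = df[bad].iloc[0]
        raise ValueError(
            f"invalid lambda value for case {r['case_id']!r} node "
            f"({int(r['i'])}, {int(r['j'])}) [{r['surface']}, {r['frame']}]")
    bad = (df["i"] < 0) | (df["i"] >= nc) | (df["j"] < 0) | (df["j"] >= nl)
    if bad.any():
        raise ValueError(f"node index out of range at CSV row {bad.idxmax() + 2}")

    protocols = sorted(df["protocol"].unique())
    case_ids = sorted(df["case_id"].unique())
    frames = tuple(fr for fr in FRAMES if fr in set(df["frame"]))
    offset = {"endo": 0, "epi": half}

    def matrix(protocol, frame):
        sub = df[(df["protocol"] == protocol) & (df["frame"] == frame)]
        out = np.full((len(case_ids), 2 * half), np.nan)
        row = [*map({c: k for k, c in enumerate(case_ids)}.get, sub["case_id"])]
        col = (sub["surface"].map(offset).to_numpy()
               + sub["i"].to_numpy() * nl + sub["j"].to_numpy())
        out[row, col] = sub["lambda"].to_numpy()
        if np.isnan(out).any():
            k = int(np.argwhere(np.isnan(out).any(axis=1))[0][0])
            raise ValueError(
                f"incomplete parameter set for case {case_ids[k]!r} "
                f"({protocol}, {frame})")
        return out

    if set(protocols) == {"GRE", "SSFP"}:
        cohort = PairedCohort(
            case_ids=case_ids, prolate=prolate, grid_shape=grid_shape,
            mu_max=mu_max,
            gre={fr: matrix("GRE", fr) for fr in frames},
            ssfp={fr: matrix("SSFP", fr) for fr in frames},
            provenance=meta.get("provenance", {}), frames=frames)
        shapes = [(p, fr, i) for p in ("GRE", "SSFP") for fr in frames
                  for i in range(len(case_ids))]
        for p, fr, i in shapes:
            cohort.shape(p, fr, i)  # raises with case id on violation
        return cohort
    if len(protocols) != 1:
        raise ValueError(f"expected one or two protocols, found {protocols}")
    cohort = Cohort(
        case_ids=case_ids, protocol=protocols[0], prolate=prolate,
        grid_shape=grid_shape, mu_max=mu_max,
        params={fr: matrix(protocols[0], fr) for fr in frames},
        provenance=meta.get("provenance", {}), frames=frames)
    for fr in frames:
        for i in range(len(case_ids)):
            cohort.shape(fr, i)
    return cohort


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def write_transform(transform: ProtocolBiasCorrector, path,
                    provenance: dict | None = None) -> None:
    path = pathlib.Path(path)
    d = transform.to_dict()
    d["format_version"] = FORMAT_VERSION
    d["frame"] = getattr(transform, "frame_", None)
    d["provenance"] = provenance or {}
    d["config_hash"] = config_hash(
        {k: d[k] for k in ("kind", "n_train", "n_parameters", "frame")})
    path.write_text(json.dumps(d, indent=1, sort_keys=True))


def read_transform(path) -> ProtocolBiasCorrector:
    d = json.loads(pathlib.Path(path).read_text())
    if d.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"unsupported transform format {d.get('format_version')}")
    est = ProtocolBiasCorrector.from_dict(d)
    if d.get("frame"):
        est.frame_ = d["frame"]
    return est


def check_manifest(transform: ProtocolBiasCorrector, cohort) -> None:
    """Raise when a transform and a cohort disagree on the parameter set."""
    p = 2 * cohort.grid_shape[0] * cohort.grid_shape[1]
    if transform.n_features_in_ != p:
        raise ValueError(
            f"transform manifest mismatch: trained on "
            f"{transform.n_features_in_} parameters, cohort has {p}")


# ---------------------------------------------------------------------------
# LGE tables
# ---------------------------------------------------------------------------

def write_lge_table(lge: pd.DataFrame, path) -> None:
    pd.DataFrame(lge)[["case_id", "segment", "grade"]].to_csv(
        path, index=False, lineterminator="\n")


def read_lge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"case_id", "segment", "grade"} - set(df.columns)
    if missing:
        raise ValueError(f"LGE table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_ply(vertices: np.ndarray, faces: np.ndarray, path,
              comment: str = "lvatlas surface") -> None:
    """ASCII PLY triangle mesh."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = [
        "ply", "format ascii 1.0", f"comment {comment}",
        f"element vertex {len(vertices)}",
        "property float x", "property float y", "property float z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices", "end_header",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in faces]
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_polydata(vertices: np.ndarray, faces: np.ndarray, path,
                       point_data: dict | None = None,
                       comment: str = "lvatlas map") -> None:
    """Legacy ASCII VTK PolyData with optional per-vertex scalar arrays."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    out = [
        "# vtk DataFile Version 3.0", comment, "ASCII", "DATASET POLYDATA",
        f"POINTS {len(vertices)} float",
    ]
    out += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in vertices]
    out.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    out += [f"3 {a} {b} {c}" for a, b, c in faces]
    if point_data:
        out.append(f"POINT_DATA {len(vertices)}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if len(values) != len(vertices):
                raise ValueError(f"scalar array {name!r} length mismatch")
            out.append(f"SCALARS {name} float 1")
            out.append("LOOKUP_TABLE default")
            out += [f"{v:.9g}" for v in values]
    pathlib.Path(path).write_text("\n".join(out) + "\n")
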