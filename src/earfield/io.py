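"""File formats: meshes (OFF / ASCII PLY), montage and parcellation TSV,
lead-field matrices with JSON sidecars, and run manifests.

Every writer here produces plain text that the package's own readers
re-parse losslessly (vertices to < 1e-9 m, faces exactly), so pipeline
stages can hand artifacts to each other through a directory.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _trimesh

from .geometry import MeshError, TriMesh
from .forward import LeadField
from .head import ElectrodeMontage, Parcellation, ShellModel

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_montage_tsv",
    "write_montage_tsv",
    "read_parcellation_tsv",
    "write_parcellation_tsv",
    "write_leadfield",
    "read_leadfield",
    "write_shells_json",
    "read_shells_json",
    "write_manifest",
]


def write_mesh(mesh: TriMesh, path: str | Path) -> None:
    """Write OFF or ASCII PLY (by extension), double precision."""
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt == "off":
        lines = ["OFF", f"{mesh.n_vertices} {mesh.n_faces} 0"]
        lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
        lines += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "ply":
        head = [
            "ply",
            "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            "property double x",
            "property double y",
            "property double z",
            f"element face {mesh.n_faces}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        body = [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
        body += [f"3 {a} {b} {c}" for a, b, c in mesh.faces]
        path.write_text("\n".join(head + body) + "\n")
    else:
        raise ValueError(f"unsupported mesh format {fmt!r} (use .off or .ply)")


def read_mesh(path: str | Path) -> TriMesh:
    """Read an OFF or ASCII PLY mesh and validate it as a closed manifold."""
    path = Path(path)
    fmt = path.suffix.lower().lstrip(".")
    if fmt not in ("off", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r} (use .off or .ply)")
    tm = _trimesh.load(path, file_type=fmt, process=False)
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
        bad = int(np.argmax((faces < 0).any(axis=1) | (faces >= len(verts)).any(axis=1)))
        raise MeshError(f"face {bad} references a vertex out of range")
    return TriMesh(verts, faces)  # full manifold validation


def write_montage_tsv(montage: ElectrodeMontage, path: str | Path) -> None:
    """TSV with header ``label<TAB>x<TAB>y<TAB>z`` (meters) and an optional
    ``side`` column."""
    df = pd.DataFrame(
        {
            "label": montage.labels,
            "x": montage.positions[:, 0],
            "y": montage.positions[:, 1],
            "z": montage.positions[:, 2],
        }
    )
    if montage.side_tag is not None:
        df["side"] = montage.side_tag
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_montage_tsv(path: str | Path) -> ElectrodeMontage:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"label": str})
    except Exception as e:
        raise ValueError(f"cannot parse montage file {path}: {e}") from e
    required = ["label", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"montage header must start with {required}, got {list(df.columns)}"
        )
    labels = df["label"].tolist()
    dup = df[df["label"].duplicated(keep=False)]
    if len(dup):
        desc = ", ".join(
            f"{lab!r} (lines {', '.join(str(i + 2) for i in grp.index)})"
            for lab, grp in dup.groupby("label")
        )
        raise ValueError(f"duplicate electrode labels: {desc}")
    for col in ("x", "y", "z"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"malformed {col!r} value on line {bad[0] + 2} of {path}"
            )
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    side = tuple(df["side"]) if "side" in df.columns else None
    return ElectrodeMontage(tuple(labels), pos, side)


def write_parcellation_tsv(parcellation: Parcellation, path: str | Path) -> None:
    """Two columns: vertex_index, patch_id (-1 = excluded)."""
    pd.DataFrame(
        {
            "vertex_index": np.arange(len(parcellation.patch_id)),
            "patch_id": parcellation.patch_id,
        }
    ).to_csv(path, sep="\t", index=False)


def read_parcellation_tsv(path: str | Path, vertex_areas: np.ndarray) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    pid = np.full(len(df), -1, dtype=np.int64)
    pid[df["vertex_index"].to_numpy()] = df["patch_id"].to_numpy()
    ids = np.unique(pid[pid >= 0])
    areas = np.array([vertex_areas[pid == p].sum() * 1e4 for p in ids])
    return Parcellation(pid, len(ids), areas)


def write_leadfield(lf: LeadField, path: str | Path) -> None:
    """Matrix as delimited text plus a ``<path>.json`` sidecar describing
    channels, source descriptors and the reference."""
    path = Path(path)
    np.savetxt(path, lf.matrix, fmt="%.17g", delimiter="\t")
    sidecar = {
        "channel_labels": list(lf.channel_labels),
        "source_positions": lf.source_positions.tolist(),
        "source_orientations": lf.source_orientations.tolist(),
        "reference_tag": lf.reference_tag,
        "units": "V per (A*m)",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_leadfield(path: str | Path) -> LeadField:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    return LeadField(
        mat,
        tuple(meta["channel_labels"]),
        np.asarray(meta["source_positions"]),
        np.asarray(meta["source_orientations"]),
        meta["reference_tag"],
    )


def write_shells_json(shell: ShellModel, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "radii_m": list(shell.radii),
                "conductivities_S_per_m": list(shell.conductivities),
                "center_m": shell.center.tolist(),
            },
            indent=1,
        )
    )


def read_shells_json(path: str | Path) -> ShellModel:
    d = json.loads(Path(path).read_text())
    return ShellModel(
        tuple(d["radii_m"]),
        tuple(d["conductivities_S_per_m"]),
        np.asarray(d["center_m"]),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, config: dict, seed: int | None, files: list[str]
) -> None:
    """Machine-readable record of a run: config echo, version, seed and
    checksums of every artifact written."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "package": "earfield",
        "version": __version__,
        "seed": seed,
        "config": config,
        "checksums_sha256": {f: _sha256(out_dir / f) for f in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
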