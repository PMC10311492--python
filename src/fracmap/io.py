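"""On-disk artifacts: labeled volumes (NIfTI), meshes (PLY/STL), per-vertex
frequency maps (PLY + CSV), cohort tables (CSV), ground truth (JSON), config (YAML).

All writers are deterministic (stable ordering, fixed float formatting) so that
re-running a pipeline with the same seed produces byte-identical files.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger("fracmap")

__version__ = "0.1.0"

SEX_LEVELS = ("male", "female")
SIDE_LEVELS = ("left", "right")
MECHANISM_LEVELS = ("MVA", "slip", "fall", "crushing")
AO_LEVELS = ("33A", "33C")


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledVolume:
    """Integer 3D label grid with voxel spacing and origin, both in mm.

    Axis order is (x, y, z): voxel index ``(i, j, k)`` sits at
    ``origin + (i, j, k) * spacing`` in mm. Label 0 is background; labels >= 1
    are bone fragments.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError(
                f"labels must be an integer grid, got dtype {self.labels.dtype}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self, mask: np.ndarray) -> np.ndarray:
        """mm coordinates of the voxel centers selected by a boolean mask."""
        idx = np.argwhere(mask)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)


@dataclass
class TemplateMesh:
    """Triangulated reference surface in mm with anatomical frame.

    ``axes`` rows are the superior, anterior and medial unit vectors; the joint
    line is the plane through ``joint_plane_point`` with normal
    ``joint_plane_normal`` (pointing superiorly).
    """

    mesh: trimesh.Trimesh
    joint_plane_point: np.ndarray
    joint_plane_normal: np.ndarray
    axes: np.ndarray  # 3x3, rows = superior, anterior, medial
    side: str = "left"

    def __post_init__(self) -> None:
        self.joint_plane_point = np.asarray(self.joint_plane_point, dtype=float)
        self.joint_plane_normal = np.asarray(self.joint_plane_normal, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.side not in SIDE_LEVELS:
            raise ValueError(f"side must be one of {SIDE_LEVELS}")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        faces = self.mesh.faces
        if faces.size and (faces.min() < 0 or faces.max() >= len(self.mesh.vertices)):
            raise ValueError("face indices out of range")

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self.mesh.vertices)

    @property
    def superior(self) -> np.ndarray:
        return self.axes[0]

    @property
    def anterior(self) -> np.ndarray:
        return self.axes[1]

    @property
    def medial(self) -> np.ndarray:
        return self.axes[2]

    def height_above_joint(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points from the joint-line plane along superior."""
        return (np.atleast_2d(points) - self.joint_plane_point) @ self.superior


@dataclass
class CaseRecord:
    case_id: str
    age: float
    sex: str
    side: str
    height: float  # m
    weight: float  # kg
    bmi: float  # kg/m^2
    mechanism: str
    ao_class: str

    def __post_init__(self) -> None:
        for name, value, levels in (
            ("sex", self.sex, SEX_LEVELS),
            ("side", self.side, SIDE_LEVELS),
            ("mechanism", self.mechanism, MECHANISM_LEVELS),
            ("ao_class", self.ao_class, AO_LEVELS),
        ):
            if value not in levels:
                raise ValueError(f"{name}={value!r} not in allowed levels {levels}")


# ---------------------------------------------------------------------------
# labeled volumes (NIfTI)
# ---------------------------------------------------------------------------

def write_labeled_volume(volume: LabeledVolume, path: str | Path) -> Path:
    """Write a labeled volume as NIfTI (int16 labels, spacing/origin in affine)."""
    path = Path(path)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.labels.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def read_labeled_volume(path: str | Path) -> LabeledVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if not np.issubdtype(dtype, np.integer):
        raise TypeError(
            f"labeled volume must hold integer labels; {path.name} has dtype {dtype}"
        )
    data = np.asarray(img.dataobj).astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"missing or non-positive voxel spacing in {path.name}")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return LabeledVolume(labels=data, spacing=tuple(float(z) for z in zooms), origin=origin)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Load a PLY or STL surface (binary or ASCII auto-detected)."""
    mesh = trimesh.load(str(path), force="mesh")
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ValueError(f"{path} does not contain a triangulated surface")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> Path:
    path = Path(path)
    mesh.export(str(path))
    return path


# ---------------------------------------------------------------------------
# frequency maps (PLY with per-vertex scalar + RGB, CSV companion)
# ---------------------------------------------------------------------------

def write_frequency_map(
    freq_map,
    template: TemplateMesh,
    path: str | Path,
    colors: np.ndarray | None = None,
    metadata: dict | None = None,
) -> tuple[Path, Path]:
    """Write a frequency map as ASCII PLY (scalar ``frequency`` + RGB) plus a
    CSV companion with vertex_id, count, frequency.

    The PLY is hand-formatted because the map carries a custom per-vertex
    scalar channel alongside colors; vertex order follows the template.
    """
    from .mapping import colorize  # deferred: avoid import cycle

    path = Path(path)
    verts = template.vertices
    if len(freq_map.counts) != len(verts):
        raise ValueError(
            f"map has {len(freq_map.counts)} vertices but template has {len(verts)}"
        )
    if colors is None:
        colors = colorize(freq_map)
    rgb = (np.clip(colors, 0.0, 1.0) * 255).round().astype(np.uint8)
    faces = template.mesh.faces
    freq = freq_map.frequency

    lines = ["ply", "format ascii 1.0"]
    for key, value in sorted((metadata or {}).items()):
        lines.append(f"comment {key}={value}")
    lines += [
        f"element vertex {len(verts)}",
        "property float x",
        "property float y",
        "property float z",
        "property uchar red",
        "property uchar green",
        "property uchar blue",
        "property float frequency",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v, c, f in zip(verts, rgb, freq):
        lines.append(
            f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g} {c[0]} {c[1]} {c[2]} {f:.6g}"
        )
    for f in faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")

    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        for key, value in sorted((metadata or {}).items()):
            fh.write(f"# {key}={value}\n")
        writer = csv.writer(fh)
        writer.writerow(["vertex_id", "count", "frequency"])
        for i, (cnt, f) in enumerate(zip(freq_map.counts, freq)):
            writer.writerow([i, int(cnt), f"{f:.6g}"])
    return path, csv_path


def read_frequency_map_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back counts and frequencies written by write_frequency_map."""
    df = pd.read_csv(path, comment="#")
    return df["count"].to_numpy(), df["frequency"].to_numpy()


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = [
    "case_id", "age", "sex", "side", "height", "weight", "bmi",
    "mechanism", "ao_class",
]


def write_cohort_table(records: Sequence[CaseRecord], path: str | Path,
                       extra: pd.DataFrame | None = None,
                       metadata: dict | None = None) -> Path:
    """Write case records (plus optional per-case metric columns) as CSV."""
    path = Path(path)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if extra is not None:
        df = pd.concat([df.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    with open(path, "w", newline="") as fh:
        for key, value in sorted((metadata or {}).items()):
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
    return path


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV, validating categorical levels.

    Returns the full table (demographics plus any metric columns) so the
    statistics stage can consume fracture morphometrics when present.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty cohort table {path.name}", stacklevel=2)
        return pd.DataFrame(columns=_REQUIRED_COLUMNS)
    if df.empty:
        warnings.warn(f"empty cohort table {path.name}", stacklevel=2)
        return df
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    for col, levels in (
        ("sex", SEX_LEVELS), ("side", SIDE_LEVELS),
        ("mechanism", MECHANISM_LEVELS), ("ao_class", AO_LEVELS),
    ):
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"unknown {col} level {df[col].iloc[row]!r} in row {row} "
                f"(allowed: {levels})"
            )
    return df


def records_from_table(df: pd.DataFrame) -> list[CaseRecord]:
    fields = {f.name for f in dataclasses.fields(CaseRecord)}
    return [
        CaseRecord(**{k: v for k, v in row.items() if k in fields})
        for row in df.to_dict("records")
    ]


# ---------------------------------------------------------------------------
# JSON / metadata helpers
# ---------------------------------------------------------------------------

def write_json(obj: dict, path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    payload = dict(obj)
    if metadata:
        payload["_metadata"] = dict(sorted(metadata.items()))
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_metadata(config) -> dict:
    """Config hash + software version, embedded in every output file.

    The hash covers the scientific parameters only — the output path does not
    change what was computed."""
    import dataclasses

    payload = {k: v for k, v in dataclasses.asdict(config).items()
               if k != "out_dir"}
    digest = hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()[:12]
    return {"config_sha256": digest, "fracmap_version": __version__}
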