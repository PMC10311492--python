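"""Fracture-line and comminution mapping onto the template surface.

Fracture interfaces are pairs of face-adjacent voxels with differing fragment
labels (6-connectivity: 26-adjacency would inflate interfaces at corners).
Where an interface meets the outer cortex it traces the fracture line; those
points, and the outer surfaces of comminuted fragments, are projected to their
nearest template vertices. Per-case vertex sets are dilated by a small surface
radius (hand-traced curves have width), then accumulated into per-vertex
frequency maps: each case contributes at most one count per vertex, and
frequency = 100 x count / n_cases.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import LabeledVolume, TemplateMesh
from .reduction import RigidTransform
from .synthetic import outer_surface_mask

logger = logging.getLogger("fracmap")

# color endpoints (RGB in [0,1]); zero frequency maps to the cool/light end
LINE_SCHEME = (np.array([0.0, 0.0, 0.545]), np.array([0.545, 0.0, 0.0]))  # dark blue -> dark red
COMMINUTION_SCHEME = (np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0]))  # white -> black


@dataclass
class FractureInterface:
    """6-adjacent voxel pairs with differing nonzero labels, plus the points
    where the interface meets the outer cortex (mm)."""

    pair_labels: np.ndarray        # (n, 2) distinct labels >= 1
    interface_mask: np.ndarray     # voxels participating in any pair
    surface_line_points: np.ndarray  # mm


@dataclass
class FrequencyMap:
    kind: str                  # "line" or "comminution"
    counts: np.ndarray         # per template vertex
    n_cases: int

    def __post_init__(self) -> None:
        if self.kind not in ("line", "comminution"):
            raise ValueError("kind must be 'line' or 'comminution'")
        self.counts = np.asarray(self.counts, dtype=int)
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.counts.min() < 0 or self.counts.max() > self.n_cases:
            raise ValueError("counts must lie in [0, n_cases]")

    @property
    def frequency(self) -> np.ndarray:
        """Percent frequency per vertex: 100 * count / n_cases."""
        return 100.0 * self.counts / self.n_cases


@dataclass
class ZoneExtent:
    threshold: float
    inferior_edge_to_joint_line: float  # mm
    superior_edge_to_joint_line: float  # mm
    sector: str

    @property
    def vertical_height(self) -> float:
        return self.superior_edge_to_joint_line - self.inferior_edge_to_joint_line


# ---------------------------------------------------------------------------
# surface and interface extraction
# ---------------------------------------------------------------------------

def extract_surface_mesh(volume: LabeledVolume, labels=None):
    """Triangulated outer surface of the selected labels (all bone by default),
    in mm coordinates — the per-case reconstructed fracture model."""
    import trimesh
    from skimage import measure

    grid = np.asarray(volume.labels)
    mask = grid > 0 if labels is None else np.isin(grid, labels)
    if not mask.any():
        raise ValueError("no voxels selected for surface extraction")
    padded = np.pad(mask, 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded.astype(np.uint8), level=0.5, spacing=volume.spacing)
    verts = verts + np.asarray(volume.origin) - np.asarray(volume.spacing)
    return trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=True)


def extract_interface(volume: LabeledVolume) -> FractureInterface:
    """Find all face-adjacent voxel pairs with differing nonzero labels.

    Surface line points are interface voxels that also lie on the outer cortex
    (6-adjacent to background), in mm coordinates.
    """
    labels = np.asarray(volume.labels)
    nonzero_labels = np.unique(labels[labels > 0])
    interface = np.zeros(labels.shape, dtype=bool)
    pairs = []
    if len(nonzero_labels) < 2:
        warnings.warn("single-label volume: empty fracture interface", stacklevel=2)
    else:
        for axis in range(3):
            a = np.take(labels, range(labels.shape[axis] - 1), axis=axis)
            b = np.take(labels, range(1, labels.shape[axis]), axis=axis)
            differ = (a > 0) & (b > 0) & (a != b)
            if not differ.any():
                continue
            pairs.append(np.stack([a[differ], b[differ]], axis=1))
            lo = np.zeros(labels.shape, dtype=bool)
            sl = [slice(None)] * 3
            sl[axis] = slice(0, labels.shape[axis] - 1)
            lo[tuple(sl)] = differ
            interface |= lo
            hi = np.zeros(labels.shape, dtype=bool)
            sl[axis] = slice(1, labels.shape[axis])
            hi[tuple(sl)] = differ
            interface |= hi
    pair_labels = (np.vstack(pairs) if pairs else np.empty((0, 2), dtype=labels.dtype))
    line_mask = interface & outer_surface_mask(labels)
    line_points = (np.argwhere(line_mask) * np.asarray(volume.spacing)
                   + np.asarray(volume.origin))
    return FractureInterface(pair_labels=pair_labels, interface_mask=interface,
                             surface_line_points=line_points)


# ---------------------------------------------------------------------------
# projection onto the template
# ---------------------------------------------------------------------------

def project_to_template(
    points_mm: np.ndarray,
    transform: RigidTransform,
    template: TemplateMesh,
    cutoff: float = 5.0,
    tree: cKDTree | None = None,
) -> tuple[np.ndarray, int]:
    """Map points (after the case-to-template transform) to nearest template
    vertices. Points farther than ``cutoff`` mm from the surface are discarded
    and counted. Returns (unique vertex indices, discard count)."""
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if points_mm.size == 0:
        return np.empty(0, dtype=int), 0
    moved = transform.apply(points_mm)
    if tree is None:
        tree = cKDTree(template.vertices)
    dist, idx = tree.query(moved)
    keep = dist <= cutoff
    discarded = int((~keep).sum())
    if discarded:
        logger.info("projection discarded %d/%d points beyond %.1f mm",
                    discarded, len(points_mm), cutoff)
    return np.unique(idx[keep]), discarded


def comminution_footprint(
    volume: LabeledVolume,
    comminuted_labels: list[int],
    transform: RigidTransform,
    template: TemplateMesh,
    cutoff: float = 5.0,
    tree: cKDTree | None = None,
) -> tuple[np.ndarray, int]:
    """Project the outer-surface voxels of the comminuted fragments onto the
    template. Empty label list yields an empty (valid) footprint."""
    if not comminuted_labels:
        return np.empty(0, dtype=int), 0
    labels = np.asarray(volume.labels)
    mask = np.isin(labels, comminuted_labels) & outer_surface_mask(labels)
    points = (np.argwhere(mask) * np.asarray(volume.spacing)
              + np.asarray(volume.origin))
    return project_to_template(points, transform, template, cutoff, tree=tree)


# ---------------------------------------------------------------------------
# frequency accumulation
# ---------------------------------------------------------------------------

def accumulate_frequency(
    case_vertex_sets: list[np.ndarray],
    n_cases: int,
    template: TemplateMesh,
    kind: str = "line",
    dilation_radius: float = 2.0,
) -> FrequencyMap:
    """Accumulate per-case vertex sets into a frequency map.

    Each case's set is dilated along the surface by ``dilation_radius``
    (Euclidean ball over template vertices — adequate at mm radii) and then
    contributes a binary indicator, so a case adds at most 1 to any vertex.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    verts = template.vertices
    counts = np.zeros(len(verts), dtype=int)
    tree = cKDTree(verts) if dilation_radius > 0 else None
    for i, vset in enumerate(case_vertex_sets):
        vset = np.asarray(vset, dtype=int)
        if vset.size == 0:
            continue
        if vset.min() < 0 or vset.max() >= len(verts):
            raise ValueError(f"case {i}: vertex index out of range")
        if dilation_radius > 0:
            hit = tree.query_ball_point(verts[vset], r=dilation_radius)
            vset = np.unique(np.concatenate([np.concatenate(hit), vset]))
        indicator = np.zeros(len(verts), dtype=bool)
        indicator[vset] = True
        counts += indicator
    return FrequencyMap(kind=kind, counts=counts, n_cases=n_cases)


def colorize(freq_map: FrequencyMap, scheme: str | None = None) -> np.ndarray:
    """Per-vertex RGB in [0,1].

    Line maps run linearly dark blue (0) to dark red (map max); comminution
    maps run white to black. Normalization is to the map's own maximum
    (relative scale); an all-zero map is uniformly the cool/light endpoint.
    """
    scheme = scheme or freq_map.kind
    lo, hi = LINE_SCHEME if scheme == "line" else COMMINUTION_SCHEME
    freq = freq_map.frequency
    fmax = freq.max()
    if fmax == 0:
        warnings.warn("all-zero frequency map: uniform color", stacklevel=2)
        return np.tile(lo, (len(freq), 1))
    t = (freq / fmax)[:, None]
    return lo * (1 - t) + hi * t


def measure_zone_extent(
    freq_map: FrequencyMap,
    threshold: float,
    template: TemplateMesh,
    sector: str = "all",
) -> ZoneExtent:
    """Extent of the supra-threshold heat zone within an anatomical sector.

    Extents are signed distances along the superior axis from the joint-line
    plane to the lowest/highest supra-threshold vertex. Sectors are half-space
    or quadrant proxies about the template axes: 'medial', 'lateral',
    'anterior', 'posterior', combinations like 'anteromedial', or 'all'.
    """
    verts = template.vertices
    hot = freq_map.frequency > threshold
    if sector != "all":
        rel = verts - template.joint_plane_point
        med = rel @ template.medial
        ant = rel @ template.anterior
        mask = np.ones(len(verts), dtype=bool)
        s = sector.lower()
        if "medial" in s:
            mask &= med > 0
        if "lateral" in s:
            mask &= med < 0
        if "antero" in s or s == "anterior":
            mask &= ant > 0
        if "postero" in s or s == "posterior":
            mask &= ant < 0
        hot &= mask
    if not hot.any():
        raise ValueError(f"empty zone: no vertex above {threshold}% in sector "
                         f"{sector!r}")
    heights = template.height_above_joint(verts[hot])
    return ZoneExtent(
        threshold=threshold,
        inferior_edge_to_joint_line=float(heights.min()),
        superior_edge_to_joint_line=float(heights.max()),
        sector=sector,
    )
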