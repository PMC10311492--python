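"""Synthetic distal-femur fracture material with known ground truth.

Patient CTs behind the original cohort are not publicly deposited, so the
pipeline ships a stylized phantom generator in their place: a watertight
distal-femur-like solid (cylindrical shaft flaring into two superellipsoid
condyles separated by an intercondylar notch wedge), fractured by parametrized
cut surfaces into labeled voxel partitions.

Two fracture archetypes are produced:

* extra-articular supracondylar patterns ("33A"): one or two oblique
  metaphyseal cuts running medial-superior to lateral-inferior, with optional
  comminution carved on the lateral/anterior/posterior supracondylar cortex;
* complete articular patterns ("33C"): supracondylar cut(s) plus a
  near-sagittal intercondylar split reaching the articular surface, forming a
  "Y", with comminution carved anteromedially.

Every case records its ground truth — fragment volumes, fracture-line points on
the outer cortex, comminution surface points, and any planted displacement —
so downstream recovery error is measurable in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .io import CaseRecord, LabeledVolume, TemplateMesh
from .reduction import RigidTransform

logger = logging.getLogger("fracmap")


# ---------------------------------------------------------------------------
# phantom specification and template construction
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Dimensions of the stylized distal femur (all mm).

    Defaults mirror the reference template bone: 439 mm total length and 82 mm
    maximum inter-condylar width.
    """

    total_length: float = 439.0
    condylar_width: float = 82.0
    shaft_radius: float = 16.0
    voxel_spacing: float = 1.0
    notch_depth: float = 10.0

    def __post_init__(self) -> None:
        for name in ("total_length", "condylar_width", "shaft_radius",
                     "voxel_spacing", "notch_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid phantom spec: {name} must be positive")
        if self.condylar_width <= 2 * self.shaft_radius:
            raise ValueError(
                "invalid phantom spec: condylar_width must exceed twice the "
                "shaft radius")
        if self.voxel_spacing > 2.0:
            raise ValueError("invalid phantom spec: voxel_spacing must be <= 2 mm")


def _phantom_mask(spec: PhantomSpec):
    """Binary solid on a voxel grid. Frame: joint line at z = 0, superior +z,
    anterior +y, medial +x (left femur)."""
    sp = spec.voxel_spacing
    W, L, r_s, nd = (spec.condylar_width, spec.total_length,
                     spec.shaft_radius, spec.notch_depth)
    # condyles: two superellipsoids tangent to z=0, spanning x in [-W/2, W/2]
    Rx, Ry, Rz = 0.28 * W, 0.35 * W, 0.30 * W
    xc = W / 2 - Rx
    zc = Rz
    # metaphyseal cone from radius R1 at the condyle equator to the shaft
    R1 = 0.40 * W
    z1 = zc
    z2 = min(zc + 0.6 * W, 0.5 * L)
    notch_halfwidth = 0.11 * W

    half_x = W / 2 + 2 * sp
    half_y = max(Ry, R1) + 2 * sp
    x = np.arange(-np.ceil(half_x / sp), np.ceil(half_x / sp) + 1) * sp
    y = np.arange(-np.ceil(half_y / sp), np.ceil(half_y / sp) + 1) * sp
    z = np.arange(-2, int(np.floor(L / sp)) + 3) * sp

    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    n_exp = 2.5
    condyles = np.zeros((len(x), len(y), len(z)), dtype=bool)
    # medial condyle (+x on a left femur) is slightly larger, as in anatomy;
    # the asymmetry also makes the side of a case geometrically meaningful
    for cx, ry, rz in ((-xc, Ry, Rz), (xc, 1.10 * Ry, 1.12 * Rz)):
        condyles |= (
            np.abs((X - cx) / Rx) ** n_exp
            + np.abs(Y / ry) ** n_exp
            + np.abs((Z - rz) / rz) ** n_exp
        ) <= 1.0
    r2 = X**2 + Y**2
    cone_r = R1 + (r_s - R1) * np.clip((Z - z1) / (z2 - z1), 0.0, 1.0)
    shaft = (r2 <= cone_r**2) & (Z >= z1) & (Z <= L)
    solid = condyles | shaft
    notch = (np.abs(X) <= notch_halfwidth) & (Z <= nd)
    solid &= ~notch
    origin = (float(x[0]), float(y[0]), float(z[0]))
    return solid, origin


def make_template(spec: PhantomSpec | None = None) -> tuple[TemplateMesh, LabeledVolume]:
    """Build the template phantom: a watertight surface mesh plus its
    voxelization, with the joint-line plane at the distal condylar tangent and
    the superior axis along the shaft."""
    spec = spec or PhantomSpec()
    solid, origin = _phantom_mask(spec)
    sp = spec.voxel_spacing
    verts, faces, _, _ = measure.marching_cubes(
        solid.astype(np.uint8), level=0.5, spacing=(sp, sp, sp))
    verts = verts + np.asarray(origin)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces[:, ::-1], process=True)
    template = TemplateMesh(
        mesh=mesh,
        joint_plane_point=np.zeros(3),
        joint_plane_normal=np.array([0.0, 0.0, 1.0]),
        axes=np.array([[0.0, 0.0, 1.0],   # superior
                       [0.0, 1.0, 0.0],   # anterior
                       [1.0, 0.0, 0.0]]), # medial (left femur)
        side="left",
    )
    volume = LabeledVolume(labels=solid.astype(np.int16), spacing=(sp, sp, sp),
                           origin=origin)
    return template, volume


# ---------------------------------------------------------------------------
# fracture plans
# ---------------------------------------------------------------------------

@dataclass
class CutSurface:
    """A fracture surface: a plane with optional low-amplitude sinusoidal
    roughness, optionally active only below ``max_height`` mm above the joint
    line (used for intercondylar splits that must not continue up the shaft)."""

    point: np.ndarray
    normal: np.ndarray
    roughness_amplitude: float = 1.0
    roughness_wavelength: float = 40.0
    phase: float = 0.0
    max_height: float | None = None

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)

    def tangent(self) -> np.ndarray:
        ref = np.array([1.0, 0.0, 0.0])
        if abs(self.normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        t = np.cross(self.normal, ref)
        return t / np.linalg.norm(t)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d = (pts - self.point) @ self.normal
        if self.roughness_amplitude > 0:
            u = (pts - self.point) @ self.tangent()
            d = d + self.roughness_amplitude * np.sin(
                2 * np.pi * u / self.roughness_wavelength + self.phase)
        return d


@dataclass
class FracturePlan:
    ao_class: str
    cuts: list[CutSurface]
    comminution_region: tuple[np.ndarray, np.ndarray] | None = None  # (lo, hi) mm
    n_comminuted: int = 0
    comminuted_volume_targets: list[float] = field(default_factory=list)
    displacements: dict[int, RigidTransform] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ao_class not in ("33A", "33C"):
            raise ValueError("ao_class must be 33A or 33C")
        if self.n_comminuted != len(self.comminuted_volume_targets):
            raise ValueError("one volume target per comminuted fragment required")
        if self.ao_class == "33C" and not any(
                c.max_height is not None and abs(c.normal[2]) < 0.5
                for c in self.cuts):
            raise ValueError(
                "33C plans need a near-sagittal intercondylar cut reaching the "
                "articular surface")


@dataclass
class GroundTruth:
    fragment_volumes: dict[int, float]           # cm^3, pre-displacement partition
    line_points_mm: np.ndarray                   # fracture lines on outer cortex
    comminution_points_mm: np.ndarray            # comminuted outer-surface voxels
    comminuted_labels: list[int]
    displacements: dict[int, RigidTransform]     # planted (forward) transforms
    phantom_volume_cm3: float


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def outer_surface_mask(labels: np.ndarray) -> np.ndarray:
    """Bone voxels 6-adjacent to background (including the grid border)."""
    bone = labels > 0
    interior = ndimage.binary_erosion(bone, structure=_FACE_STRUCT, border_value=0)
    return bone & ~interior


def simulate_fracture(
    phantom: LabeledVolume, plan: FracturePlan
) -> tuple[LabeledVolume, GroundTruth]:
    """Partition the phantom's bone voxels into fracture fragments.

    Cut surfaces induce a sign code per voxel; each nonempty code becomes a
    fragment. Comminution is carved inside the plan's region by a seeded,
    capacity-constrained nearest-seed subdivision, hitting each volume target
    within 10%. Displaced fragments are rigidly resampled and the planted
    transforms recorded.
    """
    labels = np.asarray(phantom.labels)
    bone = labels > 0
    if not bone.any():
        raise ValueError("phantom has no bone voxels")
    if len(np.unique(labels[bone])) != 1:
        raise ValueError("phantom must carry a single bone label")
    sp = np.asarray(phantom.spacing)
    voxvol = phantom.voxel_volume_mm3
    rng = np.random.default_rng(plan.seed)

    idx = np.argwhere(bone)
    coords = idx * sp + np.asarray(phantom.origin)

    # sign code per voxel: base-3 digit per cut (0 = cut inactive there)
    code = np.zeros(len(coords), dtype=np.int64)
    for i, cut in enumerate(plan.cuts):
        s = cut.signed_distance(coords)
        digit = np.where(s >= 0, 2, 1)
        if cut.max_height is not None:
            digit = np.where(coords[:, 2] > cut.max_height, 0, digit)
        code += digit * (3 ** i)
    uniq = np.unique(code)
    frag_of_voxel = np.searchsorted(uniq, code) + 1  # labels 1..K

    out = np.zeros_like(labels, dtype=np.int16)
    out[tuple(idx.T)] = frag_of_voxel
    next_label = len(uniq) + 1

    comminuted_labels: list[int] = []
    if plan.n_comminuted > 0:
        if plan.comminution_region is None:
            raise ValueError("comminution requested without a region")
        lo, hi = (np.asarray(b, dtype=float) for b in plan.comminution_region)
        in_region = np.all((coords >= lo) & (coords <= hi), axis=1)
        region_idx = np.flatnonzero(in_region)
        if region_idx.size == 0:
            raise ValueError("comminution region contains no bone voxels")
        targets_vox = [max(1, int(round(t * 1000.0 / voxvol)))
                       for t in plan.comminuted_volume_targets]
        if sum(targets_vox) > region_idx.size:
            raise ValueError(
                f"volume targets ({sum(targets_vox)} voxels) infeasible for "
                f"region size ({region_idx.size} voxels)")
        region_pts = coords[region_idx]
        # farthest-point seeding for well-separated pieces
        seeds = [region_pts[rng.integers(region_pts.shape[0])]]
        for _ in range(plan.n_comminuted - 1):
            d = np.min(
                np.linalg.norm(region_pts[:, None, :] - np.array(seeds)[None], axis=2),
                axis=1)
            seeds.append(region_pts[int(np.argmax(d))])
        taken = np.zeros(region_idx.size, dtype=bool)
        for seed_pt, tv in zip(seeds, targets_vox):
            d = np.linalg.norm(region_pts - seed_pt, axis=1)
            d[taken] = np.inf
            pick = np.argsort(d, kind="stable")[:tv]
            taken[pick] = True
            vox = idx[region_idx[pick]]
            out[tuple(vox.T)] = next_label
            comminuted_labels.append(next_label)
            next_label += 1

    # ground truth fracture lines: outer-cortex voxels on a cut surface
    surface = outer_surface_mask(out)
    surf_coords = np.argwhere(surface) * sp + np.asarray(phantom.origin)
    tol = float(np.max(sp))
    on_line = np.zeros(len(surf_coords), dtype=bool)
    for cut in plan.cuts:
        near = np.abs(cut.signed_distance(surf_coords)) <= tol
        if cut.max_height is not None:
            near &= surf_coords[:, 2] <= cut.max_height
        on_line |= near
    line_points = surf_coords[on_line]

    comm_points = np.empty((0, 3))
    if comminuted_labels:
        comm_mask = np.isin(out, comminuted_labels) & surface
        comm_points = np.argwhere(comm_mask) * sp + np.asarray(phantom.origin)

    counts = np.bincount(out.ravel(), minlength=next_label)
    fragment_volumes = {lab: counts[lab] * voxvol / 1000.0
                        for lab in range(1, next_label) if counts[lab] > 0}
    gt = GroundTruth(
        fragment_volumes=fragment_volumes,
        line_points_mm=line_points,
        comminution_points_mm=comm_points,
        comminuted_labels=comminuted_labels,
        displacements={lab: plan.displacements.get(lab, RigidTransform.identity())
                       for lab in fragment_volumes},
        phantom_volume_cm3=float(bone.sum()) * voxvol / 1000.0,
    )

    volume = LabeledVolume(labels=out, spacing=phantom.spacing, origin=phantom.origin)
    if any(not np.allclose(t.rotation, np.eye(3)) or np.any(t.translation != 0)
           for t in plan.displacements.values()):
        volume = _apply_displacements(volume, plan.displacements)
    return volume, gt


def _apply_displacements(volume: LabeledVolume,
                         transforms: dict[int, RigidTransform]) -> LabeledVolume:
    """Rigidly move fragment voxels (nearest-voxel resampling on a padded grid)."""
    labels = volume.labels
    sp = np.asarray(volume.spacing)
    pad = int(np.ceil(max(
        (np.linalg.norm(t.translation) for t in transforms.values()), default=0.0
    ) / sp.min())) + 3
    padded = np.pad(labels, pad)
    origin = np.asarray(volume.origin) - pad * sp
    out = np.zeros_like(padded)
    for lab in np.unique(labels[labels > 0]):
        t = transforms.get(int(lab), RigidTransform.identity())
        src = np.argwhere(padded == lab)
        if np.allclose(t.rotation, np.eye(3)) and not np.any(t.translation):
            out[tuple(src.T)] = lab
            continue
        src_mm = src * sp + origin
        lo = np.floor((t.apply(src_mm).min(0) - origin) / sp).astype(int) - 1
        hi = np.ceil((t.apply(src_mm).max(0) - origin) / sp).astype(int) + 2
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, padded.shape)
        grid = np.argwhere(np.ones(tuple(hi - lo), dtype=bool)) + lo
        back = t.inverse().apply(grid * sp + origin)
        back_idx = np.round((back - origin) / sp).astype(int)
        ok = np.all((back_idx >= 0) & (back_idx < padded.shape), axis=1)
        hit = np.zeros(len(grid), dtype=bool)
        hit[ok] = padded[tuple(back_idx[ok].T)] == lab
        out[tuple(grid[hit].T)] = lab
    return LabeledVolume(labels=out, spacing=volume.spacing,
                         origin=tuple(origin))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class DemographicsConfig:
    """Class-conditional demographic distributions (defaults emulate the study
    cohort: bimodal age, slight male excess in the articular class, slips and
    vehicle accidents dominating the mechanisms)."""

    p_male: dict = field(default_factory=lambda: {"33A": 25 / 53, "33C": 15 / 21})
    p_left: dict = field(default_factory=lambda: {"33A": 29 / 53, "33C": 13 / 21})
    p_mechanism: dict = field(default_factory=lambda: {
        "33A": {"MVA": 13 / 53, "slip": 31 / 53, "fall": 5 / 53, "crushing": 4 / 53},
        "33C": {"MVA": 8 / 21, "slip": 7 / 21, "fall": 5 / 21, "crushing": 1 / 21},
    })
    # bimodal age: young high-energy mode + elderly low-energy mode
    age_modes: tuple = ((40.0, 12.0, 0.30), (68.0, 9.0, 0.70))  # (mean, sd, weight)
    age_range: tuple = (18.0, 92.0)
    height_mean_sd: tuple = (1.68, 0.08)
    bmi_mean_sd: dict = field(default_factory=lambda: {
        "33A": (24.2, 3.1), "33C": (23.3, 3.0)})


@dataclass
class FracturePlanConfig:
    """Class-conditional fracture-morphology distributions.

    Chosen once to emulate the study's fracture characteristics: supracondylar
    cut heights in the metaphysis, oblique line orientations (medial-superior
    to lateral-inferior for the extra-articular class, the opposite and
    shallower for the articular class), comminution prevalence 33/53 vs 8/21,
    and sub-cm^3 comminuted fragment volumes whose per-case means straddle the
    published 0.14 vs 0.27 cm^3 class averages.
    """

    p_comminution: dict = field(default_factory=lambda: {
        "33A": 33 / 53, "33C": 8 / 21})
    n_comminuted_poisson: dict = field(default_factory=lambda: {
        "33A": 0.6, "33C": 6.0})  # n = 1 + Poisson(lam) when comminuted
    volume_range: dict = field(default_factory=lambda: {
        "33A": (0.05, 0.40), "33C": (0.35, 0.95)})  # cm^3, all < 1
    cut_height_range: tuple = (45.0, 75.0)  # mm above joint line
    obliquity_deg: dict = field(default_factory=lambda: {
        "33A": (15.0, 35.0), "33C": (5.0, 20.0)})
    p_second_cut: float = 0.5
    roughness_amplitude: float = 1.0


@dataclass
class SimulatedCase:
    volume: LabeledVolume
    ground_truth: GroundTruth
    record: CaseRecord
    plan: FracturePlan


def _draw_record(case_id: str, ao_class: str, demo: DemographicsConfig,
                 rng: np.random.Generator) -> CaseRecord:
    sex = "male" if rng.random() < demo.p_male[ao_class] else "female"
    side = "left" if rng.random() < demo.p_left[ao_class] else "right"
    mechs = list(demo.p_mechanism[ao_class].items())
    mech = mechs[rng.choice(len(mechs), p=[p for _, p in mechs])][0]
    modes = demo.age_modes
    k = rng.choice(len(modes), p=[m[2] for m in modes])
    age = float(np.clip(rng.normal(modes[k][0], modes[k][1]), *demo.age_range))
    height = float(np.clip(rng.normal(*demo.height_mean_sd), 1.45, 1.95))
    bmi = float(np.clip(rng.normal(*demo.bmi_mean_sd[ao_class]), 15.0, 40.0))
    weight = round(bmi * height**2, 1)
    return CaseRecord(case_id=case_id, age=round(age, 1), sex=sex, side=side,
                      height=round(height, 2), weight=weight,
                      bmi=weight / round(height, 2) ** 2, mechanism=mech,
                      ao_class=ao_class)


def draw_plan(ao_class: str, spec: PhantomSpec, rng: np.random.Generator,
              fracture_config: FracturePlanConfig | None = None,
              line_anchor: np.ndarray | None = None) -> FracturePlan:
    """Draw a class-conditional fracture plan.

    ``line_anchor`` forces every cut plane through a given mm point (used for
    planted-hotspot recovery experiments).
    """
    fc = fracture_config or FracturePlanConfig()
    W = spec.condylar_width
    lo, hi = fc.cut_height_range
    z0 = float(rng.uniform(lo, min(hi, 0.45 * spec.total_length)))
    theta = np.deg2rad(rng.uniform(*fc.obliquity_deg[ao_class]))
    # 33A: medial-superior -> lateral-inferior; 33C: the opposite, shallower
    sign = 1.0 if ao_class == "33A" else -1.0
    tilt2 = np.deg2rad(rng.uniform(-8, 8))
    normal = np.array([sign * np.sin(theta), np.sin(tilt2), np.cos(theta)])
    point = np.array([0.0, 0.0, z0])
    if line_anchor is not None:
        point = np.asarray(line_anchor, dtype=float)
        z0 = float(point[2])
    cuts = [CutSurface(point=point, normal=normal,
                       roughness_amplitude=fc.roughness_amplitude,
                       phase=float(rng.uniform(0, 2 * np.pi)))]
    if rng.random() < fc.p_second_cut:
        dz = float(rng.uniform(12, 22))
        cuts.append(CutSurface(
            point=point + np.array([0.0, 0.0, dz]), normal=normal,
            roughness_amplitude=fc.roughness_amplitude,
            phase=float(rng.uniform(0, 2 * np.pi))))
    if ao_class == "33C":
        sag_normal = np.array([np.cos(np.deg2rad(rng.uniform(-10, 10))),
                               np.sin(np.deg2rad(rng.uniform(-10, 10))), 0.0])
        cuts.append(CutSurface(
            point=np.array([float(rng.uniform(-3, 3)), 0.0, 0.0]),
            normal=sag_normal, roughness_amplitude=fc.roughness_amplitude,
            phase=float(rng.uniform(0, 2 * np.pi)), max_height=z0))

    comminuted = rng.random() < fc.p_comminution[ao_class]
    region = None
    n_comm = 0
    targets: list[float] = []
    if comminuted:
        n_comm = 1 + int(rng.poisson(fc.n_comminuted_poisson[ao_class]))
        targets = [float(rng.uniform(*fc.volume_range[ao_class]))
                   for _ in range(n_comm)]
        half_z = 16.0
        if ao_class == "33C":
            # anteromedial metaphysis
            region = (np.array([0.0, 0.0, z0 - half_z]),
                      np.array([0.6 * W, 0.6 * W, z0 + half_z]))
        else:
            sector = ["lateral", "anterior", "posterior"][rng.choice(3)]
            if sector == "lateral":
                region = (np.array([-0.6 * W, -0.6 * W, z0 - half_z]),
                          np.array([0.0, 0.6 * W, z0 + half_z]))
            elif sector == "anterior":
                region = (np.array([-0.6 * W, 0.0, z0 - half_z]),
                          np.array([0.6 * W, 0.6 * W, z0 + half_z]))
            else:
                region = (np.array([-0.6 * W, -0.6 * W, z0 - half_z]),
                          np.array([0.6 * W, 0.0, z0 + half_z]))
    return FracturePlan(ao_class=ao_class, cuts=cuts, comminution_region=region,
                        n_comminuted=n_comm, comminuted_volume_targets=targets,
                        seed=int(rng.integers(2**31 - 1)))


def simulate_cohort(
    n_33A: int,
    n_33C: int,
    demographics: DemographicsConfig | None = None,
    seed: int = 0,
    spec: PhantomSpec | None = None,
    fracture_config: FracturePlanConfig | None = None,
    phantom: LabeledVolume | None = None,
    line_anchor: np.ndarray | None = None,
) -> list[SimulatedCase]:
    """Simulate a cohort of fractured phantoms with demographics.

    Deterministic given ``seed``. Per-case fracture plans are drawn from
    class-conditional distributions; case records carry sex/side/age/mechanism
    drawn from the demographics config.
    """
    if n_33A < 0 or n_33C < 0:
        raise ValueError("cohort counts must be >= 0")
    spec = spec or PhantomSpec()
    demo = demographics or DemographicsConfig()
    if phantom is None:
        _, phantom = make_template(spec)
    rng = np.random.default_rng(seed)
    cases = []
    classes = ["33A"] * n_33A + ["33C"] * n_33C
    for i, ao in enumerate(classes):
        case_id = f"case_{i + 1:03d}"
        plan = draw_plan(ao, spec, rng, fracture_config, line_anchor=line_anchor)
        volume, gt = simulate_fracture(phantom, plan)
        record = _draw_record(case_id, ao, demo, rng)
        if record.side == "right":
            volume, gt = _mirror_case(volume, gt)
        cases.append(SimulatedCase(volume=volume, ground_truth=gt,
                                   record=record, plan=plan))
        logger.info("simulated %s (%s): %d fragments, %d comminuted",
                    case_id, ao, len(gt.fragment_volumes), len(gt.comminuted_labels))
    return cases


def _mirror_case(volume: LabeledVolume,
                 gt: GroundTruth) -> tuple[LabeledVolume, GroundTruth]:
    """Mirror a simulated case about the mid-sagittal plane (x -> -x).

    The phantom grid's x axis is symmetric about 0, so flipping the label array
    along axis 0 is an exact voxel-level reflection."""
    flipped = LabeledVolume(labels=np.ascontiguousarray(np.flip(volume.labels, 0)),
                            spacing=volume.spacing, origin=volume.origin)

    def refl(pts):
        if pts.size == 0:
            return pts
        out = pts.copy()
        out[:, 0] = -out[:, 0]
        return out

    gt = GroundTruth(
        fragment_volumes=gt.fragment_volumes,
        line_points_mm=refl(gt.line_points_mm),
        comminution_points_mm=refl(gt.comminution_points_mm),
        comminuted_labels=gt.comminuted_labels,
        displacements=gt.displacements,
        phantom_volume_cm3=gt.phantom_volume_cm3,
    )
    return flipped, gt


# ---------------------------------------------------------------------------
# lightweight cohort tables (statistics-stage experiments)
# ---------------------------------------------------------------------------

def simulate_cohort_table(
    n_33A: int,
    n_33C: int,
    seed: int = 0,
    fragment_count_means: tuple[float, float] = (3.96, 8.24),
    p_comminution: tuple[float, float] = (33 / 53, 8 / 21),
    comminuted_volume_means: tuple[float, float] = (0.22, 0.70),
    demographics: DemographicsConfig | None = None,
):
    """Draw a cohort table (demographics + fracture morphometrics) directly
    from class-conditional distributions, without voxel simulation.

    Used for statistical experiments that need many replicate cohorts — null
    calibration and power checks — where voxel-level detail is irrelevant.
    Setting both classes' parameters equal yields a null cohort.
    """
    import pandas as pd

    demo = demographics or DemographicsConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for ao, n, fmean, pc, vmean in (
        ("33A", n_33A, fragment_count_means[0], p_comminution[0],
         comminuted_volume_means[0]),
        ("33C", n_33C, fragment_count_means[1], p_comminution[1],
         comminuted_volume_means[1]),
    ):
        for i in range(n):
            rec = _draw_record(f"{ao}_{i + 1:03d}", ao, demo, rng)
            n_frag = 2 + int(rng.poisson(max(fmean - 2.0, 0.05)))
            comm = rng.random() < pc
            n_comm = int(np.clip(rng.poisson(2.0), 1, n_frag - 1)) if comm else 0
            vol = float(np.clip(rng.normal(vmean, 0.2), 0.02, 0.99)) if comm else 0.0
            row = rec.__dict__ | {
                "n_fragments": n_frag + n_comm,
                "has_comminution": comm,
                "n_comminuted": n_comm,
                "mean_comminuted_volume": vol,
            }
            rows.append(row)
    return pd.DataFrame(rows)
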