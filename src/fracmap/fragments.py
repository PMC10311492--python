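"""Per-case fragment quantification: labeling, volumes, comminution.

A fragment's volume is its voxel count times the voxel volume; fragments
strictly below the comminution threshold (1 cm^3 by definition) form the
comminution zone. The per-case mean comminuted volume averages comminuted
fragments only; cases without comminution carry a zero into cohort summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import LabeledVolume

logger = logging.getLogger("fracmap")

COMMINUTION_THRESHOLD_CM3 = 1.0
NOISE_FLOOR_CM3 = 0.01


@dataclass
class Fragment:
    label: int
    voxel_count: int
    volume: float          # cm^3 = voxel_count * voxel volume (mm^3) / 1000
    centroid: np.ndarray   # mm
    is_comminuted: bool = False


@dataclass
class FragmentSet:
    fragments: list[Fragment]
    voxel_volume_mm3: float
    filtered_voxels: int = 0  # mass removed by the noise floor, for the log

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def n_comminuted(self) -> int:
        return sum(f.is_comminuted for f in self.fragments)

    @property
    def has_comminution(self) -> bool:
        return self.n_comminuted >= 1

    @property
    def mean_comminuted_volume(self) -> float:
        vols = [f.volume for f in self.fragments if f.is_comminuted]
        return float(np.mean(vols)) if vols else 0.0

    @property
    def total_volume(self) -> float:
        return float(sum(f.volume for f in self.fragments))

    @property
    def comminuted_labels(self) -> list[int]:
        return [f.label for f in self.fragments if f.is_comminuted]


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_fragments(volume: LabeledVolume, relabel: bool = False,
                    connectivity: int = 26,
                    noise_floor: float = NOISE_FLOOR_CM3) -> FragmentSet:
    """Extract fragments from a labeled volume.

    With ``relabel`` the nonzero mask is re-partitioned into connected
    components (26-connectivity by default, so thin oblique fragments stay
    connected); otherwise the input labels are trusted. Fragments below the
    noise floor (cm^3) are discarded and logged.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 6 or 26")
    labels = np.asarray(volume.labels)
    if not (labels > 0).any():
        raise ValueError("no bone voxels")
    if relabel:
        labels, _ = ndimage.label(labels > 0, structure=_STRUCTS[connectivity])
    voxvol = volume.voxel_volume_mm3
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)

    ids = np.unique(labels)
    ids = ids[ids > 0]
    counts = np.bincount(labels.ravel())
    centroids = ndimage.center_of_mass(labels > 0, labels, ids)

    fragments: list[Fragment] = []
    filtered = 0
    for lab, com in zip(ids, np.atleast_2d(centroids)):
        n = int(counts[lab])
        vol = n * voxvol / 1000.0
        if vol < noise_floor:
            filtered += n
            logger.info("discarding speck label %d (%.4f cm^3 < %.2f cm^3 floor)",
                        lab, vol, noise_floor)
            continue
        fragments.append(Fragment(
            label=int(lab), voxel_count=n, volume=vol,
            centroid=np.asarray(com) * spacing + origin))
    if not fragments:
        raise ValueError("no bone voxels above the noise floor")
    return FragmentSet(fragments=fragments, voxel_volume_mm3=voxvol,
                       filtered_voxels=filtered)


def classify_comminution(fragset: FragmentSet,
                         threshold: float = COMMINUTION_THRESHOLD_CM3) -> FragmentSet:
    """Flag fragments strictly below ``threshold`` cm^3 as comminution.

    The comparison is strict: a fragment of exactly the threshold volume is
    not comminuted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fragments = [replace(f, is_comminuted=f.volume < threshold)
                 for f in fragset.fragments]
    return FragmentSet(fragments=fragments,
                       voxel_volume_mm3=fragset.voxel_volume_mm3,
                       filtered_voxels=fragset.filtered_voxels)


def case_morphometrics(fragset: FragmentSet) -> dict:
    """Per-case metric row for the cohort table."""
    return {
        "n_fragments": fragset.n_fragments,
        "has_comminution": fragset.has_comminution,
        "n_comminuted": fragset.n_comminuted,
        "mean_comminuted_volume": fragset.mean_comminuted_volume,
    }
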