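"""Derive linear measurements from annotated landmark point pairs.

Each calliper measurement is a pair of 3-D points, either in world
millimetres (RAS) or in voxel indices; voxel-space pairs require the
voxel-to-world affine, normally read from a NIfTI-1 header (only the header
geometry is used — voxel intensities are never interpreted).

Landmarks are exchanged as JSON: a list of objects
``{"label": ..., "space": "voxel"|"world", "point_a": [x,y,z], "point_b": [x,y,z]}``.
Coplanarity with an axial slice is not enforced; a warning is logged when a
pair spans more than 2 mm in world z, since the measurements are defined on
single axial slices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DuplicateLandmarkError,
    InvalidAffineError,
    MissingAffineError,
    MissingLandmarkError,
    ValidationError,
)
from .measurements import LinearMeasurementSet

__all__ = [
    "LANDMARK_LABELS",
    "LandmarkPair",
    "measure_distance",
    "measurements_from_landmarks",
    "load_landmarks",
    "load_affine",
    "validate_affine",
]

logger = logging.getLogger(__name__)

#: landmark label -> LinearMeasurementSet field
LANDMARK_LABELS: Mapping[str, str] = {
    "FH": "fh_width",
    "OH": "oh_width",
    "TH": "th_width",
    "BIP_FH": "bip_at_fh",
    "BIP_OH": "bip_at_oh",
    "BIT": "bit_at_th",
    "CTW": "ctw",
    "SKULL_MRHI": "inner_skull_diameter",
    "SKULL_EI": "ei_skull_diameter",
}

_AXIAL_WARN_MM = 2.0


@dataclass(frozen=True)
class LandmarkPair:
    """One calliper measurement: two 3-D points and the space they live in."""

    label: str
    point_a: tuple[float, float, float]
    point_b: tuple[float, float, float]
    space: str = "world"

    def __post_init__(self) -> None:
        if self.label not in LANDMARK_LABELS:
            raise ValidationError(
                f"unknown landmark label {self.label!r}; "
                f"expected one of {', '.join(LANDMARK_LABELS)}"
            )
        if self.space not in ("voxel", "world"):
            raise ValidationError(f"space must be 'voxel' or 'world', got {self.space!r}")
        a = np.asarray(self.point_a, dtype=float)
        b = np.asarray(self.point_b, dtype=float)
        if a.shape != (3,) or b.shape != (3,):
            raise ValidationError(f"{self.label}: points must be 3-vectors")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError(f"{self.label}: non-finite point coordinates")
        if np.array_equal(a, b):
            raise ValidationError(f"{self.label}: the two points coincide")
        object.__setattr__(self, "point_a", tuple(a))
        object.__setattr__(self, "point_b", tuple(b))


def validate_affine(affine: np.ndarray) -> np.ndarray:
    """Check a 4x4 homogeneous voxel-to-world affine; return it as float array."""
    A = np.asarray(affine, dtype=float)
    if A.shape != (4, 4):
        raise InvalidAffineError(f"affine must be 4x4, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise InvalidAffineError("affine contains non-finite entries")
    if not np.allclose(A[3], [0.0, 0.0, 0.0, 1.0]):
        raise InvalidAffineError("affine bottom row must be (0, 0, 0, 1)")
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise InvalidAffineError("affine is singular")
    return A


def _to_world(point: Sequence[float], space: str, affine: np.ndarray | None) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if space == "world":
        return p
    if affine is None:
        raise MissingAffineError("voxel-space landmark pair requires a voxel-to-world affine")
    A = validate_affine(affine)
    return A[:3, :3] @ p + A[:3, 3]


def measure_distance(pair: LandmarkPair, affine: np.ndarray | None = None) -> float:
    """Euclidean distance between the pair's points, in world millimetres."""
    a = _to_world(pair.point_a, pair.space, affine)
    b = _to_world(pair.point_b, pair.space, affine)
    dz = abs(a[2] - b[2])
    if dz > _AXIAL_WARN_MM:
        logger.warning(
            "landmark %s spans %.2f mm in world z (> %g mm): measurement is "
            "oblique to the axial plane",
            pair.label,
            dz,
            _AXIAL_WARN_MM,
        )
    return float(np.linalg.norm(a - b))


def measurements_from_landmarks(
    pairs: Iterable[LandmarkPair], affine: np.ndarray | None = None
) -> LinearMeasurementSet:
    """Assemble a :class:`LinearMeasurementSet` from one pair per label.

    Every one of the nine labels must appear exactly once: a duplicate raises
    :class:`DuplicateLandmarkError`, missing labels raise
    :class:`MissingLandmarkError` listing all of them.
    """
    seen: dict[str, float] = {}
    for pair in pairs:
        if pair.label in seen:
            raise DuplicateLandmarkError(f"landmark label {pair.label!r} appears more than once")
        seen[pair.label] = measure_distance(pair, affine)
    missing = set(LANDMARK_LABELS) - set(seen)
    if missing:
        raise MissingLandmarkError(missing)
    return LinearMeasurementSet(
        **{field: seen[label] for label, field in LANDMARK_LABELS.items()}
    )


def load_landmarks(path: str | Path) -> list[LandmarkPair]:
    """Read landmark pairs from the JSON schema described in the module docstring."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ValidationError("landmarks JSON must be a list of objects")
    pairs = []
    for i, entry in enumerate(raw):
        try:
            pairs.append(
                LandmarkPair(
                    label=entry["label"],
                    point_a=tuple(entry["point_a"]),
                    point_b=tuple(entry["point_b"]),
                    space=entry.get("space", "world"),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"landmark entry {i}: malformed ({exc})") from exc
    return pairs


def load_affine(nifti_path: str | Path) -> np.ndarray:
    """Read the voxel-to-world (RAS mm) affine from a NIfTI-1 header."""
    import nibabel as nib

    img = nib.load(str(nifti_path))
    return validate_affine(img.affine)
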