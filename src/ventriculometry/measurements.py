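"""Linear brain measurements and the ventriculomegaly indexes computed from them.

Three dimensionless ratios quantify ventricular enlargement on axial images:

* **BLM** (brain linear measurement index): the cumulative ventricular ratio
  ``(FH + OH + TH) / (BIP@FH + BIP@OH + BIT)`` — summed widths of the frontal
  horns, occipital horns (at the atrium) and temporal horns (at the level of
  maximal hippocampal convexity), divided by the summed inner-table skull
  diameters measured on the same three levels (bi-parietal at the FH and OH
  levels, bi-temporal at the TH level).
* **MRHI** (magnetic resonance hydrocephalic index, equivalently the
  parieto-occipital ratio): collateral trigones width / inner skull diameter.
* **Evans' index**: maximal frontal-horn width / maximal internal skull
  diameter.

All lengths are millimetres; no unit inference is performed.  An index is
classified *pathological* under a strict inequality, ``value > cutoff``.
Two cutoff profiles ship by default: ``study`` (ROC-derived: BLM 0.285,
EI 0.280, MRHI 0.461) and ``literature`` (conventional: EI 0.300, MRHI 0.579;
no published BLM cutoff exists outside the study profile).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from types import MappingProxyType
from typing import Mapping

from .errors import InvalidMeasurementError, UnknownProfileError, ValidationError

__all__ = [
    "LinearMeasurementSet",
    "IndexPanel",
    "CutoffProfile",
    "CUTOFF_PROFILES",
    "get_cutoff_profile",
    "compute_blm",
    "compute_mrhi",
    "compute_ei",
    "build_index_panel",
    "INDEX_NAMES",
]

INDEX_NAMES = ("blm", "mrhi", "ei")

#: numerator width -> the diameter it must stay strictly below
_ORDERING = (
    ("fh_width", "bip_at_fh"),
    ("oh_width", "bip_at_oh"),
    ("th_width", "bit_at_th"),
    ("ctw", "inner_skull_diameter"),
    ("fh_width", "ei_skull_diameter"),
)


@dataclass(frozen=True)
class LinearMeasurementSet:
    """The nine linear measurements (mm) needed for BLM, MRHI and Evans' index.

    Attributes
    ----------
    fh_width, oh_width, th_width
        Widths of the frontal horns, occipital horns (at the atrium) and
        temporal horns (at maximal hippocampal convexity).
    bip_at_fh, bip_at_oh, bit_at_th
        Inner-table skull diameters on the same levels: bi-parietal at the FH
        and OH levels, bi-temporal at the TH level.
    ctw
        Collateral trigones width (MRHI numerator).
    inner_skull_diameter
        Inner skull diameter on the CTW slice (MRHI denominator).
    ei_skull_diameter
        Maximal internal skull diameter (Evans' denominator); carried
        separately because it need not equal ``bip_at_fh``.
    """

    fh_width: float
    oh_width: float
    th_width: float
    bip_at_fh: float
    bip_at_oh: float
    bit_at_th: float
    ctw: float
    inner_skull_diameter: float
    ei_skull_diameter: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise InvalidMeasurementError(f.name, f"not a number: {v!r}")
            v = float(v)
            object.__setattr__(self, f.name, v)
            if not math.isfinite(v):
                raise InvalidMeasurementError(f.name, f"non-finite value {v!r}")
            if v <= 0:
                raise InvalidMeasurementError(f.name, f"must be strictly positive, got {v}")
        for width, diameter in _ORDERING:
            if getattr(self, width) >= getattr(self, diameter):
                raise InvalidMeasurementError(
                    width,
                    f"ventricular width ({getattr(self, width)} mm) must be "
                    f"strictly smaller than {diameter} ({getattr(self, diameter)} mm)",
                )


@dataclass(frozen=True)
class IndexPanel:
    """The three index values with their pathological classifications."""

    blm: float
    mrhi: float
    ei: float
    blm_pathological: bool
    mrhi_pathological: bool
    ei_pathological: bool

    def value(self, index: str) -> float:
        return getattr(self, index)

    def pathological(self, index: str) -> bool:
        return getattr(self, f"{index}_pathological")


@dataclass(frozen=True)
class CutoffProfile:
    """A named set of per-index pathological cutoffs (strict ``>`` rule).

    ``None`` means the profile defines no cutoff for that index.
    """

    name: str
    blm: float | None = None
    mrhi: float | None = None
    ei: float | None = None

    def cutoff(self, index: str) -> float | None:
        return getattr(self, index)

    def indexes(self) -> tuple[str, ...]:
        return tuple(i for i in INDEX_NAMES if getattr(self, i) is not None)


CUTOFF_PROFILES: Mapping[str, CutoffProfile] = MappingProxyType(
    {
        "study": CutoffProfile("study", blm=0.285, ei=0.280, mrhi=0.461),
        "literature": CutoffProfile("literature", ei=0.300, mrhi=0.579),
    }
)


def get_cutoff_profile(name: str | CutoffProfile) -> CutoffProfile:
    """Resolve a profile by name, raising :class:`UnknownProfileError` otherwise."""
    if isinstance(name, CutoffProfile):
        return name
    try:
        return CUTOFF_PROFILES[name]
    except KeyError:
        raise UnknownProfileError(str(name), CUTOFF_PROFILES) from None


def compute_blm(m: LinearMeasurementSet) -> float:
    """Cumulative ventricular ratio (FH + OH + TH)/(BIP@FH + BIP@OH + BIT)."""
    return (m.fh_width + m.oh_width + m.th_width) / (
        m.bip_at_fh + m.bip_at_oh + m.bit_at_th
    )


def compute_mrhi(m: LinearMeasurementSet) -> float:
    """Collateral trigones width over inner skull diameter."""
    return m.ctw / m.inner_skull_diameter


def compute_ei(m: LinearMeasurementSet) -> float:
    """Evans' index: frontal-horn width over maximal internal skull diameter."""
    return m.fh_width / m.ei_skull_diameter


def build_index_panel(
    m: LinearMeasurementSet,
    cutoffs: CutoffProfile | Mapping[str, float] | str = "study",
) -> IndexPanel:
    """Compute all three indexes and classify each against its cutoff.

    Classification is strict: ``pathological = value > cutoff``; an index
    with no cutoff in the profile is classified ``False``.
    """
    if isinstance(cutoffs, Mapping):
        cutoffs = CutoffProfile("custom", **dict(cutoffs))
    profile = get_cutoff_profile(cutoffs)
    for idx in profile.indexes():
        c = profile.cutoff(idx)
        if not (isinstance(c, (int, float)) and math.isfinite(c) and c > 0):
            raise ValidationError(f"cutoff for {idx} must be positive and finite, got {c!r}")
    values = {"blm": compute_blm(m), "mrhi": compute_mrhi(m), "ei": compute_ei(m)}
    flags = {
        f"{idx}_pathological": (
            profile.cutoff(idx) is not None and values[idx] > profile.cutoff(idx)
        )
        for idx in INDEX_NAMES
    }
    return IndexPanel(**values, **flags)


def classify(value: float, cutoff: float) -> bool:
    """Strict pathological rule shared by every index: ``value > cutoff``."""
    return value > cutoff
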