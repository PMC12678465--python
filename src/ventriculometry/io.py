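"""CSV dialect for per-subject records.

UTF-8, comma-separated, header row.  Core columns, in order:

    subject_id, group, phenotype, age, sex,
    fh_width, oh_width, th_width, bip_at_fh, bip_at_oh, bit_at_th,
    ctw, inner_skull_diameter, ei_skull_diameter, desh, hummingbird

followed by the index columns ``blm, mrhi, ei`` (written always; on reading
they are optional — when measurements are present the indexes are recomputed
from them).  Empty cells are allowed for the optional columns (phenotype,
desh, hummingbird, measurements).  Any additional numeric column is carried
as a per-subject clinical score (e.g. UPDRS-ME, INPHGS, MMSE) and appears in
the group-comparison table.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import IncompleteRecordError, ValidationError
from .cohort import SubjectRecord
from .measurements import (
    INDEX_NAMES,
    IndexPanel,
    LinearMeasurementSet,
    build_index_panel,
)

__all__ = ["MEASUREMENT_COLUMNS", "CORE_COLUMNS", "write_cohort_csv", "read_cohort_csv"]

MEASUREMENT_COLUMNS = (
    "fh_width",
    "oh_width",
    "th_width",
    "bip_at_fh",
    "bip_at_oh",
    "bit_at_th",
    "ctw",
    "inner_skull_diameter",
    "ei_skull_diameter",
)

CORE_COLUMNS = (
    "subject_id",
    "group",
    "phenotype",
    "age",
    "sex",
    *MEASUREMENT_COLUMNS,
    "desh",
    "hummingbird",
)

_GROUPS = ("iNPH", "PSP")
_PHENOTYPES = ("PSP-RS", "PSP-P")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest round-tripping decimal
    return str(value)


def write_cohort_csv(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write records in the dialect above; float formatting round-trips exactly."""
    score_names = sorted({k for r in records for k in r.clinical_scores})
    columns = [*CORE_COLUMNS, *INDEX_NAMES, *score_names]
    lines = [",".join(columns)]
    for r in records:
        m = r.measurements
        row = [
            r.subject_id,
            r.group,
            r.phenotype or "",
            _fmt(r.age),
            r.sex,
            *(_fmt(getattr(m, c)) if m is not None else "" for c in MEASUREMENT_COLUMNS),
            _fmt(r.desh),
            _fmt(r.hummingbird),
            *(_fmt(r.indexes.value(i)) for i in INDEX_NAMES),
            *(_fmt(r.clinical_scores.get(s)) for s in score_names),
        ]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _opt_bool(cell) -> bool | None:
    if _isnan_str(cell):
        return None
    if isinstance(cell, bool):
        return cell
    s = str(cell).strip().lower()
    if s in ("true", "yes"):
        return True
    if s in ("false", "no"):
        return False
    try:
        f = float(s)
    except ValueError:
        f = None
    if f in (0.0, 1.0):
        return bool(f)
    raise ValidationError(f"boolean cell must be 0/1/true/false, got {cell!r}")


def _isnan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return True


def read_cohort_csv(
    path: str | Path, cutoff_profile: str = "study"
) -> list[SubjectRecord]:
    """Read a cohort CSV into :class:`SubjectRecord` objects.

    When a row carries a complete measurement set, the indexes are computed
    from it; otherwise the precomputed ``blm/mrhi/ei`` columns are used.  A
    row with neither raises :class:`IncompleteRecordError`.
    """
    df = pd.read_csv(
        path, dtype={"subject_id": str, "group": str}, float_precision="round_trip"
    )
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValidationError(f"cohort CSV missing required columns: {sorted(missing)}")
    known = set(CORE_COLUMNS) | set(INDEX_NAMES)
    score_names = [c for c in df.columns if c not in known]

    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        group = str(row["group"])
        if group not in _GROUPS:
            raise ValidationError(
                f"subject {row['subject_id']}: group must be one of {_GROUPS}, got {group!r}"
            )
        measurements = None
        m_cells = [row.get(c) for c in MEASUREMENT_COLUMNS]
        if all(not _isnan(c) for c in m_cells):
            measurements = LinearMeasurementSet(*(float(c) for c in m_cells))
            panel = build_index_panel(measurements, cutoff_profile)
        else:
            vals = {i: row.get(i) for i in INDEX_NAMES}
            if any(_isnan(v) for v in vals.values()):
                raise IncompleteRecordError(
                    f"subject {row['subject_id']}: neither a complete measurement "
                    "set nor precomputed blm/mrhi/ei values"
                )
            panel = IndexPanel(
                blm=float(vals["blm"]),
                mrhi=float(vals["mrhi"]),
                ei=float(vals["ei"]),
                blm_pathological=False,
                mrhi_pathological=False,
                ei_pathological=False,
            )
        phenotype = row.get("phenotype")
        phenotype = None if _isnan_str(phenotype) else str(phenotype)
        if phenotype is not None and phenotype not in _PHENOTYPES:
            raise ValidationError(
                f"subject {row['subject_id']}: phenotype must be one of "
                f"{_PHENOTYPES}, got {phenotype!r}"
            )
        scores = {
            s: float(row[s]) for s in score_names if not _isnan(row.get(s))
        }
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=group,
                phenotype=phenotype,
                age=float(row["age"]) if not _isnan(row.get("age")) else math.nan,
                sex=str(row.get("sex", "")),
                indexes=panel,
                measurements=measurements,
                desh=_opt_bool(row.get("desh")),
                hummingbird=_opt_bool(row.get("hummingbird")),
                clinical_scores=scores,
            )
        )
    return records


def _isnan_str(cell) -> bool:
    if cell is None or cell == "":
        return True
    if isinstance(cell, float) and math.isnan(cell):
        return True
    return False
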