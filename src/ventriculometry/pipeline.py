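"""End-to-end study orchestration.

`run_study` takes per-subject records and produces a :class:`StudyReport`
holding everything the diagnostic-accuracy workflow reports:

* a comparison table (age, sex, each index, any clinical scores) with the
  normality-gated test per variable;
* per-index ROC analysis with the Youden-optimal cutoff and the confusion
  metrics at that cutoff;
* per-index classification counts at the configured cutoff profile(s);
* per-index logistic regression of diagnosis on age, sex and the index;
* the PSP-phenotype subanalysis (iNPH vs PSP-RS and iNPH vs PSP-P on BLM).

The JSON serialization is a pure function of (records, options): identical
inputs give byte-identical reports.  The Markdown rendering rounds
percentages half-up to one decimal and prints p-values below 0.001 as
"< 0.001"; the JSON keeps full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .cohort import SubjectRecord
from .errors import (
    CollinearityError,
    ConvergenceError,
    DegenerateCohortError,
    DegenerateDataError,
    IncompleteRecordError,
    UnsupportedSizeError,
)
from .measurements import INDEX_NAMES, CutoffProfile, get_cutoff_profile
from .stats import (
    ComparisonResult,
    ConfusionMetrics,
    LogisticFit,
    ROCResult,
    chi_squared_proportions,
    compare_groups,
    confusion_metrics,
    logistic_fit,
    roc_curve,
    round_half_up,
)

__all__ = ["StudyReport", "run_study", "apply_external_cutoffs", "render_markdown"]

_SMALL_GROUP = 10  # below this, asymptotic p-values are flagged unreliable

INDEX_LABELS = {"blm": "BLM", "mrhi": "MRHI", "ei": "EI"}


@dataclass
class ClassificationRow:
    """Counts of pathological calls per arm for one index at one cutoff."""

    index: str
    cutoff: float
    n_inph_pathological: int
    n_inph: int
    n_psp_pathological: int
    n_psp: int
    metrics: ConfusionMetrics | None  # None when a margin is empty


@dataclass
class StudyReport:
    """Full study output; see the module docstring for contents."""

    n_inph: int
    n_psp: int
    comparisons: list[ComparisonResult]
    roc: dict[str, ROCResult]
    classification: dict[str, list[ClassificationRow]]  # profile name -> rows
    logistic: dict[str, LogisticFit | str]  # index -> fit, or failure message
    phenotype_comparisons: dict[str, ComparisonResult | str]
    warnings: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        return _jsonify(
            {
                "n_inph": self.n_inph,
                "n_psp": self.n_psp,
                "comparisons": [vars(c) for c in self.comparisons],
                "roc": {
                    k: {
                        "auc": r.auc,
                        "optimal_cutoff": r.optimal_cutoff,
                        "youden_j": r.youden_j,
                        "degenerate": r.degenerate,
                        "metrics_at_cutoff": _metrics_dict(r.metrics_at_cutoff),
                    }
                    for k, r in self.roc.items()
                },
                "classification": {
                    profile: [
                        {
                            "index": row.index,
                            "cutoff": row.cutoff,
                            "n_inph_pathological": row.n_inph_pathological,
                            "n_inph": row.n_inph,
                            "n_psp_pathological": row.n_psp_pathological,
                            "n_psp": row.n_psp,
                            "metrics": _metrics_dict(row.metrics),
                        }
                        for row in rows
                    ]
                    for profile, rows in self.classification.items()
                },
                "logistic": {
                    k: (
                        f
                        if isinstance(f, str)
                        else {
                            "names": list(f.names),
                            "coefficients": list(f.coefficients),
                            "standard_errors": list(f.standard_errors),
                            "wald_z": list(f.wald_z),
                            "p_values": list(f.p_values),
                            "converged": f.converged,
                            "separation_detected": f.separation_detected,
                            "n_iterations": f.n_iterations,
                        }
                    )
                    for k, f in self.logistic.items()
                },
                "phenotype_comparisons": {
                    k: (vars(c) if isinstance(c, ComparisonResult) else c)
                    for k, c in self.phenotype_comparisons.items()
                },
                "warnings": self.warnings,
                "provenance": self.provenance,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _metrics_dict(m: ConfusionMetrics | None) -> dict | None:
    if m is None:
        return None
    d = {
        "tp": m.tp,
        "fn": m.fn,
        "tn": m.tn,
        "fp": m.fp,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "accuracy": m.accuracy,
    }
    d.update(m.as_percent())
    return d


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _split(records: Sequence[SubjectRecord]):
    inph = [r for r in records if r.group == "iNPH"]
    psp = [r for r in records if r.group == "PSP"]
    if not inph or not psp:
        raise DegenerateCohortError("both iNPH and PSP subjects are required")
    return inph, psp


def _index_values(records: Sequence[SubjectRecord], index: str) -> np.ndarray:
    vals = []
    for r in records:
        if r.indexes is None:
            raise IncompleteRecordError(f"subject {r.subject_id}: no index panel")
        vals.append(r.indexes.value(index))
    return np.asarray(vals, dtype=float)


def _compare_or_note(a, b, variable: str, warnings_out: list[str]):
    """Normality-gated comparison, degrading gracefully below the Shapiro n=3 floor."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        from scipy import stats as sps

        stat, p = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        warnings_out.append(
            f"{variable}: group below n=3, normality gate skipped; "
            "Mann-Whitney p-value unreliable"
        )
        return ComparisonResult(
            variable=variable,
            summary_a=f"{a.mean():.3g}",
            summary_b=f"{b.mean():.3g}",
            test="mann_whitney",
            statistic=float(stat),
            p_value=float(p),
            normality_p=None,
            n_a=int(a.size),
            n_b=int(b.size),
        )
    return compare_groups(a, b, variable=variable)


def classification_row(
    records: Sequence[SubjectRecord], index: str, cutoff: float
) -> ClassificationRow:
    """Pathological-call counts per arm at one cutoff (strict value > cutoff)."""
    inph, psp = _split(records)
    v_inph = _index_values(inph, index)
    v_psp = _index_values(psp, index)
    tp = int((v_inph > cutoff).sum())
    fp = int((v_psp > cutoff).sum())
    fn, tn = len(inph) - tp, len(psp) - fp
    try:
        metrics = confusion_metrics(tp=tp, fn=fn, tn=tn, fp=fp)
    except DegenerateDataError:
        metrics = None
    return ClassificationRow(
        index=index,
        cutoff=float(cutoff),
        n_inph_pathological=tp,
        n_inph=len(inph),
        n_psp_pathological=fp,
        n_psp=len(psp),
        metrics=metrics,
    )


def apply_external_cutoffs(
    records: Sequence[SubjectRecord], profile: str | CutoffProfile
) -> list[ClassificationRow]:
    """Classification counts and metrics at a named cutoff profile.

    Typically used with the ``literature`` profile (MRHI > 0.579, EI > 0.300)
    to contrast externally derived cutoffs with the study-derived ones.
    """
    prof = get_cutoff_profile(profile)
    return [
        classification_row(records, index, prof.cutoff(index))
        for index in prof.indexes()
    ]


def run_study(
    records: Sequence[SubjectRecord],
    cutoff_profile: str | CutoffProfile = "study",
    extra_profiles: Sequence[str] = ("literature",),
    seed: int | None = None,
) -> StudyReport:
    """Run the full diagnostic-accuracy workflow on a cohort.

    Parameters
    ----------
    records
        Subject records with index panels (both groups present).
    cutoff_profile
        Profile whose cutoffs drive the primary classification table.
    extra_profiles
        Additional profiles reported alongside (default: ``literature``).
    seed
        Recorded in provenance only; the analysis itself is deterministic.
    """
    inph, psp = _split(records)
    warnings_out: list[str] = []
    if min(len(inph), len(psp)) < _SMALL_GROUP:
        warnings_out.append(
            f"smallest group has n={min(len(inph), len(psp))} < {_SMALL_GROUP}: "
            "asymptotic p-values are unreliable"
        )

    # --- comparison table: age, sex, indexes, clinical scores
    comparisons: list[ComparisonResult] = []
    comparisons.append(
        _compare_or_note(
            [r.age for r in inph], [r.age for r in psp], "age", warnings_out
        )
    )
    sex_table = [
        [sum(r.sex == "M" for r in inph), sum(r.sex != "M" for r in inph)],
        [sum(r.sex == "M" for r in psp), sum(r.sex != "M" for r in psp)],
    ]
    try:
        comparisons.append(chi_squared_proportions(sex_table, variable="sex_male"))
    except DegenerateDataError as exc:
        warnings_out.append(f"sex comparison skipped: {exc}")
    for index in INDEX_NAMES:
        comparisons.append(
            _compare_or_note(
                _index_values(inph, index),
                _index_values(psp, index),
                index,
                warnings_out,
            )
        )
    score_names = sorted({k for r in records for k in r.clinical_scores})
    for score in score_names:
        a = [r.clinical_scores[score] for r in inph if score in r.clinical_scores]
        b = [r.clinical_scores[score] for r in psp if score in r.clinical_scores]
        if len(a) >= 2 and len(b) >= 2:
            comparisons.append(_compare_or_note(a, b, score, warnings_out))
        else:
            warnings_out.append(f"{score}: present in only one group, comparison skipped")

    # --- ROC per index (iNPH positive, higher = more iNPH-like)
    labels = np.array([r.group == "iNPH" for r in records])
    roc: dict[str, ROCResult] = {
        index: roc_curve(_index_values(records, index), labels)
        for index in INDEX_NAMES
    }

    # --- classification tables at the requested profiles
    primary = get_cutoff_profile(cutoff_profile)
    profiles = [primary] + [
        get_cutoff_profile(p) for p in extra_profiles if get_cutoff_profile(p).name != primary.name
    ]
    classification = {
        prof.name: apply_external_cutoffs(records, prof) for prof in profiles
    }

    # --- adjusted logistic regression per index: group ~ age + sex + index
    logistic: dict[str, LogisticFit | str] = {}
    y = labels.astype(float)
    age = np.array([r.age for r in records], dtype=float)
    sex = np.array([1.0 if r.sex == "M" else 0.0 for r in records])
    for index in INDEX_NAMES:
        X = np.column_stack([age, sex, _index_values(records, index)])
        try:
            logistic[index] = logistic_fit(
                y, X, names=("intercept", "age", "sex_male", index)
            )
        except (CollinearityError, ConvergenceError, UnsupportedSizeError) as exc:
            logistic[index] = f"not fitted: {exc}"
            warnings_out.append(f"logistic fit for {index} failed: {exc}")

    # --- phenotype subanalysis on BLM
    phenotype_comparisons: dict[str, ComparisonResult | str] = {}
    blm_inph = _index_values(inph, "blm")
    for ph in ("PSP-RS", "PSP-P"):
        sub = [r for r in psp if r.phenotype == ph]
        key = f"iNPH_vs_{ph}"
        if len(sub) >= 2:
            phenotype_comparisons[key] = _compare_or_note(
                blm_inph, _index_values(sub, "blm"), f"blm_{key}", warnings_out
            )
        else:
            phenotype_comparisons[key] = f"skipped: only {len(sub)} {ph} subjects"

    return StudyReport(
        n_inph=len(inph),
        n_psp=len(psp),
        comparisons=comparisons,
        roc=roc,
        classification=classification,
        logistic=logistic,
        phenotype_comparisons=phenotype_comparisons,
        warnings=warnings_out,
        provenance={
            "software": "ventriculometry",
            "version": __version__,
            "cutoff_profile": primary.name,
            "extra_profiles": [p.name for p in profiles[1:]],
            "seed": seed,
            "n_records": len(records),
        },
    )


# ---------------------------------------------------------------------------
# rendering


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def _pct(num: int, den: int) -> str:
    return f"{round_half_up(100 * num / den)}" if den else "-"


def render_markdown(report: StudyReport) -> str:
    """Human-readable Markdown report (rounded; JSON keeps full precision)."""
    L: list[str] = []
    L.append("# Diagnostic-accuracy report: iNPH vs PSP")
    L.append("")
    L.append(
        f"Cohort: {report.n_inph} iNPH, {report.n_psp} PSP "
        f"(cutoff profile: {report.provenance['cutoff_profile']}, "
        f"ventriculometry {report.provenance['version']})"
    )
    L.append("")
    L.append("## Group comparisons")
    L.append("")
    L.append("| Variable | iNPH | PSP | Test | p |")
    L.append("|---|---|---|---|---|")
    for c in report.comparisons:
        L.append(
            f"| {c.variable} | {c.summary_a} | {c.summary_b} | {c.test} | {_fmt_p(c.p_value)} |"
        )
    L.append("")
    L.append("## ROC analysis (iNPH = positive class)")
    L.append("")
    L.append("| Index | AUC | Youden cutoff | J | Sens % | Spec % | Acc % |")
    L.append("|---|---|---|---|---|---|---|")
    for index in INDEX_NAMES:
        r = report.roc[index]
        m = r.metrics_at_cutoff
        pc = m.as_percent()
        L.append(
            f"| {INDEX_LABELS[index]} | {r.auc:.3f} | {r.optimal_cutoff:.3f} | "
            f"{r.youden_j:.3f} | {pc['sensitivity_pct']} | {pc['specificity_pct']} | "
            f"{pc['accuracy_pct']} |"
        )
    L.append("")
    for profile, rows in report.classification.items():
        L.append(f"## Classification at '{profile}' cutoffs")
        L.append("")
        L.append(
            "| Index | Cutoff | iNPH pathological n (%) | PSP pathological n (%) "
            "| Sens % | Spec % | Acc % |"
        )
        L.append("|---|---|---|---|---|---|---|")
        for row in rows:
            m = row.metrics
            sens = f"{m.as_percent()['sensitivity_pct']}" if m else "-"
            spec = f"{m.as_percent()['specificity_pct']}" if m else "-"
            acc = f"{m.as_percent()['accuracy_pct']}" if m else "-"
            L.append(
                f"| {INDEX_LABELS[row.index]} | {row.cutoff:.3f} "
                f"| {row.n_inph_pathological} ({_pct(row.n_inph_pathological, row.n_inph)}) "
                f"| {row.n_psp_pathological} ({_pct(row.n_psp_pathological, row.n_psp)}) "
                f"| {sens} | {spec} | {acc} |"
            )
        L.append("")
    L.append("## Adjusted logistic regression (group ~ age + sex + index)")
    L.append("")
    L.append("| Index | Coefficient | SE | Wald z | p | Separation |")
    L.append("|---|---|---|---|---|---|")
    for index in INDEX_NAMES:
        f = report.logistic[index]
        if isinstance(f, str):
            L.append(f"| {INDEX_LABELS[index]} | {f} | | | | |")
        else:
            k = f.names.index(index)
            L.append(
                f"| {INDEX_LABELS[index]} | {f.coefficients[k]:.3g} | "
                f"{f.standard_errors[k]:.3g} | {f.wald_z[k]:.2f} | "
                f"{_fmt_p(f.p_values[k])} | {'yes' if f.separation_detected else 'no'} |"
            )
    L.append("")
    L.append("## PSP-phenotype subanalysis (BLM)")
    L.append("")
    for key, c in report.phenotype_comparisons.items():
        if isinstance(c, str):
            L.append(f"- {key}: {c}")
        else:
            L.append(
                f"- {key}: iNPH {c.summary_a} vs {c.summary_b} "
                f"({c.test}, p {_fmt_p(c.p_value)})"
            )
    if report.warnings:
        L.append("")
        L.append("## Warnings")
        L.append("")
        for w in report.warnings:
            L.append(f"- {w}")
    L.append("")
    return "\n".join(L)


def write_report(report: StudyReport, out_dir: str | Path) -> tuple[Path, Path]:
    """Write report.json (full precision) and report.md (rounded) to `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / "report.json"
    md_path = out / "report.md"
    json_path.write_text(report.to_json() + "\n", encoding="utf-8")
    md_path.write_text(render_markdown(report), encoding="utf-8")
    return json_path, md_path
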