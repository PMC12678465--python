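"""Synthetic two-arm cohort generation.

Simulates iNPH-vs-PSP cohorts whose marginal index distributions, age, sex
balance, sample sizes and PSP phenotype split reproduce the published
group-level characteristics of the clinical sample the pipeline was designed
around: 35 iNPH vs 39 PSP; BLM 0.332 ± 0.04 vs 0.234 ± 0.02; MRHI
0.533 ± 0.050 vs 0.419 ± 0.038; Evans' index 0.341 ± 0.05 vs 0.233 ± 0.02;
age 74.5 ± 7.1 vs 69.4 ± 7.7 years; 71.4% vs 38.5% male; PSP split 24 PSP-RS
(BLM 0.230 ± 0.021) to 15 PSP-P (BLM 0.240 ± 0.019).

Indexes are drawn from per-arm Gaussians truncated to (0.05, 0.60) by
rejection (the bounds sit many standard deviations from every configured
mean, so the truncation bias is negligible).  Indexes are independent by
default; an optional shared latent "ventriculomegaly factor" induces
positive cross-index correlation.  In ``measurement_level`` mode each
subject additionally receives a full set of linear measurements solved to
reproduce their index panel exactly, so the landmark -> measurement -> index
path can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigValidationError, InfeasibleTargetError
from .measurements import INDEX_NAMES, IndexPanel, LinearMeasurementSet

__all__ = [
    "GaussianSpec",
    "ArmConfig",
    "PhenotypeSplit",
    "DenominatorPriors",
    "CohortConfig",
    "SubjectRecord",
    "generate_cohort",
    "synthesize_measurements",
]


@dataclass(frozen=True)
class GaussianSpec:
    """Mean and standard deviation of one simulated variable."""

    mean: float
    sd: float


@dataclass(frozen=True)
class ArmConfig:
    """Distribution parameters for one diagnostic arm."""

    n: int
    blm: GaussianSpec
    mrhi: GaussianSpec
    ei: GaussianSpec
    age: GaussianSpec
    male_proportion: float

    def index_spec(self, index: str) -> GaussianSpec:
        return getattr(self, index)


@dataclass(frozen=True)
class PhenotypeSplit:
    """PSP phenotype mixture: proportion PSP-RS and phenotype-specific BLM."""

    rs_proportion: float
    blm_rs: GaussianSpec
    blm_p: GaussianSpec


@dataclass(frozen=True)
class DenominatorPriors:
    """Adult priors (mm) for skull/inner-table diameters and width caps.

    Diameters are drawn uniformly from their ranges; numerator widths solved
    from the target indexes must stay below both their paired diameter and a
    plausibility cap.
    """

    bip_range: tuple[float, float] = (115.0, 140.0)
    bit_range: tuple[float, float] = (100.0, 130.0)
    inner_skull_range: tuple[float, float] = (115.0, 145.0)
    ei_skull_range: tuple[float, float] = (120.0, 150.0)
    fh_cap: float = 70.0
    oh_cap: float = 80.0
    th_cap: float = 45.0
    ctw_cap: float = 90.0


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to simulate a two-arm cohort deterministically.

    Defaults reproduce the published group-level characteristics; ``seed``
    fully determines the cohort.
    """

    n_inph: int = 35
    n_psp: int = 39
    inph: ArmConfig = field(
        default_factory=lambda: ArmConfig(
            n=35,
            blm=GaussianSpec(0.332, 0.04),
            mrhi=GaussianSpec(0.533, 0.050),
            ei=GaussianSpec(0.341, 0.05),
            age=GaussianSpec(74.5, 7.1),
            male_proportion=0.714,
        )
    )
    psp: ArmConfig = field(
        default_factory=lambda: ArmConfig(
            n=39,
            blm=GaussianSpec(0.234, 0.02),
            mrhi=GaussianSpec(0.419, 0.038),
            ei=GaussianSpec(0.233, 0.02),
            age=GaussianSpec(69.4, 7.7),
            male_proportion=0.385,
        )
    )
    psp_phenotype_split: PhenotypeSplit | None = field(
        default_factory=lambda: PhenotypeSplit(
            rs_proportion=24 / 39,
            blm_rs=GaussianSpec(0.230, 0.021),
            blm_p=GaussianSpec(0.240, 0.019),
        )
    )
    index_bounds: tuple[float, float] = (0.05, 0.60)
    age_bounds: tuple[float, float] = (30.0, 100.0)
    latent_loading: float = 0.0  # 0 = independent indexes; e.g. 0.7 for correlation
    mode: str = "index_level"  # index_level | measurement_level
    with_qualitative: bool = False  # DESH / hummingbird flags
    denominator_priors: DenominatorPriors = field(default_factory=DenominatorPriors)
    seed: int = 0

    def __post_init__(self) -> None:
        v: list[str] = []
        if self.n_inph < 2:
            v.append(f"n_inph must be >= 2, got {self.n_inph}")
        if self.n_psp < 2:
            v.append(f"n_psp must be >= 2, got {self.n_psp}")
        for arm_name in ("inph", "psp"):
            arm = getattr(self, arm_name)
            for var in ("blm", "mrhi", "ei", "age"):
                spec = getattr(arm, var)
                if spec.sd <= 0:
                    v.append(f"{arm_name}.{var}.sd must be positive, got {spec.sd}")
            if not 0.0 <= arm.male_proportion <= 1.0:
                v.append(
                    f"{arm_name}.male_proportion must be in [0, 1], got {arm.male_proportion}"
                )
        split = self.psp_phenotype_split
        if split is not None:
            if not 0.0 <= split.rs_proportion <= 1.0:
                v.append(f"rs_proportion must be in [0, 1], got {split.rs_proportion}")
            for var in ("blm_rs", "blm_p"):
                if getattr(split, var).sd <= 0:
                    v.append(f"{var}.sd must be positive")
        for name, bounds in (("index_bounds", self.index_bounds), ("age_bounds", self.age_bounds)):
            if bounds[0] >= bounds[1]:
                v.append(f"{name} must be ordered, got {bounds}")
        if not 0.0 <= self.latent_loading < 1.0:
            v.append(f"latent_loading must be in [0, 1), got {self.latent_loading}")
        if self.mode not in ("index_level", "measurement_level"):
            v.append(f"mode must be index_level or measurement_level, got {self.mode!r}")
        if v:
            raise ConfigValidationError(v)

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        """Build a config from plain nested dicts (JSON/YAML-friendly)."""

        def gauss(d):
            return GaussianSpec(**d) if isinstance(d, Mapping) else GaussianSpec(*d)

        kwargs = dict(data)
        for arm_name in ("inph", "psp"):
            if arm_name in kwargs and isinstance(kwargs[arm_name], Mapping):
                arm = dict(kwargs[arm_name])
                for var in ("blm", "mrhi", "ei", "age"):
                    if var in arm:
                        arm[var] = gauss(arm[var])
                kwargs[arm_name] = ArmConfig(**arm)
        split = kwargs.get("psp_phenotype_split")
        if isinstance(split, Mapping):
            split = dict(split)
            for var in ("blm_rs", "blm_p"):
                if var in split:
                    split[var] = gauss(split[var])
            kwargs["psp_phenotype_split"] = PhenotypeSplit(**split)
        if "denominator_priors" in kwargs and isinstance(
            kwargs["denominator_priors"], Mapping
        ):
            kwargs["denominator_priors"] = DenominatorPriors(**kwargs["denominator_priors"])
        for key in ("index_bounds", "age_bounds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigValidationError([str(exc)]) from exc


@dataclass
class SubjectRecord:
    """One simulated or ingested subject."""

    subject_id: str
    group: str  # iNPH | PSP
    phenotype: str | None  # PSP-RS | PSP-P | None (iNPH)
    age: float
    sex: str  # M | F
    indexes: IndexPanel
    measurements: LinearMeasurementSet | None = None
    desh: bool | None = None
    hummingbird: bool | None = None
    clinical_scores: dict[str, float] = field(default_factory=dict)


def _truncated_normal(
    rng: np.random.Generator, spec: GaussianSpec, bounds: tuple[float, float], size: int
) -> np.ndarray:
    """Rejection sampling from N(mean, sd) truncated to `bounds`."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(spec.mean, spec.sd, size=size - filled)
        ok = draw[(draw > bounds[0]) & (draw < bounds[1])]
        out[filled : filled + ok.size] = ok
        filled += ok.size
    return out


def _correlated_indexes(
    rng: np.random.Generator,
    specs: Mapping[str, GaussianSpec],
    bounds: tuple[float, float],
    loading: float,
    size: int,
) -> dict[str, np.ndarray]:
    """Draw the three indexes with a shared latent factor, rejecting per subject."""
    lam = loading
    res = np.sqrt(1.0 - lam * lam)
    out = {k: np.empty(size) for k in specs}
    filled = 0
    while filled < size:
        m = size - filled
        z = rng.standard_normal(m)
        draws = {
            k: s.mean + s.sd * (lam * z + res * rng.standard_normal(m))
            for k, s in specs.items()
        }
        ok = np.ones(m, dtype=bool)
        for d in draws.values():
            ok &= (d > bounds[0]) & (d < bounds[1])
        n_ok = int(ok.sum())
        for k, d in draws.items():
            out[k][filled : filled + n_ok] = d[ok]
        filled += n_ok
    return out


def generate_cohort(config: CohortConfig | None = None, **overrides) -> list[SubjectRecord]:
    """Simulate a two-arm cohort; identical config (incl. seed) -> identical cohort.

    Keyword overrides are applied on top of `config` (or the defaults), e.g.
    ``generate_cohort(seed=7, n_inph=1000)``.
    """
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    if config.n_inph != config.inph.n:
        config = replace(config, inph=replace(config.inph, n=config.n_inph))
    if config.n_psp != config.psp.n:
        config = replace(config, psp=replace(config.psp, n=config.n_psp))

    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    for group, arm in (("iNPH", config.inph), ("PSP", config.psp)):
        n = arm.n
        specs = {k: arm.index_spec(k) for k in INDEX_NAMES}
        phenotypes: list[str | None] = [None] * n
        if group == "PSP" and config.psp_phenotype_split is not None:
            split = config.psp_phenotype_split
            n_rs = int(round(split.rs_proportion * n))
            phenotypes = ["PSP-RS"] * n_rs + ["PSP-P"] * (n - n_rs)

        if config.latent_loading > 0:
            idx = _correlated_indexes(
                rng, specs, config.index_bounds, config.latent_loading, n
            )
        else:
            idx = {
                k: _truncated_normal(rng, specs[k], config.index_bounds, n)
                for k in INDEX_NAMES
            }
        # phenotype-specific BLM overrides the arm-level draw
        if group == "PSP" and config.psp_phenotype_split is not None:
            split = config.psp_phenotype_split
            for ph, spec in (("PSP-RS", split.blm_rs), ("PSP-P", split.blm_p)):
                mask = np.array([p == ph for p in phenotypes])
                if mask.any():
                    idx["blm"][mask] = _truncated_normal(
                        rng, spec, config.index_bounds, int(mask.sum())
                    )

        ages = _truncated_normal(rng, arm.age, config.age_bounds, n)
        sexes = np.where(rng.random(n) < arm.male_proportion, "M", "F")
        desh = hummingbird = None
        if config.with_qualitative:
            desh = np.full(n, group == "iNPH")
            hb_rate = 0.457 if group == "iNPH" else 0.615
            hummingbird = rng.random(n) < hb_rate

        for i in range(n):
            panel = IndexPanel(
                blm=float(idx["blm"][i]),
                mrhi=float(idx["mrhi"][i]),
                ei=float(idx["ei"][i]),
                blm_pathological=False,
                mrhi_pathological=False,
                ei_pathological=False,
            )
            measurements = None
            if config.mode == "measurement_level":
                measurements = synthesize_measurements(
                    panel, config.denominator_priors, rng=rng
                )
            records.append(
                SubjectRecord(
                    subject_id=f"{'inph' if group == 'iNPH' else 'psp'}-{i + 1:05d}",
                    group=group,
                    phenotype=phenotypes[i],
                    age=float(ages[i]),
                    sex=str(sexes[i]),
                    indexes=panel,
                    measurements=measurements,
                    desh=None if desh is None else bool(desh[i]),
                    hummingbird=None if hummingbird is None else bool(hummingbird[i]),
                )
            )
    return records


def synthesize_measurements(
    target_panel: IndexPanel,
    templates: DenominatorPriors | None = None,
    rng: np.random.Generator | int | None = None,
) -> LinearMeasurementSet:
    """Invert an index panel into a plausible :class:`LinearMeasurementSet`.

    Denominators (bi-parietal, bi-temporal, skull diameters) are drawn from
    adult priors; numerator widths are solved so that recomputing BLM, MRHI
    and Evans' index reproduces the targets to within 1e-9.  Targets that
    would force a width past its diameter or plausibility cap raise
    :class:`InfeasibleTargetError`.
    """
    pri = templates or DenominatorPriors()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for idx in INDEX_NAMES:
        v = target_panel.value(idx)
        if not 0.0 < v < 1.0:
            raise InfeasibleTargetError(f"target {idx}={v} outside (0, 1)")

    last_reason = ""
    for _ in range(50):  # retry denominator draws; only systematic targets fail
        bip_fh = float(rng.uniform(*pri.bip_range))
        bip_oh = float(rng.uniform(*pri.bip_range))
        bit = float(rng.uniform(*pri.bit_range))
        inner_skull = float(rng.uniform(*pri.inner_skull_range))
        ei_skull = float(rng.uniform(*pri.ei_skull_range))

        ctw = target_panel.mrhi * inner_skull
        if ctw >= min(inner_skull, pri.ctw_cap):
            last_reason = (
                f"MRHI {target_panel.mrhi} needs CTW {ctw:.1f} mm >= "
                f"cap {min(inner_skull, pri.ctw_cap):.1f} mm"
            )
            continue
        fh = target_panel.ei * ei_skull
        if fh >= min(bip_fh, ei_skull, pri.fh_cap):
            last_reason = (
                f"EI {target_panel.ei} needs FH {fh:.1f} mm >= "
                f"cap {min(bip_fh, ei_skull, pri.fh_cap):.1f} mm"
            )
            continue
        rest = target_panel.blm * (bip_fh + bip_oh + bit) - fh  # oh + th
        # prefer a 60:40 occipital:temporal split, clamped to the caps
        th = min(0.4 * rest, 0.98 * min(bit, pri.th_cap))
        oh = rest - th
        if rest <= 0 or th <= 0 or oh >= min(bip_oh, pri.oh_cap):
            last_reason = (
                f"BLM {target_panel.blm} infeasible with FH {fh:.1f} mm and "
                f"denominators ({bip_fh:.0f}, {bip_oh:.0f}, {bit:.0f}) mm"
            )
            continue
        return LinearMeasurementSet(
            fh_width=fh,
            oh_width=oh,
            th_width=th,
            bip_at_fh=bip_fh,
            bip_at_oh=bip_oh,
            bit_at_th=bit,
            ctw=ctw,
            inner_skull_diameter=inner_skull,
            ei_skull_diameter=ei_skull,
        )
    raise InfeasibleTargetError(last_reason)
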