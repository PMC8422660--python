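"""Seeded generator of paired-technique DVH cohorts.

Emulates a 30-patient post-mastectomy planning study at the DVH level: each
patient gets two plans (arm A = fixed-field IMRT-like reference, arm B =
VMAT-like) built from the same latent anatomy draw, with arm B applying
configurable multiplicative dose effects per structure.  There is no
geometry or beam model — target curves are probit-shaped cumulative falls
around the prescription, OAR curves an in-field high-dose component plus an
exponential low-dose tail — but the cohort-level statistical structure
(means, spreads, paired arm effects, age distribution, MU/time models) is
the one the downstream comparison assumes.

Determinism: each patient is generated from an independent stream keyed by
``(seed, patient_index)``, so the same seed reproduces the cohort bit-for-bit
and adding patients never perturbs earlier ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import norm, truncnorm

from .compare import Cohort, PlanRecord
from .dvh import DEFAULT_BIN_WIDTH_GY, DoseVolumeHistogram
from .errors import GenerationError, InvalidDvhError, PlanriskError

__all__ = [
    "TargetShape", "OarShape", "StructureSpec", "ArmModel", "CohortSpec",
    "default_cohort_spec", "generate_patient", "generate_cohort",
]

_Z98 = norm.ppf(0.98)  # 2.0537…, maps the D2/D98 span onto the probit width


@dataclass(frozen=True)
class TargetShape:
    """Target DVH: cumulative volume falls as a probit around the
    prescription, parametrised directly by the intended D2% and D98%."""

    prescription: float = 50.0
    d2: float = 54.5
    d98: float = 48.3

    def __post_init__(self):
        if not (0 < self.d98 < self.d2):
            raise GenerationError("target shape needs 0 < d98 < d2")

    @property
    def mu(self) -> float:
        return 0.5 * (self.d2 + self.d98)

    @property
    def sigma(self) -> float:
        return (self.d2 - self.d98) / (2.0 * _Z98)


@dataclass(frozen=True)
class OarShape:
    """OAR DVH: an in-field fraction at high dose (probit component) plus an
    exponential low-dose scatter tail; the dose axis is rescaled so the
    curve's mean dose equals ``dmean`` exactly."""

    dmean: float
    in_field_fraction: float = 0.0       # fraction of organ in the high-dose region
    in_field_mu: float = 40.0            # Gy, before mean-rescaling
    in_field_sigma: float = 8.0
    tail_decay: float = 3.0              # Gy, exponential tail constant

    def __post_init__(self):
        if not (0 <= self.in_field_fraction <= 1):
            raise GenerationError("in_field_fraction must lie in [0, 1]")
        if self.dmean <= 0 or self.tail_decay <= 0 or self.in_field_sigma <= 0:
            raise GenerationError("dmean, tail_decay, in_field_sigma must be > 0")


@dataclass(frozen=True)
class StructureSpec:
    """One structure's generative settings.

    ``dose_sd`` is the lognormal SD of the patient-level dose-scale factor,
    ``arm_noise_sd`` the lognormal SD of the per-plan (within-patient)
    residual, and ``effect_b`` the multiplicative arm-B dose effect.
    ``uses_anatomy`` couples the structure to the shared latent anatomy-size
    factor (the only cross-structure correlation mechanism).
    """

    name: str
    shape: TargetShape | OarShape
    volume_cc: float
    volume_sd: float = 0.15
    dose_sd: float = 0.05
    arm_noise_sd: float = 0.01
    effect_b: float = 1.0
    uses_anatomy: bool = True

    def __post_init__(self):
        if self.volume_cc <= 0 or self.effect_b <= 0:
            raise GenerationError("volume_cc and effect_b must be > 0")
        if min(self.volume_sd, self.dose_sd, self.arm_noise_sd) < 0:
            raise GenerationError("all SDs must be >= 0")


@dataclass(frozen=True)
class ArmModel:
    """Mean/SD of a per-plan scalar (MU, times, CI, CN) for each arm."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


@dataclass
class CohortSpec:
    """Full description of the simulated paired cohort (defaults = the
    30-patient study conditions: table-scale doses, ages 47 [25, 65])."""

    n_patients: int = 30
    seed: int = 17
    technique_a: str = "IMRT"
    technique_b: str = "VMAT"
    age_mean: float = 47.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (25.0, 65.0)
    anatomy_sd: float = 0.03
    structures: list[StructureSpec] = field(default_factory=list)
    mu_model: ArmModel = field(default_factory=lambda: ArmModel(893, 142, 611, 54))
    bot_model: ArmModel = field(default_factory=lambda: ArmModel(1.49, 0.24, 1.46, 0.06))
    time_model: ArmModel = field(default_factory=lambda: ArmModel(7.00, 0.62, 2.00, 0.04))
    ci_model: ArmModel = field(default_factory=lambda: ArmModel(1.17, 0.05, 1.10, 0.03))
    cn_model: ArmModel = field(default_factory=lambda: ArmModel(0.78, 0.04, 0.84, 0.02))
    bin_width: float = DEFAULT_BIN_WIDTH_GY

    def __post_init__(self):
        if self.n_patients < 2:
            raise GenerationError("need at least 2 patients")
        if self.age_bounds[0] >= self.age_bounds[1]:
            raise GenerationError("age bounds must be ordered")
        if self.anatomy_sd < 0:
            raise GenerationError("anatomy_sd must be >= 0")

    def structure(self, name: str) -> StructureSpec:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(name)


def default_cohort_spec(n_patients: int = 30, seed: int = 17) -> CohortSpec:
    """The default paired cohort: two probit targets near 50 Gy and five
    OARs at the reference-arm dose scales, with arm-B effects equal to the
    between-technique mean-dose ratios of the emulated study."""
    structures = [
        StructureSpec("PTV1", TargetShape(50.0, d2=54.5, d98=48.3),
                      volume_cc=367.2, volume_sd=0.22, dose_sd=0.004,
                      arm_noise_sd=0.003, effect_b=52.6 / 52.4, uses_anatomy=False),
        StructureSpec("PTV2", TargetShape(50.0, d2=54.1, d98=50.2),
                      volume_cc=163.5, volume_sd=0.19, dose_sd=0.005,
                      arm_noise_sd=0.003, effect_b=52.6 / 52.5, uses_anatomy=False),
        StructureSpec("ipsilateral_lung",
                      OarShape(dmean=12.6, in_field_fraction=0.25,
                               in_field_mu=40.0, in_field_sigma=8.0, tail_decay=3.0),
                      volume_cc=1100.0, volume_sd=0.15, dose_sd=0.047,
                      arm_noise_sd=0.02, effect_b=11.5 / 12.6),
        StructureSpec("heart",
                      OarShape(dmean=6.0, in_field_fraction=0.08,
                               in_field_mu=40.0, in_field_sigma=8.0, tail_decay=3.5),
                      volume_cc=600.0, volume_sd=0.15, dose_sd=0.181,
                      arm_noise_sd=0.05, effect_b=5.2 / 6.0),
        StructureSpec("contralateral_breast",
                      OarShape(dmean=2.5, in_field_fraction=0.0, tail_decay=2.5),
                      volume_cc=500.0, volume_sd=0.20, dose_sd=0.238,
                      arm_noise_sd=0.12, effect_b=1.0),
        StructureSpec("contralateral_lung",
                      OarShape(dmean=1.5, in_field_fraction=0.0, tail_decay=1.5),
                      volume_cc=1200.0, volume_sd=0.15, dose_sd=0.332,
                      arm_noise_sd=0.10, effect_b=1.6 / 1.5),
        StructureSpec("lung_all",
                      OarShape(dmean=6.5, in_field_fraction=0.12,
                               in_field_mu=40.0, in_field_sigma=8.0, tail_decay=2.8),
                      volume_cc=2300.0, volume_sd=0.15, dose_sd=0.071,
                      arm_noise_sd=0.02, effect_b=6.1 / 6.5),
    ]
    return CohortSpec(n_patients=n_patients, seed=seed, structures=structures)


# ----------------------------------------------------------------- base curves

def _base_curve(shape: TargetShape | OarShape, bin_width: float,
                name: str) -> DoseVolumeHistogram:
    """Rasterize a shape onto a regular dose grid (unit total volume)."""
    if isinstance(shape, TargetShape):
        dmax = shape.mu + 4.5 * shape.sigma
        edges = np.arange(0.0, dmax + bin_width, bin_width)
        cum = norm.sf(edges, loc=shape.mu, scale=shape.sigma)
    else:
        dmax = max(shape.in_field_mu + 5 * shape.in_field_sigma,
                   12 * shape.tail_decay)
        edges = np.arange(0.0, dmax + bin_width, bin_width)
        f = shape.in_field_fraction
        cum = (f * norm.sf(edges, loc=shape.in_field_mu, scale=shape.in_field_sigma)
               + (1 - f) * np.exp(-edges / shape.tail_decay))
    cum = cum / cum[0]
    try:
        dvh = DoseVolumeHistogram(name, edges, cum, 1.0)
    except InvalidDvhError as exc:
        raise GenerationError(f"shape for {name} produced an invalid curve: {exc}")
    if isinstance(shape, OarShape):
        raw_mean = dvh.mean_dose()
        dvh = dvh.scale_dose(shape.dmean / raw_mean)
    return dvh


def _lognormal_unit_mean(rng: np.random.Generator, sd: float) -> float:
    """Lognormal draw with E[X] = 1 (so configured means are unbiased)."""
    if sd == 0:
        return 1.0
    return float(rng.lognormal(mean=-0.5 * sd * sd, sigma=sd))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise GenerationError(f"could not draw a positive value from N({mean}, {sd})")


def _draw_conformity(rng: np.random.Generator, v_ptv: float, ci_mean: float,
                     ci_sd: float, cn_mean: float, cn_sd: float
                     ) -> tuple[float, float, float]:
    """Draw (v_ptv, v_rx, v_ptv_rx) consistent with CI/CN around their means.

    ``v_rx = CI * v_ptv`` and ``v_ptv_rx = v_ptv * sqrt(CN * CI)`` inverts the
    Paddick identity ``CN = v_ptv_rx^2 / (v_ptv * v_rx)``; draws violating the
    geometric bound ``v_ptv_rx <= min(v_ptv, v_rx)`` are redrawn.
    """
    for _ in range(1000):
        ci = rng.normal(ci_mean, ci_sd)
        cn = rng.normal(cn_mean, cn_sd)
        if ci <= 0 or not (0 < cn < 1):
            continue
        coverage = np.sqrt(cn * ci)
        if coverage <= min(1.0, ci):
            return v_ptv, ci * v_ptv, coverage * v_ptv
    raise GenerationError("could not draw geometrically consistent CI/CN volumes")


# -------------------------------------------------------------------- patients

def generate_patient(spec: CohortSpec, patient_index: int
                     ) -> tuple[PlanRecord, PlanRecord]:
    """Generate the matched (arm A, arm B) plan pair for one patient.

    Deterministic given ``(spec.seed, patient_index)``; both arms share the
    patient's latent anatomy and per-structure dose-scale draws, and arm B
    additionally applies each structure's ``effect_b``.
    """
    if not (0 <= patient_index < spec.n_patients):
        raise GenerationError(f"patient_index {patient_index} outside cohort")
    rng = np.random.default_rng([spec.seed, patient_index])
    pid = f"P{patient_index + 1:03d}"
    age = _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_bounds)
    anatomy = _lognormal_unit_mean(rng, spec.anatomy_sd)

    dvhs_a: dict[str, DoseVolumeHistogram] = {}
    dvhs_b: dict[str, DoseVolumeHistogram] = {}
    for s in spec.structures:
        base = _base_curve(s.shape, spec.bin_width, s.name)
        patient_scale = _lognormal_unit_mean(rng, s.dose_sd)
        if s.uses_anatomy:
            patient_scale *= anatomy
        volume = s.volume_cc * _lognormal_unit_mean(rng, s.volume_sd)
        noise_a = _lognormal_unit_mean(rng, s.arm_noise_sd)
        noise_b = _lognormal_unit_mean(rng, s.arm_noise_sd)
        try:
            dvh_a = base.scale_dose(patient_scale * noise_a)
            dvh_b = base.scale_dose(patient_scale * noise_b * s.effect_b)
        except InvalidDvhError as exc:      # pragma: no cover - defensive
            raise GenerationError(str(exc))
        dvhs_a[s.name] = DoseVolumeHistogram(s.name, dvh_a.dose_edges,
                                             dvh_a.cumulative_volume, volume)
        dvhs_b[s.name] = DoseVolumeHistogram(s.name, dvh_b.dose_edges,
                                             dvh_b.cumulative_volume, volume)

    v_ptv = dvhs_a[spec.structures[0].name].total_volume
    conf_a = _draw_conformity(rng, v_ptv, spec.ci_model.mean_a, spec.ci_model.sd_a,
                              spec.cn_model.mean_a, spec.cn_model.sd_a)
    conf_b = _draw_conformity(rng, v_ptv, spec.ci_model.mean_b, spec.ci_model.sd_b,
                              spec.cn_model.mean_b, spec.cn_model.sd_b)

    def plan(technique, dvhs, mu_mean, mu_sd, bot_mean, bot_sd, t_mean, t_sd, conf):
        return PlanRecord(
            patient_id=pid, technique=technique, age_x=age, dvhs=dvhs,
            mu=int(round(_positive_normal(rng, mu_mean, mu_sd))),
            beam_on_min=_positive_normal(rng, bot_mean, bot_sd),
            treat_time_min=_positive_normal(rng, t_mean, t_sd),
            conformity_volumes=conf,
        )

    rec_a = plan(spec.technique_a, dvhs_a, spec.mu_model.mean_a, spec.mu_model.sd_a,
                 spec.bot_model.mean_a, spec.bot_model.sd_a,
                 spec.time_model.mean_a, spec.time_model.sd_a, conf_a)
    rec_b = plan(spec.technique_b, dvhs_b, spec.mu_model.mean_b, spec.mu_model.sd_b,
                 spec.bot_model.mean_b, spec.bot_model.sd_b,
                 spec.time_model.mean_b, spec.time_model.sd_b, conf_b)
    return rec_a, rec_b


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None,
                    overwrite: bool = False
                    ) -> tuple[Cohort, Cohort, dict]:
    """Generate the full paired cohort; optionally write DVH CSV files.

    Returns ``(cohort_a, cohort_b, manifest)``.  With ``out_dir`` set, one
    CSV per plan is written under ``<out_dir>/<technique>/<patient>.csv``
    plus a ``manifest.json`` echoing the spec, seed and file checksums.
    """
    pairs = [generate_patient(spec, i) for i in range(spec.n_patients)]
    cohort_a = Cohort([p[0] for p in pairs], spec.technique_a)
    cohort_b = Cohort([p[1] for p in pairs], spec.technique_b)
    manifest: dict = {
        "seed": spec.seed,
        "n_patients": spec.n_patients,
        "techniques": [spec.technique_a, spec.technique_b],
        "spec": _spec_echo(spec),
        "files": {},
    }
    if out_dir is not None:
        from .io import write_plan_record  # local import to avoid a cycle

        out_dir = Path(out_dir)
        for cohort in (cohort_a, cohort_b):
            arm_dir = out_dir / cohort.technique
            arm_dir.mkdir(parents=True, exist_ok=True)
            for rec in cohort:
                path = arm_dir / f"{rec.patient_id}.csv"
                if path.exists() and not overwrite:
                    raise PlanriskError(
                        f"refusing to overwrite {path} (pass overwrite=True)")
                write_plan_record(rec, path)
                digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
                manifest["files"][str(path.relative_to(out_dir))] = digest
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return cohort_a, cohort_b, manifest


def _spec_echo(spec: CohortSpec) -> dict:
    d = asdict(spec)
    for s, raw in zip(d["structures"], spec.structures):
        s["shape"]["kind"] = "target" if isinstance(raw.shape, TargetShape) else "oar"
    return d
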