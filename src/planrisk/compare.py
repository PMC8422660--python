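"""Paired two-technique cohort comparison.

A matched cohort (same patients planned with technique A and technique B) is
compared metric-by-metric: mean +/- SD per arm, mean per-patient difference
(B - A), optional mean per-patient ratio (B / A), and a classic paired
t-test.  The comparison is exposed statsmodels-style:

    model = PairedPlanComparison(cohort_a, cohort_b, panel=default_panel())
    results = model.fit()
    print(results.summary())
    results.table          # tidy pandas DataFrame, one row per metric

Two deliberate statistical conventions:

* difference rows are the mean of per-patient differences (which equals the
  difference of arm means);
* ratio rows are the mean of per-patient ratios, which does NOT equal the
  ratio of arm means — for strongly varying metrics (e.g. heart NTCP) the
  two can differ substantially, so the distinction is load-bearing;
* SDs use the n-1 (sample) denominator; no multiple-testing correction is
  applied — p-values are raw per-metric paired-t values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dvh import DoseVolumeHistogram, compute_structure_metrics, conformity
from .errors import CohortMismatchError, ConfigError, DomainError
from .radiobio import (EarParams, LkbParams, ParamSet, SerialityParams,
                       SccpParams, DEFAULT_REGISTRY, lkb_ntcp, oed_linear,
                       seriality_ntcp, sccp as sccp_fn, ear as ear_fn)

__all__ = [
    "PlanRecord", "Cohort", "ComparisonRow", "PairedTResult",
    "paired_t_test", "percent_reduction", "ratio_summary",
    "StructurePanel", "MetricPanel", "default_panel",
    "evaluate_plan", "PairedPlanComparison", "PlanComparisonResults",
]

_DEGENERATE_TOL = 1e-12


# ----------------------------------------------------------------- plan data

@dataclass
class PlanRecord:
    """One treatment plan: per-structure DVHs plus delivery metadata."""

    patient_id: str
    technique: str
    age_x: float                                   # age at radiotherapy, years
    dvhs: dict[str, DoseVolumeHistogram]
    mu: int = 0                                    # monitor units
    beam_on_min: float = 0.0
    treat_time_min: float = 0.0
    # CI/CN inputs need the 3-D dose grid, so they travel as precomputed
    # volumes (cc): (v_ptv, v_rx, v_ptv_rx); None when unavailable
    conformity_volumes: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not (0 < self.age_x < 120):
            raise DomainError(f"{self.patient_id}: age {self.age_x} outside (0, 120)")
        if self.mu < 0:
            raise DomainError(f"{self.patient_id}: MU must be >= 0")


class Cohort:
    """A list of :class:`PlanRecord` for one technique, indexed by patient."""

    def __init__(self, records: Iterable[PlanRecord], technique: str | None = None):
        self.records = sorted(records, key=lambda r: r.patient_id)
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortMismatchError(f"duplicate patient ids in cohort: {dupes}")
        self.technique = technique or (self.records[0].technique if self.records else "")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    def __getitem__(self, patient_id: str) -> PlanRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)


# ------------------------------------------------------------ paired statistics

@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    mean_diff: float
    degenerate: bool = False


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> PairedTResult:
    """Classic paired t-test on per-patient differences (two-sided, df = n-1).

    Degenerate inputs are flagged rather than erroring: zero-variance
    differences with nonzero mean give p = 0 (t infinite); all-zero
    differences give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("paired arms must be 1-D and equal length")
    n = a.size
    if n < 2:
        raise DomainError("paired t-test needs at least 2 pairs")
    d = b - a
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d < _DEGENERATE_TOL * max(1.0, abs(mean_d)):
        if abs(mean_d) < _DEGENERATE_TOL:
            return PairedTResult(0.0, 1.0, n - 1, mean_d, degenerate=True)
        return PairedTResult(float(np.sign(mean_d)) * np.inf, 0.0, n - 1,
                             mean_d, degenerate=True)
    res = stats.ttest_rel(b, a)
    return PairedTResult(float(res.statistic), float(res.pvalue), n - 1, mean_d)


def percent_reduction(mean_a: float, mean_b: float) -> float:
    """Percent reduction of B relative to A: ``100 (A - B) / A``."""
    if mean_a <= 0:
        raise DomainError(f"reference mean must be > 0, got {mean_a}")
    return 100.0 * (mean_a - mean_b) / mean_a


def ratio_summary(values_a: Sequence[float], values_b: Sequence[float],
                  patient_ids: Sequence[str] | None = None) -> tuple[float, float]:
    """Mean and sample SD of the per-patient ratios b/a."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("ratio arms must be 1-D and equal length")
    zero = np.nonzero(a == 0)[0]
    if zero.size:
        who = (patient_ids[int(zero[0])] if patient_ids is not None
               else f"index {int(zero[0])}")
        raise DomainError(f"zero denominator in ratio for patient {who}")
    r = b / a
    sd = float(r.std(ddof=1)) if r.size > 1 else 0.0
    return float(r.mean()), sd


# ------------------------------------------------------------------ the panel

@dataclass
class StructurePanel:
    """Which metrics to evaluate for one structure.

    ``ntcp`` / ``sccp`` / ``ear`` name parameter sets in the radiobiology
    registry; dosimetric thresholds are doses in Gy (``v_gy``) or percent of
    prescription (``v_pct_rx``).
    """

    structure: str
    v_pct_rx: list[float] = field(default_factory=list)
    v_gy: list[float] = field(default_factory=list)
    d_pct: list[float] = field(default_factory=list)   # e.g. [2, 98]
    dmean: bool = True
    hi: bool = False
    ntcp: str | None = None
    sccp: str | None = None
    ear: str | None = None


@dataclass
class MetricPanel:
    """Full report definition: structures x metrics, plus plan-level items."""

    prescription_gy: float = 50.0
    structures: list[StructurePanel] = field(default_factory=list)
    conformity_structure: str | None = None   # plan-level CI/CN row owner
    efficiency: list[str] = field(default_factory=list)  # MU / BOT(min) / TxTime(min)
    attained_age: float = 75.0

    def __post_init__(self):
        if self.prescription_gy <= 0:
            raise ConfigError("prescription must be > 0 Gy")

    def is_empty(self) -> bool:
        return not (self.structures or self.conformity_structure or self.efficiency)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetricPanel":
        structures = [StructurePanel(**s) for s in d.get("structures", [])]
        return cls(
            prescription_gy=float(d.get("prescription_gy", 50.0)),
            structures=structures,
            conformity_structure=d.get("conformity_structure"),
            efficiency=list(d.get("efficiency", [])),
            attained_age=float(d.get("attained_age", 75.0)),
        )

    def to_dict(self) -> dict:
        return {
            "prescription_gy": self.prescription_gy,
            "structures": [asdict(s) for s in self.structures],
            "conformity_structure": self.conformity_structure,
            "efficiency": list(self.efficiency),
            "attained_age": self.attained_age,
        }


_EFFICIENCY_METRICS = ("MU", "BOT(min)", "TxTime(min)")


def default_panel() -> MetricPanel:
    """The standard two-target / four-OAR breast-PMRT report panel."""
    return MetricPanel(
        prescription_gy=50.0,
        structures=[
            StructurePanel("PTV1", v_pct_rx=[95, 100, 107, 110], d_pct=[2, 98],
                           dmean=True, hi=True),
            StructurePanel("PTV2", v_pct_rx=[95, 100, 107, 110], d_pct=[2, 98],
                           dmean=True, hi=True),
            StructurePanel("ipsilateral_lung", v_gy=[2.5, 5, 10, 20, 30, 40],
                           ntcp="lung_lkb_pneumonitis", sccp="sccp_lung",
                           ear="ear_lung"),
            StructurePanel("heart", v_gy=[2.5, 5, 10, 20, 30, 40],
                           ntcp="heart_seriality_mortality"),
            StructurePanel("contralateral_breast", v_gy=[2.5, 5, 10, 20],
                           sccp="sccp_breast", ear="ear_breast"),
            StructurePanel("contralateral_lung", v_gy=[2.5, 5, 10],
                           sccp="sccp_lung", ear="ear_lung"),
            StructurePanel("lung_all", v_gy=[2.5, 5, 10, 20, 30, 40],
                           ntcp="lung_lkb_pneumonitis", sccp="sccp_lung",
                           ear="ear_lung"),
        ],
        conformity_structure="PTV1",
        efficiency=list(_EFFICIENCY_METRICS),
    )


# ------------------------------------------------------------- plan evaluation

#: metrics reported as per-patient B/A ratios (risk-table convention)
_RATIO_METRICS = frozenset({"NTCP(%)", "SCCP(%)", "EAR"})


def _resolve(registry: Mapping[str, ParamSet], name: str, expected: tuple) -> ParamSet:
    if name not in registry:
        raise ConfigError(f"panel references unknown parameter set {name!r}")
    params = registry[name]
    if not isinstance(params, expected):
        raise ConfigError(
            f"parameter set {name!r} has type {type(params).__name__}, expected "
            f"{'/'.join(t.__name__ for t in expected)}")
    return params


def evaluate_plan(record: PlanRecord, panel: MetricPanel,
                  registry: Mapping[str, ParamSet] | None = None,
                  ) -> dict[tuple[str, str], float]:
    """Evaluate every panel metric on one plan.

    Returns an ordered ``{(structure, metric): value}`` mapping; probabilities
    (NTCP) are reported in percent at this layer to match table conventions.
    Raises :class:`ConfigError` listing every missing structure.
    """
    registry = registry if registry is not None else DEFAULT_REGISTRY
    needed = [sp.structure for sp in panel.structures]
    missing = [s for s in needed if s not in record.dvhs]
    if missing:
        raise ConfigError(
            f"plan {record.patient_id}/{record.technique} lacks structures: {missing}")
    out: dict[tuple[str, str], float] = {}
    rx = panel.prescription_gy
    for sp in panel.structures:
        dvh = record.dvhs[sp.structure]
        for pct in sp.v_pct_rx:
            out[(sp.structure, f"V{pct:g}%(%)")] = dvh.volume_at_dose(pct / 100.0 * rx)
        for gy in sp.v_gy:
            out[(sp.structure, f"V{gy:g}Gy(%)")] = dvh.volume_at_dose(gy)
        for pct in sp.d_pct:
            out[(sp.structure, f"D{pct:g}%(Gy)")] = dvh.dose_at_volume(pct / 100.0)
        if sp.dmean:
            out[(sp.structure, "Dmean(Gy)")] = dvh.mean_dose()
        if sp.hi:
            m = compute_structure_metrics(dvh, include_hi=True)
            out[(sp.structure, "HI")] = m.hi
        if sp.ntcp:
            params = _resolve(registry, sp.ntcp, (LkbParams, SerialityParams))
            if isinstance(params, LkbParams):
                p = lkb_ntcp(dvh, params)
            else:
                p = seriality_ntcp(dvh, params)
            out[(sp.structure, "NTCP(%)")] = 100.0 * p
        if sp.sccp or sp.ear:
            oed = oed_linear(dvh)
            if sp.sccp:
                params = _resolve(registry, sp.sccp, (SccpParams,))
                out[(sp.structure, "SCCP(%)")] = sccp_fn(oed, params)
            if sp.ear:
                params = _resolve(registry, sp.ear, (EarParams,))
                from dataclasses import replace
                params = replace(params, attained_age=panel.attained_age)
                out[(sp.structure, "EAR")] = ear_fn(oed, params, record.age_x)
    if panel.conformity_structure:
        if record.conformity_volumes is None:
            raise ConfigError(
                f"plan {record.patient_id}/{record.technique}: panel requests CI/CN "
                "but the plan carries no conformity volumes")
        c = conformity(*record.conformity_volumes)
        out[(panel.conformity_structure, "CI")] = c.ci
        out[(panel.conformity_structure, "CN")] = c.cn
    for name in panel.efficiency:
        if name == "MU":
            out[("plan", "MU")] = float(record.mu)
        elif name == "BOT(min)":
            out[("plan", "BOT(min)")] = record.beam_on_min
        elif name == "TxTime(min)":
            out[("plan", "TxTime(min)")] = record.treat_time_min
        else:
            raise ConfigError(f"unknown efficiency metric {name!r}; "
                              f"known: {_EFFICIENCY_METRICS}")
    return out


# ------------------------------------------------------------- model / results

@dataclass(frozen=True)
class ComparisonRow:
    """One metric compared across techniques (one line of the report)."""

    structure: str
    metric: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    diff: float                       # mean per-patient (B - A)
    ratio_mean: float | None
    ratio_sd: float | None
    t: float
    p: float
    degenerate: bool


class PairedPlanComparison:
    """Paired comparison of two plan cohorts over a metric panel.

    Parameters
    ----------
    cohort_a, cohort_b : Cohort
        Matched cohorts (identical patient ids); A is the reference arm for
        differences (B - A) and ratios (B / A).
    panel : MetricPanel, optional
        Report definition; defaults to :func:`default_panel`.
    registry : mapping, optional
        Radiobiology parameter registry; defaults to the built-in sets.
    """

    def __init__(self, cohort_a: Cohort, cohort_b: Cohort,
                 panel: MetricPanel | None = None,
                 registry: Mapping[str, ParamSet] | None = None):
        self.panel = panel if panel is not None else default_panel()
        if self.panel.is_empty():
            raise ConfigError("metric panel is empty: nothing to compare")
        ids_a, ids_b = cohort_a.patient_ids, cohort_b.patient_ids
        if ids_a != ids_b:
            only_a = sorted(set(ids_a) - set(ids_b))
            only_b = sorted(set(ids_b) - set(ids_a))
            raise CohortMismatchError(
                f"cohorts are not matched; only in A: {only_a}, only in B: {only_b}")
        if len(cohort_a) < 2:
            raise CohortMismatchError("paired comparison needs at least 2 patients")
        self.cohort_a, self.cohort_b = cohort_a, cohort_b
        self.registry = dict(registry) if registry is not None else dict(DEFAULT_REGISTRY)

    def fit(self) -> "PlanComparisonResults":
        """Evaluate the panel on every plan and assemble the comparison rows."""
        per_a = [evaluate_plan(r, self.panel, self.registry) for r in self.cohort_a]
        per_b = [evaluate_plan(r, self.panel, self.registry) for r in self.cohort_b]
        keys = list(per_a[0].keys())   # deterministic: declaration order
        ids = self.cohort_a.patient_ids
        rows = []
        for structure, metric in keys:
            a = np.array([m[(structure, metric)] for m in per_a])
            b = np.array([m[(structure, metric)] for m in per_b])
            tt = paired_t_test(a, b)
            if metric in _RATIO_METRICS:
                r_mean, r_sd = ratio_summary(a, b, ids)
            else:
                r_mean = r_sd = None
            rows.append(ComparisonRow(
                structure, metric, len(ids),
                float(a.mean()), float(a.std(ddof=1)),
                float(b.mean()), float(b.std(ddof=1)),
                tt.mean_diff, r_mean, r_sd, tt.t, tt.p, tt.degenerate))
        return PlanComparisonResults(self, rows)


class PlanComparisonResults:
    """Fitted comparison: rows, tidy table, summary text, and writers."""

    def __init__(self, model: PairedPlanComparison, rows: list[ComparisonRow]):
        self.model = model
        self.rows = rows
        self.label_a = model.cohort_a.technique
        self.label_b = model.cohort_b.technique

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])

    def row(self, structure: str, metric: str) -> ComparisonRow:
        for r in self.rows:
            if r.structure == structure and r.metric == metric:
                return r
        raise KeyError((structure, metric))

    def percent_reduction(self, structure: str, metric: str) -> float:
        """Percent reduction of arm B relative to arm A for one metric."""
        r = self.row(structure, metric)
        return percent_reduction(r.mean_a, r.mean_b)

    # ------------------------------------------------------------- sub-tables

    def _select(self, predicate) -> pd.DataFrame:
        df = self.table
        return df[df.apply(predicate, axis=1)].reset_index(drop=True)

    def target_table(self) -> pd.DataFrame:
        """Target coverage/homogeneity/conformity rows."""
        targets = {sp.structure for sp in self.model.panel.structures if sp.hi}
        if self.model.panel.conformity_structure:
            targets.add(self.model.panel.conformity_structure)
        return self._select(lambda r: r.structure in targets)

    def oar_table(self) -> pd.DataFrame:
        """Dosimetric OAR rows (VxGy and Dmean)."""
        targets = {sp.structure for sp in self.model.panel.structures if sp.hi}
        return self._select(lambda r: r.structure not in targets
                            and r.structure != "plan"
                            and r.metric not in _RATIO_METRICS)

    def risk_table(self) -> pd.DataFrame:
        """Radiobiological rows (NTCP/SCCP/EAR) with B/A ratios."""
        return self._select(lambda r: r.metric in _RATIO_METRICS)

    def efficiency_table(self) -> pd.DataFrame:
        """MU / beam-on time / treatment time rows."""
        return self._select(lambda r: r.structure == "plan")

    # ---------------------------------------------------------------- display

    def summary(self) -> str:
        """Human-readable report table (display rounding only; the underlying
        values in ``table`` are never rounded)."""
        la, lb = self.label_a or "A", self.label_b or "B"
        lines = [
            "Paired two-technique plan comparison",
            f"  n = {len(self.model.cohort_a)} matched patients; "
            f"arm A = {la}, arm B = {lb}",
            f"  prescription = {self.model.panel.prescription_gy:g} Gy; "
            "difference = mean per-patient (B - A); ratio = mean per-patient B/A",
            "",
            f"{'structure':<22}{'metric':<13}{la + ' mean±SD':>18}"
            f"{lb + ' mean±SD':>18}{'B-A':>9}{'B/A':>14}{'p':>10}",
            "-" * 104,
        ]
        for r in self.rows:
            prec = 2 if r.metric in ("HI", "CI", "CN") else 1
            ab = f"{r.mean_a:.{prec}f} ± {r.sd_a:.{prec}f}"
            bb = f"{r.mean_b:.{prec}f} ± {r.sd_b:.{prec}f}"
            ratio = (f"{r.ratio_mean:.2f} ± {r.ratio_sd:.2f}"
                     if r.ratio_mean is not None else "")
            p = "degen." if r.degenerate else (
                "<0.001" if r.p < 0.001 else f"{r.p:.3f}")
            lines.append(f"{r.structure:<22}{r.metric:<13}{ab:>18}{bb:>18}"
                         f"{r.diff:>9.{prec}f}{ratio:>14}{p:>10}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot_mean_dvh(self, structure: str, ax=None):
        """Overlay the arm-mean cumulative DVHs for one structure."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cohort, label, style in ((self.model.cohort_a, self.label_a, "-"),
                                     (self.model.cohort_b, self.label_b, "--")):
            grids = [r.dvhs[structure] for r in cohort]
            dmax = max(g.max_dose_edge for g in grids)
            dose = np.linspace(0, dmax, 400)
            mean_cum = np.mean([np.interp(dose, g.dose_edges, g.cumulative_volume,
                                          right=0.0) for g in grids], axis=0)
            ax.plot(dose, 100 * mean_cum, style, label=f"{structure} ({label})")
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("volume (%)")
        ax.legend()
        return ax
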