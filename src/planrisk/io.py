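"""Readers/writers for the plain-text DVH export dialect, run configuration,
and the end-to-end pipeline.

DVH CSV dialect (one file per plan)
-----------------------------------
::

    # patient=P001 technique=IMRT age=47.3 mu=893 beam_on_min=1.490 treat_time_min=7.000
    # structure_volume_cc PTV1=367.2
    # structure_volume_cc heart=612.5
    structure,dose_gy,volume_pct
    PTV1,0.00,100
    PTV1,0.05,100
    ...

* the first line is a ``key=value`` header; ``patient``, ``technique`` and
  ``age`` are required, delivery metadata and the three conformity volumes
  (``v_ptv_cc``, ``v_rx_cc``, ``v_ptv_rx_cc``) optional;
* one ``structure_volume_cc`` sidecar comment per structure gives absolute
  volumes;
* rows are cumulative volume-percent versus ascending dose within each
  structure block.  If the header declares ``volume_unit=cc`` the third
  column is absolute cc instead and is normalised by the sidecar volume.

Validation failures raise :class:`~planrisk.errors.DvhParseError` carrying
the offending line number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .compare import (Cohort, MetricPanel, PairedPlanComparison,
                      PlanComparisonResults, PlanRecord, default_panel)
from .dvh import DoseVolumeHistogram
from .errors import (ConfigError, DvhParseError, InvalidDvhError)
from .radiobio import load_registry, registry_fingerprint
from .synthetic import CohortSpec, default_cohort_spec, generate_cohort

__all__ = [
    "read_dvh_file", "write_plan_record", "read_cohort",
    "RunConfig", "load_run_config", "load_panel", "run_pipeline",
]

_REQUIRED_HEADER = ("patient", "technique", "age")


# ----------------------------------------------------------------- DVH files

def write_plan_record(record: PlanRecord, path: str | Path) -> None:
    """Write one plan to the DVH CSV dialect (cumulative volume percent)."""
    path = Path(path)
    head = [f"patient={record.patient_id}", f"technique={record.technique}",
            f"age={record.age_x:.10g}", f"mu={record.mu}",
            f"beam_on_min={record.beam_on_min:.10g}",
            f"treat_time_min={record.treat_time_min:.10g}"]
    if record.conformity_volumes is not None:
        v_ptv, v_rx, v_ptv_rx = record.conformity_volumes
        head += [f"v_ptv_cc={v_ptv:.10g}", f"v_rx_cc={v_rx:.10g}",
                 f"v_ptv_rx_cc={v_ptv_rx:.10g}"]
    lines = ["# " + " ".join(head)]
    for name, dvh in record.dvhs.items():
        lines.append(f"# structure_volume_cc {name}={dvh.total_volume:.10g}")
    lines.append("structure,dose_gy,volume_pct")
    for name, dvh in record.dvhs.items():
        for d, v in zip(dvh.dose_edges, dvh.cumulative_volume):
            lines.append(f"{name},{d:.10g},{100.0 * v:.10g}")
    path.write_text("\n".join(lines) + "\n")


def _parse_header(line: str, lineno: int) -> dict[str, str]:
    fields = line.lstrip("#").split()
    out = {}
    for tok in fields:
        if "=" not in tok:
            raise DvhParseError(f"malformed header token {tok!r}", lineno)
        k, v = tok.split("=", 1)
        out[k] = v
    missing = [k for k in _REQUIRED_HEADER if k not in out]
    if missing:
        raise DvhParseError(f"header missing required keys {missing}", lineno)
    return out


def read_dvh_file(path: str | Path) -> PlanRecord:
    """Parse one DVH CSV export into a fully validated :class:`PlanRecord`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise DvhParseError("first line must be the '# key=value' header", 1)
    header = _parse_header(lines[0], 1)
    unit = header.get("volume_unit", "percent")
    if unit not in ("percent", "cc"):
        raise DvhParseError(f"unknown volume unit {unit!r}", 1)

    sidecar: dict[str, float] = {}
    rows: dict[str, list[tuple[int, float, float]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("structure_volume_cc"):
                try:
                    name, vol = body.split(None, 1)[1].split("=", 1)
                    sidecar[name] = float(vol)
                except (IndexError, ValueError):
                    raise DvhParseError("malformed structure_volume_cc sidecar", lineno)
            continue
        if line.lower().startswith("structure,"):
            continue  # column header
        parts = line.split(",")
        if len(parts) != 3:
            raise DvhParseError(f"expected 'structure,dose_gy,volume', got {line!r}",
                                lineno)
        name = parts[0].strip()
        try:
            dose, vol = float(parts[1]), float(parts[2])
        except ValueError:
            raise DvhParseError(f"non-numeric dose/volume in {line!r}", lineno)
        if name not in rows:
            rows[name] = []
            order.append(name)
        rows[name].append((lineno, dose, vol))

    if not rows:
        raise DvhParseError("file contains no DVH rows", len(lines))

    dvhs: dict[str, DoseVolumeHistogram] = {}
    for name in order:
        entries = rows[name]
        for (l_prev, d_prev, _), (l_cur, d_cur, _) in zip(entries, entries[1:]):
            if d_cur <= d_prev:
                raise DvhParseError(
                    f"{name}: dose must be strictly ascending "
                    f"({d_cur} after {d_prev})", l_cur)
        for (_, _, v_prev), (l_cur, _, v_cur) in zip(entries, entries[1:]):
            if v_cur > v_prev + 1e-9:
                raise DvhParseError(
                    f"{name}: cumulative volume must be non-increasing "
                    f"({v_cur} after {v_prev})", l_cur)
        doses = np.array([e[1] for e in entries])
        vols = np.array([e[2] for e in entries])
        if unit == "cc":
            if name not in sidecar:
                raise DvhParseError(
                    f"{name}: volume_unit=cc requires a structure_volume_cc "
                    "sidecar row", entries[0][0])
            total = sidecar[name]
            frac = vols / total
        else:
            total = sidecar.get(name, 1.0)
            frac = vols / 100.0
        try:
            dvhs[name] = DoseVolumeHistogram(name, doses, frac, total)
        except InvalidDvhError as exc:
            raise DvhParseError(str(exc), entries[0][0])

    conf = None
    if all(k in header for k in ("v_ptv_cc", "v_rx_cc", "v_ptv_rx_cc")):
        conf = (float(header["v_ptv_cc"]), float(header["v_rx_cc"]),
                float(header["v_ptv_rx_cc"]))
    try:
        return PlanRecord(
            patient_id=header["patient"], technique=header["technique"],
            age_x=float(header["age"]), dvhs=dvhs,
            mu=int(float(header.get("mu", 0))),
            beam_on_min=float(header.get("beam_on_min", 0.0)),
            treat_time_min=float(header.get("treat_time_min", 0.0)),
            conformity_volumes=conf)
    except ValueError as exc:
        raise DvhParseError(str(exc), 1)


def read_cohort(directory: str | Path, technique: str | None = None) -> Cohort:
    """Read every ``*.csv`` plan file in a directory into one cohort."""
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise DvhParseError(f"no DVH CSV files found in {directory}")
    return Cohort([read_dvh_file(f) for f in files], technique)


# -------------------------------------------------------------- configuration

@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either point ``cohort_a_dir``/``cohort_b_dir`` at existing DVH exports or
    leave them unset to simulate a cohort from ``cohort_spec``.
    """

    out_dir: str | Path = "planrisk_out"
    seed: int = 17
    n_patients: int = 30
    panel: MetricPanel = field(default_factory=default_panel)
    registry_overrides: Mapping[str, Mapping[str, float]] | None = None
    cohort_a_dir: str | Path | None = None
    cohort_b_dir: str | Path | None = None
    cohort_spec: CohortSpec | None = None
    write_simulated_dvhs: bool = False

    def __post_init__(self):
        if self.panel.is_empty():
            raise ConfigError("metric panel is empty")
        if (self.cohort_a_dir is None) != (self.cohort_b_dir is None):
            raise ConfigError("provide both cohort directories or neither")


def load_panel(path: str | Path) -> MetricPanel:
    """Load a metric panel from a YAML or JSON file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return MetricPanel.from_dict(data)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML or JSON file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    panel = (MetricPanel.from_dict(data["panel"]) if "panel" in data
             else default_panel())
    return RunConfig(
        out_dir=data.get("out_dir", "planrisk_out"),
        seed=int(data.get("seed", 17)),
        n_patients=int(data.get("n_patients", 30)),
        panel=panel,
        registry_overrides=data.get("registry_overrides"),
        cohort_a_dir=data.get("cohort_a_dir"),
        cohort_b_dir=data.get("cohort_b_dir"),
        write_simulated_dvhs=bool(data.get("write_simulated_dvhs", False)),
    )


# ------------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig) -> PlanComparisonResults:
    """simulate (or load) -> metrics -> radiobiology -> paired comparison.

    Writes, under ``config.out_dir``: ``comparison.csv`` (every row),
    ``targets.csv`` / ``oars.csv`` / ``risk.csv`` / ``efficiency.csv``
    (sub-table views), ``summary.txt`` and ``run_log.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry(config.registry_overrides)

    if config.cohort_a_dir is not None:
        cohort_a = read_cohort(config.cohort_a_dir)
        cohort_b = read_cohort(config.cohort_b_dir)
        source = {"cohort_a_dir": str(config.cohort_a_dir),
                  "cohort_b_dir": str(config.cohort_b_dir)}
    else:
        spec = config.cohort_spec or default_cohort_spec(
            n_patients=config.n_patients, seed=config.seed)
        dvh_dir = out / "dvhs" if config.write_simulated_dvhs else None
        cohort_a, cohort_b, _ = generate_cohort(spec, out_dir=dvh_dir,
                                                overwrite=True)
        source = {"simulated": True, "seed": spec.seed,
                  "n_patients": spec.n_patients}

    results = PairedPlanComparison(cohort_a, cohort_b, config.panel,
                                   registry).fit()
    results.to_csv(out / "comparison.csv")
    results.target_table().to_csv(out / "targets.csv", index=False)
    results.oar_table().to_csv(out / "oars.csv", index=False)
    results.risk_table().to_csv(out / "risk.csv", index=False)
    results.efficiency_table().to_csv(out / "efficiency.csv", index=False)
    (out / "summary.txt").write_text(results.summary() + "\n")
    log = {
        "planrisk_version": __version__,
        "seed": config.seed,
        "n_patients": len(cohort_a),
        "source": source,
        "registry_fingerprint": registry_fingerprint(registry),
        "panel": config.panel.to_dict(),
        "rows": len(results.rows),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return results
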