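"""Radiobiological models evaluated on cumulative DVHs.

Implements the model chain used for two-technique plan comparison in
post-mastectomy breast radiotherapy:

* gEUD — generalized equivalent uniform dose ``(sum v_i D_i^a)^(1/a)``;
* LKB NTCP — Lyman–Kutcher–Burman probit on EUD with volume exponent
  ``a = 1/n`` (radiation pneumonitis of the lung);
* relative seriality NTCP — Poisson-based voxel response combined through a
  seriality parameter ``s`` (cardiac mortality);
* OED — organ equivalent dose under the linear response model, which equals
  the organ mean dose;
* SCCP — secondary cancer complication probability, OED times an
  organ-specific absolute incidence rate in % per Gy;
* EAR — excess absolute risk of a radiation-induced second cancer per
  10,000 person-years, with age-at-exposure and attained-age modifiers
  (Schneider's formulation).

All models act on physical dose; no fractionation (LQ/EQD2) correction is
applied.  The default parameter registry carries the organ/endpoint sets
used for the lung, heart and contralateral breast; every value can be
overridden from a YAML/JSON mapping via :func:`load_registry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Union

import numpy as np
from scipy.stats import norm

from .dvh import DoseVolumeHistogram
from .errors import ConfigError, DomainError

__all__ = [
    "LkbParams", "SerialityParams", "EarParams", "SccpParams", "RadiobioResult",
    "geud", "lkb_ntcp", "seriality_ntcp", "oed_linear", "sccp", "ear",
    "ear_age_modifier", "DEFAULT_REGISTRY", "load_registry", "registry_fingerprint",
]


@dataclass(frozen=True)
class LkbParams:
    """Lyman–Kutcher–Burman parameters: tolerance dose D50 (Gy), volume-effect
    exponent n (EUD exponent a = 1/n), and probit slope m."""

    d50: float
    n: float
    m: float

    def __post_init__(self):
        if self.d50 <= 0 or self.n <= 0 or self.m <= 0:
            raise DomainError("LKB parameters d50, n, m must all be > 0")


@dataclass(frozen=True)
class SerialityParams:
    """Relative seriality parameters: D50 (Gy), seriality s (1 = fully
    serial), and normalized dose-response slope gamma."""

    d50: float
    s: float
    gamma: float

    def __post_init__(self):
        if self.d50 <= 0 or self.s <= 0 or self.gamma <= 0:
            raise DomainError("seriality parameters d50, s, gamma must all be > 0")


@dataclass(frozen=True)
class EarParams:
    """Excess-absolute-risk dose-response: initial slope beta (excess cases
    per 10,000 person-years per Gy) and age modifiers gamma_e (per year of
    age at exposure, centred at 30) and gamma_a (on ln(attained age / 70))."""

    beta: float
    gamma_e: float
    gamma_a: float
    attained_age: float = 75.0

    def __post_init__(self):
        if self.beta <= 0:
            raise DomainError("EAR beta must be > 0")
        if self.attained_age <= 0:
            raise DomainError("attained age must be > 0 years")


@dataclass(frozen=True)
class SccpParams:
    """Organ-specific absolute cancer incidence rate In_org in % per Gy."""

    incidence_rate: float

    def __post_init__(self):
        if self.incidence_rate <= 0:
            raise DomainError("incidence_rate must be > 0 %/Gy")


@dataclass(frozen=True)
class RadiobioResult:
    """NTCP/OED/SCCP/EAR bundle for one structure of one plan."""

    structure_name: str
    ntcp: float | None = None       # probability in [0, 1]
    oed: float | None = None        # Gy
    sccp: float | None = None       # %
    ear: float | None = None        # excess cases per 10,000 person-years


# --------------------------------------------------------------------- models

def geud(dvh: DoseVolumeHistogram, a: float) -> float:
    """Generalized equivalent uniform dose ``(sum v_i D_i^a)^(1/a)``.

    ``a = 1`` gives the mean dose; large ``a`` approaches the maximum dose;
    negative ``a`` emphasises cold spots and is undefined when any occupied
    bin has zero dose.
    """
    if a == 0:
        raise DomainError("gEUD exponent a must be nonzero")
    mids, vols = dvh.differential()
    occupied = vols > 0
    mids, vols = mids[occupied], vols[occupied]
    total = vols.sum()
    if total <= 0:
        return 0.0
    vols = vols / total
    if a < 0 and np.any(mids <= 1e-6):
        # bins below 1e-6 Gy count as zero dose (raster half-bins included)
        raise DomainError("gEUD with a < 0 is undefined for zero-dose bins")
    return float(np.dot(vols, np.power(mids, a)) ** (1.0 / a))


def lkb_ntcp(dvh: DoseVolumeHistogram, params: LkbParams) -> float:
    """LKB complication probability: probit of ``(EUD - D50) / (m D50)``
    with ``EUD = gEUD(1/n)``.  Evaluated with the closed-form normal CDF."""
    eud = geud(dvh, 1.0 / params.n)
    t = (eud - params.d50) / (params.m * params.d50)
    return float(norm.cdf(t))


def _seriality_bin_response(dose: np.ndarray, params: SerialityParams) -> np.ndarray:
    """Poisson cell-kill response ``P(D) = 2^(-exp(e*gamma*(1 - D/D50)))``."""
    x = math.e * params.gamma * (1.0 - np.asarray(dose, dtype=float) / params.d50)
    # clip the inner exponent: exp(>700) overflows, and P is 0/1 far sooner
    return np.exp2(-np.exp(np.clip(x, -700.0, 700.0)))


def seriality_ntcp(dvh: DoseVolumeHistogram, params: SerialityParams) -> float:
    """Relative seriality NTCP over the differential bins:

    ``NTCP = [1 - prod_i (1 - P(D_i)^s)^(v_i)]^(1/s)``

    with volume fractions ``v_i`` and the per-bin response ``P`` above.
    For ``s = 1`` this reduces to ``1 - prod (1 - P(D_i))^(v_i)``.
    """
    mids, vols = dvh.differential()
    occupied = vols > 0
    mids, vols = mids[occupied], vols[occupied]
    p = _seriality_bin_response(mids, params)
    ps = np.power(p, params.s)
    with np.errstate(divide="ignore"):
        log_surv = np.dot(vols, np.log1p(-ps))       # -inf if any bin fully responds
    if np.isneginf(log_surv):
        return 1.0
    inner = -np.expm1(log_surv)                      # 1 - prod(...)
    inner = min(max(inner, 0.0), 1.0)
    return float(inner ** (1.0 / params.s))


def oed_linear(dvh: DoseVolumeHistogram) -> float:
    """Organ equivalent dose under the linear response model,
    ``(1/V_t) sum V_i D_i`` — identically the organ mean dose."""
    return dvh.mean_dose()


def sccp(oed: float, params: SccpParams) -> float:
    """Secondary cancer complication probability in %, ``OED * In_org``."""
    if oed < 0:
        raise DomainError("OED must be >= 0 Gy")
    return oed * params.incidence_rate


def ear_age_modifier(params: EarParams, age_at_exposure: float) -> float:
    """Age modifier ``exp(gamma_e (age_x - 30) + gamma_a ln(age_a / 70))``;
    equals 1 at age 30 with attained age 70."""
    if not (0 < age_at_exposure < params.attained_age):
        raise DomainError(
            f"need 0 < age at exposure ({age_at_exposure}) < attained age "
            f"({params.attained_age})"
        )
    return math.exp(params.gamma_e * (age_at_exposure - 30.0)
                    + params.gamma_a * math.log(params.attained_age / 70.0))


def ear(oed: float, params: EarParams, age_at_exposure: float) -> float:
    """Excess absolute risk per 10,000 person-years:
    ``EAR = OED * beta * exp(gamma_e (age_x - 30) + gamma_a ln(age_a / 70))``.

    Proportional to OED; the modifier is 1 for exposure at 30 attained at 70.
    """
    if oed < 0:
        raise DomainError("OED must be >= 0 Gy")
    return oed * params.beta * ear_age_modifier(params, age_at_exposure)


# ------------------------------------------------------------------- registry

ParamSet = Union[LkbParams, SerialityParams, EarParams, SccpParams]

#: Named parameter sets for the modelled organ/endpoint pairs: pneumonitis
#: NTCP of the lung (LKB), cardiac mortality NTCP (relative seriality), and
#: second-cancer SCCP/EAR rates for lung tissue and the contralateral breast.
DEFAULT_REGISTRY: dict[str, ParamSet] = {
    "lung_lkb_pneumonitis": LkbParams(d50=30.80, n=0.98, m=0.37),
    "heart_seriality_mortality": SerialityParams(d50=52.4, s=1.0, gamma=1.3),
    "ear_lung": EarParams(beta=7.5, gamma_e=0.002, gamma_a=4.23),
    "ear_breast": EarParams(beta=9.2, gamma_e=-0.037, gamma_a=1.7),
    "sccp_lung": SccpParams(incidence_rate=1.68),
    "sccp_breast": SccpParams(incidence_rate=0.78),
}


def load_registry(overrides: Mapping[str, Mapping[str, float]] | None = None
                  ) -> dict[str, ParamSet]:
    """Return the default registry with per-field overrides applied.

    ``overrides`` maps a registry name to a partial field mapping, e.g.
    ``{"lung_lkb_pneumonitis": {"m": 0.45}}``.  Unknown names or fields
    raise :class:`ConfigError`.
    """
    registry = dict(DEFAULT_REGISTRY)
    for name, fields in (overrides or {}).items():
        if name not in registry:
            raise ConfigError(
                f"unknown parameter set {name!r}; known: {sorted(registry)}")
        try:
            registry[name] = replace(registry[name], **dict(fields))
        except TypeError as exc:
            raise ConfigError(f"bad override for {name!r}: {exc}") from exc
    return registry


def registry_fingerprint(registry: Mapping[str, ParamSet]) -> str:
    """Stable hash of a parameter registry, recorded in run logs."""
    import hashlib
    import json

    payload = {k: vars(v) for k, v in sorted(registry.items())}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def evaluate_structure(
    dvh: DoseVolumeHistogram,
    *,
    ntcp_params: LkbParams | SerialityParams | None = None,
    sccp_params: SccpParams | None = None,
    ear_params: EarParams | None = None,
    age_at_exposure: float | None = None,
) -> RadiobioResult:
    """Evaluate the configured model set on one structure's DVH."""
    ntcp_val = None
    if isinstance(ntcp_params, LkbParams):
        ntcp_val = lkb_ntcp(dvh, ntcp_params)
    elif isinstance(ntcp_params, SerialityParams):
        ntcp_val = seriality_ntcp(dvh, ntcp_params)
    elif ntcp_params is not None:
        raise ConfigError(f"unsupported NTCP parameter type {type(ntcp_params).__name__}")
    oed = oed_linear(dvh) if (sccp_params or ear_params) else None
    sccp_val = sccp(oed, sccp_params) if sccp_params else None
    ear_val = None
    if ear_params:
        if age_at_exposure is None:
            raise ConfigError("EAR evaluation needs the patient's age at exposure")
        ear_val = ear(oed, ear_params, age_at_exposure)
    return RadiobioResult(dvh.structure_name, ntcp_val, oed, sccp_val, ear_val)
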