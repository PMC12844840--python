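"""Organ clearance models.

Renal and hepatic clearance built from the parallel/in-series calculus,
alongside the differential-equation-derived alternatives they are
compared against:

* renal: blood flow in series with the parallel sum of filtration and
  net tubular transport, ``1/CL_R = 1/Q_R + 1/(f_uB·GFR + CL_sec − CL_reab)``;
* hepatic: blood flow, net basolateral transport and intrinsic
  elimination in series,
  ``1/CL_H = 1/Q_H + 1/(f_uB·(CL_int,influx − CL_int,efflux)) + 1/(f_uB·CL_int)``;
* the familiar flow/intrinsic-clearance form
  ``Q·f_uB·CL_int/(Q + f_uB·CL_int)`` (historically called the
  well-stirred model) as the transport-free reduction;
* the Extended Clearance Concept (ECC), which keeps influx and efflux
  as separate parameters, for side-by-side comparison;
* back-calculation of intrinsic clearance from single-pass perfusion
  steady states under the well-stirred and parallel-tube conventions.

All clearances are in L/h internally; ``*_ml_min`` constructors accept
the renal-physiology convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import pandas as pd

from .errors import (
    InfeasibleModelError,
    InfeasibleObservationError,
    InputError,
    NonRateDefiningError,
)
from .network import combine_series, entering_leaving_total
from .units import ml_min_to_l_h

__all__ = [
    "RenalParameters",
    "HepaticParameters",
    "PerfusionSteadyState",
    "RateLimitClassification",
    "renal_clearance",
    "renal_net_secretion_from_observed",
    "hepatic_clearance",
    "well_stirred_form",
    "hepatic_transport_limited",
    "ecc_clearance",
    "compare_ecc_vs_kirchhoff",
    "classify_rate_limiting_step",
    "intrinsic_clearance_from_perfusion",
    "hepatic_bioavailability",
]


@dataclass(frozen=True)
class RenalParameters:
    """Kidney disposition parameters (canonical units L/h).

    Attributes
    ----------
    Q_R : renal blood flow, L/h
    f_uB : fraction unbound in blood, in (0, 1]
    GFR : glomerular filtration rate, L/h
    CL_sec : tubular secretory clearance, L/h (≥ 0)
    CL_reab : tubular reabsorptive clearance, L/h (≥ 0)
    """

    Q_R: float
    f_uB: float
    GFR: float
    CL_sec: float = 0.0
    CL_reab: float = 0.0

    def __post_init__(self) -> None:
        for f in ("Q_R", "f_uB", "GFR", "CL_sec", "CL_reab"):
            object.__setattr__(self, f, float(getattr(self, f)))
        if self.Q_R <= 0:
            raise InputError("renal blood flow Q_R must be positive")
        if not 0 < self.f_uB <= 1:
            raise InputError("f_uB must lie in (0, 1]")
        if self.GFR < 0 or self.CL_sec < 0 or self.CL_reab < 0:
            raise InputError("GFR, CL_sec and CL_reab must be non-negative")

    @classmethod
    def from_ml_min(cls, Q_R, f_uB, GFR, CL_sec=0.0, CL_reab=0.0) -> "RenalParameters":
        return cls(
            Q_R=ml_min_to_l_h(Q_R),
            f_uB=f_uB,
            GFR=ml_min_to_l_h(GFR),
            CL_sec=ml_min_to_l_h(CL_sec),
            CL_reab=ml_min_to_l_h(CL_reab),
        )

    @property
    def net_transport(self) -> float:
        return self.CL_sec - self.CL_reab


@dataclass(frozen=True)
class HepaticParameters:
    """Liver disposition parameters (canonical units L/h).

    ``CL_int`` is the sum of the intrinsic metabolic and biliary
    clearances.  ``transport_in_scope`` marks whether basolateral
    transport is treated as a rate-defining series stage; when False the
    transport clearances are ignored and the model reduces to the
    flow/intrinsic-clearance form.
    """

    Q_H: float
    f_uB: float
    CL_int: float
    CL_int_influx: float = 0.0
    CL_int_efflux: float = 0.0
    transport_in_scope: bool = False

    def __post_init__(self) -> None:
        for f in ("Q_H", "f_uB", "CL_int", "CL_int_influx", "CL_int_efflux"):
            object.__setattr__(self, f, float(getattr(self, f)))
        if self.Q_H <= 0:
            raise InputError("hepatic blood flow Q_H must be positive")
        if not 0 < self.f_uB <= 1:
            raise InputError("f_uB must lie in (0, 1]")
        if self.CL_int < 0:
            raise InputError("CL_int must be non-negative")
        if self.CL_int_influx < 0 or self.CL_int_efflux < 0:
            raise InputError("transporter intrinsic clearances must be non-negative")

    @property
    def net_transport(self) -> float:
        return self.CL_int_influx - self.CL_int_efflux


@dataclass(frozen=True)
class PerfusionSteadyState:
    """A single-pass organ perfusion steady state.

    ``C_in_u``/``C_out_u`` are unbound inlet/outlet concentrations; for
    an eliminating organ ``C_in_u > C_out_u > 0``.  ``C_blood`` is the
    systemic (reference) total blood concentration; the convention used
    to choose it (here: inlet total) travels with the fixture.
    """

    C_in_u: float
    C_out_u: float
    C_blood: float
    Q_H: float
    f_uB: float
    convention: str = "inlet_total"

    def __post_init__(self) -> None:
        if not self.C_in_u > self.C_out_u > 0:
            raise InputError(
                "an eliminating organ requires C_in_u > C_out_u > 0 "
                f"(got {self.C_in_u}, {self.C_out_u})"
            )
        if self.C_blood <= 0 or self.Q_H <= 0 or not 0 < self.f_uB <= 1:
            raise InputError("C_blood, Q_H must be positive and 0 < f_uB <= 1")


@dataclass(frozen=True)
class RateLimitClassification:
    """Which in-series stage dominates 1/CL_H.

    ``label`` is one of blood_flow_limited / net_transport_limited /
    elimination_limited / mixed; ``dominance_ratio`` is the largest
    single-stage share of the total reciprocal clearance.
    """

    label: str
    dominance_ratio: float


# --- renal ------------------------------------------------------------------

def renal_clearance(p: RenalParameters) -> float:
    """Renal clearance with blood flow in series with the leaving processes.

    The leaving stage is the parallel sum of filtration (f_uB·GFR) and
    net tubular transport (CL_sec − CL_reab); a non-positive leaving
    stage (net reabsorption exceeding filtration) is not rate-defining
    and raises rather than being clamped.
    """
    leaving = p.f_uB * p.GFR + p.net_transport
    if leaving <= 0:
        raise NonRateDefiningError(
            "filtration plus net tubular transport is non-positive "
            f"({leaving:.4g} L/h); the leaving stage is not rate-defining"
        )
    if p.net_transport > 0:
        # filtration and net secretion are parallel leaving processes, in
        # series with delivery by renal blood flow
        return entering_leaving_total([p.Q_R], [p.f_uB * p.GFR, p.net_transport])
    # net reabsorption: the leaving stage is still positive overall
    return combine_series([p.Q_R, leaving])


def renal_net_secretion_from_observed(
    CL_R_obs: float,
    Q_R: float,
    f_uB: float,
    GFR: float,
    include_blood_flow: bool = True,
) -> float:
    """Net tubular secretory clearance implied by an observed renal clearance.

    With ``include_blood_flow`` the series equation is inverted:
    ``net = 1/(1/CL_R − 1/Q_R) − f_uB·GFR``; otherwise the traditional
    flow-free estimate ``CL_R − f_uB·GFR`` is returned.  All magnitudes
    share one unit (L/h or mL/min) since the expression is homogeneous.
    """
    if CL_R_obs <= 0:
        raise InputError("observed renal clearance must be positive")
    if include_blood_flow:
        if CL_R_obs >= Q_R:
            raise InfeasibleObservationError(
                f"observed CL_R {CL_R_obs} >= renal blood flow {Q_R}: no "
                "series decomposition exists"
            )
        leaving = 1.0 / (1.0 / CL_R_obs - 1.0 / Q_R)
        return leaving - f_uB * GFR
    return CL_R_obs - f_uB * GFR


# --- hepatic ----------------------------------------------------------------

def hepatic_clearance(p: HepaticParameters) -> float:
    """Hepatic clearance as up to three in-series rate-defining stages.

    Stages: blood flow Q_H; net basolateral transport
    f_uB·(CL_int,influx − CL_int,efflux) when in scope; intrinsic
    elimination f_uB·CL_int.  With ``transport_in_scope=False`` this is
    exactly :func:`well_stirred_form`.
    """
    if p.CL_int <= 0:
        raise InputError("hepatic elimination requires CL_int > 0")
    stages = [p.Q_H]
    if p.transport_in_scope:
        if p.net_transport <= 0:
            raise NonRateDefiningError(
                f"net basolateral transport {p.net_transport:.4g} L/h is not "
                "positive and cannot be rate-defining"
            )
        stages.append(p.f_uB * p.net_transport)
    stages.append(p.f_uB * p.CL_int)
    return combine_series(stages)


def well_stirred_form(Q_H: float, f_uB: float, CL_int: float) -> float:
    """The flow/intrinsic-clearance series form Q·f_uB·CL_int/(Q + f_uB·CL_int).

    Here it is the two-stage series combination of blood flow and
    intrinsic elimination, derived without any intra-organ mixing
    assumption — though it is algebraically the classical well-stirred
    model expression.
    """
    if Q_H <= 0 or f_uB <= 0 or CL_int <= 0:
        raise InputError("Q_H, f_uB and CL_int must be positive")
    return combine_series([Q_H, f_uB * CL_int])


def hepatic_transport_limited(p: HepaticParameters) -> float:
    """Hepatic clearance when blood flow is non-limiting (Q_H → ∞).

    ``CL_H = f_uB·CL_int·net/(CL_int + net)`` with
    ``net = CL_int,influx − CL_int,efflux``.
    """
    net = p.net_transport
    if net <= 0:
        raise NonRateDefiningError(
            f"net basolateral transport {net:.4g} L/h is not positive and "
            "cannot be rate-defining"
        )
    if p.CL_int <= 0:
        raise InputError("hepatic elimination requires CL_int > 0")
    return combine_series([p.f_uB * net, p.f_uB * p.CL_int])


def ecc_clearance(p: HepaticParameters, simplified: bool = False) -> float:
    """Hepatic clearance under the Extended Clearance Concept.

    Full form:
    ``Q_H·CL_influx·f_uB·CL_int / (CL_influx·f_uB·CL_int + Q_H·CL_int + Q_H·CL_efflux)``.
    With ``simplified=True`` the Q_H → ∞ limit
    ``CL_influx·f_uB·CL_int/(CL_int + CL_efflux)`` is used.

    Influx ≤ efflux is permitted: the ECC carries the two directions as
    separate parameters rather than as a net difference.
    """
    num_core = p.CL_int_influx * p.f_uB * p.CL_int
    if simplified:
        denom = p.CL_int + p.CL_int_efflux
        if denom <= 0:
            raise InfeasibleModelError("degenerate ECC parameters: zero denominator")
        return num_core / denom
    denom = num_core + p.Q_H * p.CL_int + p.Q_H * p.CL_int_efflux
    if denom <= 0:
        raise InfeasibleModelError("degenerate ECC parameters: zero denominator")
    return p.Q_H * num_core / denom


def compare_ecc_vs_kirchhoff(p: HepaticParameters) -> dict:
    """Evaluate the net-transport series form and the ECC on identical inputs.

    Returns a report dict with per-framework values (or the reason one
    is unavailable), their ratio when both exist, and the rate-limit
    classification of the series form.  Framework failures are reported
    inside the result, never raised.
    """
    report: dict = {
        "parameters": p,
        "CL_kirchhoff": None,
        "CL_ecc": None,
        "ratio_ecc_over_kirchhoff": None,
        "kirchhoff_note": "",
        "ecc_note": "",
        "rate_limit": None,
    }
    try:
        report["CL_ecc"] = ecc_clearance(p, simplified=True)
    except InfeasibleModelError as exc:
        report["ecc_note"] = str(exc)
    try:
        report["CL_kirchhoff"] = hepatic_transport_limited(p)
        report["rate_limit"] = classify_rate_limiting_step(
            replace(p, transport_in_scope=True)
        )
    except (NonRateDefiningError, InputError) as exc:
        report["kirchhoff_note"] = str(exc)
    if report["CL_ecc"] is not None and report["CL_kirchhoff"]:
        report["ratio_ecc_over_kirchhoff"] = report["CL_ecc"] / report["CL_kirchhoff"]
    return report


def ecc_kirchhoff_sweep(parameter_grid) -> pd.DataFrame:
    """Tabulate :func:`compare_ecc_vs_kirchhoff` over an iterable of parameter sets."""
    rows = []
    for p in parameter_grid:
        r = compare_ecc_vs_kirchhoff(p)
        rows.append(
            {
                "Q_H": p.Q_H,
                "f_uB": p.f_uB,
                "CL_int": p.CL_int,
                "CL_int_influx": p.CL_int_influx,
                "CL_int_efflux": p.CL_int_efflux,
                "CL_kirchhoff": r["CL_kirchhoff"],
                "CL_ecc": r["CL_ecc"],
                "ratio_ecc_over_kirchhoff": r["ratio_ecc_over_kirchhoff"],
                "rate_limit": r["rate_limit"].label if r["rate_limit"] else None,
                "kirchhoff_note": r["kirchhoff_note"],
            }
        )
    return pd.DataFrame(rows)


def classify_rate_limiting_step(
    p: HepaticParameters, dominance_fraction: float = 0.9
) -> RateLimitClassification:
    """Label the in-series stage dominating 1/CL_H, if any.

    A stage is rate-limiting when its reciprocal contributes at least
    ``dominance_fraction`` of the reciprocal total; otherwise the
    classification is "mixed".
    """
    if not 0.5 < dominance_fraction < 1:
        raise InputError("dominance_fraction must lie in (0.5, 1)")
    recips = {"blood_flow_limited": 1.0 / p.Q_H}
    if p.transport_in_scope:
        if p.net_transport <= 0:
            raise NonRateDefiningError(
                "net basolateral transport is not positive; cannot classify"
            )
        recips["net_transport_limited"] = 1.0 / (p.f_uB * p.net_transport)
    if p.CL_int <= 0:
        raise InputError("CL_int must be positive to classify")
    recips["elimination_limited"] = 1.0 / (p.f_uB * p.CL_int)
    total = sum(recips.values())
    label, share = max(recips.items(), key=lambda kv: kv[1])
    ratio = share / total
    if ratio < dominance_fraction:
        label = "mixed"
    return RateLimitClassification(label=label, dominance_ratio=ratio)


def intrinsic_clearance_from_perfusion(ss: PerfusionSteadyState, model: str) -> float:
    """Back-calculate intrinsic clearance from a perfusion steady state.

    The organ clearance is the extraction-based
    ``CL_H = Q_H·(C_in_u − C_out_u)/C_in_u``; each mechanistic model
    then references CL_int to its own average unbound concentration:

    * WSM — outlet: ``CL_int = CL_H·C_blood/C_out_u``
    * PTM — logarithmic mean: ``CL_int = CL_H·C_blood·ln(C_in_u/C_out_u)/(C_in_u − C_out_u)``

    Because C_out_u ≤ logarithmic mean ≤ C_in_u, CL_int,WSM ≥ CL_int,PTM
    for any nonzero extraction.
    """
    CL_H = ss.Q_H * (ss.C_in_u - ss.C_out_u) / ss.C_in_u
    if model == "WSM":
        return CL_H * ss.C_blood / ss.C_out_u
    if model == "PTM":
        log_mean = (ss.C_in_u - ss.C_out_u) / math.log(ss.C_in_u / ss.C_out_u)
        return CL_H * ss.C_blood / log_mean
    raise InputError(f"unknown perfusion model {model!r}; expected 'WSM' or 'PTM'")


def hepatic_bioavailability(CL_H: float, Q_H: float) -> float:
    """Hepatic availability F_H = 1 − CL_H/Q_H for 0 < CL_H < Q_H."""
    if not 0 < CL_H < Q_H:
        raise InfeasibleModelError(
            f"hepatic clearance {CL_H} must lie strictly between 0 and the "
            f"organ blood flow {Q_H}"
        )
    return 1.0 - CL_H / Q_H
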