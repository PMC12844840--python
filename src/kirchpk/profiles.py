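"""Noncompartmental analysis and the oral/iv bioavailability calculus.

Given fitted polyexponential disposition curves after an iv bolus and
an oral dose of the same drug, with cumulative unchanged drug in urine
(U∞) for both routes, this module computes:

* the standard iv NCA set — AUC, AUMC, MRT, CL, CL_R, CL_H, Vss,
  V_initial;
* bioavailability from urine (assumption-free) and from plasma AUC;
* mean absorption time MAT = MRT(oral) − MRT(iv), the moment statement
  of in-series input;
* the clearance chain for oral dosing:
  ``1/CL(oral) = 1/CL(iv bolus) + 1/CL(absorption site)``, whose
  inversion yields the clearance from the absorption site — the key
  quantity behind plasma bioavailability estimates exceeding unity
  when absorption is very slow;
* flip-flop composition of absorption and elimination rate constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .curves import PolyexponentialCurve
from .errors import InfeasibleChainError, InputError, InvalidCurveError
from .network import combine_series

__all__ = [
    "StudyRecord",
    "NCASummary",
    "OralAnalysis",
    "auc_inf",
    "aumc_inf",
    "nca_iv",
    "mean_absorption_time",
    "bioavailability",
    "oral_clearance_chain",
    "flip_flop_rate",
]


@dataclass(frozen=True)
class StudyRecord:
    """Paired iv-bolus and oral data for one subject.

    Doses in mg; urine amounts U∞ are cumulative unchanged drug (mg),
    0 ≤ U∞ ≤ dose per route.  Either route may be absent (None) for
    single-route analyses.
    """

    dose_iv: Optional[float] = None
    dose_oral: Optional[float] = None
    curve_iv: Optional[PolyexponentialCurve] = None
    curve_oral: Optional[PolyexponentialCurve] = None
    U_inf_iv: Optional[float] = None
    U_inf_oral: Optional[float] = None

    def __post_init__(self) -> None:
        for dose, u, route in (
            (self.dose_iv, self.U_inf_iv, "iv"),
            (self.dose_oral, self.U_inf_oral, "oral"),
        ):
            if dose is not None and dose <= 0:
                raise InputError(f"{route} dose must be positive")
            if u is not None:
                if dose is None:
                    raise InputError(f"urine amount given without a {route} dose")
                if not 0 <= u <= dose:
                    raise InputError(
                        f"{route} urinary recovery {u} mg must lie in [0, dose]"
                    )


@dataclass(frozen=True)
class NCASummary:
    """IV-bolus noncompartmental parameter set (concentrations in mg/L)."""

    AUC_0_inf: float       # mg·h/L
    AUMC_0_inf: float      # mg·h²/L
    MRT: float             # h
    CL: float              # L/h
    CL_R: Optional[float]  # L/h, requires urine data
    CL_H: Optional[float]  # L/h, total minus renal
    Vss: float             # L
    V_initial: float       # L


@dataclass(frozen=True)
class OralAnalysis:
    """Bioavailability and absorption-site clearance results."""

    F_urine: float
    F_plasma: float
    MAT: float
    CL_system_oral: float
    CL_absorption_site: float
    k_absorption: Optional[float] = None
    V_absorption_site: Optional[float] = None
    flip_flop_label: Optional[str] = None
    mat_warning: Optional[str] = None


def auc_inf(curve: PolyexponentialCurve) -> float:
    """AUC(0→∞) = Σ c_i/λ_i, signed terms included."""
    return curve.auc_inf()


def aumc_inf(curve: PolyexponentialCurve) -> float:
    """AUMC(0→∞) = Σ c_i/λ_i²."""
    return curve.aumc_inf()


def nca_iv(record: StudyRecord) -> NCASummary:
    """Standard moment NCA of the iv-bolus route.

    CL = dose/AUC; CL_R = (U∞/dose)·CL when urine data exist;
    CL_H = CL − CL_R; MRT = AUMC/AUC; Vss = CL·MRT;
    V_initial = dose/C(0) with C(0) the coefficient sum.
    """
    if record.curve_iv is None or record.dose_iv is None:
        raise InputError("iv curve and dose are required for iv NCA")
    curve = record.curve_iv
    c0 = curve.value_at_zero()
    if c0 <= 0:
        raise InvalidCurveError("iv curve has non-positive concentration at t=0")
    auc = curve.auc_inf()
    aumc = curve.aumc_inf()
    if auc <= 0:
        raise InvalidCurveError("iv curve has non-positive AUC")
    cl = record.dose_iv / auc
    mrt = aumc / auc
    cl_r = cl_h = None
    if record.U_inf_iv is not None:
        cl_r = (record.U_inf_iv / record.dose_iv) * cl
        cl_h = cl - cl_r
    return NCASummary(
        AUC_0_inf=auc,
        AUMC_0_inf=aumc,
        MRT=mrt,
        CL=cl,
        CL_R=cl_r,
        CL_H=cl_h,
        Vss=cl * mrt,
        V_initial=record.dose_iv / c0,
    )


def mean_absorption_time(record: StudyRecord) -> float:
    """MAT = MRT(oral) − MRT(iv bolus), each from curve moments.

    A non-positive MAT (possible with noisy fitted inputs) is returned
    with a warning rather than raised.
    """
    if record.curve_iv is None or record.curve_oral is None:
        raise InputError("both iv and oral curves are required for MAT")
    mat = record.curve_oral.mrt() - record.curve_iv.mrt()
    if mat <= 0:
        warnings.warn(
            f"MAT = {mat:.4g} h is not positive; likely a sampling or "
            "fitting artifact",
            stacklevel=2,
        )
    return mat


def bioavailability(record: StudyRecord) -> dict:
    """Dose-corrected bioavailability from urine and from plasma AUC.

    ``F_urine = (U∞,oral/U∞,iv)·(dose_iv/dose_oral)`` carries no
    modelling assumption.  ``F_plasma = (AUC_oral/AUC_iv)·(dose_iv/
    dose_oral)`` assumes clearance is route-independent — an assumption
    that fails when absorption-site clearance is slow, so values above
    1 are reported as computed, never clamped.
    """
    if record.curve_iv is None or record.curve_oral is None:
        raise InputError("both curves are required for bioavailability")
    if record.dose_iv is None or record.dose_oral is None:
        raise InputError("both doses are required for bioavailability")
    dose_ratio = record.dose_iv / record.dose_oral
    f_plasma = (record.curve_oral.auc_inf() / record.curve_iv.auc_inf()) * dose_ratio
    if record.U_inf_iv is None or record.U_inf_oral is None:
        raise InputError("urinary recoveries are required for F_urine")
    if record.U_inf_iv == 0:
        raise InputError("F_urine is undefined when the iv urinary recovery is zero")
    f_urine = (record.U_inf_oral / record.U_inf_iv) * dose_ratio
    return {"F_urine": f_urine, "F_plasma": f_plasma}


def oral_clearance_chain(
    record: StudyRecord, k_absorption: Optional[float] = None
) -> OralAnalysis:
    """Full oral analysis: F values, MAT, and the absorption-site clearance.

    The systemic clearance measured after oral dosing uses the
    assumption-free urinary bioavailability:
    ``CL(oral) = F_urine·dose_oral/AUC_oral``.  Because iv-bolus
    clearance and absorption-site clearance act in series,
    ``CL(absorption site) = 1/(1/CL(oral) − 1/CL(iv))``; a measured
    oral clearance at or above the iv value leaves no room for the
    absorption stage and raises.

    When the absorption rate constant is supplied, the absorption-site
    volume of distribution follows as
    ``V = CL(absorption site)/k_absorption``.
    """
    f = bioavailability(record)
    iv = nca_iv(record)
    auc_oral = record.curve_oral.auc_inf()
    cl_oral = f["F_urine"] * record.dose_oral / auc_oral
    if cl_oral >= iv.CL:
        raise InfeasibleChainError(
            f"oral-route systemic clearance {cl_oral:.4g} L/h is not below the "
            f"iv bolus clearance {iv.CL:.4g} L/h; an in-series total cannot "
            "exceed a component stage"
        )
    cl_abs = 1.0 / (1.0 / cl_oral - 1.0 / iv.CL)
    mat_warning = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        mat = mean_absorption_time(record)
        if caught:
            mat_warning = str(caught[0].message)
    v_abs = None
    label = None
    if k_absorption is not None:
        if k_absorption <= 0:
            raise InputError("k_absorption must be positive")
        v_abs = cl_abs / k_absorption
        label = flip_flop_rate(1.0 / iv.MRT, k_absorption)["label"]
    return OralAnalysis(
        F_urine=f["F_urine"],
        F_plasma=f["F_plasma"],
        MAT=mat,
        CL_system_oral=cl_oral,
        CL_absorption_site=cl_abs,
        k_absorption=k_absorption,
        V_absorption_site=v_abs,
        flip_flop_label=label,
        mat_warning=mat_warning,
    )


def flip_flop_rate(
    k_elim: float, k_absorption: float, threshold_ratio: float = 3.0
) -> dict:
    """Compose elimination and absorption into the observed oral rate constant.

    The two first-order steps are in series, so
    ``k(oral) = k_elim·k_abs/(k_elim + k_abs)``.  The label flags which
    step dominates the terminal slope: "absorption_limited" (flip-flop)
    when k_abs is more than ``threshold_ratio``-fold slower than
    k_elim, "elimination_limited" in the opposite regime, else
    "comparable".  The composition itself is exact and label-free.
    """
    if k_elim <= 0 or k_absorption <= 0:
        raise InputError("rate constants must be positive")
    k = combine_series([k_elim, k_absorption])
    if k_absorption * threshold_ratio < k_elim:
        label = "absorption_limited"
    elif k_absorption > k_elim * threshold_ratio:
        label = "elimination_limited"
    else:
        label = "comparable"
    return {"k_system_oral": k, "label": label}
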