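"""Named worked-example fixtures.

Every quantitative example in the package's documentation and test
suite is desk-scale and fully specified by a handful of constants:

* ``scheme1`` — the demonstration catenary chain C1→C2→C3→C5 with a
  parallel loss C2→C4 (k12 = 0.06, k23 = 0.15, k24 = 0.20,
  k35 = 0.50 h⁻¹; 300 mg of C1 at t = 0);
* ``scheme2`` — the same chain plus a reversible, non-eliminating side
  exchange C1↔C6, whose rate constants are *not* rate-defining;
* ``metformin`` — the renal parameter set (Q_R ≈ 1200 mL/min,
  f_uB ≈ 1, GFR ≈ 120 mL/min) for which an observed renal clearance of
  600 mL/min implies a net secretory clearance of 1080 mL/min once
  blood flow is accounted for;
* ``kl25a`` — a hypothetical poorly-absorbed neutral drug: 2500 mg iv
  bolus (biexponential 15·e^(−1.39t) + 16·e^(−0.173t) mg/L, U∞ =
  1430 mg) and 5000 mg oral (22.7·e^(−0.105t) − 22.7·e^(−1.16t) mg/L,
  U∞ = 220 mg).
"""

from __future__ import annotations

from .curves import PolyexponentialCurve
from .linear import FirstOrderNetwork
from .network import Leaf, Parallel, ProcessNetwork, RateDefiningProcess, Series
from .organs import RenalParameters
from .profiles import StudyRecord

__all__ = [
    "scheme1_network",
    "scheme2_network",
    "scheme1_process_network",
    "metformin_renal",
    "kl25a_study",
    "paper_fixtures",
]

SCHEME1_RATES = {"k12": 0.06, "k23": 0.15, "k24": 0.20, "k35": 0.50}
SCHEME1_DOSE_MG = 300.0


def scheme1_network() -> FirstOrderNetwork:
    """The demonstration chain: C1→C2; C2→C3 and C2→C4 in parallel; C3→C5."""
    r = SCHEME1_RATES
    return FirstOrderNetwork(
        species=("C1", "C2", "C3"),
        edges=(
            ("C1", "C2", r["k12"]),
            ("C2", "C3", r["k23"]),
            ("C2", "C4", r["k24"]),
            ("C3", "C5", r["k35"]),
        ),
        initial_amounts={"C1": SCHEME1_DOSE_MG},
    )


def scheme2_network(k16: float, k61: float) -> FirstOrderNetwork:
    """Scheme 1 plus a reversible non-eliminating side species C6 on C1."""
    base = scheme1_network()
    return FirstOrderNetwork(
        species=base.species + ("C6",),
        edges=base.edges + (("C1", "C6", k16), ("C6", "C1", k61)),
        initial_amounts=dict(base.initial_amounts),
    )


def scheme1_process_network() -> ProcessNetwork:
    """Scheme 1 as a rate-defining-process tree: series[k12, (k23 ∥ k24), k35]."""
    r = SCHEME1_RATES

    def leaf(name):
        return Leaf(RateDefiningProcess(name, "rate_constant", r[name]))

    return ProcessNetwork(
        Series((leaf("k12"), Parallel((leaf("k23"), leaf("k24"))), leaf("k35")))
    )


def metformin_renal() -> RenalParameters:
    """Metformin kidney parameters (stored canonically in L/h).

    CL_sec = 1080 mL/min is the net secretory clearance implied by the
    observed CL_R of 600 mL/min when renal blood flow is included.
    """
    return RenalParameters.from_ml_min(
        Q_R=1200.0, f_uB=1.0, GFR=120.0, CL_sec=1080.0, CL_reab=0.0
    )


METFORMIN_OBSERVED_CLR_ML_MIN = 600.0


def kl25a_study() -> StudyRecord:
    """The KL25A paired iv/oral study record."""
    return StudyRecord(
        dose_iv=2500.0,
        dose_oral=5000.0,
        curve_iv=PolyexponentialCurve(
            [(15.0, 1.39), (16.0, 0.173)], role="iv_disposition"
        ),
        curve_oral=PolyexponentialCurve(
            [(22.7, 0.105), (-22.7, 1.16)], role="oral_disposition"
        ),
        U_inf_iv=1430.0,
        U_inf_oral=220.0,
    )


def paper_fixtures() -> dict:
    """Catalogue of all named fixtures keyed by short name."""
    return {
        "scheme1": scheme1_network(),
        "scheme1_process_network": scheme1_process_network(),
        "scheme2_example": scheme2_network(k16=0.3, k61=0.1),
        "metformin": metformin_renal(),
        "metformin_observed_CLR_ml_min": METFORMIN_OBSERVED_CLR_ML_MIN,
        "kl25a": kl25a_study(),
    }
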