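"""Polyexponential curves and their moment summaries.

A disposition or amount curve is a signed sum of exponentials
``y(t) = Σ_i c_i · exp(−λ_i t)`` with strictly positive exponents λ_i
(1/h).  For such a curve the zeroth and first moments to infinite time
have closed forms:

``AUC(0→∞)  = Σ c_i / λ_i``
``AUMC(0→∞) = Σ c_i / λ_i²``
``MRT       = AUMC / AUC``

Concentrations are carried in mg/L, numerically identical to µg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .errors import InvalidCurveError

ROLES = ("iv_disposition", "oral_disposition", "amount_curve")


@dataclass(frozen=True)
class PolyexponentialCurve:
    """Signed sum of exponential terms ``Σ c_i exp(−λ_i t)``.

    Terms are canonicalised to strictly decreasing exponent order at
    construction; coincident exponents are merged.

    Parameters
    ----------
    terms
        Sequence of ``(coefficient, exponent)`` pairs; exponents in 1/h,
        coefficients in mg/L (disposition roles) or mg (amount curves).
    role
        "iv_disposition" (all coefficients > 0), "oral_disposition"
        (signed terms allowed; must evaluate ≥ 0 for t ≥ 0) or
        "amount_curve".
    """

    terms: Tuple[Tuple[float, float], ...]
    role: str = "amount_curve"

    def __init__(self, terms: Iterable[Sequence[float]], role: str = "amount_curve"):
        if role not in ROLES:
            raise InvalidCurveError(f"unknown curve role {role!r}")
        canon = _canonicalise(terms)
        if not canon:
            raise InvalidCurveError("curve has no terms")
        if any(lam <= 0 or not np.isfinite(lam) for _, lam in canon):
            raise InvalidCurveError("exponents must be strictly positive and finite")
        if role == "iv_disposition" and any(c <= 0 for c, _ in canon):
            raise InvalidCurveError(
                "an iv bolus disposition curve must have all-positive coefficients"
            )
        object.__setattr__(self, "terms", canon)
        object.__setattr__(self, "role", role)

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for c, _ in self.terms])

    @property
    def exponents(self) -> np.ndarray:
        return np.array([lam for _, lam in self.terms])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        vals = np.exp(-t[..., None] * self.exponents) @ self.coefficients
        return float(vals) if vals.ndim == 0 else vals

    def auc_inf(self) -> float:
        """Area under the curve from 0 to infinity, Σ c_i/λ_i."""
        return float(np.sum(self.coefficients / self.exponents))

    def aumc_inf(self) -> float:
        """Area under the first-moment (t·y) curve, Σ c_i/λ_i²."""
        return float(np.sum(self.coefficients / self.exponents**2))

    def mrt(self) -> float:
        """Mean residence time AUMC/AUC."""
        return self.aumc_inf() / self.auc_inf()

    def value_at_zero(self) -> float:
        return float(np.sum(self.coefficients))

    def scaled(self, factor: float) -> "PolyexponentialCurve":
        return PolyexponentialCurve(
            [(c * factor, lam) for c, lam in self.terms], role=self.role
        )


def _canonicalise(terms: Iterable[Sequence[float]]) -> Tuple[Tuple[float, float], ...]:
    merged: dict = {}
    for c, lam in terms:
        c, lam = float(c), float(lam)
        # merge exponents coinciding to ~1 part in 1e12
        key = next(
            (k for k in merged if abs(k - lam) <= 1e-12 * max(abs(k), abs(lam))), lam
        )
        merged[key] = merged.get(key, 0.0) + c
    out = [(c, lam) for lam, c in merged.items() if c != 0.0]
    out.sort(key=lambda t: -t[1])
    return tuple(out)
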