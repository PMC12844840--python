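"""Exact analysis of linear first-order transfer networks.

A network of species connected by first-order edges, dosed as a bolus,
obeys ``dA/dt = M·A`` with a constant rate matrix M.  This module
provides the independent oracle against which the parallel/in-series
calculus is checked:

* the analytic amount–time solution per species, as a signed sum of
  exponentials, via eigendecomposition of M;
* Bateman-type closed-form coefficients for unidirectional catenary
  chains with branch losses;
* species-wise AUC, AUMC and MRT from matrix moments, without any
  curve: ``M·AUC = −A(0)`` and ``M·AUMC = −AUC``.

Species whose edges all point nowhere (appearing only as edge targets)
are treated as terminal sinks: they accumulate mass, are excluded from
the (invertible) rate matrix, and make total mass conservation exactly
checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import scipy.linalg
import yaml

from .curves import PolyexponentialCurve
from .errors import (
    DegenerateRatesError,
    InputError,
    NonDrainingError,
)
from .network import mrt_of_series

__all__ = [
    "FirstOrderNetwork",
    "SpeciesMoments",
    "transfer_matrix",
    "analytic_curves",
    "sample_amounts",
    "catenary_coefficients",
    "species_moments",
    "kirchhoff_vs_oracle",
]


@dataclass(frozen=True)
class FirstOrderNetwork:
    """Species, first-order edges and initial amounts.

    Parameters
    ----------
    species
        Ordered labels of the dynamic species (e.g. C1…C3).  Edge
        targets not listed here are terminal sinks (products).
    edges
        ``(source, target, k)`` triples with k > 0 in 1/h; no
        self-edges, no duplicate (source, target) pairs.
    initial_amounts
        mg per species at t = 0; at least one must be nonzero.
    """

    species: Tuple[str, ...]
    edges: Tuple[Tuple[str, str, float], ...]
    initial_amounts: Dict[str, float] = field(default_factory=dict)

    def __init__(self, species, edges, initial_amounts=None):
        species = tuple(species)
        edges = tuple((s, t, float(k)) for s, t, k in edges)
        initial_amounts = dict(initial_amounts or {})
        if len(set(species)) != len(species):
            raise InputError("duplicate species labels")
        seen = set()
        for s, t, k in edges:
            if s == t:
                raise InputError(f"self-edge on {s!r}")
            if s not in species:
                raise InputError(f"edge source {s!r} is not a dynamic species")
            if (s, t) in seen:
                raise InputError(f"duplicate edge {s!r} -> {t!r}")
            seen.add((s, t))
            if not k > 0:
                raise InputError(f"rate constant for {s!r}->{t!r} must be positive")
        for sp, amt in initial_amounts.items():
            if sp not in species:
                raise InputError(f"initial amount given for unknown species {sp!r}")
            if amt < 0:
                raise InputError("initial amounts must be non-negative")
        if not any(a > 0 for a in initial_amounts.values()):
            raise InputError("at least one species must carry a nonzero initial amount")
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "initial_amounts", initial_amounts)

    @property
    def sinks(self) -> Tuple[str, ...]:
        """Edge targets that are not dynamic species, in first-seen order."""
        out: List[str] = []
        for _, t, _ in self.edges:
            if t not in self.species and t not in out:
                out.append(t)
        return tuple(out)

    def a0(self) -> np.ndarray:
        return np.array([self.initial_amounts.get(sp, 0.0) for sp in self.species])

    # --- I/O ----------------------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "FirstOrderNetwork":
        """Read ``{"species": [...], "edges": [[src, dst, k], ...],
        "initial_amounts": {...}}``."""
        try:
            return cls(
                species=data["species"],
                edges=[tuple(e) for e in data["edges"]],
                initial_amounts=data.get("initial_amounts", {}),
            )
        except KeyError as exc:
            raise InputError(f"missing network field {exc}") from exc

    @classmethod
    def from_yaml(cls, text: str) -> "FirstOrderNetwork":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_json(cls, text: str) -> "FirstOrderNetwork":
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "edges": [list(e) for e in self.edges],
            "initial_amounts": dict(self.initial_amounts),
        }


@dataclass(frozen=True)
class SpeciesMoments:
    """Per-species AUC (mg·h), AUMC (mg·h²) and MRT (h) of amount curves."""

    auc: Dict[str, float]
    aumc: Dict[str, float]
    mrt: Dict[str, float]


def transfer_matrix(net: FirstOrderNetwork) -> np.ndarray:
    """Rate matrix M over the dynamic species, with dA/dt = M·A.

    ``M[j, i] = k(i→j)`` for i ≠ j and ``M[i, i] = −Σ outflows of i``
    (including flows to sinks), so each column sums to minus the total
    sink outflow of that species.
    """
    idx = {sp: i for i, sp in enumerate(net.species)}
    n = len(net.species)
    M = np.zeros((n, n))
    for s, t, k in net.edges:
        i = idx[s]
        M[i, i] -= k
        if t in idx:
            M[idx[t], i] += k
    return M


def _full_matrix(net: FirstOrderNetwork) -> Tuple[np.ndarray, List[str]]:
    """Rate matrix augmented with absorbing sink rows (mass-conserving)."""
    labels = list(net.species) + list(net.sinks)
    idx = {sp: i for i, sp in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n))
    for s, t, k in net.edges:
        i = idx[s]
        M[i, i] -= k
        M[idx[t], i] += k
    return M, labels


def sample_amounts(net: FirstOrderNetwork, times: Sequence[float]):
    """Amounts of every species *and sink* at the given times via expm.

    Returns a pandas DataFrame indexed by time with one column per
    species/sink.  Mass is conserved exactly: each row sums to the total
    dose.
    """
    import pandas as pd

    M, labels = _full_matrix(net)
    a0 = np.zeros(len(labels))
    a0[: len(net.species)] = net.a0()
    rows = [scipy.linalg.expm(M * t) @ a0 for t in times]
    return pd.DataFrame(rows, index=np.asarray(times, dtype=float), columns=labels)


def analytic_curves(
    net: FirstOrderNetwork, species: str, separation_tol: float = 1e-10
) -> PolyexponentialCurve:
    """Closed-form amount curve of one species via eigendecomposition.

    Requires the rate matrix to have pairwise-distinct eigenvalues
    (separation > ``separation_tol``·spectral radius); coincident
    eigenvalues have no simple-exponential expansion and raise
    :class:`DegenerateRatesError` — use :func:`sample_amounts` for a
    numeric solution in that case.
    """
    if species not in net.species:
        raise InputError(f"unknown species {species!r}")
    M = transfer_matrix(net)
    eigvals, eigvecs = np.linalg.eig(M)
    radius = float(np.max(np.abs(eigvals))) or 1.0
    for i in range(len(eigvals)):
        for j in range(i + 1, len(eigvals)):
            if abs(eigvals[i] - eigvals[j]) <= separation_tol * radius:
                raise DegenerateRatesError(
                    "repeated eigenvalues: no closed-form term list; "
                    "use sample_amounts() for a numeric solution"
                )
    weights = np.linalg.solve(eigvecs, net.a0())
    row = list(net.species).index(species)
    terms = []
    for m, lam in enumerate(eigvals):
        c = eigvecs[row, m] * weights[m]
        terms.append((float(np.real(c)), float(-np.real(lam))))
    terms = [(c, lam) for c, lam in terms if abs(c) > 0.0]
    return PolyexponentialCurve(terms, role="amount_curve")


def catenary_coefficients(
    chain_rates: Sequence[float],
    branch_losses: Sequence[float],
    dose: float,
) -> PolyexponentialCurve:
    """Bateman-type closed form for the terminal species of a catenary chain.

    Stage i of the chain has a through rate ``chain_rates[i]`` (transfer
    to the next species, or elimination for the last stage) and a
    parallel loss ``branch_losses[i]``; its total exit rate is the sum
    of the two.  The amount of the terminal species is

    ``A_n(t) = dose · Π(through rates except last) ·
    Σ_m exp(−λ_m t) / Π_{j≠m} (λ_j − λ_m)``

    with λ the stage totals, which must be pairwise distinct.
    """
    chain_rates = [float(k) for k in chain_rates]
    branch_losses = [float(b) for b in branch_losses]
    if len(chain_rates) != len(branch_losses):
        raise InputError("chain_rates and branch_losses must have equal length")
    if any(k <= 0 for k in chain_rates) or any(b < 0 for b in branch_losses):
        raise InputError("through rates must be positive, branch losses non-negative")
    if dose <= 0:
        raise InputError("dose must be positive")
    lambdas = [k + b for k, b in zip(chain_rates, branch_losses)]
    n = len(lambdas)
    for i in range(n):
        for j in range(i + 1, n):
            if lambdas[i] == lambdas[j]:
                raise DegenerateRatesError(
                    f"stage totals {lambdas[i]} coincide; closed form is degenerate"
                )
    prefactor = dose * float(np.prod(chain_rates[:-1]))
    terms = []
    for m in range(n):
        denom = np.prod([lambdas[j] - lambdas[m] for j in range(n) if j != m])
        terms.append((prefactor / float(denom), lambdas[m]))
    return PolyexponentialCurve(terms, role="amount_curve")


def species_moments(net: FirstOrderNetwork) -> SpeciesMoments:
    """AUC, AUMC and MRT for every dynamic species by matrix moments.

    Integrating dA/dt = M·A from 0 to ∞ (amounts vanish at infinity when
    every species drains) gives ``M·AUC = −A(0)``; multiplying by t
    first gives ``M·AUMC = −AUC``.  Raises :class:`NonDrainingError` if
    M is singular, i.e. some dosed mass is trapped forever.
    """
    M = transfer_matrix(net)
    a0 = net.a0()
    try:
        auc = np.linalg.solve(M, -a0)
        aumc = np.linalg.solve(M, -auc)
    except np.linalg.LinAlgError as exc:
        raise NonDrainingError(
            "rate matrix is singular: a compartment traps mass and the "
            "moments diverge"
        ) from exc
    if np.any(auc < -1e-12 * max(1.0, float(a0.sum()))):
        raise NonDrainingError("negative AUC solution: network does not drain")
    auc_d = dict(zip(net.species, map(float, auc)))
    aumc_d = dict(zip(net.species, map(float, aumc)))
    mrt_d = {
        sp: (aumc_d[sp] / auc_d[sp]) if auc_d[sp] > 0 else float("nan")
        for sp in net.species
    }
    return SpeciesMoments(auc=auc_d, aumc=aumc_d, mrt=mrt_d)


def kirchhoff_vs_oracle(
    net: FirstOrderNetwork, species: str, kirchhoff_stages: Sequence[float]
) -> dict:
    """Compare the moment-oracle MRT of one species with the in-series sum.

    ``kirchhoff_stages`` are the stage total rate constants of the
    rate-defining chain leading to the species (parallel routes already
    summed).  The report carries both MRTs and their absolute
    difference; it encodes no judgement about which is "correct" — for
    chains with reversible side exchange the two notions genuinely
    differ (the moment MRT feels the side compartment, the stage sum
    does not).
    """
    if species not in net.species:
        raise InputError(f"unknown species {species!r}")
    mrt_oracle = species_moments(net).mrt[species]
    mrt_k = mrt_of_series(kirchhoff_stages)
    return {
        "species": species,
        "mrt_oracle": mrt_oracle,
        "mrt_kirchhoff": mrt_k,
        "abs_difference": abs(mrt_oracle - mrt_k),
    }
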