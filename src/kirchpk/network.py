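"""The parallel/in-series calculus for rate-defining processes.

A *rate-defining process* is a kinetic step that, were it the only slow
step, would by itself determine the measured total rate constant or
clearance.  For linear kinetics the measured total obeys two composition
rules:

* **parallel** processes (independent simultaneous routes) — totals add:
  ``k_total = Σ k_i``;
* **in-series** processes (sequential steps, each feeding the next) —
  mean times add, i.e. reciprocals of totals add:
  ``1/k_total = Σ 1/k_i``.

The same algebra applies verbatim to clearances (L/h) and to first-order
rate constants (1/h); mixing the two kinds in one network is rejected.
Because the reciprocal of a first-order rate constant is a mean time,
the series rule for rate constants is exactly the statement that the
mean residence time of the terminal species is the sum of the stage mean
residence times.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import yaml

from .errors import (
    InputError,
    MixedKindsError,
    NonPositiveValueError,
    NonRateDefiningError,
    NoProcessesError,
)
from .units import KNOWN_UNITS, kind_of_units, to_canonical

__all__ = [
    "RateDefiningProcess",
    "NetDifferenceProcess",
    "Leaf",
    "Parallel",
    "Series",
    "ProcessNetwork",
    "combine_parallel",
    "combine_series",
    "evaluate_network",
    "mrt_of_series",
    "entering_leaving_total",
]


def _check_values(values: Sequence[float]) -> None:
    if len(values) == 0:
        raise NoProcessesError("no processes: an empty group has no rate-defining total")
    for v in values:
        if not (v > 0) or not math.isfinite(v):
            raise NonPositiveValueError(
                f"process value {v!r} is not a positive finite magnitude and "
                "cannot be rate-defining"
            )


def combine_parallel(values: Sequence[float]) -> float:
    """Total of parallel rate-defining processes: the arithmetic sum.

    Parameters
    ----------
    values
        Positive magnitudes sharing one kind (all 1/h or all L/h).

    Returns
    -------
    float
        ``Σ values``, which is ≥ max(values).
    """
    _check_values(values)
    return float(sum(values))


def combine_series(values: Sequence[float]) -> float:
    """Total of in-series rate-defining processes: 1 / Σ(1/value).

    The result is ≤ min(values): a chain is never faster than its
    slowest step.
    """
    _check_values(values)
    return 1.0 / sum(1.0 / v for v in values)


def mrt_of_series(rate_constants: Sequence[float]) -> float:
    """Mean residence time of the terminal species of an in-series chain.

    Each first-order stage contributes a mean time 1/k; the chain's MRT
    is their sum, equal to ``1 / combine_series(rate_constants)``.

    Returns
    -------
    float
        MRT in hours when the inputs are in 1/h.
    """
    _check_values(rate_constants)
    return float(sum(1.0 / k for k in rate_constants))


def entering_leaving_total(
    entering: Sequence[float], leaving: Sequence[float]
) -> float:
    """Total clearance (or rate constant) of a delivery stage in series with
    an elimination stage.

    ``entering`` are the parallel processes delivering drug to the site
    of elimination (e.g. organ blood flow); ``leaving`` are the parallel
    processes removing it.  The two stages are in series:

    ``1/total = 1/Σ(entering) + 1/Σ(leaving)``
    """
    return combine_series([combine_parallel(entering), combine_parallel(leaving)])


@dataclass(frozen=True)
class RateDefiningProcess:
    """One named rate-defining process.

    Parameters
    ----------
    name : str
        Label used in reports.
    kind : {"rate_constant", "clearance"}
    value : float
        Positive magnitude; 1/h for rate constants, L/h for clearances.
    provenance : str
        Free-text note, e.g. "net of influx − efflux".
    """

    name: str
    kind: str
    value: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("rate_constant", "clearance"):
            raise MixedKindsError(f"unknown process kind {self.kind!r}")
        _check_values([self.value])


@dataclass(frozen=True)
class NetDifferenceProcess:
    """A forward/backward transporter pair that may or may not be rate-defining.

    Only the *net* forward flux can be measured across a membrane; the
    pair reduces to a rate-defining process of value ``forward −
    backward`` only when that difference is positive.
    """

    forward: float
    backward: float
    name: str = "net"
    kind: str = "clearance"

    def __post_init__(self) -> None:
        _check_values([self.forward])
        if self.backward < 0:
            raise NonPositiveValueError("backward magnitude must be >= 0")

    @property
    def net(self) -> float:
        return self.forward - self.backward

    @property
    def is_rate_defining(self) -> bool:
        return self.net > 0

    def resolve(self) -> RateDefiningProcess:
        """Reduce to a plain process; raises if the net value is not positive."""
        if not self.is_rate_defining:
            raise NonRateDefiningError(
                f"net process {self.name!r} has forward {self.forward} <= "
                f"backward {self.backward}; a non-positive net cannot be rate-defining"
            )
        return RateDefiningProcess(
            self.name, self.kind, self.net, provenance="net of forward − backward"
        )


# --- network tree -----------------------------------------------------------

@dataclass(frozen=True)
class Leaf:
    process: Union[RateDefiningProcess, NetDifferenceProcess]


@dataclass(frozen=True)
class Parallel:
    children: tuple


@dataclass(frozen=True)
class Series:
    children: tuple


Node = Union[Leaf, Parallel, Series]


def _iter_leaves(node: Node) -> Iterable[Leaf]:
    if isinstance(node, Leaf):
        yield node
    else:
        for child in node.children:
            yield from _iter_leaves(child)


@dataclass(frozen=True)
class ProcessNetwork:
    """A finite tree of rate-defining processes combined in parallel/series.

    All leaves must share one kind; evaluation walks the tree applying
    :func:`combine_parallel` / :func:`combine_series`.
    """

    root: Node
    drop_non_rate_defining: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        leaves = list(_iter_leaves(self.root))
        if not leaves:
            raise NoProcessesError("network has no leaves")
        kinds = {leaf.process.kind for leaf in leaves}
        if len(kinds) > 1:
            raise MixedKindsError(
                f"network mixes process kinds {sorted(kinds)}; rate constants and "
                "clearances cannot be combined in one total"
            )

    @property
    def kind(self) -> str:
        return next(_iter_leaves(self.root)).process.kind

    def evaluate(self) -> float:
        return self._evaluate(self.root)

    def _evaluate(self, node: Node) -> float:
        if isinstance(node, Leaf):
            proc = node.process
            if isinstance(proc, NetDifferenceProcess):
                proc = proc.resolve()
            return proc.value
        values = []
        for child in node.children:
            try:
                values.append(self._evaluate(child))
            except NonRateDefiningError:
                if self.drop_non_rate_defining and isinstance(node, Series):
                    # a non-rate-defining process simply does not appear in
                    # the total; the remaining stages carry the chain
                    warnings.warn(
                        "dropping non-rate-defining series stage", stacklevel=2
                    )
                    continue
                raise
        if isinstance(node, Parallel):
            return combine_parallel(values)
        return combine_series(values)

    # --- construction helpers ----------------------------------------------

    @classmethod
    def series(cls, *values: float, kind: str = "rate_constant") -> "ProcessNetwork":
        return cls(Series(tuple(_leaf(v, kind) for v in values)))

    @classmethod
    def parallel(cls, *values: float, kind: str = "rate_constant") -> "ProcessNetwork":
        return cls(Parallel(tuple(_leaf(v, kind) for v in values)))

    # --- (de)serialisation --------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "ProcessNetwork":
        """Build a network from the nested mapping format.

        Example::

            {"units": "1/h",
             "series": [{"k": 0.06},
                        {"parallel": [{"k": 0.15}, {"k": 0.20}]},
                        {"k": 0.50}]}

        Leaves carry ``k`` (or ``cl``/``value``), an optional ``name``,
        or a ``forward``/``backward`` pair for a net-difference process.
        Recognised units: "1/h", "L/h", "mL/min" (converted to L/h).
        """
        units = data.get("units", "1/h")
        if units not in KNOWN_UNITS:
            raise InputError(f"unknown units {units!r}; expected one of {KNOWN_UNITS}")
        kind = kind_of_units(units)
        body = {k: v for k, v in data.items() if k != "units"}
        return cls(_node_from_dict(body, kind, units))

    @classmethod
    def from_yaml(cls, text: str) -> "ProcessNetwork":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_json(cls, text: str) -> "ProcessNetwork":
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        units = "1/h" if self.kind == "rate_constant" else "L/h"
        out = _node_to_dict(self.root)
        out["units"] = units
        return out


def _leaf(value: float, kind: str) -> Leaf:
    return Leaf(RateDefiningProcess(name="", kind=kind, value=value))


def _node_from_dict(data: dict, kind: str, units: str) -> Node:
    if not isinstance(data, dict):
        raise InputError(f"network node must be a mapping, got {type(data).__name__}")
    if "series" in data:
        children = tuple(_node_from_dict(c, kind, units) for c in data["series"])
        if not children:
            raise NoProcessesError("empty series group")
        return Series(children)
    if "parallel" in data:
        children = tuple(_node_from_dict(c, kind, units) for c in data["parallel"])
        if not children:
            raise NoProcessesError("empty parallel group")
        return Parallel(children)
    name = data.get("name", "")
    if "forward" in data:
        return Leaf(
            NetDifferenceProcess(
                forward=to_canonical(data["forward"], units),
                backward=to_canonical(data.get("backward", 0.0), units),
                name=name,
                kind=kind,
            )
        )
    for key in ("k", "cl", "value"):
        if key in data:
            return Leaf(
                RateDefiningProcess(
                    name=name, kind=kind, value=to_canonical(data[key], units)
                )
            )
    raise InputError(f"unrecognised network node: {data!r}")


def _node_to_dict(node: Node) -> dict:
    if isinstance(node, Leaf):
        proc = node.process
        if isinstance(proc, NetDifferenceProcess):
            out = {"forward": proc.forward, "backward": proc.backward}
        else:
            key = "k" if proc.kind == "rate_constant" else "cl"
            out = {key: proc.value}
        if getattr(proc, "name", ""):
            out["name"] = proc.name
        return out
    tag = "parallel" if isinstance(node, Parallel) else "series"
    return {tag: [_node_to_dict(c) for c in node.children]}


def evaluate_network(net: ProcessNetwork) -> float:
    """Evaluate a :class:`ProcessNetwork` to its total rate constant or clearance."""
    return net.evaluate()
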