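"""Exception hierarchy.

All domain failures derive from :class:`KirchpkError` so callers (and the
CLI) can distinguish bad input (:class:`InputError`) from models that are
structurally infeasible on valid input (:class:`InfeasibleModelError`).
"""


class KirchpkError(Exception):
    """Base class for all package-specific errors."""


class InputError(KirchpkError, ValueError):
    """Malformed or out-of-domain input (CLI exit code 2)."""


class InfeasibleModelError(KirchpkError, ValueError):
    """Structurally valid input for which the model has no solution (CLI exit code 3)."""


class NoProcessesError(InputError):
    """An empty parallel or series group: neither 0 nor infinity is rate-defining."""


class NonPositiveValueError(InputError):
    """A rate constant or clearance that is not strictly positive."""


class MixedKindsError(InputError):
    """Rate constants and clearances mixed inside one process network."""


class NonRateDefiningError(InfeasibleModelError):
    """A net forward-minus-backward process with non-positive net value.

    A negative or zero net clearance cannot, on its own, define a measured
    total and therefore cannot appear as an in-series stage.
    """


class InfeasibleObservationError(InfeasibleModelError):
    """An observed organ clearance that equals or exceeds the organ blood flow."""


class DegenerateRatesError(InfeasibleModelError):
    """Closed-form catenary/eigen solution unavailable: stage totals coincide."""


class NonDrainingError(InfeasibleModelError):
    """A dosed compartment network with a trap holding mass forever (singular rate matrix)."""


class InvalidCurveError(InputError):
    """A polyexponential curve violating its role's sign/positivity constraints."""


class InfeasibleChainError(InfeasibleModelError):
    """An in-series total reported larger than one of its component stages."""
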