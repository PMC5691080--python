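"""Exception taxonomy shared across the package.

Validation errors signal ill-formed inputs (schema/ordering violations),
balance errors a broken flow-rate closure, domain errors out-of-range
physical quantities, and degenerate-input errors inputs on which the
requested statistic is undefined (e.g. a perfectly flat baseline).
"""


class NeuroperfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NeuroperfError):
    """Structurally invalid input (ordering, shape, schema)."""


class BalanceError(ValidationError):
    """Flow-rate balance Q_inj − Q_inlet_wd = Q_outlet_wd violated."""


class DomainError(NeuroperfError):
    """Physically out-of-range argument (non-positive volume, L too long, ...)."""


class DegenerateInputError(NeuroperfError):
    """Input on which the requested statistic is undefined (zero spread)."""
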