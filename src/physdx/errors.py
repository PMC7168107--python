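"""Exception hierarchy shared across the package."""

from __future__ import annotations


class PhysdxError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(PhysdxError, ValueError):
    """A model or observation file could not be parsed into the expected shape."""


class ModelValidationError(PhysdxError, ValueError):
    """A model violates one or more structural invariants.

    Attributes
    ----------
    violations : list of str
        One human-readable description per violated invariant.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid model: " + "; ".join(self.violations))


class UnknownComponentError(PhysdxError, KeyError):
    """A component id was referenced that does not exist in the model."""


class ConfigError(PhysdxError, ValueError):
    """A configuration value is out of its admissible range."""


class ModelInconsistencyError(PhysdxError, ValueError):
    """A failed test implicates no faultable component (cannot happen on a
    structurally valid model, where every dermatome has a faultable ancestor)."""


class InconsistentAnswerError(PhysdxError, ValueError):
    """A probe answer eliminated every remaining diagnosis.

    Under the weak fault model this means the true fault set is not a minimal
    diagnosis of the initial observations. The partial probe log is attached.
    """

    def __init__(self, probe: str, records: list):
        self.probe = probe
        self.records = list(records)
        super().__init__(
            f"probe {probe!r} failed but its ancestor closure intersects no "
            "remaining diagnosis"
        )


class GenerationError(PhysdxError, RuntimeError):
    """The scenario generator exhausted its retry budget."""


class UndefinedMetricError(PhysdxError, ValueError):
    """A metric is undefined for the given inputs (e.g. entropy of an empty
    diagnosis set, ROC against an empty fault set)."""
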