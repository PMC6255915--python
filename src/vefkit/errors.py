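"""Exception hierarchy.

``VefError`` is the package root; ``ValidationError`` covers malformed
inputs and configs (CLI exit code 1), everything else maps to runtime
failures (exit code 2).
"""


class VefError(Exception):
    """Base class for all vefkit errors."""


class ValidationError(VefError):
    """Malformed session files, configs, or arguments."""


class UndefinedMetricError(VefError):
    """A metric was requested for a trial/set where it is not defined."""


class FitError(VefError):
    """Sigmoid fitting failed to converge."""


class NotBimodalError(VefError):
    """Local-PR distribution fails the bimodality criterion (BC <= 0.55)."""
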