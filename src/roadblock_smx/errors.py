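"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed inputs and configuration (CLI exit
code 2); ``ComputationError`` covers failures of a numerical procedure on
well-formed input (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Input, configuration, or schema violation."""


class ConfigurationError(ValidationError):
    """A run configuration is internally inconsistent (e.g. an operator
    present on the template with no matching kinetics entry)."""


class ComputationError(RuntimeError):
    """A numerical procedure failed on otherwise valid input."""


class FitError(ComputationError):
    """A model fit did not converge or is degenerate; the message carries
    the optimizer diagnostics."""
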