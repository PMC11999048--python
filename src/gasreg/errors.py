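"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: config errors -> 2, data/format errors -> 3,
anything else -> 1.
"""


class GasregError(Exception):
    """Base class for all package errors."""


class FormatError(GasregError, ValueError):
    """Malformed input file or record."""


class BoundsError(GasregError, ValueError):
    """A genomic interval falls outside its chromosome or reference."""


class CapacityError(GasregError, ValueError):
    """A synthetic genome is too small for the requested features."""


class ConfigError(GasregError, ValueError):
    """Invalid pipeline configuration."""

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DegenerateInputError(GasregError, ValueError):
    """Input is structurally valid but degenerate for the operation."""
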