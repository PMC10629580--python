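"""Exception hierarchy shared across the package.

The command-line layer maps these onto exit codes (config 2,
data validation 3, numerical failure 4).
"""


class ChronodivError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ChronodivError):
    """Invalid or inconsistent configuration."""


class TreeError(ChronodivError):
    """A phylogeny violates a structural invariant (polytomy, missing
    branch length, non-ultrametric beyond tolerance, ...)."""


class DataError(ChronodivError):
    """Tabular or series input violates a contract."""


class NumericalError(ChronodivError):
    """A numerical routine failed (overflow, no converged optimizer
    start, degenerate statistic)."""
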