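"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, InputError -> 3,
FitError -> 4.
"""


class SubnucError(Exception):
    """Base class for all package-specific errors."""


class SpecificationError(SubnucError, ValueError):
    """A generator or analysis specification violates its invariants
    (weights that do not sum to one, negative noise, out-of-range indices...)."""


class InputError(SubnucError, ValueError):
    """Input data violate a precondition (missing t=0 lane, no matched
    residues, empty selection...)."""


class ConfigError(SubnucError, ValueError):
    """A run configuration is malformed (unknown keys, missing seed,
    out-of-range parameters)."""


class FitError(SubnucError, RuntimeError):
    """A least-squares fit failed to converge or is degenerate."""
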