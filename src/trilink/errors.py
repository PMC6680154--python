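"""Exception hierarchy.

``DesignError``/``ConfigError`` signal invalid cross designs or simulation
configurations (user input that can never be analysed); ``DataError`` signals
observations that are inconsistent with a valid design (possible contaminant,
selfing, or file corruption).  The CLI maps the former to exit code 2 and the
latter to exit code 3.
"""


class TrilinkError(Exception):
    """Base class for all package errors."""


class DesignError(TrilinkError):
    """A cross design violates its invariants (duplicate loci, bad tester...)."""


class ConfigError(TrilinkError):
    """A simulation or run configuration is infeasible or malformed."""


class DataError(TrilinkError):
    """Observed data inconsistent with the declared design."""


class AmbiguousPhenotypeError(DataError):
    """A (partially unscored) phenotype matches more than one gamete class."""

    def __init__(self, message: str, candidates=()):
        super().__init__(message)
        self.candidates = tuple(candidates)
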