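"""Exception hierarchy for the exorna pipeline."""


class ExornaError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(ExornaError, ValueError):
    """Invalid configuration (bad parameters, empty tiers, impossible requests)."""


class DataError(ExornaError, ValueError):
    """Invalid data encountered at run time (bad characters, unknown taxa, empty pools)."""


class UndefinedFractionError(ExornaError, ZeroDivisionError):
    """A fraction was requested over an empty denominator (e.g. zero processed reads)."""
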