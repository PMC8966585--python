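"""Exception hierarchy shared by all stages."""


class NoduleSegError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(NoduleSegError, ValueError):
    """Input lacks the variation a stage needs (e.g. constant image for Otsu)."""


class SeedingError(NoduleSegError, RuntimeError):
    """Automatic seed generation failed; the message suggests a parameter change."""


class NumericalError(NoduleSegError, ArithmeticError):
    """A numerical quantity left its admissible range (non-finite weight, bad solve)."""


class UndefinedMetricError(NoduleSegError, ZeroDivisionError):
    """A metric's denominator is zero; raised instead of silently returning 0."""


class DataError(NoduleSegError, ValueError):
    """A feature table or label vector violates the classifier's input contract."""


class ConfigError(NoduleSegError, ValueError):
    """A run configuration contains unknown or invalid keys."""
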