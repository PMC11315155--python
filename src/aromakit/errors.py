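"""Exception hierarchy for aromakit.

All package errors derive from :class:`AromakitError` so callers can catch
one base class; the pipeline maps validation-type errors to exit code 2 and
computation-type errors to exit code 3.
"""


class AromakitError(Exception):
    """Base class for all aromakit errors."""


class FormatError(AromakitError):
    """A delimited input file is malformed (missing columns, bad types)."""


class ValidationError(AromakitError):
    """Input data violates a structural invariant (duplicate IS peak, ...)."""


class CalibrationError(AromakitError):
    """Alkane ladder is unusable (non-monotone, too few rungs)."""


class AnnotationError(AromakitError):
    """Peak annotation cannot proceed (library without reference RIs)."""


class QuantificationError(AromakitError):
    """Semi-quantification cannot proceed (replicate missing its IS peak)."""


class ConfigurationError(AromakitError):
    """A user-supplied option refers to something that does not exist."""


class FixtureIntegrityError(AromakitError):
    """Packaged reference tables fail their checksum."""


class ModelError(AromakitError):
    """A latent-variable model cannot be fitted as requested."""


class ConvergenceError(ModelError):
    """NIPALS iteration failed to converge within the iteration cap."""


class StratificationError(ModelError):
    """A cross-validation fold would lose a class from its training split."""
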