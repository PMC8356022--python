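"""Exception hierarchy.

All package-specific failures derive from :class:`NucdynError` so callers can
catch one base class at pipeline boundaries.
"""


class NucdynError(Exception):
    """Base class for all nucdyn errors."""


class SchemaError(NucdynError):
    """An input table is missing a required column or has a malformed header."""


class ParseError(NucdynError):
    """A cell in an input table could not be parsed (e.g. non-numeric depth)."""


class SamplingError(NucdynError):
    """A trajectory violates the uniform-sampling contract."""


class InsufficientDataError(NucdynError):
    """Too few frames/values for the requested computation."""


class ParameterError(NucdynError):
    """An argument is outside its valid domain (e.g. even smoothing window)."""


class FeatureMissingError(NucdynError):
    """An optional trajectory feature (tangential coordinates) is absent."""


class DegenerateFitError(NucdynError):
    """A model fit has no information to constrain its coefficient."""


class DesignError(NucdynError):
    """A statistical design is invalid (e.g. a factor with a single level)."""


class ConfigError(NucdynError):
    """A simulation configuration is internally inconsistent."""
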