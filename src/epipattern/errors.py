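"""Exception hierarchy for epipattern."""


class EpipatternError(Exception):
    """Base class for all package errors."""


class GeometryError(EpipatternError):
    """Invalid embryo geometry (non-positive radius, bad sector width, ...)."""


class ParameterError(EpipatternError):
    """Invalid generative or analysis parameter."""


class PackingError(EpipatternError):
    """Requested cell density cannot be packed into the counting region."""


class EstimationError(EpipatternError):
    """A statistic is undefined for the given input (e.g. empty cell table)."""


class IntegrityError(EpipatternError):
    """Input table violates an integrity constraint (duplicate ids, ...)."""


class SchemaError(EpipatternError):
    """A file does not conform to the documented CSV/JSON schema."""


class InsufficientDataError(EpipatternError):
    """Too few observations for a statistical test."""
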