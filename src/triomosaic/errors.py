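"""Exception types shared across the package."""


class TrioMosaicError(Exception):
    """Base class for package errors."""


class InvalidInputError(TrioMosaicError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedVAFError(InvalidInputError):
    """VAF requested at a site with zero read depth."""


class InsufficientDataError(TrioMosaicError, ValueError):
    """Too few observations to run the requested estimator."""


class DegenerateFitError(TrioMosaicError, ValueError):
    """A regression predictor is constant or the fit is otherwise singular."""


class SchemaError(TrioMosaicError, ValueError):
    """An input table is missing a mandatory column or field."""
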