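"""Exception hierarchy shared across the package."""


class EpichemError(Exception):
    """Base class for all package-specific errors."""


class StructureError(EpichemError):
    """A SMILES string could not be parsed into a valid molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"invalid structure: {smiles!r}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class ConfigurationError(EpichemError):
    """A required column, file, or option is missing or inconsistent."""


class ContractError(EpichemError, ValueError):
    """A caller violated an operation precondition (e.g. length mismatch)."""


class CapacityError(EpichemError):
    """More distinct scaffolds were requested than the template set can supply."""


class DegenerateDistributionError(EpichemError):
    """A similarity distribution has zero variance; no threshold can be derived."""


class UndefinedCurveError(EpichemError):
    """A scaffold recovery curve is undefined (no ring-bearing compounds)."""


class ParameterError(EpichemError, ValueError):
    """An algorithm parameter is outside its valid range."""


class StageError(EpichemError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
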