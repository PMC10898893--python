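"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class OncoValueError(Exception):
    """Base class for all package errors."""


class SchemaValidationError(OncoValueError):
    """Input failed schema or invariant validation.

    ``pointer`` is a JSON-pointer-style path to the first failing field.
    """

    def __init__(self, message: str, pointer: str = ""):
        super().__init__(message)
        self.pointer = pointer


class UndefinedRatioError(OncoValueError):
    """Toxicity ratio undefined (comparator point total is not positive)."""


class NonPositiveBenefitError(OncoValueError):
    """Cost per benefit point undefined for NHB <= 0."""


class NoEfficacyEvidenceError(OncoValueError):
    """No rung of the clinical-benefit hierarchy is available."""
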