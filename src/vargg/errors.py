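"""Exception hierarchy shared across the package."""


class VarggError(Exception):
    """Base class for all package errors."""


class InputError(VarggError):
    """A required input file or field is missing or unreadable."""


class ConsistencyError(VarggError):
    """Cross-referenced inputs disagree (e.g. barcodes vs positions)."""


class ParameterError(VarggError):
    """A parameter is outside its valid range."""


class ContractError(VarggError):
    """A pluggable component violated its interface contract."""


class StageError(VarggError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code
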