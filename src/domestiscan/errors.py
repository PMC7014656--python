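"""Exception hierarchy used across the package."""


class DomestiscanError(Exception):
    """Base class for all package errors."""


class ValidationError(DomestiscanError):
    """Input fails a structural or semantic precondition."""


class VcfParseError(DomestiscanError):
    """A VCF record could not be parsed; the message names the line."""


class DataIntegrityError(DomestiscanError):
    """Cross-file inconsistency, e.g. VCF REF disagrees with the FASTA."""


class PipelineError(DomestiscanError):
    """A stage of the full analysis failed.

    Attributes
    ----------
    stage : str
        Name of the stage that raised.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
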