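"""Exception hierarchy shared across the pipeline stages."""


class RenovolError(Exception):
    """Base class for all package errors."""


class MetadataError(RenovolError):
    """Missing or inconsistent spacing/orientation metadata."""


class FormatError(RenovolError):
    """Unreadable or mixed-format image input (e.g. mixed-orientation DICOM series)."""


class SchemeViolationError(RenovolError):
    """A label map contains values not declared by its class scheme."""

    def __init__(self, offending, scheme_name=""):
        self.offending = sorted(int(v) for v in offending)
        msg = f"label values {self.offending} are not declared by the scheme"
        if scheme_name:
            msg += f" '{scheme_name}'"
        super().__init__(msg)


class EmptyForegroundError(RenovolError):
    """crop_nonzero was asked to crop an all-background volume."""


class LocalizationError(RenovolError):
    """No lung-containing axial slice was found."""


class PhantomSpecError(RenovolError):
    """A phantom specification violates its geometric invariants."""


class ParameterError(RenovolError):
    """An operation received an out-of-range parameter."""


class StageError(RenovolError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage, message):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
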