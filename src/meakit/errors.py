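"""Exception hierarchy shared by all meakit modules."""


class MeaKitError(Exception):
    """Base class for all meakit-specific errors."""


class FormatError(MeaKitError):
    """A file is not in the format the reader expects."""


class TruncatedFileError(FormatError):
    """A data file ends mid-record.

    Attributes
    ----------
    byte_offset : int
        Offset of the incomplete record in the file.
    """

    def __init__(self, message: str, byte_offset: int):
        super().__init__(f"{message} (at byte offset {byte_offset})")
        self.byte_offset = byte_offset


class SchemaError(MeaKitError):
    """A container or table is missing a required attribute or column."""


class ParameterError(MeaKitError, ValueError):
    """A parameter violates its documented constraints."""


class DegenerateEnsembleError(MeaKitError):
    """Waveform ensemble has zero residual noise; SNR is undefined."""
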