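"""Exception hierarchy for the rfqpack compressor."""


class RfqError(Exception):
    """Base class for all rfqpack errors."""


class FastqParseError(RfqError):
    """Malformed FASTQ input (truncated record, length mismatch, bad marker)."""


class PairingError(RfqError):
    """R1/R2 files do not contain the same number of records."""


class NotAnRfqFileError(RfqError):
    """Input does not start with the .rfq magic bytes."""


class UnsupportedVersionError(RfqError):
    """The .rfq file was written by a newer, incompatible format version."""


class CorruptionError(RfqError):
    """A frame failed its CRC check or a payload could not be decoded."""
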