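"""Exception hierarchy."""


class PtrfError(Exception):
    """Base class for all ptrf errors."""


class ValidationError(PtrfError):
    """Invalid input data (duplicate ids, bad alphabet, malformed intervals)."""


class CoordinateError(PtrfError):
    """Genomic coordinates fall outside the named chromosome."""


class MissingSequenceError(PtrfError):
    """A requested chromosome is absent from the genome."""


class FastqFormatError(PtrfError):
    """A FASTQ record is structurally malformed."""


class InternalConsistencyError(PtrfError):
    """An internal invariant was violated (indicates a pipeline bug)."""
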