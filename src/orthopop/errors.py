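"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: InputError -> 2, InsufficientDataError -> 3,
ConvergenceError -> 4.
"""


class OrthopopError(Exception):
    """Base class for all package errors."""


class InputError(OrthopopError):
    """Malformed or unreadable input (bad FASTA, bad sample sheet, bad config)."""


class AlignmentFormatError(InputError):
    """Records in an aligned FASTA do not have uniform length."""


class MetadataError(InputError):
    """Inconsistent accession/species metadata."""


class InsufficientDataError(OrthopopError):
    """Not enough usable data to compute the requested statistic."""


class EmptyDataError(InsufficientDataError):
    """No evaluable sites / all genes filtered out."""


class ConvergenceError(OrthopopError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
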