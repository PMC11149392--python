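"""Exception hierarchy.

Every error raised by this package derives from :class:`OrthocliqueError` so
callers can catch pipeline failures without masking programming errors.
"""


class OrthocliqueError(Exception):
    """Base class for all orthoclique errors."""


class FastaParseError(OrthocliqueError):
    """Malformed or empty FASTA input."""


class HeaderSchemeError(OrthocliqueError):
    """A sequence header does not match the configured naming scheme."""


class DuplicateRecordError(OrthocliqueError):
    """Two records resolve to the same (gene_id, isotig_id) within a sample."""


class SequenceAlphabetError(OrthocliqueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


class HspValidationError(OrthocliqueError):
    """An HSP row violates its invariants (e.g. nident > length - gaps)."""


class SampleMismatchError(OrthocliqueError):
    """Forward/reverse tables or pair tables disagree on sample identities."""


class BlastNotFoundError(OrthocliqueError):
    """A required BLAST+ executable is not on PATH."""


class BlastRuntimeError(OrthocliqueError):
    """A BLAST+ invocation exited with a nonzero status."""


class NoComparableOrthologsError(OrthocliqueError):
    """A gene match table is empty; the similarity statistic is undefined."""


class EmptyMatchTableError(OrthocliqueError):
    """A sample pair has no surviving match rows after filtering."""


class NoIdealComponentsError(OrthocliqueError):
    """The gene matches graph contains no ideal component."""


class SimulationError(OrthocliqueError):
    """Tree or sequence simulation could not be completed."""
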