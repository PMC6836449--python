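"""Exception hierarchy.

Every user-facing failure derives from :class:`PolyguideError` so callers
(and the CLI) can catch one type; input-validation failures are
distinguishable by subclass so tests can assert the precise failure mode.
"""


class PolyguideError(Exception):
    """Base class for all errors raised by polyguide."""


class InputError(PolyguideError, ValueError):
    """Invalid user-supplied input (files, sequences, options)."""


class MissingFileError(InputError):
    """A required input file does not exist."""


class EmptyFileError(InputError):
    """An input file exists but contains no records."""


class DuplicateContigError(InputError):
    """Two FASTA records share a contig id."""


class AnnotationError(InputError):
    """Invalid or inconsistent GFF3 annotation."""


class UnknownContigError(AnnotationError):
    """A feature references a contig absent from the genome."""


class FeatureBoundsError(AnnotationError):
    """A feature extends beyond its contig."""


class CdsOutsideExonError(AnnotationError):
    """A CDS interval is not contained in its isoform's exon union."""


class OrphanFeatureError(AnnotationError):
    """An mRNA/exon/CDS feature has no resolvable parent."""


class OutOfBoundsError(InputError):
    """A genomic position lies outside its contig."""


class ContractError(PolyguideError, ValueError):
    """An argument violates an operation's stated precondition."""


class TableIntegrityError(PolyguideError):
    """A score table is incomplete or inconsistent with its schema."""


class UnknownGeneError(PolyguideError, KeyError):
    """A queried gene id is absent from the database."""


class UsageError(PolyguideError):
    """A mode/option combination the tool does not support."""


class FixtureError(PolyguideError):
    """A synthetic-genome specification cannot be realised."""
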