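"""Exception hierarchy.

Every error raised by this package derives from :class:`RegsigError`, so
callers (and the CLI) can catch one type.  Subclasses are grouped roughly by
module; messages carry the offending record id / line number where the
contract promises one.
"""


class RegsigError(Exception):
    """Base class for all package errors."""


class AlignmentShapeError(RegsigError):
    """Sequences in a site alignment do not share a single length."""


class AlignmentContentError(RegsigError):
    """A site alignment contains gaps or non-DNA characters."""


class ProvenanceError(RegsigError):
    """An operation needs per-sequence genome provenance that is absent."""


class FlankBoundaryError(RegsigError):
    """Extending an alignment would run past a replicon end."""

    def __init__(self, message, sequence_ids=()):
        super().__init__(message)
        self.sequence_ids = list(sequence_ids)


class ProfileParseError(RegsigError):
    """A MEME motif file (or its side-car) could not be parsed."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ConfigurationError(RegsigError):
    """A cutoff/setting required by an operation is missing or invalid."""


class GenBankFormatError(RegsigError):
    """A GenBank flat file violates the format (e.g. no ORIGIN sequence)."""


class AnnotationMissingError(RegsigError):
    """A record lacks the gene/CDS annotation a context filter requires."""


class SelectorError(RegsigError):
    """A feature selector matched zero or several features."""

    def __init__(self, message, n_matches):
        super().__init__(message)
        self.n_matches = n_matches


class TrackError(RegsigError):
    """A coverage track file is malformed (bad field or ordering)."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class LayoutError(RegsigError):
    """A synthetic-genome configuration cannot fit in the requested length."""


class OptimizationCollapseError(RegsigError):
    """Profile optimisation retained zero sites in some round."""

    def __init__(self, message, round_number):
        super().__init__(message)
        self.round_number = round_number
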