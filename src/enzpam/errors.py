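"""Exception hierarchy shared by all enzpam modules."""


class EnzpamError(Exception):
    """Base class for all errors raised by enzpam."""


class SpecParseError(EnzpamError):
    """The user spec table is malformed (missing columns, duplicates, empty rows)."""


class ECValidationError(EnzpamError):
    """A string does not form a valid EC number."""

    def __init__(self, text: str, reason: str):
        self.text = text
        self.reason = reason
        super().__init__(f"invalid EC number {text!r}: {reason}")


class SourceError(EnzpamError):
    """A record source (snapshot directory or REST endpoint) failed."""


class DbFormatError(EnzpamError):
    """A custom-database FASTA violates the header convention."""


class AnnotationParseError(EnzpamError):
    """A Prokka-style annotation file is malformed."""


class AnnotatorError(EnzpamError):
    """The external annotator could not be run or exited non-zero."""


class ReferenceError_(EnzpamError):
    """A synonym refers to an enzyme absent from the spec table."""


class MatrixError(EnzpamError):
    """Matrix construction or comparison received inconsistent labels."""


class PipelineError(EnzpamError):
    """A pipeline step is missing an upstream artifact or has a bad config."""


class FixtureError(EnzpamError):
    """A fixture configuration is impossible to satisfy."""
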