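"""Exception hierarchy shared across the pipeline."""


class ProbeDockError(Exception):
    """Base class for every error raised by this package."""


class MalformedInputError(ProbeDockError):
    """Input text violates the expected dialect (e.g. a PDB with no ATOM records)."""


class TemplateMismatchError(ProbeDockError):
    """A probe residue's atoms do not match its registry template."""


class PerceptionError(ProbeDockError):
    """Pharmacophore features could not be assigned to a probe."""


class ParseError(ProbeDockError):
    """A structured text file failed to parse; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownClusterError(ProbeDockError):
    """A requested crosscluster id does not exist in the parsed result."""


class EmptyInputError(ProbeDockError):
    """An operation that requires non-empty input received an empty one."""
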