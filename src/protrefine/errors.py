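"""Exception hierarchy shared across the package."""


class ProtrefineError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ProtrefineError, ValueError):
    """Input violates a documented precondition or invariant."""


class PDBParseError(ProtrefineError, ValueError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyModelError(ProtrefineError, ValueError):
    """A structure file contained no ATOM records."""


class FitError(ProtrefineError, ValueError):
    """Rigid-body fit is undefined (too few or degenerate points)."""


class CorrespondenceError(ProtrefineError, ValueError):
    """No residue correspondence could be established between two chains."""


class SiteTooSmallError(ProtrefineError, ValueError):
    """Fewer than three paired residues fall inside a binding-site radius."""


class PipelineError(ProtrefineError, RuntimeError):
    """A pipeline stage (e.g. an external minimizer hook) failed."""
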