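"""Exception hierarchy shared across the toolkit."""


class EhrPhenError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(EhrPhenError, ValueError):
    """A caller supplied an argument that violates a precondition."""


class FormatError(EhrPhenError, ValueError):
    """A file does not conform to its documented on-disk format."""


class DuplicateEntryError(FormatError):
    """A code list contains the same code more than once."""


class CoverageMismatchError(EhrPhenError, ValueError):
    """Two annotation sets do not cover the same terms."""

    def __init__(self, message: str, symmetric_difference=()):
        super().__init__(message)
        self.symmetric_difference = list(symmetric_difference)


class ConfigError(EhrPhenError, ValueError):
    """A generator or pipeline configuration is invalid."""


class NoDataError(EhrPhenError, ValueError):
    """An operation received an empty input it cannot work with."""


class DegenerateInputError(EhrPhenError, ValueError):
    """Input is formally valid but statistically degenerate."""


class ConvergenceError(EhrPhenError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
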