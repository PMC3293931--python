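"""Exception hierarchy shared across the package."""


class PtarefError(Exception):
    """Base class for all package-specific errors."""


class FastaParseError(PtarefError):
    """Malformed FASTA input (bad header, empty file, duplicate IDs)."""


class AlphabetError(PtarefError):
    """Sequence contains characters outside the RNA/DNA alphabet."""


class InvariantError(PtarefError):
    """A domain-type invariant was violated (lengths, coordinates, states)."""


class ParameterError(PtarefError):
    """A user-settable parameter is outside its allowed range."""


class BackendUnavailableError(PtarefError):
    """An external hybridization backend was requested but is not configured."""


class LayoutError(PtarefError):
    """Feature-vector layout does not match the model it is scored against."""


class TrainingError(PtarefError):
    """SVR training preconditions not met (empty class, bad shapes)."""


class ModelFormatError(PtarefError):
    """Model file is corrupted or has an unsupported version tag."""


class UndefinedMetricError(PtarefError):
    """Confusion-matrix metric requested with an all-zero denominator."""


class FoldError(PtarefError):
    """Cross-validation fold layout infeasible for the given class sizes."""


class ZeroVarianceError(PtarefError):
    """Pearson correlation undefined for a constant vector."""


class SiteNotFoundError(PtarefError):
    """Type-II validation: the supplied site sequence is absent from the transcript."""


class AmbiguousSiteError(PtarefError):
    """Type-II validation: the site sequence occurs more than once."""

    def __init__(self, positions):
        self.positions = list(positions)
        pos = ", ".join(str(p + 1) for p in self.positions)
        super().__init__(f"site sequence occurs at multiple positions (1-based): {pos}")


class PipelineError(PtarefError):
    """Pipeline configuration problem (missing model/library, unknown miRNA)."""
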