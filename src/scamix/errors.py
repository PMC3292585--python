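"""Exception hierarchy for the scamix pipeline.

Every runtime error raised by the pipeline derives from :class:`ScamixError`
so callers (and the CLI) can distinguish method failures from programming
errors. Errors raised inside a per-sample decomposition are annotated with
the sample id and the parameter setting that produced them.
"""


class ScamixError(Exception):
    """Base class for all scamix runtime errors."""


class FormatError(ScamixError):
    """Malformed input file (ragged rows, non-numeric cells, bad layout)."""


class LabelError(ScamixError):
    """Sample labels cannot be mapped onto the two-class {1, -1} coding."""


class DimensionError(ScamixError):
    """Shape mismatch between matrices, labels or identifier lists."""


class ScpEmptyError(ScamixError):
    """No single-component points pass the directionality criterion.

    Carries ``n_selected`` (always 0) so callers can report the count.
    """

    def __init__(self, message: str, n_selected: int = 0):
        super().__init__(message)
        self.n_selected = n_selected


class ClusteringError(ScamixError):
    """Mixing-matrix estimation failed (too few SCPs or degenerate geometry)."""


class SolverDivergenceError(ScamixError):
    """The iterative shrinkage solver produced a non-finite objective."""
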