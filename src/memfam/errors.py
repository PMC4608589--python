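"""Exception types shared across the package."""


class MemfamError(Exception):
    """Base class for all package errors."""


class SequenceLoadError(MemfamError):
    """A FASTA record could not be parsed or validated; names the offender."""


class DegenerateNullError(MemfamError):
    """The shuffle-score distribution has zero spread, so no z can be formed.

    Raised for pathological inputs such as homopolymers, where every
    composition-preserving permutation yields the same alignment score.
    """


class StageError(MemfamError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
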