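"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PrespeechError`, so callers (and
the CLI) can distinguish bad inputs (exit code 2) from stage failures
(exit code 3).
"""


class PrespeechError(Exception):
    """Base class for all package errors."""


class ParseError(PrespeechError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(PrespeechError):
    """A file is structurally wrong (e.g. missing landmark columns)."""


class ValidationError(PrespeechError):
    """Parsed content violates an invariant (e.g. offset <= onset)."""


class TieBreakError(ValidationError):
    """Two utterances share an onset and no tie-break policy was set."""


class EmptySetError(PrespeechError):
    """An operation was asked to summarize an empty analysis set."""


class InsufficientDataError(PrespeechError):
    """Too few qualifying observations for the requested statistic."""


class LexiconLookupError(PrespeechError):
    """A word is absent from the pronunciation lexicon and overrides."""

    def __init__(self, word: str):
        self.word = word
        super().__init__(
            f"word {word!r} not found in lexicon or overrides; "
            "supply a manual override entry"
        )


class MissingWordsError(PrespeechError):
    """Aggregated report of out-of-lexicon words for a whole corpus."""

    def __init__(self, words):
        self.words = sorted(set(words))
        super().__init__(
            f"{len(self.words)} word(s) unresolvable via lexicon or "
            f"overrides: {', '.join(self.words)}"
        )


class EpochRangeError(PrespeechError):
    """The requested epoch window lies entirely outside the track."""


class DesignError(PrespeechError):
    """The fixed-effects design matrix is rank deficient or degenerate."""


class ConvergenceError(PrespeechError):
    """Model fitting failed even for the fallback structure."""


class BootstrapError(PrespeechError):
    """Too many bootstrap refits failed to trust the intervals."""


class FeasibilityError(PrespeechError):
    """A simulated posture ramp does not fit in the available time.

    Carries the list of (dyad, utterance index) offenders.
    """

    def __init__(self, offenders):
        self.offenders = list(offenders)
        ids = ", ".join(f"{d}/utt{i}" for d, i in self.offenders[:10])
        more = "" if len(self.offenders) <= 10 else f" (+{len(self.offenders) - 10} more)"
        super().__init__(
            f"posture lead exceeds available inter-utterance time for "
            f"{len(self.offenders)} utterance(s): {ids}{more}"
        )


class StageError(PrespeechError):
    """Wraps an error with the pipeline stage and record that caused it."""

    def __init__(self, stage: str, record_id: str, cause: Exception):
        self.stage = stage
        self.record_id = record_id
        self.cause = cause
        super().__init__(f"stage {stage!r}, record {record_id!r}: {cause}")
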