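"""Exception and warning hierarchy.

All library-raised errors derive from :class:`MicardError` so callers (and the
CLI) can separate data/validation failures from programming errors.
"""


class MicardError(Exception):
    """Base class for all micard errors."""


class InputError(MicardError):
    """Missing, empty, or otherwise unusable input."""


class EmptyInputError(InputError):
    """An input that must be non-empty is empty (zero valid rows, empty MIC...)."""


class FormatError(MicardError):
    """A file does not conform to the expected layout; names the offending field."""


class BuildError(MicardError):
    """MIC construction failed (e.g. no species-specific ions survive)."""


class GenerationError(MicardError):
    """Synthetic-data generation failed (e.g. infeasible ion density)."""


class MicardWarning(UserWarning):
    """Base class for micard warnings."""


class RejectedRowsWarning(MicardWarning):
    """Rows of a peak list were dropped during parsing."""


class ShortfallWarning(MicardWarning):
    """Fewer ions available than requested (top-N selection below its target)."""


class DegenerateDataWarning(MicardWarning):
    """Statistic undefined on the given data (e.g. zero rank variance)."""
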