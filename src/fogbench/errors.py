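"""Exception hierarchy shared across the toolkit.

Undefined metrics raise rather than silently returning 0: a silent zero in
a leaderboard-style evaluation corrupts every aggregate built on top of it.
"""


class FogbenchError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(FogbenchError):
    """A CSV file does not match its declared dialect (missing/extra column)."""


class FormatError(FogbenchError):
    """A file is structurally invalid (empty, non-uniform time index, ...)."""


class ValidationError(FogbenchError):
    """A value violates a documented precondition (NaN score, negative count)."""


class AlignmentError(FogbenchError):
    """Two per-sample series that must share a length do not."""


class UndefinedMetricError(FogbenchError):
    """A metric has no defined value for this input (e.g. no positives)."""


class InsufficientDataError(FogbenchError):
    """Too few subjects/observations for the requested statistical test."""
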