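"""Exception hierarchy for the ASLT pipeline.

All pipeline errors derive from :class:`AsltError` so callers can catch one
type at the boundary; stage failures in the full pipeline wrap the original
error with the stage name attached.
"""

from __future__ import annotations


class AsltError(Exception):
    """Base class for all package errors."""


class FormatError(AsltError):
    """Input file does not match the expected layout (e.g. missing column)."""


class ValidationError(AsltError):
    """Input data violates a domain invariant (e.g. no time-0 row)."""


class FitFailureError(AsltError):
    """Nonlinear fit failed to converge.

    Carries the best candidate found so callers can inspect how close the
    optimizer got.
    """

    def __init__(self, message: str, best_params=None, best_sse: float | None = None):
        super().__init__(message)
        self.best_params = best_params
        self.best_sse = best_sse


class StageError(AsltError):
    """A pipeline stage failed; ``stage`` names where."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
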