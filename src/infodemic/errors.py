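"""Package exception hierarchy."""

from __future__ import annotations

__all__ = ["InfodemicError", "ValidationError", "StageError"]


class InfodemicError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(InfodemicError, ValueError):
    """Invalid input data or out-of-range parameter."""


class StageError(InfodemicError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
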