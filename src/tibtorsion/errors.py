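"""Exception hierarchy for the torsion pipeline.

Every pipeline stage raises a subclass of :class:`TorsionError`; errors that
occur inside a named stage of a full measurement carry the stage name so that
CLI output and reports can point at the failing step.
"""

from __future__ import annotations


class TorsionError(Exception):
    """Base class for all package errors."""

    #: CLI exit code family: 2 input validation, 3 geometry, 4 I/O.
    exit_code = 1

    def __init__(self, message: str, *, stage: str | None = None):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" if stage else message)


class ValidationError(TorsionError):
    """Input violates a documented contract (counts, ranges, missing fields)."""

    exit_code = 2


class FormatError(TorsionError):
    """A file could not be parsed as the expected format."""

    exit_code = 2


class IOErrorTorsion(TorsionError):
    """Filesystem-level read/write failure."""

    exit_code = 4


class GeometryError(TorsionError):
    """A geometric computation failed on otherwise valid input."""

    exit_code = 3


class InsufficientDataError(GeometryError):
    """Too few points/samples for the requested fit."""


class DegenerateFitError(GeometryError):
    """Degenerate configuration (collinear points, identical points, ...)."""


class SliceError(GeometryError):
    """A required mesh cross-section is empty or missing."""


class CoverageError(GeometryError):
    """The mesh does not extend far enough for a required construction."""


def stage_wrap(stage: str, exc: TorsionError) -> TorsionError:
    """Re-raise helper: attach a stage name to a propagating error."""
    if exc.stage is None:
        exc.stage = stage
        exc.args = (f"[{stage}] {exc.args[0]}",) if exc.args else (f"[{stage}]",)
    return exc
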