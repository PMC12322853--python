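"""Exception hierarchy for the elicitation and scoring engines."""

from __future__ import annotations


class PyMacbethError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PyMacbethError, ValueError):
    """An argument violates a precondition (bad shape, unknown id, out-of-range value)."""


class DegenerateRangeError(PyMacbethError, ValueError):
    """Performance data has zero spread, so five distinct reference levels cannot exist."""


class DegenerateDataError(PyMacbethError, ValueError):
    """Rating data has no between-item variance, so reliability is undefined."""


class ConsistencyError(PyMacbethError, ValueError):
    """A judgment matrix is internally inconsistent.

    Carries the :class:`~pymacbeth.elicitation.ConsistencyReport` that
    diagnoses which judgments jointly have no cardinal representation.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report
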