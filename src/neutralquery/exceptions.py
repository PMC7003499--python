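"""Exception hierarchy for :mod:`neutralquery`.

All package errors derive from :class:`NeutralQueryError`, so callers can
catch the whole family with one clause.  Errors that signal bad user input
also subclass :class:`ValueError`.
"""


class NeutralQueryError(Exception):
    """Base class for all neutralquery errors."""


class ParameterError(NeutralQueryError, ValueError):
    """A model / design / rule parameter is out of its admissible range."""


class ImpossibleEvidenceError(NeutralQueryError, ValueError):
    """A statement has zero likelihood under every hypothesis; no posterior exists."""


class DataError(NeutralQueryError, ValueError):
    """Observed data are unusable for the requested operation."""


class InsufficientDataError(DataError):
    """A required stratum of the data is empty (e.g. no verifiable incorrect answers)."""


class EmptySummaryError(DataError):
    """Attempt to summarize an empty record collection."""


class DegenerateSplitError(DataError):
    """A median split is requested but fewer than two distinct ages are present."""


class DegenerateTableError(DataError):
    """A contingency table has a structure (zero expected cell, all-zero counts)
    under which the requested statistic is undefined."""


class UndefinedStatisticError(DataError):
    """The statistic is undefined for the given input (0/0 odds ratio,
    correlation of a constant vector)."""


class FixtureIntegrityError(NeutralQueryError):
    """The embedded count fixtures fail their checksum or internal invariants."""
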