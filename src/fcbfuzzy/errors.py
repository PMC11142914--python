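"""Exception hierarchy.

``FCBError`` covers everything the user can cause (bad data, bad rulebook,
degenerate inputs); anything else escaping the package is a genuine bug.
"""


class FCBError(Exception):
    """Base class for all package errors."""


class InputError(FCBError):
    """Invalid input value (non-finite, out of range, wrong shape)."""


class RulebookError(FCBError):
    """Structurally invalid rulebook or trait declaration."""


class InsufficientDataError(InputError):
    """Too few observations to estimate fuzzy-set breakpoints."""


class DegenerateDistributionError(InputError):
    """All observations identical; quantile-based fuzzy sets are undefined."""


class EmptyRecordError(InputError):
    """A species record declares none of the rulebook's traits."""


class UndefinedScoreError(FCBError):
    """An index received no accumulated membership at all.

    Carries the index (and species where known) so callers can report rather
    than crash during sensitivity analysis.
    """

    def __init__(self, index: str, species_id: str | None = None):
        self.index = index
        self.species_id = species_id
        where = f" for species {species_id!r}" if species_id else ""
        super().__init__(
            f"no accumulated membership in any potential category for index "
            f"{index!r}{where}; the score is undefined"
        )


class UndefinedCorrelationError(FCBError):
    """Rank correlation undefined (constant vector)."""
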