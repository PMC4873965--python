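"""Exception hierarchy.

All package-specific failures derive from :class:`AllomselError` so callers
(and the CLI) can distinguish data problems (exit 1) from usage problems
(exit 2, handled by click).
"""


class AllomselError(Exception):
    """Base class for all allomsel errors."""


class DegenerateInputError(AllomselError):
    """Too few points to fit (n < 3)."""


class SingularFitError(AllomselError):
    """Zero variance on the predictor axis; the fit is undefined."""


class UndefinedSignError(AllomselError):
    """RMA slope sign is undefined because the correlation is exactly zero."""


class UnitMismatchError(AllomselError):
    """Records and fit are expressed in different length units."""


class DegenerateGroupError(AllomselError):
    """A group in a homogeneity test is too small or singular."""

    def __init__(self, group, reason):
        self.group = group
        super().__init__(f"group {group!r} is degenerate: {reason}")


class InsufficientCandidatesError(AllomselError):
    """Asked to select more individuals than were measured."""


class WeightMismatchError(AllomselError):
    """Offspring-count weights supplied for ids that are not sires."""


class MissingControlError(AllomselError):
    """No control-line males for a (replicate, generation) cell."""

    def __init__(self, replicate, generation):
        self.replicate = replicate
        self.generation = generation
        super().__init__(
            f"no control-line males for replicate {replicate!r}, "
            f"generation {generation}"
        )


class SingularRegressionError(AllomselError):
    """Regressor is constant; the slope is undefined."""


class SchemaError(AllomselError):
    """A required column is missing or a row fails validation."""


class ExtinctionError(AllomselError):
    """A simulated line died out (no sire bred); use larger cohorts."""
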