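"""Exception types shared across the package."""


class TTOutcomesError(Exception):
    """Base class for all package errors."""


class ScoreRangeError(TTOutcomesError, ValueError):
    """A score lies outside its measure's valid range."""

    def __init__(self, measure: str, score: int, lo: int, hi: int):
        self.measure = measure
        self.score = score
        super().__init__(f"score {score} outside range [{lo}, {hi}] for measure {measure!r}")


class PairMismatchError(TTOutcomesError, ValueError):
    """Two score pairs being compared do not use the same measures."""


class StructuralError(TTOutcomesError, ValueError):
    """A patient series lacks data the requested operation requires."""


class ConfigError(TTOutcomesError, ValueError):
    """Invalid registry, policy or simulation configuration."""


class CohortValidationError(TTOutcomesError, ValueError):
    """One or more rows of a cohort file failed validation.

    ``problems`` is a list of ``(line_number, message)`` tuples, line numbers
    counted as in the CSV file (header = line 1).
    """

    def __init__(self, problems):
        self.problems = list(problems)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.problems[:20])
        more = "" if len(self.problems) <= 20 else f" (+{len(self.problems) - 20} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {lines}{more}")
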