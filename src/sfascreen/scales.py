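"""Registry of the five cognitive/neuropsychological test scales.

The battery covers global cognition (MMSE, ADAS-13) and single domains:
verbal memory (RAVLT immediate recall), executive function / processing
speed (TMT part B, in seconds) and processing speed (DSST).  Each scale
carries its nominal floor/ceiling and its direction — whether a higher
score means better functioning.  The nominal range is only a fallback;
model evaluation normalises errors by the *empirical* range observed in
the data (see :func:`sfascreen.sfa_regression.empirical_range`).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TestScale", "SCALES", "TESTS", "get_scale"]


@dataclass(frozen=True)
class TestScale:
    """Metadata for one cognitive test scale.

    Attributes
    ----------
    name:
        Test identifier, one of ``MMSE, ADAS13, RAVLT_imm, TMT_B, DSST``.
    min_score, max_score:
        Scale floor and ceiling (points, or seconds for TMT_B).
    direction:
        ``"higher_better"`` or ``"lower_better"``.
    """

    name: str
    min_score: float
    max_score: float
    direction: str

    def __post_init__(self) -> None:
        if not self.min_score < self.max_score:
            raise ValueError(f"{self.name}: min_score must be < max_score")
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"{self.name}: bad direction {self.direction!r}")

    @property
    def nominal_range(self) -> float:
        return self.max_score - self.min_score

    def contains(self, value: float) -> bool:
        return self.min_score <= value <= self.max_score


#: The five tests, in the canonical order used throughout the package.
SCALES: dict[str, TestScale] = {
    "MMSE": TestScale("MMSE", 0.0, 30.0, "higher_better"),
    "ADAS13": TestScale("ADAS13", 0.0, 85.0, "lower_better"),
    "RAVLT_imm": TestScale("RAVLT_imm", 0.0, 75.0, "higher_better"),
    "TMT_B": TestScale("TMT_B", 0.0, 300.0, "lower_better"),
    "DSST": TestScale("DSST", 0.0, 93.0, "higher_better"),
}

TESTS: tuple[str, ...] = tuple(SCALES)


def get_scale(name: str) -> TestScale:
    try:
        return SCALES[name]
    except KeyError:
        raise KeyError(f"unknown test scale {name!r}; known: {sorted(SCALES)}") from None
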