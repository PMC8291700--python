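"""Bowel-viability scoring: the macroscopic score and the Chiu grade.

Two complementary expert assessments accompany the fluorescence metrics.
The macroscopic score rates four features of the exposed bowel segment —
color, peristalsis, edema formation, and mesenteric hemorrhage — each on a
1 (normal) to 4 (worst) scale, summed to a 4–16 total that is categorised
into none/mild (< 6), moderate (6–9) and severe (> 9) ischemia.  The Chiu
grade is the ordinal 0–5 histopathology scale of ischemic mucosal injury,
from normal mucosa (0) through subepithelial lifting to digestion and
disintegration of the lamina propria with hemorrhage and ulceration (5).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

_COMPONENT_MIN, _COMPONENT_MAX = 1, 4
SCORE_MIN = 4 * _COMPONENT_MIN
SCORE_MAX = 4 * _COMPONENT_MAX

#: Ordinal levels of the two graded histology features.
_SUBEPITHELIAL_LEVELS = ("none", "small", "extended")
_LIFTING_LEVELS = ("none", "moderate", "massive")


@dataclass(frozen=True)
class MacroScoreInput:
    """Component grades of the macroscopic viability score, each 1–4."""

    color: int
    peristalsis: int
    edema: int
    mesenteric_hemorrhage: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or not (_COMPONENT_MIN <= v <= _COMPONENT_MAX):
                raise ValueError(
                    f"{f.name} must be an integer grade in "
                    f"[{_COMPONENT_MIN}, {_COMPONENT_MAX}], got {v!r}"
                )

    @property
    def components(self) -> tuple[int, int, int, int]:
        return (self.color, self.peristalsis, self.edema, self.mesenteric_hemorrhage)


class IschemiaCategory(str, enum.Enum):
    NONE_MILD = "none/mild"
    MODERATE = "moderate"
    SEVERE = "severe"


def total_macro_score(score_input: MacroScoreInput) -> int:
    """Sum of the four component grades (4 = fully viable, 16 = worst)."""
    return sum(score_input.components)


def categorize_ischemia(score: int) -> IschemiaCategory:
    """Categorise a total macroscopic score: < 6 none/mild, 6–9 moderate,
    > 9 severe (both boundary scores 6 and 9 count as moderate)."""
    if not isinstance(score, int) or not (SCORE_MIN <= score <= SCORE_MAX):
        raise ValueError(
            f"score must be an integer in [{SCORE_MIN}, {SCORE_MAX}], got {score!r}"
        )
    if score < 6:
        return IschemiaCategory.NONE_MILD
    if score <= 9:
        return IschemiaCategory.MODERATE
    return IschemiaCategory.SEVERE


@dataclass(frozen=True)
class HistoDescriptor:
    """Structured histology findings underlying the Chiu grade.

    Features are ordered from superficial to deep injury.  The only
    hard consistency requirement is that disintegration of the lamina
    propria implies the lamina propria is denuded; shallower features are
    not force-implied so that partial assessments remain representable.
    """

    subepithelial_space: str = "none"
    epithelial_lifting: str = "none"
    denuded_tips: bool = False
    lamina_propria_denuded: bool = False
    dilated_capillaries_exposed: bool = False
    lamina_propria_disintegration: bool = False
    hemorrhage: bool = False
    ulceration: bool = False

    def __post_init__(self) -> None:
        if self.subepithelial_space not in _SUBEPITHELIAL_LEVELS:
            raise ValueError(
                f"subepithelial_space must be one of {_SUBEPITHELIAL_LEVELS}, "
                f"got {self.subepithelial_space!r}"
            )
        if self.epithelial_lifting not in _LIFTING_LEVELS:
            raise ValueError(
                f"epithelial_lifting must be one of {_LIFTING_LEVELS}, "
                f"got {self.epithelial_lifting!r}"
            )
        if self.lamina_propria_disintegration and not self.lamina_propria_denuded:
            raise ValueError(
                "inconsistent descriptor: lamina_propria_disintegration requires "
                "lamina_propria_denuded"
            )


def chiu_grade(descriptor: HistoDescriptor) -> int:
    """Chiu grade 0–5: the highest grade whose defining features are all
    present.

    5 — digestion and disintegration of the lamina propria with hemorrhage
    and ulceration; 4 — denuded villi including lamina propria with exposed
    dilated capillaries; 3 — massive epithelial lifting down the villus
    sides with denudation of some tips; 2 — extended subepithelial space
    with at least moderate lifting; 1 — small subepithelial (Gruenhagen)
    space; 0 — normal mucosa.
    """
    d = descriptor
    lifting = _LIFTING_LEVELS.index(d.epithelial_lifting)
    subep = _SUBEPITHELIAL_LEVELS.index(d.subepithelial_space)
    if d.lamina_propria_disintegration and d.hemorrhage and d.ulceration:
        return 5
    if d.lamina_propria_denuded and d.dilated_capillaries_exposed:
        return 4
    if lifting >= 2 and d.denuded_tips:
        return 3
    if subep >= 2 and lifting >= 1:
        return 2
    if subep >= 1:
        return 1
    return 0


def descriptor_for_grade(grade: int) -> HistoDescriptor:
    """Canonical descriptor exhibiting a given Chiu grade, with all
    shallower features present (the typical fully-developed lesion)."""
    if not isinstance(grade, int) or not (0 <= grade <= 5):
        raise ValueError(f"grade must be an integer in [0, 5], got {grade!r}")
    return HistoDescriptor(
        subepithelial_space=_SUBEPITHELIAL_LEVELS[min(grade, 2)],
        epithelial_lifting=_LIFTING_LEVELS[min(max(grade - 1, 0), 2)],
        denuded_tips=grade >= 3,
        lamina_propria_denuded=grade >= 4,
        dilated_capillaries_exposed=grade >= 4,
        lamina_propria_disintegration=grade >= 5,
        hemorrhage=grade >= 5,
        ulceration=grade >= 5,
    )
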