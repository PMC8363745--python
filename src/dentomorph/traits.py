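"""ASUDAS non-metric trait grades, dichotomization, and prevalence tables.

Four traits are handled, scored on the outer enamel surface under the
Arizona State University Dental Anthropology System (ASUDAS):

========  ==========  =============  ==================
trait     tooth       grade scale    moderate/heavy from
========  ==========  =============  ==================
hypocone    udm2      0-6            4
carabelli   udm2      0-7            5
entoconulid ldm2      0-5            3
metaconulid ldm2      0,1,1A,2,3,4   2
========  ==========  =============  ==================

Grades below the threshold are "none/light". The metaconulid grade ``1A``
orders strictly between 1 and 2 and dichotomizes as none/light.

Prevalence tables report per-population class percentages rounded to
integers for display using largest-remainder rounding (so each trait's
percentages sum to 100); raw counts are always retained, and the Chi-square
test consumes counts, never rounded percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import SpecimenMetadata, ValidationError
from .inference import ContingencyTable
import numpy as np

__all__ = [
    "TRAITS",
    "NONE_LIGHT",
    "MODERATE_HEAVY",
    "TraitScore",
    "dichotomize_grade",
    "load_trait_scores",
    "prevalence_table",
    "trait_contingency",
]

NONE_LIGHT = "none_light"
MODERATE_HEAVY = "moderate_heavy"

# trait -> (tooth_class, ordered grade scale, first moderate/heavy grade)
TRAITS: dict[str, tuple[str, tuple[str, ...], str]] = {
    "hypocone": ("udm2", ("0", "1", "2", "3", "4", "5", "6"), "4"),
    "carabelli": ("udm2", ("0", "1", "2", "3", "4", "5", "6", "7"), "5"),
    "entoconulid": ("ldm2", ("0", "1", "2", "3", "4", "5"), "3"),
    "metaconulid": ("ldm2", ("0", "1", "1A", "2", "3", "4"), "2"),
}


def dichotomize_grade(trait: str, grade) -> str:
    """Collapse an ordinal ASUDAS grade into none/light vs moderate/heavy."""
    if trait not in TRAITS:
        raise ValidationError(f"unknown trait {trait!r}; expected one of {sorted(TRAITS)}")
    _, scale, threshold = TRAITS[trait]
    g = str(grade).strip().upper()
    if g not in scale:
        raise ValidationError(f"invalid grade {grade!r} for trait {trait!r} (scale {scale})")
    return MODERATE_HEAVY if scale.index(g) >= scale.index(threshold) else NONE_LIGHT


@dataclass
class TraitScore:
    """One specimen's ordinal grade for one trait."""

    specimen_id: str
    trait: str
    grade: str
    population: str | None = None

    def __post_init__(self) -> None:
        self.grade = str(self.grade).strip().upper()
        self.dichotomized = dichotomize_grade(self.trait, self.grade)

    @property
    def tooth_class(self) -> str:
        return TRAITS[self.trait][0]


def load_trait_scores(path) -> list[TraitScore]:
    """Read trait scores from a CSV with columns specimen_id, trait, grade.

    An optional ``population`` column is carried through so prevalence can
    be computed without a separate manifest.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("specimen_id", "trait", "grade"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    has_pop = "population" in df.columns
    return [
        TraitScore(
            row["specimen_id"],
            row["trait"],
            row["grade"],
            population=row["population"] if has_pop else None,
        )
        for _, row in df.iterrows()
    ]


def _largest_remainder_percent(counts: list[int]) -> list[int]:
    total = sum(counts)
    if total == 0:
        return [0 for _ in counts]
    quotas = [100.0 * c / total for c in counts]
    floors = [int(np.floor(q)) for q in quotas]
    short = 100 - sum(floors)
    # distribute by largest remainder; ties go to the larger quota
    order = sorted(
        range(len(counts)), key=lambda i: (quotas[i] - floors[i], quotas[i]), reverse=True
    )
    for i in order[:short]:
        floors[i] += 1
    return floors


def _population_of(score: TraitScore, metadata: dict[str, SpecimenMetadata] | None) -> str:
    if metadata is not None and score.specimen_id in metadata:
        return metadata[score.specimen_id].population
    if score.population:
        return score.population
    raise ValidationError(f"no population known for specimen {score.specimen_id}")


def prevalence_table(
    scores: list[TraitScore],
    metadata: list[SpecimenMetadata] | dict[str, SpecimenMetadata] | None = None,
) -> pd.DataFrame:
    """Per-population prevalence of dichotomized trait classes.

    Returns a tidy DataFrame with one row per (trait, population, class):
    columns ``trait, tooth_class, population, cls, count, n, percent``.
    ``percent`` is the display percentage (largest-remainder integer
    rounding within each trait-population pair); counts are exact.
    """
    if isinstance(metadata, list):
        metadata = {m.specimen_id: m for m in metadata}
    rows = []
    by_key: dict[tuple[str, str], list[TraitScore]] = {}
    for s in scores:
        by_key.setdefault((s.trait, _population_of(s, metadata)), []).append(s)
    for (trait, pop), group in sorted(by_key.items()):
        n = len(group)
        counts = [
            sum(1 for s in group if s.dichotomized == cls)
            for cls in (NONE_LIGHT, MODERATE_HEAVY)
        ]
        pcts = _largest_remainder_percent(counts)
        for cls, cnt, pct in zip((NONE_LIGHT, MODERATE_HEAVY), counts, pcts):
            rows.append(
                {
                    "trait": trait,
                    "tooth_class": TRAITS[trait][0],
                    "population": pop,
                    "cls": cls,
                    "count": cnt,
                    "n": n,
                    "percent": pct,
                }
            )
    return pd.DataFrame(rows)


def trait_contingency(
    scores: list[TraitScore],
    trait: str,
    focal_population: str = "Baka",
    metadata: list[SpecimenMetadata] | dict[str, SpecimenMetadata] | None = None,
) -> ContingencyTable:
    """Counts of a focal population vs all others by dichotomized class.

    This is the 2x2 layout behind the trait Chi-square comparisons: rows are
    (focal, pooled rest), columns (none/light, moderate/heavy).
    """
    if isinstance(metadata, list):
        metadata = {m.specimen_id: m for m in metadata}
    wanted = [s for s in scores if s.trait == trait]
    if not wanted:
        raise ValidationError(f"no scores for trait {trait!r}")
    counts = np.zeros((2, 2), dtype=int)
    for s in wanted:
        row = 0 if _population_of(s, metadata) == focal_population else 1
        col = 0 if s.dichotomized == NONE_LIGHT else 1
        counts[row, col] += 1
    return ContingencyTable(
        counts,
        (focal_population, f"non-{focal_population}"),
        (NONE_LIGHT, MODERATE_HEAVY),
    )
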