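"""Core containers for landmark-based dental shape data.

The study design distinguishes two tooth classes (upper and lower deciduous
second molars, ``udm2`` / ``ldm2``) and four landmark feature sets per tooth:

``dentinal_crown``
    anatomical landmarks on the dentine horn tips and marginal-ridge groove
    points, plus curve semilandmarks resampling the enamel-dentine junction
    (EDJ) marginal edge, plus 24 pseudo-landmarks on the cervical outline.
``edj_only``
    the anatomical + curve blocks without the outline.
``cervical_outline`` / ``crown_outline``
    24 equiangular pseudo-landmarks on the respective closed crown contour,
    collected in the cervical-plane frame.

Point counts per template are fixed by the landmarking protocol:
ldm2 dentinal crown = 8 anatomical + 23 curve + 24 outline = 55 points;
udm2 dentinal crown = 7 + 47 + 24 = 78 points.

Within a template the storage order is frozen: the anatomical block first,
then curve semilandmarks (mesio-buccal first, clockwise in occlusal view),
then outline pseudo-landmarks starting at the mesial reference ray.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TOOTH_CLASSES",
    "FEATURE_SETS",
    "POPULATIONS",
    "ROLE_ANATOMICAL",
    "ROLE_CURVE",
    "ROLE_OUTLINE",
    "Template",
    "TEMPLATES",
    "template_for",
    "SpecimenMetadata",
    "LandmarkConfiguration",
    "ShapeDataset",
    "ValidationError",
]

TOOTH_CLASSES = ("udm2", "ldm2")
FEATURE_SETS = ("dentinal_crown", "edj_only", "cervical_outline", "crown_outline")
POPULATIONS = (
    "Baka",
    "European",
    "Bedouin",
    "SouthAmerican",
    "Egyptian",
    "SoutheastAsian",
    "other",
)
SEXES = ("f", "m", "unknown")
SIDES = ("left", "right")

ROLE_ANATOMICAL = "anatomical"
ROLE_CURVE = "curve_semilandmark"
ROLE_OUTLINE = "outline_pseudolandmark"


class ValidationError(ValueError):
    """A record violates a template or metadata invariant."""


@dataclass(frozen=True)
class Template:
    """Point-count contract for one (tooth_class, feature_set) pair."""

    tooth_class: str
    feature_set: str
    n_anatomical: int
    n_curve: int
    n_outline: int

    @property
    def n_points(self) -> int:
        return self.n_anatomical + self.n_curve + self.n_outline

    @property
    def roles(self) -> tuple[str, ...]:
        return (
            (ROLE_ANATOMICAL,) * self.n_anatomical
            + (ROLE_CURVE,) * self.n_curve
            + (ROLE_OUTLINE,) * self.n_outline
        )

    def anatomical_indices(self) -> np.ndarray:
        return np.arange(self.n_anatomical)

    def curve_indices(self) -> np.ndarray:
        return np.arange(self.n_anatomical, self.n_anatomical + self.n_curve)

    def outline_indices(self) -> np.ndarray:
        return np.arange(self.n_anatomical + self.n_curve, self.n_points)


TEMPLATES: dict[tuple[str, str], Template] = {}
for _tc, _na, _nc in (("ldm2", 8, 23), ("udm2", 7, 47)):
    TEMPLATES[(_tc, "dentinal_crown")] = Template(_tc, "dentinal_crown", _na, _nc, 24)
    TEMPLATES[(_tc, "edj_only")] = Template(_tc, "edj_only", _na, _nc, 0)
    TEMPLATES[(_tc, "cervical_outline")] = Template(_tc, "cervical_outline", 0, 0, 24)
    TEMPLATES[(_tc, "crown_outline")] = Template(_tc, "crown_outline", 0, 0, 24)


# Anatomical landmark names in template order, and the marginal-ridge loop:
# the EDJ occlusal edge runs through a cycle of on-loop anatomical anchors
# (template indices), with the curve-semilandmark block distributed along the
# gaps between consecutive anchors (gap sizes sum to the curve count).
ANATOMICAL_NAMES = {
    "ldm2": (
        "protoconid_horn",
        "metaconid_horn",
        "entoconid_horn",
        "hypoconid_horn",
        "hypoconulid_horn",
        "groove_metaconid_entoconid",
        "groove_protoconid_hypoconid",
        "groove_hypoconid_hypoconulid",
    ),
    "udm2": (
        "paracone_horn",
        "protocone_horn",
        "metacone_horn",
        "hypocone_horn",
        "central_fovea",
        "distal_fossa",
        "hypocone_lingual_ridge",
    ),
}

# (anchor cycle of anatomical indices along the loop, semilandmarks per gap)
EDJ_LOOPS = {
    "ldm2": ((0, 1, 5, 2, 4, 7, 3, 6), (3, 3, 3, 3, 3, 3, 3, 2)),  # 23 sLM
    "udm2": ((0, 1, 6, 3, 2), (10, 10, 9, 9, 9)),  # 47 sLM; indices 4, 5 interior
}


def template_for(tooth_class: str, feature_set: str) -> Template:
    try:
        return TEMPLATES[(tooth_class, feature_set)]
    except KeyError:
        raise ValidationError(
            f"no template for tooth_class={tooth_class!r}, feature_set={feature_set!r}"
        ) from None


@dataclass
class SpecimenMetadata:
    """Study metadata for one individual.

    ``wear_stage_upper`` / ``wear_stage_lower`` follow the 1-5 occlusal wear
    scale and are ``None`` when the tooth is absent or unscored.
    """

    specimen_id: str
    population: str
    sex: str = "unknown"
    wear_stage_upper: int | None = None
    wear_stage_lower: int | None = None
    side: str = "left"
    tooth_classes_present: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValidationError(
                f"{self.specimen_id}: unknown population {self.population!r}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"{self.specimen_id}: invalid sex {self.sex!r}")
        if self.side not in SIDES:
            raise ValidationError(f"{self.specimen_id}: invalid side {self.side!r}")
        for name in ("wear_stage_upper", "wear_stage_lower"):
            w = getattr(self, name)
            if w is not None and not (1 <= int(w) <= 5):
                raise ValidationError(
                    f"{self.specimen_id}: {name}={w} outside the 1-5 wear scale"
                )
        bad = set(self.tooth_classes_present) - set(TOOTH_CLASSES)
        if bad:
            raise ValidationError(f"{self.specimen_id}: unknown tooth classes {bad}")
        self.tooth_classes_present = frozenset(self.tooth_classes_present)


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 3D point set under a named template.

    ``points`` is an (k, 3) float array in millimetres; ``named_map`` maps
    anatomical names (e.g. ``protoconid_horn``) to point indices.
    """

    specimen_id: str
    tooth_class: str
    feature_set: str
    points: np.ndarray
    named_map: dict[str, int] = field(default_factory=dict)
    side: str = "left"
    mirrored: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        tpl = self.template
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(
                f"{self.specimen_id}: points must be (k, 3), got {self.points.shape}"
            )
        if self.points.shape[0] != tpl.n_points:
            raise ValidationError(
                f"{self.specimen_id}: {self.points.shape[0]} points, but template "
                f"({self.tooth_class}, {self.feature_set}) requires {tpl.n_points}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValidationError(f"{self.specimen_id}: non-finite coordinates")
        if self.side not in SIDES:
            raise ValidationError(f"{self.specimen_id}: invalid side {self.side!r}")
        for name, idx in self.named_map.items():
            if not (0 <= idx < tpl.n_points):
                raise ValidationError(
                    f"{self.specimen_id}: named point {name!r} index {idx} out of range"
                )

    @property
    def template(self) -> Template:
        return template_for(self.tooth_class, self.feature_set)

    @property
    def roles(self) -> tuple[str, ...]:
        return self.template.roles

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            specimen_id=self.specimen_id,
            tooth_class=self.tooth_class,
            feature_set=self.feature_set,
            points=self.points.copy(),
            named_map=dict(self.named_map),
            side=self.side,
            mirrored=self.mirrored,
        )


class ShapeDataset:
    """A stack of template-consistent configurations plus specimen metadata.

    This is the unit every analysis consumes. All configurations must share
    one (tooth_class, feature_set) template, and every configuration must
    have a metadata record.
    """

    def __init__(
        self,
        configurations: list[LandmarkConfiguration],
        metadata: list[SpecimenMetadata] | dict[str, SpecimenMetadata],
    ) -> None:
        if isinstance(metadata, dict):
            meta_map = dict(metadata)
        else:
            meta_map = {m.specimen_id: m for m in metadata}
            if len(meta_map) != len(metadata):
                raise ValidationError("duplicate specimen_id in metadata")
        keys = {(c.tooth_class, c.feature_set) for c in configurations}
        if len(keys) > 1:
            raise ValidationError(f"mixed templates in dataset: {sorted(keys)}")
        ids = [c.specimen_id for c in configurations]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate specimen_id among configurations")
        missing = [i for i in ids if i not in meta_map]
        if missing:
            raise ValidationError(f"configurations without metadata: {missing}")
        self.configurations = list(configurations)
        self.metadata = meta_map

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    @property
    def tooth_class(self) -> str:
        return self.configurations[0].tooth_class

    @property
    def feature_set(self) -> str:
        return self.configurations[0].feature_set

    @property
    def template(self) -> Template:
        return self.configurations[0].template

    def coords(self) -> np.ndarray:
        """Stack all configurations into an (n, k, 3) array."""
        return np.stack([c.points for c in self.configurations])

    def populations(self) -> list[str]:
        return [self.metadata[i].population for i in self.ids]

    def sexes(self) -> list[str]:
        return [self.metadata[i].sex for i in self.ids]

    def subset(self, ids: list[str]) -> "ShapeDataset":
        wanted = set(ids)
        configs = [c for c in self.configurations if c.specimen_id in wanted]
        return ShapeDataset(configs, {c.specimen_id: self.metadata[c.specimen_id] for c in configs})

    def with_coords(self, coords: np.ndarray) -> "ShapeDataset":
        """Return a copy whose point arrays are replaced row-by-row."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), self.template.n_points, 3):
            raise ValidationError(
                f"coords shape {coords.shape} does not match dataset "
                f"({len(self)}, {self.template.n_points}, 3)"
            )
        configs = []
        for c, pts in zip(self.configurations, coords):
            c2 = c.copy()
            c2.points = pts.copy()
            configs.append(c2)
        return ShapeDataset(configs, dict(self.metadata))
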