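"""Synthetic landmark cohorts with the statistical structure the analyses assume.

Landmark data of this kind are rarely released, so this module generates
cohorts from idealized crown templates: a closed convex-ish cervical outline in the
cervical plane, a marginal-ridge loop through the dentine horn tips for the
EDJ curve, and the correct point counts and roles per tooth-class template
(ldm2 dentinal crown 8 + 23 + 24 = 55 points; udm2 7 + 47 + 24 = 78).

A specimen is built in shape space - template (at unit centroid size) plus
group mean offset, sex effect, and isotropic Gaussian landmark noise - and
then pushed into "raw data" space by scaling with a lognormal size draw and
applying a random rotation and translation, so that superimposition has
real work to do. Noise is therefore expressed in consensus units. Paired
upper/lower dyads share a latent factor that drives one shape axis per
block, calibrated so the theoretical first-singular-warp score correlation
equals the requested rho.

Default group sizes and the ordering of size means across populations
mirror the reference study design (e.g. Baka ldm2 n = 32, European ldm2
n = 11; South Americans and Baka largest, Europeans and Bedouins smallest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (
    ANATOMICAL_NAMES,
    EDJ_LOOPS,
    POPULATIONS,
    LandmarkConfiguration,
    ShapeDataset,
    SpecimenMetadata,
    template_for,
)
from .gpa import centroid_size

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "make_template",
    "generate_cohort",
    "generate_dyad_cohort",
    "default_study_groups",
    "similarity_basis",
]


# ---------------------------------------------------------------------------
# templates

# per-anchor loop geometry: angle (deg), radius, height; indices follow
# ANATOMICAL_NAMES order
_LDM2_ANCHORS = {
    0: (60.0, 0.78, 0.80),   # protoconid horn
    1: (120.0, 0.78, 0.78),  # metaconid horn
    5: (180.0, 0.70, 0.48),  # groove metaconid-entoconid
    2: (225.0, 0.76, 0.74),  # entoconid horn
    4: (280.0, 0.74, 0.66),  # hypoconulid horn
    7: (305.0, 0.70, 0.46),  # groove hypoconid-hypoconulid
    3: (330.0, 0.78, 0.76),  # hypoconid horn
    6: (380.0, 0.70, 0.47),  # groove protoconid-hypoconid
}
_UDM2_ANCHORS = {
    0: (45.0, 0.78, 0.80),   # paracone horn
    1: (135.0, 0.78, 0.76),  # protocone horn
    6: (215.0, 0.68, 0.50),  # lingual marginal ridge of the hypocone
    3: (270.0, 0.74, 0.68),  # hypocone horn
    2: (340.0, 0.76, 0.74),  # metacone horn
}
_UDM2_INTERIOR = {4: (0.10, 0.05, 0.36), 5: (-0.45, 0.00, 0.42)}  # fovea, fossa


def _outline_points(k: int, scale: float, z: float) -> np.ndarray:
    """Closed convex-ish crown contour: 24 equiangular points on a superellipse."""
    theta = 2.0 * np.pi * np.arange(k) / k
    a, b = 1.10 * scale, 0.92 * scale  # mesio-distal slightly longer
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    r = r * (1.0 + 0.04 * np.cos(2 * theta + 0.6))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), np.full(k, z)])


def _loop_points(anchors: dict[int, tuple[float, float, float]], cycle, gaps):
    """Anchor coordinates plus semilandmarks interpolated along the loop."""
    anat = {}
    for idx, (ang, rad, z) in anchors.items():
        a = np.deg2rad(ang)
        anat[idx] = np.array([rad * np.cos(a), rad * np.sin(a), z])
    curve = []
    items = [anchors[i] for i in cycle]
    for g, gap in enumerate(gaps):
        a0, r0, z0 = items[g]
        a1, r1, z1 = items[(g + 1) % len(items)]
        if a1 <= a0:
            a1 += 360.0
        for s in range(1, gap + 1):
            t = s / (gap + 1)
            ang = np.deg2rad(a0 + t * (a1 - a0))
            rad = r0 + t * (r1 - r0)
            z = z0 + t * (z1 - z0) - 0.06 * np.sin(np.pi * t)  # ridge sag
            curve.append([rad * np.cos(ang), rad * np.sin(ang), z])
    return anat, np.array(curve)


def make_template(tooth_class: str, feature_set: str) -> LandmarkConfiguration:
    """Deterministic idealized crown template with correct counts and roles."""
    tpl = template_for(tooth_class, feature_set)
    blocks = []
    named = {}
    if tpl.n_anatomical:
        anchors = _LDM2_ANCHORS if tooth_class == "ldm2" else _UDM2_ANCHORS
        cycle, gaps = EDJ_LOOPS[tooth_class]
        anat, curve = _loop_points(anchors, cycle, gaps)
        if tooth_class == "udm2":
            anat.update({i: np.array(v) for i, v in _UDM2_INTERIOR.items()})
        anat_block = np.stack([anat[i] for i in range(tpl.n_anatomical)])
        blocks.append(anat_block)
        blocks.append(curve)
        named = {name: i for i, name in enumerate(ANATOMICAL_NAMES[tooth_class])}
    if tpl.n_outline:
        scale = 1.0 if feature_set != "crown_outline" else 1.08
        blocks.append(_outline_points(tpl.n_outline, scale, 0.0))
    pts = np.vstack(blocks)
    assert pts.shape[0] == tpl.n_points
    return LandmarkConfiguration(
        specimen_id=f"template_{tooth_class}_{feature_set}",
        tooth_class=tooth_class,
        feature_set=feature_set,
        points=pts,
        named_map=named,
    )


def similarity_basis(template_flat: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity directions at a configuration.

    Columns span translations (3), infinitesimal rotations (3) and scaling
    (1) of the flattened (3k,) configuration; shape effects planted
    orthogonally to this subspace survive superimposition.
    """
    pts = template_flat.reshape(-1, 3)
    k = pts.shape[0]
    cols = []
    for d in range(3):
        t = np.zeros((k, 3))
        t[:, d] = 1.0
        cols.append(t.ravel())
    gens = [
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
        np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
    ]
    for g in gens:
        cols.append((pts @ g.T).ravel())
    cols.append(template_flat.copy())
    basis, _ = np.linalg.qr(np.column_stack(cols))
    return basis


def _off_similarity_direction(rng: np.random.Generator, template_flat: np.ndarray) -> np.ndarray:
    basis = similarity_basis(template_flat)
    v = rng.standard_normal(template_flat.size)
    v -= basis @ (basis.T @ v)
    return v / np.linalg.norm(v)


@dataclass
class GroupSpec:
    """One population group of a synthetic cohort."""

    label: str
    n: int
    offset: float | np.ndarray = 0.0  # mean-shape offset: magnitude or (3k,) vector
    lncs_mean: float = 3.0
    lncs_sd: float = 0.05
    sex_labels: bool = False  # alternate f/m labels (Baka-style metadata)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1")


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort; reproducible from ``seed``."""

    tooth_class: str = "ldm2"
    feature_set: str = "dentinal_crown"
    groups: list[GroupSpec] = field(default_factory=lambda: [GroupSpec("Baka", 20)])
    noise_sd: float = 0.02  # isotropic landmark noise, consensus units
    dyad_rho: float = 0.8  # latent upper/lower coupling, in [0, 1]
    sex_effect: float = 0.0  # male-female mean shape distance (0 = null)
    allometry: float = 0.0  # shape change (consensus units) per unit lnCS
    rigid_transforms: bool = True  # random rotation+translation of raw specimens
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.dyad_rho <= 1.0:
            raise ValueError("dyad_rho must lie in [0, 1]")
        if not self.groups:
            raise ValueError("at least one group required")


# Group sizes follow the reference sample; size means are ordered
# SouthAmerican >= Baka > SoutheastAsian > Egyptian > European ~ Bedouin.
_STUDY_N = {
    "ldm2": {"Baka": 32, "European": 11, "Egyptian": 7, "Bedouin": 4,
             "SoutheastAsian": 3, "SouthAmerican": 2},
    "udm2": {"Baka": 23, "European": 22, "Egyptian": 6, "Bedouin": 2,
             "SoutheastAsian": 5, "SouthAmerican": 2},
}
_LNCS_MEANS = {
    "SouthAmerican": 3.08, "Baka": 3.06, "SoutheastAsian": 3.02,
    "Egyptian": 3.00, "European": 2.96, "Bedouin": 2.96,
}


def default_study_groups(tooth_class: str = "ldm2", offset: float = 0.03) -> list[GroupSpec]:
    """Study-sized groups with study-ordered size means and Baka sex labels."""
    return [
        GroupSpec(
            label=pop,
            n=n,
            offset=offset,
            lncs_mean=_LNCS_MEANS[pop],
            lncs_sd=0.05,
            sex_labels=(pop == "Baka"),
        )
        for pop, n in _STUDY_N[tooth_class].items()
    ]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return q


def _unit_template_flat(tooth_class: str, feature_set: str) -> tuple[LandmarkConfiguration, np.ndarray]:
    tmpl = make_template(tooth_class, feature_set)
    pts = tmpl.points - tmpl.points.mean(axis=0)
    pts /= centroid_size(pts)
    return tmpl, pts.ravel()


def _resolve_offset(off, rng, template_flat) -> np.ndarray:
    if np.isscalar(off):
        if off == 0:
            return np.zeros_like(template_flat)
        return float(off) * _off_similarity_direction(rng, template_flat)
    off = np.asarray(off, dtype=float)
    if off.shape != template_flat.shape:
        raise ValueError("offset vector length must equal 3k")
    return off


def _emit(
    spec: CohortSpec,
    rng: np.random.Generator,
    template: LandmarkConfiguration,
    flat_shapes: list[np.ndarray],
    meta: list[SpecimenMetadata],
    lncs: np.ndarray,
) -> ShapeDataset:
    """Turn unit-size flat shapes into raw-space configurations + metadata."""
    configs = []
    for i, flat in enumerate(flat_shapes):
        pts = flat.reshape(-1, 3)
        pts = pts * np.exp(lncs[i]) / centroid_size(pts)
        if spec.rigid_transforms:
            pts = pts @ _random_rotation(rng).T + rng.uniform(-5, 5, size=3)
        configs.append(
            LandmarkConfiguration(
                specimen_id=meta[i].specimen_id,
                tooth_class=template.tooth_class,
                feature_set=template.feature_set,
                points=pts,
                named_map=dict(template.named_map),
            )
        )
    return ShapeDataset(configs, meta)


def _group_metadata(spec: CohortSpec, tooth_class: str) -> list[SpecimenMetadata]:
    meta = []
    i = 0
    for g in spec.groups:
        pop = g.label if g.label in POPULATIONS else "other"
        for j in range(g.n):
            sex = ("f", "m")[j % 2] if g.sex_labels else "unknown"
            meta.append(
                SpecimenMetadata(
                    specimen_id=f"{g.label}{i + 1:03d}",
                    population=pop,
                    sex=sex,
                    tooth_classes_present={tooth_class},
                )
            )
            i += 1
    return meta


def generate_cohort(spec: CohortSpec) -> ShapeDataset:
    """Generate one tooth-class cohort according to ``spec``.

    Each specimen = template + group offset + sex effect + isotropic noise
    in shape space, scaled by exp(lnCS draw) and (by default) randomly
    rotated and translated. Identical seeds give identical datasets.
    """
    rng = np.random.default_rng(spec.seed)
    template, tflat = _unit_template_flat(spec.tooth_class, spec.feature_set)
    sex_axis = _off_similarity_direction(rng, tflat)
    allo_axis = _off_similarity_direction(rng, tflat)
    meta = _group_metadata(spec, spec.tooth_class)
    flats, lncs = [], []
    for g in spec.groups:
        offset = _resolve_offset(g.offset, rng, tflat)
        for j in range(g.n):
            sex = ("f", "m")[j % 2] if g.sex_labels else None
            s = 0.0
            if sex is not None and spec.sex_effect:
                s = (0.5 if sex == "m" else -0.5) * spec.sex_effect
            size = rng.normal(g.lncs_mean, g.lncs_sd)
            allo = spec.allometry * (size - g.lncs_mean)
            noise = rng.normal(scale=spec.noise_sd, size=tflat.size)
            flats.append(tflat + offset + s * sex_axis + allo * allo_axis + noise)
            lncs.append(size)
    return _emit(spec, rng, template, flats, meta, np.array(lncs))


def planted_allometry_pct(spec: CohortSpec) -> float:
    """Expected percent of tangent-space shape variance explained by lnCS.

    For a single-group cohort with planted allometry coefficient ``a``,
    size spread ``s`` and noise sd ``sigma`` over ``D = 3k - 7`` effective
    tangent dimensions (seven dimensions are absorbed by similarity
    normalization): ``100 a^2 s^2 / (a^2 s^2 + D sigma^2)``.
    """
    tpl = template_for(spec.tooth_class, spec.feature_set)
    d_eff = 3 * tpl.n_points - 7
    g = spec.groups[0]
    signal = (spec.allometry * g.lncs_sd) ** 2
    return 100.0 * signal / (signal + d_eff * spec.noise_sd**2)


def generate_dyad_cohort(spec: CohortSpec) -> tuple[ShapeDataset, ShapeDataset]:
    """Generate paired upper/lower cohorts coupled by a shared latent factor.

    Per individual a latent scalar u ~ N(0,1) drives one shape axis in each
    tooth's shape space, with independent isotropic residual noise. The
    axis loading is calibrated so the theoretical correlation of the paired
    first-singular-warp scores equals ``spec.dyad_rho``; at rho = 1 the
    residual is removed entirely, making the coupling deterministic.
    Individual IDs pair the two blocks (same row order).
    """
    rho = spec.dyad_rho
    rng = np.random.default_rng(spec.seed)
    tmpl_u, flat_u = _unit_template_flat("udm2", spec.feature_set)
    tmpl_l, flat_l = _unit_template_flat("ldm2", spec.feature_set)
    axis_u = _off_similarity_direction(rng, flat_u)
    axis_l = _off_similarity_direction(rng, flat_l)
    sd = spec.noise_sd
    if rho >= 1.0:
        a = sd  # any positive loading; residual on the axis removed below
    else:
        a = sd * np.sqrt(rho / (1.0 - rho))

    meta_u = _group_metadata(spec, "udm2")
    for m in meta_u:
        m.tooth_classes_present = frozenset({"udm2", "ldm2"})
    meta_l = [replace(m) for m in meta_u]

    shapes_u, shapes_l, lncs_u, lncs_l = [], [], [], []
    gi = 0
    for g in spec.groups:
        off_u = _resolve_offset(g.offset, rng, flat_u)
        off_l = _resolve_offset(g.offset, rng, flat_l)
        for _ in range(g.n):
            u = rng.standard_normal()
            nu = rng.normal(scale=sd, size=flat_u.size)
            nl = rng.normal(scale=sd, size=flat_l.size)
            if rho >= 1.0:
                # deterministic coupling: zero residual, so the paired
                # singular-warp scores correlate perfectly
                nu[:] = 0.0
                nl[:] = 0.0
            shapes_u.append(flat_u + off_u + a * u * axis_u + nu)
            shapes_l.append(flat_l + off_l + a * u * axis_l + nl)
            lncs_u.append(rng.normal(g.lncs_mean, g.lncs_sd))
            lncs_l.append(rng.normal(g.lncs_mean, g.lncs_sd))
            gi += 1
    ds_u = _emit(spec, rng, tmpl_u, shapes_u, meta_u, np.array(lncs_u))
    ds_l = _emit(spec, rng, tmpl_l, shapes_l, meta_l, np.array(lncs_l))
    return ds_u, ds_l
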