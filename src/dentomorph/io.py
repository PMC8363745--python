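"""Read and write landmark datasets and study metadata.

Three interchange dialects are supported:

``tps``
    the classic landmark file format; 3D blocks use ``LM3=<k>`` followed by
    one ``x y z`` line per point, then an ``ID=<specimen>`` record.
    ``SCALE=`` lines are accepted and ignored.
``wide_csv``
    one row per specimen, columns ``x0,y0,z0,x1,...`` plus identity columns.
``long_csv``
    one row per (specimen, point index) with a ``role`` column.

Coordinates are serialized with 17 significant digits so a write/read
round-trip is exact at double precision.
"""

from __future__ import annotations

import csv
import importlib.resources
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    TEMPLATES,
    LandmarkConfiguration,
    ShapeDataset,
    SpecimenMetadata,
    ValidationError,
    template_for,
)

__all__ = [
    "read_landmark_table",
    "write_landmark_table",
    "load_study_manifest",
    "bundled_manifest_path",
    "bundled_trait_scores_path",
    "ParseError",
]

DIALECTS = ("tps", "wide_csv", "long_csv")

_FMT = "%.17g"


class ParseError(ValueError):
    """A landmark or manifest file is malformed."""


def _placeholder_metadata(ids: list[str], tooth_class: str) -> list[SpecimenMetadata]:
    return [
        SpecimenMetadata(specimen_id=i, population="other", tooth_classes_present={tooth_class})
        for i in ids
    ]


def _infer_template(n_points: int) -> tuple[str, str]:
    hits = [key for key, tpl in TEMPLATES.items() if tpl.n_points == n_points]
    if len(hits) == 1:
        return hits[0]
    if not hits:
        raise ValidationError(f"no template has {n_points} points")
    raise ValidationError(
        f"point count {n_points} is ambiguous among templates {sorted(hits)}; "
        "pass tooth_class= and feature_set= explicitly"
    )


def read_landmark_table(
    path,
    dialect: str,
    tooth_class: str | None = None,
    feature_set: str | None = None,
    metadata: list[SpecimenMetadata] | None = None,
) -> ShapeDataset:
    """Read a landmark file into a template-validated :class:`ShapeDataset`.

    Point order is preserved exactly as stored. For the ``tps`` dialect the
    template is inferred from the block point count where unique (55 -> ldm2
    dentinal crown, 78 -> udm2); 24-point outline blocks are ambiguous and
    require explicit ``tooth_class``/``feature_set``. When no ``metadata``
    is supplied, placeholder records (population ``other``) are created.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "tps":
        configs, parsed_meta = _read_tps(path, tooth_class, feature_set), None
    elif dialect == "wide_csv":
        configs, parsed_meta = _read_wide(path, tooth_class, feature_set)
    else:
        configs, parsed_meta = _read_long(path, tooth_class, feature_set)

    if not configs:
        if tooth_class is None or feature_set is None:
            raise ValidationError(
                "empty landmark file: pass tooth_class= and feature_set= to type it"
            )
        return ShapeDataset([], metadata or [])
    if metadata is None:
        metadata = parsed_meta or _placeholder_metadata(
            [c.specimen_id for c in configs], configs[0].tooth_class
        )
    return ShapeDataset(configs, metadata)


def _read_tps(path: Path, tooth_class, feature_set) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    block_pts: list[list[float]] = []
    declared: int | None = None
    block_id: str | None = None
    block_line = 0

    def flush(lineno: int) -> None:
        nonlocal block_pts, declared, block_id, block_line
        if declared is None:
            return
        if len(block_pts) != declared:
            raise ParseError(
                f"{path}:{block_line}: block declares LM3={declared} but has "
                f"{len(block_pts)} point lines"
            )
        sid = block_id if block_id is not None else f"specimen_{len(configs) + 1}"
        if tooth_class is not None and feature_set is not None:
            tc, fs = tooth_class, feature_set
        else:
            tc, fs = _infer_template(declared)
        configs.append(
            LandmarkConfiguration(sid, tc, fs, np.array(block_pts, dtype=float))
        )
        block_pts, declared, block_id = [], None, None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = re.match(r"^LM3\s*=\s*(\d+)$", line, flags=re.IGNORECASE)
            if m:
                flush(lineno)
                declared = int(m.group(1))
                block_line = lineno
                continue
            if re.match(r"^ID\s*=", line, flags=re.IGNORECASE):
                if declared is None:
                    raise ParseError(f"{path}:{lineno}: ID= record outside an LM3 block")
                block_id = line.split("=", 1)[1].strip()
                continue
            if re.match(r"^SCALE\s*=", line, flags=re.IGNORECASE):
                continue  # accepted, ignored
            if declared is None:
                raise ParseError(f"{path}:{lineno}: coordinate line outside an LM3 block")
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                block_pts.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    flush(-1)
    return configs


_ID_COLS = ["specimen_id", "tooth_class", "feature_set", "side", "population", "sex"]


def _meta_from_row(row, tooth_class: str) -> SpecimenMetadata:
    return SpecimenMetadata(
        specimen_id=str(row["specimen_id"]),
        population=row.get("population", "other") or "other",
        sex=row.get("sex", "unknown") or "unknown",
        side=row.get("side", "left") or "left",
        tooth_classes_present={tooth_class},
    )


def _read_wide(path: Path, tooth_class, feature_set):
    try:
        df = pd.read_csv(path, dtype={"specimen_id": str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    if df.empty:
        return [], None
    for col in _ID_COLS[:3]:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    has_meta = "population" in df.columns
    configs, meta = [], []
    for _, row in df.iterrows():
        tc = tooth_class or row["tooth_class"]
        fs = feature_set or row["feature_set"]
        k = template_for(tc, fs).n_points
        cols = [f"{ax}{j}" for j in range(k) for ax in "xyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: specimen {row['specimen_id']}: missing {missing[0]}")
        pts = row[cols].to_numpy(dtype=float).reshape(k, 3)
        configs.append(
            LandmarkConfiguration(
                str(row["specimen_id"]), tc, fs, pts, side=row.get("side", "left")
            )
        )
        if has_meta:
            meta.append(_meta_from_row(row, tc))
    return configs, (meta if has_meta else None)


def _read_long(path: Path, tooth_class, feature_set):
    try:
        df = pd.read_csv(path, dtype={"specimen_id": str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from None
    if df.empty:
        return [], None
    needed = ["specimen_id", "tooth_class", "feature_set", "point_index", "role", "x", "y", "z"]
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    has_meta = "population" in df.columns
    configs, meta = [], []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        tc = tooth_class or grp["tooth_class"].iloc[0]
        fs = feature_set or grp["feature_set"].iloc[0]
        tpl = template_for(tc, fs)
        idx = grp["point_index"].to_numpy()
        if not np.array_equal(idx, np.arange(tpl.n_points)):
            raise ValidationError(
                f"{path}: specimen {sid}: point indices are not 0..{tpl.n_points - 1}"
            )
        roles = tuple(grp["role"])
        if roles != tpl.roles:
            raise ValidationError(f"{path}: specimen {sid}: role sequence violates template")
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        side = grp["side"].iloc[0] if "side" in grp.columns else "left"
        configs.append(LandmarkConfiguration(str(sid), tc, fs, pts, side=side))
        if has_meta:
            meta.append(_meta_from_row(grp.iloc[0], tc))
    return configs, (meta if has_meta else None)


def write_landmark_table(dataset: ShapeDataset, path, dialect: str) -> Path:
    """Write a dataset so that :func:`read_landmark_table` reproduces it exactly."""
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "tps":
        with open(path, "w") as fh:
            for c in dataset:
                fh.write(f"LM3={c.n_points}\n")
                for p in c.points:
                    fh.write(" ".join(_FMT % v for v in p) + "\n")
                fh.write(f"ID={c.specimen_id}\n")
    elif dialect == "wide_csv":
        k = dataset.template.n_points if len(dataset) else 0
        cols = _ID_COLS + [f"{ax}{j}" for j in range(k) for ax in "xyz"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for c in dataset:
                m = dataset.metadata[c.specimen_id]
                row = [c.specimen_id, c.tooth_class, c.feature_set, c.side,
                       m.population, m.sex]
                row += [_FMT % v for v in c.points.ravel()]
                w.writerow(row)
    else:  # long_csv: one row per (specimen, point index)
        cols = ["specimen_id", "tooth_class", "feature_set", "side", "population",
                "sex", "point_index", "role", "x", "y", "z"]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for c in dataset:
                m = dataset.metadata[c.specimen_id]
                for j, (p, role) in enumerate(zip(c.points, c.roles)):
                    w.writerow(
                        [c.specimen_id, c.tooth_class, c.feature_set, c.side,
                         m.population, m.sex, j, role]
                        + [_FMT % v for v in p]
                    )
    return path


_WEAR_RE = re.compile(r"^\s*(\d)")


def _parse_wear(raw) -> int | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"nan", "none", "-"}:
        return None
    m = _WEAR_RE.match(s)
    if not m:
        raise ValidationError(f"cannot parse wear stage {raw!r}")
    return int(m.group(1))  # ranges like "3-4" are stored as their lower bound


def load_study_manifest(path) -> list[SpecimenMetadata]:
    """Load specimen metadata from a manifest CSV.

    Required columns: ``id, population, sex, wear_u, wear_l``; an optional
    ``side`` column defaults to left. A tooth class is recorded as present
    when its wear column is non-empty. Sex values ``?`` and blanks map to
    ``unknown``; anything other than ``f``/``m``/``unknown`` is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    needed = ["id", "population", "sex", "wear_u", "wear_l"]
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        sex = row["sex"].strip()
        if sex in {"", "?"}:
            sex = "unknown"
        wu = _parse_wear(row["wear_u"])
        wl = _parse_wear(row["wear_l"])
        present = set()
        if str(row["wear_u"]).strip():
            present.add("udm2")
        if str(row["wear_l"]).strip():
            present.add("ldm2")
        records.append(
            SpecimenMetadata(
                specimen_id=row["id"],
                population=row["population"],
                sex=sex,
                wear_stage_upper=wu,
                wear_stage_lower=wl,
                side=row.get("side", "left") or "left",
                tooth_classes_present=present,
            )
        )
    ids = [r.specimen_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate specimen ids")
    return records


def bundled_manifest_path() -> Path:
    """Path to the bundled study-sample manifest fixture."""
    return Path(importlib.resources.files("dentomorph.data") / "study_manifest.csv")


def bundled_trait_scores_path() -> Path:
    """Path to the bundled per-specimen ASUDAS grade fixture."""
    return Path(importlib.resources.files("dentomorph.data") / "trait_grades.csv")
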