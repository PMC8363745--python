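"""Config-driven orchestration of the full crown-shape analysis.

For each requested tooth class the pipeline runs the four per-tooth
analyses - cervical outline, crown outline, EDJ, and dentinal crown (EDJ +
cervical outline) - superimposing outline sets by centering and scaling
only (they are digitized in a common cervical frame) and the EDJ-bearing
sets by full GPA preceded by bending-energy semilandmark sliding. It then
reports, in the layout of a comparative dm2 study's result tables:

* per-analysis PC variance percentages (first three PCs),
* two-block PLS of the upper/lower dentinal-crown dyads and of the
  cervical-vs-crown outline pairs within each tooth class,
* size statistics on lnCS (Mann-Whitney U Baka vs rest and Baka vs
  Europeans, Kruskal-Wallis across populations) plus lnCS boxplot data,
* the sex permutation test on Baka dentinal-crown shape,
* allometric regression of shape on lnCS,
* Baka and European Procrustes variances,
* ASUDAS trait prevalences and the hypocone Chi-square comparison.

Every output file carries the seed and a hash of the configuration in a
``#``-prefixed comment line, and a ``log.json`` records all settings and
one structured entry per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .datatypes import ShapeDataset
from .gpa import generalized_procrustes
from .inference import (
    chi_square_independence,
    kruskal_wallis,
    mann_whitney_u,
    permutation_mean_shape_test,
)
from .shape_stats import (
    group_shape_variance,
    pc_warp_endpoints,
    shape_pca,
    size_shape_regression,
    two_block_pls,
)
from .synthetic import CohortSpec, GroupSpec, default_study_groups, generate_cohort, generate_dyad_cohort
from .tps import slide_semilandmarks
from .traits import load_trait_scores, prevalence_table, trait_contingency

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("dentomorph.pipeline")

OUTLINE_SETS = ("cervical_outline", "crown_outline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All analysis-relevant settings of one pipeline run."""

    # input: either files per (tooth_class, feature_set), or synthetic
    inputs: dict = field(default_factory=dict)  # "tooth_class/feature_set" -> path
    dialect: str = "wide_csv"
    simulate: bool = True  # generate study-sized synthetic cohorts
    tooth_classes: list = field(default_factory=lambda: ["ldm2", "udm2"])
    feature_sets: list = field(
        default_factory=lambda: ["cervical_outline", "crown_outline", "edj_only", "dentinal_crown"]
    )
    noise_sd: float = 0.02
    dyad_n_baka: int = 13  # reference dyad sample: n = 20 of which 13 Baka
    dyad_n_other: int = 7
    dyad_rho: float = 0.8
    gpa_tol: float = 1e-10
    gpa_max_iter: int = 100
    sliding_iters: int = 3
    n_components: int = 3
    warp_scores: list = field(default_factory=lambda: [0.15, 0.07])
    n_perm: int = 10_000
    trait_scores: str | None = None  # CSV path; None -> bundled fixture
    seed: int = 0
    out_dir: str = "dentomorph_out"

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Read a plain-text (YAML-compatible ``key: value``) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"config: unknown keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stamp_and_write(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def _load_or_simulate(cfg: PipelineConfig, rng: np.random.Generator) -> dict:
    """Return {(tooth_class, feature_set): ShapeDataset}."""
    datasets: dict[tuple[str, str], ShapeDataset] = {}
    for tc in cfg.tooth_classes:
        for fs in cfg.feature_sets:
            key = f"{tc}/{fs}"
            if key in cfg.inputs:
                path = Path(cfg.inputs[key])
                if not path.exists():
                    raise PipelineError(f"input: missing file {path}")
                datasets[(tc, fs)] = dio.read_landmark_table(
                    path, cfg.dialect, tooth_class=tc, feature_set=fs
                )
            elif cfg.simulate:
                spec = CohortSpec(
                    tooth_class=tc,
                    feature_set=fs,
                    groups=default_study_groups(tc),
                    noise_sd=cfg.noise_sd,
                    rigid_transforms=fs not in OUTLINE_SETS,
                    seed=int(rng.integers(2**31)),
                )
                datasets[(tc, fs)] = generate_cohort(spec)
            else:
                raise PipelineError(f"input: no file for {key} and simulate is off")
    return datasets


def _superimpose(cfg: PipelineConfig, tc: str, fs: str, ds: ShapeDataset, stages: list):
    """Outline sets: scale-only normalization; EDJ sets: sliding + full GPA."""
    mode = "scale_only" if fs in OUTLINE_SETS else "full"
    if mode == "full":
        slid = slide_semilandmarks(ds, outer_iters=cfg.sliding_iters)
        ds = slid.dataset
        stages.append(
            {
                "stage": "slide",
                "analysis": f"{tc}/{fs}",
                "iterations": slid.iterations,
                "final_energy": slid.energy_history[-1] if slid.energy_history else None,
            }
        )
    res = generalized_procrustes(ds, mode=mode, tol=cfg.gpa_tol, max_iter=cfg.gpa_max_iter)
    stages.append(
        {
            "stage": "gpa",
            "analysis": f"{tc}/{fs}",
            "mode": mode,
            "n": res.n_specimens,
            "iterations": res.iterations,
            "converged": bool(res.converged),
        }
    )
    log.info("gpa %s/%s mode=%s n=%d iter=%d converged=%s",
             tc, fs, mode, res.n_specimens, res.iterations, res.converged)
    return res


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured analyses; returns the report bundle as a dict.

    Writes the tabular reports and ``log.json`` into ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    stages: list[dict] = []
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed}

    try:
        datasets = _load_or_simulate(cfg, rng)
    except Exception as exc:
        raise PipelineError(f"stage input: {exc}") from exc

    gpa_results = {}
    pca_rows = []
    lncs_rows = []
    for (tc, fs), ds in datasets.items():
        try:
            res = _superimpose(cfg, tc, fs, ds, stages)
        except Exception as exc:
            raise PipelineError(f"stage gpa ({tc}/{fs}): {exc}") from exc
        gpa_results[(tc, fs)] = res
        try:
            pca = shape_pca(res.tangent_coords, consensus=res.consensus)
        except Exception as exc:
            raise PipelineError(f"stage pca ({tc}/{fs}): {exc}") from exc
        top = pca.variance_fractions[: cfg.n_components]
        pca_rows.append(
            {
                "tooth_class": tc,
                "feature_set": fs,
                **{f"PC{i + 1}_pct": round(float(v), 1) for i, v in enumerate(top)},
                "total_pct": round(float(np.sum(top)), 1),
            }
        )
        if fs == "dentinal_crown" and cfg.warp_scores:
            warp_rows = []
            for pc in range(min(2, pca.n_components)):
                for score in cfg.warp_scores:
                    minus, plus, _ = pc_warp_endpoints(
                        pca, pc, abs(float(score)), range_check=False
                    )
                    for sgn, ep in ((-1.0, minus), (1.0, plus)):
                        for j, (x, y, z) in enumerate(ep):
                            warp_rows.append(
                                {"tooth_class": tc, "pc": pc + 1,
                                 "score": sgn * abs(float(score)),
                                 "point_index": j, "x": x, "y": y, "z": z}
                            )
            _stamp_and_write(
                pd.DataFrame(warp_rows), out / f"warps_{tc}.csv", cfg
            )
        for sid, lncs in zip(ds.ids, res.ln_centroid_sizes):
            lncs_rows.append(
                {
                    "tooth_class": tc,
                    "feature_set": fs,
                    "specimen_id": sid,
                    "population": ds.metadata[sid].population,
                    "sex": ds.metadata[sid].sex,
                    "lnCS": float(lncs),
                }
            )
        stages.append({"stage": "pca", "analysis": f"{tc}/{fs}",
                       "pc1_pct": float(pca.variance_fractions[0])})
    pc_table = pd.DataFrame(pca_rows)
    _stamp_and_write(pc_table, out / "pc_variance.csv", cfg)
    lncs_table = pd.DataFrame(lncs_rows)
    _stamp_and_write(lncs_table, out / "lncs.csv", cfg)
    report["pc_variance"] = pc_table.to_dict("records")

    # ---- two-block PLS ---------------------------------------------------
    pls_rows = []
    if cfg.simulate and "dentinal_crown" in cfg.feature_sets and len(cfg.tooth_classes) == 2:
        spec = CohortSpec(
            feature_set="dentinal_crown",
            groups=[GroupSpec("Baka", cfg.dyad_n_baka), GroupSpec("European", cfg.dyad_n_other)],
            noise_sd=cfg.noise_sd,
            dyad_rho=cfg.dyad_rho,
            seed=int(rng.integers(2**31)),
        )
        du, dl = generate_dyad_cohort(spec)
        ru = generalized_procrustes(du, tol=cfg.gpa_tol)
        rl = generalized_procrustes(dl, tol=cfg.gpa_tol)
        pls = two_block_pls(ru.tangent_coords, rl.tangent_coords,
                            n_perm=cfg.n_perm, seed=int(rng.integers(2**31)))
        pls_rows.append(
            {
                "block_x": "udm2 dentinal_crown",
                "block_y": "ldm2 dentinal_crown",
                "n": len(du),
                "r1": round(float(pls.pairwise_correlations[0]), 2),
                "pct_total_covariance_sw1": round(float(pls.pct_total_squared_covariance[0])),
                "rv": round(float(pls.rv_coefficient), 2),
                "p_perm": pls.p_value,
            }
        )
        stages.append({"stage": "pls", "analysis": "udm2-vs-ldm2 dentinal_crown",
                       "r1": float(pls.pairwise_correlations[0])})
    for tc in cfg.tooth_classes:
        pair = [(tc, "cervical_outline"), (tc, "crown_outline")]
        if all(p in gpa_results for p in pair):
            a, b = (gpa_results[p] for p in pair)
            ids_a = a.dataset.ids if a.dataset else None
            ids_b = b.dataset.ids if b.dataset else None
            if ids_a != ids_b:
                stages.append({"stage": "pls", "analysis": f"{tc} outlines",
                               "skipped": "blocks are not the same specimens"})
                continue
            pls = two_block_pls(a.tangent_coords, b.tangent_coords,
                                n_perm=cfg.n_perm, seed=int(rng.integers(2**31)))
            pls_rows.append(
                {
                    "block_x": f"{tc} cervical_outline",
                    "block_y": f"{tc} crown_outline",
                    "n": a.n_specimens,
                    "r1": round(float(pls.pairwise_correlations[0]), 2),
                    "pct_total_covariance_sw1": round(float(pls.pct_total_squared_covariance[0])),
                    "rv": round(float(pls.rv_coefficient), 2),
                    "p_perm": pls.p_value,
                }
            )
            stages.append({"stage": "pls", "analysis": f"{tc} outlines",
                           "r1": float(pls.pairwise_correlations[0])})
    if pls_rows:
        pls_table = pd.DataFrame(pls_rows)
        _stamp_and_write(pls_table, out / "pls.csv", cfg)
        report["pls"] = pls_table.to_dict("records")

    # ---- size tests (lnCS) ----------------------------------------------
    size_rows = []
    for (tc, fs), res in gpa_results.items():
        ds = datasets[(tc, fs)]
        pops = np.array(ds.populations())
        lncs = res.ln_centroid_sizes
        baka = lncs[pops == "Baka"]
        if len(baka) == 0 or len(baka) == len(lncs):
            continue
        u1, z1, p1 = mann_whitney_u(baka, lncs[pops != "Baka"])
        row = {
            "tooth_class": tc, "feature_set": fs,
            "n_baka": len(baka), "n_rest": int(len(lncs) - len(baka)),
            "Z_baka_vs_rest": round(z1, 3), "p_baka_vs_rest": round(p1, 3),
        }
        eur = lncs[pops == "European"]
        if len(eur):
            u2, z2, p2 = mann_whitney_u(baka, eur)
            row.update({"n_european": len(eur),
                        "Z_baka_vs_european": round(z2, 3),
                        "p_baka_vs_european": round(p2, 3)})
        groups = [lncs[pops == p] for p in dict.fromkeys(pops.tolist()) if (pops == p).sum() >= 2]
        if len(groups) >= 2:
            h, df_kw, p_kw = kruskal_wallis(groups)
            row.update({"kruskal_H": round(h, 2), "kruskal_df": df_kw,
                        "kruskal_p": round(p_kw, 3)})
        size_rows.append(row)
        stages.append({"stage": "size_tests", "analysis": f"{tc}/{fs}"})
    if size_rows:
        size_table = pd.DataFrame(size_rows)
        _stamp_and_write(size_table, out / "size_tests.csv", cfg)
        report["size_tests"] = size_table.to_dict("records")

    # ---- sex permutation test, regression, group variances ---------------
    extra_rows = []
    for tc in cfg.tooth_classes:
        key = (tc, "dentinal_crown")
        if key not in gpa_results:
            continue
        res = gpa_results[key]
        ds = datasets[key]
        pops = np.array(ds.populations())
        sexes = np.array(ds.sexes())
        entry = {"tooth_class": tc}
        baka_sexed = (pops == "Baka") & np.isin(sexes, ["f", "m"])
        if baka_sexed.sum() >= 4 and len(set(sexes[baka_sexed])) == 2:
            pt = permutation_mean_shape_test(
                res.tangent_coords[baka_sexed], sexes[baka_sexed],
                n_perm=cfg.n_perm, seed=int(rng.integers(2**31)),
            )
            entry.update({"sex_perm_stat": round(pt.observed_statistic, 5),
                          "sex_perm_p": round(pt.p_value, 3)})
        reg = size_shape_regression(res.tangent_coords, res.ln_centroid_sizes)
        entry["allometry_pct_explained"] = round(reg.pct_variance_explained, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gv = group_shape_variance(res.tangent_coords, pops)
        for pop in ("Baka", "European"):
            if pop in gv:
                entry[f"proc_variance_{pop}"] = round(gv[pop], 4)
        extra_rows.append(entry)
        stages.append({"stage": "shape_tests", "analysis": f"{tc}/dentinal_crown"})
    if extra_rows:
        extra_table = pd.DataFrame(extra_rows)
        _stamp_and_write(extra_table, out / "shape_tests.csv", cfg)
        report["shape_tests"] = extra_table.to_dict("records")

    # ---- traits ----------------------------------------------------------
    trait_path = cfg.trait_scores or dio.bundled_trait_scores_path()
    try:
        scores = load_trait_scores(trait_path)
        prev = prevalence_table(scores)
        _stamp_and_write(prev, out / "prevalence.csv", cfg)
        chi2, df_chi, p_chi = chi_square_independence(trait_contingency(scores, "hypocone"))
        report["hypocone_chi2"] = {"chi2": round(chi2, 1), "df": df_chi, "p": round(p_chi, 3)}
        stages.append({"stage": "traits", "chi2": round(chi2, 2)})
    except Exception as exc:
        raise PipelineError(f"stage traits: {exc}") from exc

    report["stages"] = stages
    with open(out / "log.json", "w") as fh:
        json.dump({"config": asdict(cfg), **report}, fh, indent=2, default=str)
    log.info("pipeline complete: %s", out)
    return report
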