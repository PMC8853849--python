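"""Configuration, orchestration and table validation for full pipeline runs.

A :class:`RunConfig` (YAML-serializable) fixes every stage's parameters and
seeds; :func:`run_all` executes simulate -> ICA -> EFA -> associate into a
run directory, writing TSV tables plus a JSON manifest with the config hash,
all seeds and per-file checksums, so a run is reproducible bit-for-bit.
User-provided tables can replace the simulation stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ica as ica_mod
from . import efa as efa_mod
from . import mapping as mapping_mod
from .synthetic import CohortConfig, SyntheticCohort, make_cohort, read_cohort, write_cohort

__all__ = ["RunConfig", "run_all", "validate_tables"]

log = logging.getLogger("dimbrain")


@dataclass
class RunConfig:
    """All parameters and seeds of a full pipeline run."""

    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides
    input_dir: str | None = None  # user tables replace the simulate stage
    # ICA stage
    ica_k_min: int = 2
    ica_k_max: int = 10
    ica_runs: int = 100
    ica_tol: float = 1e-5
    ica_max_iter: int = 500
    loso_runs: int = 10
    run_loso: bool = False
    # EFA stage
    efa_max_factors: int = 10
    efa_epsilon: float = 0.01
    efa_starts: int = 30
    efa_parallel_sims: int = 100
    # KRLS / association stage
    krls_n_cap: int = 2500
    assoc_reps: int = 100
    assoc_frac: float = 0.5
    assoc_alpha: float = 0.05
    motion_modalities: tuple = ("dmri", "rsfmri")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "motion_modalities" in data:
            data["motion_modalities"] = tuple(data["motion_modalities"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and return the manifest.

    Stages: simulate (or load user tables) -> ICA model-order selection ->
    polychoric EFA -> per-modality association mapping for both
    decompositions.  Any stage failure halts with the stage name while
    earlier outputs stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": {},
        "files": {},
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("simulate", "ica", "efa", "associate"), rng.integers(0, 2**31 - 1, size=4)
    )}
    manifest["stage_seeds"] = stage_seeds
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if config.input_dir:
            data = read_cohort(config.input_dir)
            ratings, covariates = data["ratings"], data["covariates"]
            sites, features = data["sites"], data["features"]
            manifest["stages"][stage] = {"provenance": "external", "dir": config.input_dir}
        else:
            cohort = make_cohort(CohortConfig(**{**config.cohort, "seed": stage_seeds[stage]}))
            write_cohort(cohort, outdir / "cohort")
            ratings, covariates = cohort.ratings, cohort.covariates
            sites, features = cohort.sites, cohort.features
            manifest["stages"][stage] = {
                "provenance": "simulated",
                "n_subjects": cohort.n_subjects,
            }
        manifest["stages"][stage]["seconds"] = round(time.perf_counter() - t0, 2)
        log.info("stage %s done (%.1fs)", stage, time.perf_counter() - t0)

        stage = "ica"
        t0 = time.perf_counter()
        curve, ica_sol = ica_mod.select_model_order(
            ratings,
            k_range=range(config.ica_k_min, config.ica_k_max + 1),
            n_runs=config.ica_runs,
            seed=stage_seeds[stage],
            tol=config.ica_tol,
            max_iter=config.ica_max_iter,
        )
        _write_tsv(ica_sol.loadings, outdir / "ica_loadings.tsv")
        _write_tsv(ica_sol.scores, outdir / "ica_scores.tsv")
        curve_df = pd.DataFrame(
            {"k": curve.k_range, "stability": [curve.stability_by_k[k] for k in curve.k_range]}
        ).set_index("k")
        _write_tsv(curve_df, outdir / "stability_curve.tsv")
        manifest["stages"][stage] = {
            "selected_k": curve.selected_k,
            "overall_stability": ica_sol.overall_stability,
            "converged_runs": ica_sol.converged_runs,
            "seconds": round(time.perf_counter() - t0, 2),
        }
        if config.run_loso:
            report = ica_mod.leave_one_site_out_stability(
                ratings, sites, k=curve.selected_k, n_runs=config.loso_runs,
                seed=stage_seeds[stage] + 1, full_solution=ica_sol,
            )
            site_df = pd.DataFrame(
                {"site": list(report.per_site), "stability": list(report.per_site.values())}
            ).set_index("site")
            _write_tsv(site_df, outdir / "site_stability.tsv")
            manifest["stages"][stage]["loso_range"] = report.range
        log.info("stage ica done: k=%d stability=%.3f", curve.selected_k,
                 ica_sol.overall_stability)

        stage = "efa"
        t0 = time.perf_counter()
        efa_sol = efa_mod.run_efa(
            ratings,
            max_factors=config.efa_max_factors,
            epsilon=config.efa_epsilon,
            n_starts=config.efa_starts,
            n_sims=config.efa_parallel_sims,
            seed=stage_seeds[stage],
        )
        _write_tsv(efa_sol.polychoric.matrix, outdir / "polychoric.tsv")
        _write_tsv(efa_sol.loadings_rotated, outdir / "efa_loadings.tsv")
        _write_tsv(pd.DataFrame(efa_sol.phi), outdir / "efa_phi.tsv")
        _write_tsv(efa_sol.scores, outdir / "efa_scores.tsv")
        manifest["stages"][stage] = {
            "retained_by_parallel": efa_sol.retained_by_parallel,
            "m": efa_sol.m,
            "criterion": efa_sol.criterion_value,
            "smoothing_applied": efa_sol.polychoric.smoothing_applied,
            "seconds": round(time.perf_counter() - t0, 2),
        }
        log.info("stage efa done: m=%d", efa_sol.m)

        stage = "associate"
        t0 = time.perf_counter()
        suite = mapping_mod.run_comparison_suite(
            ica_sol.scores,
            efa_sol.scores,
            {"features": features, "covariates": covariates},
            n_reps=config.assoc_reps,
            frac=config.assoc_frac,
            alpha=config.assoc_alpha,
            seed=stage_seeds[stage],
            motion_modalities=tuple(config.motion_modalities),
            n_cap=config.krls_n_cap,
        )
        rows = []
        for (method, dim, modality), smap in suite.stability.items():
            t = smap.table.reset_index()
            t.insert(0, "modality", modality)
            t.insert(0, "dimension", dim)
            t.insert(0, "method", method)
            rows.append(t)
        if rows:
            pd.concat(rows).to_csv(outdir / "stability_map.tsv", sep="\t", index=False)
        sim_rows = []
        for modality, mat in suite.similarity.items():
            m2 = mat.copy()
            m2.insert(0, "modality", modality)
            sim_rows.append(m2)
        pd.concat(sim_rows).to_csv(outdir / "similarity_matrices.tsv", sep="\t")
        _write_tsv(suite.score_correlation, outdir / "score_correlation.tsv")
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 2)}
    except Exception as e:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    for f in sorted(outdir.rglob("*.tsv")):
        manifest["files"][str(f.relative_to(outdir))] = _checksum(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def validate_tables(directory: str | Path) -> dict:
    """Schema/alignment checks on a cohort directory; report-only.

    Checks: required tables present, subject_id alignment across tables,
    ordinal ratings restricted to {0,1,2}, and missing values.  Returns a
    machine-readable report with an overall ``passed`` flag.
    """
    directory = Path(directory)
    report: dict = {"directory": str(directory), "checks": [], "passed": True}

    def check(name: str, ok: bool, detail: str = "") -> None:
        report["checks"].append({"check": name, "passed": bool(ok), "detail": detail})
        if not ok:
            report["passed"] = False

    ratings_path = directory / "ratings.tsv"
    cov_path = directory / "covariates.tsv"
    check("ratings_present", ratings_path.exists())
    check("covariates_present", cov_path.exists())
    if not report["passed"]:
        return report
    ratings = pd.read_csv(ratings_path, sep="\t", index_col=0)
    cov = pd.read_csv(cov_path, sep="\t", index_col=0)
    check("ratings_index_named", ratings.index.name == "subject_id",
          f"index name {ratings.index.name!r}")
    vals = ratings.stack(future_stack=True).dropna().unique()
    bad = sorted(set(vals) - {0, 1, 2})
    if bad:
        bad_items = [
            c for c in ratings.columns if not ratings[c].dropna().isin([0, 1, 2]).all()
        ]
        check("ordinal_range", False, f"values outside {{0,1,2}} in items {bad_items[:5]}")
    else:
        check("ordinal_range", True)
    check("no_missing_ratings", not ratings.isna().any().any())
    check("alignment_covariates", ratings.index.equals(cov.index),
          "subject order differs between ratings and covariates")
    check("site_column", "site" in cov.columns)
    for f in sorted(directory.glob("features_*.tsv")):
        feats = pd.read_csv(f, sep="\t", index_col=0)
        check(f"alignment_{f.stem}", ratings.index.equals(feats.index),
              "subject order differs from ratings")
        check(f"no_missing_{f.stem}", not feats.isna().any().any())
    return report
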