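"""End-to-end study orchestration.

One call runs the whole comparison: generate a synthetic cohort, build the
reduced-detail dataset variants, rigidly register each variant, establish
particle correspondence, fit the PCA shape model, compute the evaluation
curves, cluster, and score against the ground-truth class labels.  The
headline comparison is the AMI of the full-detail (R=1, "trabeculated")
dataset versus the 4x-reduced ("simplified") dataset.

Everything is deterministic in the master seed; all result artifacts
(CSV/JSON) are written with fixed formatting so identical configurations
produce byte-identical outputs.  Stage timings go to a separate
``timings.jsonl`` which carries the only non-deterministic content.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering_eval import ClusteringResult, cluster_and_score, retain_pcs
from .mesh_core import DEFAULT_TARGET_VOLUME, write_mesh
from .model_evaluation import evaluation_suite
from .registration import multiview_register
from .shape_model import establish_correspondence, fit_pca
from .simplification import ReductionLevel, simplify_dataset
from .synthetic_anatomy import CohortSpec, draw_cohort_specs, generate_shape

_FLOAT_FMT = "%.12g"


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    factors: tuple = (1, 2, 4, 8, 16)
    n_particles: int = 1024
    n_init_particles: int = 128
    n_modes_max: int | None = None
    specificity_draws: int = 1000
    variance_threshold: float = 0.85
    k_min: int = 2
    k_max: int = 10
    master_seed: int = 0
    register: bool = True
    registration_rounds: int = 2
    icp_samples: int = 2000
    icp_max_iter: int = 60
    save_meshes: bool = False
    target_volume: float = DEFAULT_TARGET_VOLUME

    def __post_init__(self) -> None:
        self.factors = tuple(sorted(set(int(f) for f in self.factors)))
        if 1 not in self.factors:
            raise ValueError("the reference level (factor 1) is required")
        self.cohort.validate()

    @classmethod
    def desk_scale(cls, **overrides) -> "ExperimentConfig":
        """CI-friendly defaults: a 40-shape cohort, 256 particles."""
        cohort = overrides.pop("cohort", CohortSpec(n_shapes=40,
                                                    mesh_resolution=0.9))
        defaults = dict(cohort=cohort, n_particles=256, n_init_particles=64,
                        specificity_draws=500)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def full_scale(cls, **overrides) -> "ExperimentConfig":
        """The full-scale study design: 85 shapes, 1024 particles from 128."""
        cohort = overrides.pop("cohort", CohortSpec(n_shapes=85))
        defaults = dict(cohort=cohort, n_particles=1024, n_init_particles=128)
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["factors"] = list(self.factors)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortSpec(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)

    def to_yaml(self, path: str | Path) -> None:
        out = dataclasses.asdict(self)
        out["factors"] = list(self.factors)
        Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def _seed_from(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None) -> dict:
    """Run the full pipeline; returns (and optionally writes) the report.

    The report maps each reduction factor to its evaluation summary and
    clustering outcome, plus a headline AMI comparison between the
    reference (R=1) and the 4x-reduced dataset when present.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: list[dict] = []

    def _stage(name):
        t0 = time.perf_counter()

        def done(**extra):
            timings.append({"stage": name,
                            "seconds": round(time.perf_counter() - t0, 3),
                            **extra})
        return done

    ss = np.random.SeedSequence((config.master_seed, 0xe9b))
    s_cohort, s_simplify, s_register, s_corr, s_eval = ss.spawn(5)

    # --- cohort ------------------------------------------------------------
    done = _stage("generate")
    cohort_spec = dataclasses.replace(config.cohort,
                                      master_seed=_seed_from(s_cohort))
    specs = draw_cohort_specs(cohort_spec)
    meshes = [generate_shape(s) for s in specs]
    labels = np.array([s.label for s in specs])
    shape_ids = [f"shape_{i:03d}" for i in range(len(meshes))]
    done(n_shapes=len(meshes))

    if out is not None:
        pd.DataFrame({"shape_id": shape_ids, "label": labels}).to_csv(
            out / "labels.csv", index=False)
        (out / "cohort_manifest.json").write_text(json.dumps(
            [dataclasses.asdict(s) for s in specs], indent=2, sort_keys=True))

    report: dict = {
        "n_shapes": len(meshes),
        "factors": list(config.factors),
        "levels": {},
    }

    corrs = {}
    models = {}
    simplify_seeds = s_simplify.spawn(len(config.factors))
    register_seeds = s_register.spawn(len(config.factors))
    corr_seeds = s_corr.spawn(len(config.factors))

    for idx, factor in enumerate(config.factors):
        level = ReductionLevel.from_factor(factor)

        done = _stage(f"simplify_r{factor}")
        dataset = simplify_dataset(meshes, level,
                                   seed=_seed_from(simplify_seeds[idx]),
                                   target_volume=config.target_volume)
        done(factor=factor)

        if config.register and len(dataset) > 1:
            done = _stage(f"register_r{factor}")
            transforms, reg_report = multiview_register(
                dataset, reference_index=0,
                max_rounds=config.registration_rounds,
                n_samples=config.icp_samples,
                max_iter=config.icp_max_iter,
                seed=_seed_from(register_seeds[idx]))
            for mesh, t in zip(dataset, transforms):
                mesh.vertices = t.apply(mesh.vertices)
            done(factor=factor, converged=reg_report.converged,
                 min_fraction=round(reg_report.fraction, 4),
                 rounds=reg_report.rounds)

        if out is not None and config.save_meshes:
            mesh_dir = out / f"meshes_r{factor}"
            mesh_dir.mkdir(exist_ok=True)
            for sid, mesh in zip(shape_ids, dataset):
                write_mesh(mesh, mesh_dir / f"{sid}.ply")

        done = _stage(f"correspond_r{factor}")
        corr = establish_correspondence(
            dataset, n_particles=config.n_particles,
            n_init=config.n_init_particles,
            seed=_seed_from(corr_seeds[idx]), shape_ids=shape_ids)
        corrs[factor] = corr
        models[factor] = fit_pca(corr)
        done(factor=factor)

    # --- evaluation curves --------------------------------------------------
    done = _stage("evaluate")
    curves, diffs = evaluation_suite(
        corrs, n_modes_max=config.n_modes_max,
        n_draws=config.specificity_draws, seed=_seed_from(s_eval))
    done()

    if out is not None:
        for factor, cur in curves.items():
            cur.to_frame().to_csv(out / f"curves_r{factor}.csv", index=False,
                                  float_format=_FLOAT_FMT)
        diffs.to_csv(out / "diff_vs_reference.csv", index=False,
                     float_format=_FLOAT_FMT)

    # --- clustering ----------------------------------------------------------
    reference_n_modes = retain_pcs(models[1], config.variance_threshold)
    clusterings: dict[int, ClusteringResult] = {}
    for factor in config.factors:
        done = _stage(f"cluster_r{factor}")
        result = cluster_and_score(
            models[factor], labels,
            reference_n_modes=reference_n_modes,
            threshold=config.variance_threshold,
            k_min=config.k_min,
            k_max=min(config.k_max, len(meshes) - 1))
        clusterings[factor] = result
        done(factor=factor)
        if out is not None:
            result.save(out / f"clustering_r{factor}.json")
            pd.DataFrame(result.linkage_record,
                         columns=["id_a", "id_b", "height", "size"]).to_csv(
                out / f"linkage_r{factor}.csv", index=False,
                float_format=_FLOAT_FMT)

    for factor in config.factors:
        cur = curves[factor]
        res = clusterings[factor]
        nm = min(reference_n_modes, len(cur.n_modes)) - 1
        report["levels"][str(factor)] = {
            "n_modes_used": res.n_modes_used,
            "variance_fraction": res.variance_fraction,
            "compactness_norm_at_n_modes": float(cur.compactness_norm[nm]),
            "generalisation_mm_at_n_modes": float(cur.generalisation_mm[nm]),
            "specificity_mm_at_n_modes": float(cur.specificity_mm[nm]),
            "k": res.k,
            "silhouette": res.silhouette,
            "ami": res.ami_score,
            "cluster_sizes": res.cluster_sizes,
            "stable_across_thresholds": res.stable_across_thresholds,
        }

    report["reference_n_modes"] = int(reference_n_modes)
    report["headline"] = {
        "ami_trabeculated": clusterings[1].ami_score,
        "ami_simplified_4x": clusterings[4].ami_score if 4 in clusterings else None,
    }

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        with open(out / "timings.jsonl", "w") as fh:
            for row in timings:
                fh.write(json.dumps(row) + "\n")
    report["timings"] = timings
    return report


def report_summary(report: dict) -> str:
    """Per-level metric table, one row per reduction factor."""
    rows = []
    for factor, lvl in sorted(report.get("levels", {}).items(),
                              key=lambda kv: int(kv[0])):
        rows.append({
            "factor": int(factor),
            "n_modes": lvl.get("n_modes_used"),
            "compactness": lvl.get("compactness_norm_at_n_modes"),
            "generalisation_mm": lvl.get("generalisation_mm_at_n_modes"),
            "specificity_mm": lvl.get("specificity_mm_at_n_modes"),
            "k": lvl.get("k"),
            "silhouette": lvl.get("silhouette"),
            "ami": lvl.get("ami"),
        })
    if not rows:
        return "(no levels)"
    frame = pd.DataFrame(rows)
    return frame.to_string(index=False, float_format=lambda x: f"{x:.4f}")
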