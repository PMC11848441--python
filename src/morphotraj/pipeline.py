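"""End-to-end orchestration: simulate -> screen -> atlas -> project -> stats.

One flat :class:`PipelineConfig` (YAML round-trippable, explicit seeds per
stage) drives every module, so a run is reproducible from its manifest.
The run directory layout is fixed::

    out/
      simulate/   feature tables + ground truth (synthetic runs)
      profiles/   normalized well profiles, distances, hit table
      models/     frozen embedding, cluster, doublet and trajectory models
      states/     per-cell trajectory states for atlas and screen cells
      reports/    assay QC, composition, chi-square and pseudotime tables
      manifest.json

Stages can be run individually; a stage that needs a frozen model loads it
from ``models/`` and fails with the missing artifact's name if a previous
stage has not produced it.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import yaml

from .io_qc import FeatureTable, QcRule, aggregate_profiles, apply_cell_qc, apply_image_qc
from .perturb import chisq_vs_reference, compare_pseudotime, summarize_composition, LINEAGE_LABELS
from .preprocess import (
    anchor_standardize,
    classify_and_remove,
    downsample_per_group,
    fit_embedding,
    train_doublet_model,
)
from .profiling import (
    assay_qc,
    call_hits,
    distance_to_control,
    robust_z_normalize,
    select_features,
)
from .simulate import (
    AtlasSimConfig,
    CompoundEffect,
    PlateSimConfig,
    Treatment,
    simulate_atlas,
    simulate_plate,
)
from .trajectory import (
    PrincipalTrajectory,
    cluster_cells,
    infer_lineages,
    select_backbone,
)

__all__ = ["PipelineConfig", "run_pipeline", "default_treatments"]


def _pkg_version() -> str:
    from morphotraj import __version__

    return __version__

MODES = ("simulate", "screen", "atlas", "project", "stats", "all")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the study's constants as defaults."""

    # synthetic atlas
    n_timepoints: int = 20
    cells_per_timepoint: int = 500
    n_features: int = 788
    t_branch_true: float = 3.0
    p_hep: float = 0.5
    noise_sd: float = 0.8
    # synthetic screen plate
    cells_per_well: int = 100
    n_control_wells_per_class: int = 16
    images_per_well: int = 4
    doublet_rate: float = 0.03
    qc_fail_rate: float = 0.02
    # image / cell QC
    min_cells_per_image: int = 5
    # well profiling
    normalization_mode: str = "all_samples"
    corr_threshold: float = 0.9
    theta_p: float = 0.9
    theta_e: float = 1.7
    # single-cell prep
    cap: int = 15000
    n_pcs: int = 10
    n_neighbors: int = 15
    min_dist: float = 0.1
    # trajectory
    k_min: int = 2
    k_max: int = 10
    span: float = 0.1
    smoother_df: float = 5.0
    n_curve_points: int = 200
    t_b_override: float | None = None
    # statistics
    reference_role: str = "differentiated_control"
    # seeds (one per stochastic stage)
    seed_sim: int = 1
    seed_downsample: int = 5
    seed_doublet: int = 3
    seed_embed: int = 7
    seed_cluster: int = 7
    seed_qc: int = 0

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def atlas_sim_config(self) -> AtlasSimConfig:
        return AtlasSimConfig(
            n_timepoints=self.n_timepoints,
            cells_per_timepoint=self.cells_per_timepoint,
            n_features=self.n_features,
            t_branch_true=self.t_branch_true,
            p_hep=self.p_hep,
            noise_sd=self.noise_sd,
            seed=self.seed_sim,
        )

    def plate_sim_config(self) -> PlateSimConfig:
        return PlateSimConfig(
            cells_per_well=self.cells_per_well,
            n_control_wells_per_class=self.n_control_wells_per_class,
            images_per_well=self.images_per_well,
            treatments=default_treatments(),
            doublet_rate=self.doublet_rate,
            qc_fail_rate=self.qc_fail_rate,
            seed=self.seed_sim + 1,
        )


def default_treatments(dose: float = 10.0, n_wells: int = 3) -> tuple[Treatment, ...]:
    """The bundled synthetic compound panel.

    ``mimic`` drives differentiation exactly as fast as the supplement (a
    true hit), ``null`` is inert, ``enricher`` shifts hepatocyte commitment
    to 0.8 (a fate-shifting modulator) and ``accelerator`` speeds
    differentiation past the control without changing fate ratios.
    """
    return (
        Treatment("mimic", dose, CompoundEffect(accel=1.0, ec50=0.01), n_wells),
        Treatment("null", dose, CompoundEffect(), n_wells),
        Treatment("enricher", dose, CompoundEffect(delta_p_hep=0.3, accel=1.0, ec50=0.01), n_wells),
        Treatment("accelerator", dose, CompoundEffect(accel=1.5, ec50=0.01), n_wells),
    )


def _need(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact for this mode: {what} expected at {path}; "
            "run the producing stage first"
        )
    return path


def run_pipeline(config: PipelineConfig, out_dir: str | Path, mode: str = "all") -> dict:
    """Run the requested stage(s); returns in-memory results keyed by stage."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    out = Path(out_dir)
    for sub in ("simulate", "profiles", "models", "states", "reports"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    results: dict = {}
    timings: dict[str, float] = {}

    def stage(name):
        return mode in (name, "all")

    if stage("simulate"):
        t0 = time.perf_counter()
        atlas_tab, atlas_truth = simulate_atlas(config.atlas_sim_config())
        plate_tab, plate_truth = simulate_plate(config.atlas_sim_config(), config.plate_sim_config())
        atlas_tab.write(out / "simulate" / "atlas_cells.tsv")
        atlas_truth.write(out / "simulate" / "atlas_truth.tsv")
        plate_tab.write(out / "simulate" / "plate_cells.tsv")
        plate_truth.write(out / "simulate" / "plate_truth.tsv")
        plate_truth.images.to_csv(out / "simulate" / "plate_truth_images.tsv", sep="\t", index=False)
        plate_truth.wells.to_csv(out / "simulate" / "plate_truth_wells.tsv", sep="\t", index=False)
        joblib.dump(
            {"atlas": (atlas_tab, atlas_truth), "plate": (plate_tab, plate_truth)},
            out / "simulate" / "tables.joblib",
        )
        results["simulate"] = {
            "atlas": (atlas_tab, atlas_truth),
            "plate": (plate_tab, plate_truth),
        }
        timings["simulate"] = time.perf_counter() - t0

    def load_sim():
        if "simulate" in results:
            return results["simulate"]
        blob = joblib.load(_need(out / "simulate" / "tables.joblib", "synthetic tables"))
        return blob

    if stage("screen"):
        t0 = time.perf_counter()
        sim = load_sim()
        plate_tab, plate_truth = sim["plate"]
        rules = [QcRule("n_cells", lower=config.min_cells_per_image, scope="image")]
        qc_tab, removed_images = apply_image_qc(plate_tab, rules)
        qc_tab, removed_cells = apply_cell_qc(qc_tab)
        profiles = aggregate_profiles(qc_tab, level="well")
        normalized, norm_model = robust_z_normalize(profiles, config.normalization_mode)
        selection = select_features(normalized, config.corr_threshold)
        distances = distance_to_control(normalized, selection, config.reference_role)
        hits = call_hits(distances, config.theta_p, config.theta_e)
        qc_report = assay_qc(distances, normalized, selection, seed=config.seed_qc)
        normalized.to_csv(out / "profiles" / "well_profiles_normalized.tsv", sep="\t", index=False)
        hits.to_csv(out / "profiles" / "hit_table.tsv", sep="\t", index=False)
        qc_report.classifier_report.to_csv(out / "reports" / "control_classifier.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"plate": list(qc_report.zprime_per_plate), "zprime": list(qc_report.zprime_per_plate.values())}
        ).to_csv(out / "reports" / "zprime.tsv", sep="\t", index=False)
        with open(out / "reports" / "screen_log.txt", "w") as fh:
            fh.write(f"images removed by QC: {len(removed_images)}\n")
            fh.write(f"cells removed by area QC: {len(removed_cells)}\n")
            fh.write(f"features retained: {len(selection.retained)}\n")
            fh.write(f"hits: {int(hits['is_hit'].sum())} / {len(hits)} wells\n")
            fh.write(f"CV% of d_P per class: {qc_report.cv_percent}\n")
        results["screen"] = {
            "profiles": normalized,
            "selection": selection,
            "distances": distances,
            "hits": hits,
            "assay_qc": qc_report,
            "removed_images": removed_images,
            "removed_cells": removed_cells,
        }
        timings["screen"] = time.perf_counter() - t0

    if stage("atlas"):
        t0 = time.perf_counter()
        sim = load_sim()
        atlas_tab, atlas_truth = sim["atlas"]
        plate_tab, plate_truth = sim["plate"]

        # screen-side single-cell QC mirrors the well-level stage
        rules = [QcRule("n_cells", lower=config.min_cells_per_image, scope="image")]
        plate_qc, _ = apply_image_qc(plate_tab, rules)
        atlas_ds = downsample_per_group(atlas_tab, config.cap, config.seed_downsample)
        plate_ds = downsample_per_group(plate_qc, config.cap, config.seed_downsample + 1)
        merged, anchor_models = anchor_standardize([atlas_ds, plate_ds], ["atlas", "screen"])

        # doublet removal on the screen half, trained on synthetic truth labels
        screen_mask = (merged.data["dataset"] == "screen").to_numpy()
        screen_part = merged.subset(screen_mask)
        truth_idx = plate_truth.cells.set_index("cell_id")
        raw_ids = screen_part.data["cell_id"].str.split(":", n=1).str[1]
        is_doublet = truth_idx.loc[raw_ids, "doublet"].to_numpy()
        labels = np.where(
            is_doublet,
            "Doublet",
            np.where(screen_part.data["role"] == "progenitor_control", "Progenitor", "Inlier"),
        )
        doublet_model = train_doublet_model(screen_part, labels, seed=config.seed_doublet)
        screen_clean, removed_doublets = classify_and_remove(screen_part, doublet_model)

        atlas_part = merged.subset((merged.data["dataset"] == "atlas").to_numpy())
        emb_model, emb = fit_embedding(
            atlas_part,
            n_pcs=config.n_pcs,
            seed=config.seed_embed,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
        )
        cluster_model = cluster_cells(
            emb, range(config.k_min, config.k_max + 1), seed=config.seed_cluster
        )
        timepoints = atlas_part.data["timepoint"].to_numpy(dtype=float)
        start, ends = select_backbone(cluster_model, timepoints)
        # name lineages from morphology: the hepatocyte fate has larger cells
        areas = atlas_part.data["cell_area"].to_numpy()
        mean_area = [areas[cluster_model.labels == e].mean() for e in ends]
        if mean_area[0] < mean_area[1]:
            ends = ends[::-1]
        tree = infer_lineages(cluster_model, start, ends)
        traj = PrincipalTrajectory(
            emb,
            cluster_model,
            tree,
            span=config.span,
            df=config.smoother_df,
            n_points=config.n_curve_points,
        )
        traj_results = traj.fit()
        if config.t_b_override is not None:
            traj_results.t_b = float(config.t_b_override)
            traj_results.states = traj_results.project(emb)

        joblib.dump(
            {
                "anchor_models": anchor_models,
                "doublet_model": doublet_model,
                "embedding_model": emb_model,
                "cluster_model": cluster_model,
                "tree": tree,
                "trajectory": traj_results,
                "screen_clean": screen_clean,
                "atlas_part": atlas_part,
            },
            out / "models" / "atlas_models.joblib",
        )
        np.savetxt(out / "models" / "curve_hepatocyte.tsv", traj_results.curves[0], delimiter="\t")
        np.savetxt(out / "models" / "curve_biliary.tsv", traj_results.curves[1], delimiter="\t")
        (out / "models" / "trajectory.json").write_text(
            json.dumps(
                {
                    "t_b": traj_results.t_b,
                    "lineages": list(traj_results.lineage_names),
                    "curve_lengths": traj_results.curve_lengths,
                    "k": cluster_model.k,
                    "start": start,
                    "ends": list(ends),
                },
                indent=2,
            )
        )
        atlas_states = traj_results.states.copy()
        atlas_states.insert(0, "cell_id", atlas_part.data["cell_id"].to_numpy())
        atlas_states.to_csv(out / "states" / "atlas_states.tsv", sep="\t", index=False)
        results["atlas"] = {
            "merged": merged,
            "atlas_part": atlas_part,
            "screen_clean": screen_clean,
            "embedding_model": emb_model,
            "embedding": emb,
            "cluster_model": cluster_model,
            "tree": tree,
            "trajectory": traj_results,
            "doublet_model": doublet_model,
            "removed_doublets": removed_doublets,
        }
        timings["atlas"] = time.perf_counter() - t0

    def load_models():
        if "atlas" in results:
            return results["atlas"]
        blob = joblib.load(_need(out / "models" / "atlas_models.joblib", "fitted atlas models"))
        return blob

    if stage("project"):
        t0 = time.perf_counter()
        models = load_models()
        screen_clean = models["screen_clean"]
        emb_model = models["embedding_model"]
        traj_results = models["trajectory"]
        coords = emb_model.transform(screen_clean)
        states = traj_results.project(coords)
        meta = screen_clean.data[["cell_id", "well", "role", "compound", "dose", "replicate"]]
        states = pd.concat([meta.reset_index(drop=True), states], axis=1)
        states["treatment"] = np.where(
            states["role"] == "treatment", states["compound"], states["role"]
        )
        states.to_csv(out / "states" / "screen_states.tsv", sep="\t", index=False)
        results["project"] = {"states": states, "coords": coords}
        timings["project"] = time.perf_counter() - t0

    if stage("stats"):
        t0 = time.perf_counter()
        if "project" in results:
            states = results["project"]["states"]
        else:
            states = pd.read_csv(
                _need(out / "states" / "screen_states.tsv", "projected screen states"), sep="\t"
            )
        per_rep, per_trt = summarize_composition(states)
        ref_name = config.reference_role
        ref_counts = (
            per_rep[per_rep["treatment"] == ref_name][[f"count_{l}" for l in LINEAGE_LABELS]]
            .sum()
            .to_numpy()
        )
        ref_frac = ref_counts / ref_counts.sum()
        tests = []
        for (trt, rep), block in per_rep.groupby(["treatment", "replicate"]):
            if trt == ref_name:
                continue
            obs = block[[f"count_{l}" for l in LINEAGE_LABELS]].to_numpy()[0]
            ct = chisq_vs_reference(obs, ref_frac, LINEAGE_LABELS, ref_name)
            tests.append(
                {
                    "treatment": trt,
                    "replicate": rep,
                    "chisq": ct.statistic,
                    "df": ct.df,
                    "p_value": ct.p_value,
                }
            )
        tests = pd.DataFrame(tests)
        hep = states[states["label"] == "Hepatocyte"]
        ref_pt = hep.loc[hep["treatment"] == ref_name, "pseudotime"].to_numpy()
        pt_rows = []
        for trt, block in hep.groupby("treatment"):
            if trt == ref_name or len(block) < 10 or len(ref_pt) < 10:
                continue
            cmp_res = compare_pseudotime(block["pseudotime"].to_numpy(), ref_pt, seed=config.seed_qc)
            pt_rows.append(
                {
                    "treatment": trt,
                    "median": cmp_res.median_a,
                    "reference_median": cmp_res.median_b,
                    "U": cmp_res.statistic,
                    "p_value": cmp_res.p_value,
                    "shapiro_p": cmp_res.shapiro_p_a,
                }
            )
        pt_table = pd.DataFrame(pt_rows)
        per_rep.to_csv(out / "reports" / "composition_per_replicate.tsv", sep="\t", index=False)
        per_trt.to_csv(out / "reports" / "composition_mean_sd.tsv", sep="\t", index=False)
        tests.to_csv(out / "reports" / "chisq_vs_reference.tsv", sep="\t", index=False)
        pt_table.to_csv(out / "reports" / "pseudotime_vs_reference.tsv", sep="\t", index=False)
        results["stats"] = {
            "composition_per_replicate": per_rep,
            "composition_mean_sd": per_trt,
            "chisq": tests,
            "pseudotime": pt_table,
        }
        timings["stats"] = time.perf_counter() - t0

    manifest = {
        "morphotraj_version": _pkg_version(),
        "mode": mode,
        "config": dataclasses.asdict(config),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    mpath = out / "manifest.json"
    if mpath.exists():
        old = json.loads(mpath.read_text())
        old_t = old.get("timings_s", {})
        old_t.update(manifest["timings_s"])
        manifest["timings_s"] = old_t
    mpath.write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
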