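"""End-to-end orchestration: simulate -> condition -> map -> aggregate -> verify.

A single YAML-serializable :class:`RunConfig` drives the whole pipeline; one
rng seed is fanned out to independent per-stage substreams so that a change
in one stage's draw count cannot perturb another stage. Outputs (maps,
matrices, cluster solutions, verification report, log, config snapshot) are
written to a run directory together with a manifest of SHA-256 hashes;
rerunning with the same config and seed reproduces all outputs bit
identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from interomap import io as iomod
from interomap.cohort import (
    GroundTruth,
    RoiSpec,
    SimConfig,
    build_grid_rois,
    cortico_cortical_scenario,
    default_ground_truth,
    emit_edge_list,
    subcortico_cortical_scenario,
    subcortico_subcortical_scenario,
    simulate_cohort,
)
from interomap.conditioning import condition_subject, framewise_displacement
from interomap.mapping import (
    BinaryMask,
    ConsistencyMap,
    binarize_positive,
    bootstrap_consistency,
    consistency_cutoff,
    consistency_mask,
    group_map,
    masked_group_map,
    seed_matrix,
    seed_zmaps,
    subsample_size,
)
from interomap.networks import (
    cluster_conjunctions,
    conjunction,
    connecting_regions,
    kmeans_over_k,
    similarity_matrix,
)
from interomap.verify import verification_summary, edge_confirmed

SCENARIOS = ("default", "cortico_cortical", "subcortico_cortical", "subcortico_subcortical", "full")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run.

    The study-scale analysis constants are B = 1000 subsampling iterations
    at fraction 0.8 with alpha = 0.05 and the 95% survival criterion,
    k-means over k = 2..10 with 10 restarts. The default cohort is a
    desk-scale synthetic stand-in (see :class:`SimConfig`); ``scenario``
    selects which documented edge lists are planted.
    """

    rng_seed: int = 0
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    scenario: str = "full"
    edge_weight: float = 0.5
    sim: SimConfig = field(default_factory=SimConfig)
    low_hz: float = 0.008
    high_hz: float = 0.09
    B: int = 1000
    fraction: float = 0.8
    alpha: float = 0.05
    consistency_criterion: float = 0.95
    k_range: tuple[int, int] = (2, 10)
    restarts: int = 10
    kmeans_max_iter: int = 1000
    verification_rule: str = "matrix_or_map"
    min_voxel_fraction: float = 0.05
    write_bold: bool = False

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0 < self.fraction <= 1):
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.consistency_criterion <= 1):
            raise ValueError("consistency_criterion must be in (0, 1]")
        if subsample_size(self.sim.n_subjects, self.fraction) < 3:
            raise ValueError("subsample size below 3; increase n_subjects or fraction")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid k range {self.k_range}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError("need 0 <= low_hz < high_hz")
        if self.high_hz >= 0.5 / self.sim.tr_s:
            raise ValueError("high_hz at or above Nyquist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        for key in ("grid_dims", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        d["k_range"] = list(self.k_range)
        return d


def ground_truth_for_scenario(config: RunConfig) -> GroundTruth:
    w = config.edge_weight
    if config.scenario == "default":
        return default_ground_truth()
    if config.scenario == "cortico_cortical":
        return cortico_cortical_scenario(edge_weight=w)
    if config.scenario == "subcortico_cortical":
        return subcortico_cortical_scenario(edge_weight=w)
    if config.scenario == "subcortico_subcortical":
        return subcortico_subcortical_scenario(edge_weight=w)
    # full: all three documented lists planted together
    gt = cortico_cortical_scenario(edge_weight=w)
    for other in (subcortico_cortical_scenario(edge_weight=w),
                  subcortico_subcortical_scenario(edge_weight=w)):
        gt.planted_edges.update(other.planted_edges)
        gt.unsupported_edges |= other.unsupported_edges
        gt.system_factors.update(other.system_factors)
    return gt


def _spawn_seeds(rng_seed: int, n: int) -> list[int]:
    """Independent per-stage integer seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(rng_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``.

    Returns a result dictionary with the in-memory objects of each stage
    (cohort sizes, cluster solutions, verification report, manifest path).
    Any stage failure is re-raised annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = logging.getLogger(f"interomap.run.{out.name}")
    logger.setLevel(logging.INFO)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)

    cohort_seed, boot_seed, cluster_seed = _spawn_seeds(config.rng_seed, 3)
    results: dict = {}
    written: list[Path] = []
    stage = "setup"
    t0 = time.time()
    try:
        stage = "simulate"
        grid, rois = build_grid_rois(config.grid_dims, RoiSpec(), rng_seed=cohort_seed,
                                     voxel_size_mm=config.voxel_size_mm)
        gt = ground_truth_for_scenario(config)
        cohort, confounds = simulate_cohort(grid, rois, gt, config.sim, rng_seed=cohort_seed)
        logger.info("simulated %d subjects on grid %s (%d voxels)",
                    len(cohort), grid.dims, grid.n_voxels)
        iomod.save_rois_nifti(rois, out / "rois.nii")
        written.append(out / "rois.nii")
        edges = emit_edge_list(gt, rois)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        written.append(out / "edges.tsv")
        iomod.save_json(gt.to_dict(), out / "ground_truth.json")
        written.append(out / "ground_truth.json")
        for ts, conf in zip(cohort, confounds):
            p = out / f"{ts.subject_id}_confounds.tsv"
            iomod.save_confounds_tsv(conf, p)
            written.append(p)
            if config.write_bold:
                bp = out / f"{ts.subject_id}_bold.nii"
                iomod.save_subject_nifti(ts, grid, bp)
                written.append(bp)

        stage = "condition"
        motion = {}
        for i, (ts, conf) in enumerate(zip(cohort, confounds)):
            cohort[i], _ = condition_subject(ts, conf, config.low_hz, config.high_hz)
            motion[ts.subject_id] = framewise_displacement(
                conf, voxel_size_mm=grid.voxel_size_mm
            ).to_dict()
        iomod.save_json(motion, out / "motion_summary.json")
        written.append(out / "motion_summary.json")
        logger.info("conditioned %d subjects (band %.3f-%.3f Hz)",
                    len(cohort), config.low_hz, config.high_hz)

        stage = "map"
        z = seed_zmaps(cohort, rois)
        counts = bootstrap_consistency(z, B=config.B, fraction=config.fraction,
                                       alpha=config.alpha, rng_seed=boot_seed)
        cutoff = consistency_cutoff(config.B, config.consistency_criterion)
        logger.info("bootstrap: B=%d, subsample %d/%d, cutoff > %d",
                    config.B, subsample_size(len(cohort), config.fraction), len(cohort), cutoff)
        group_maps, masked_maps, binarized = {}, {}, {}
        for li, label in enumerate(rois.labels):
            gmap = group_map(z[:, li], grid)
            cmask = consistency_mask(
                ConsistencyMap(grid=grid, counts=counts[li], B=config.B,
                               fraction=config.fraction, alpha=config.alpha), cutoff)
            group_maps[label] = gmap
            masked_maps[label] = masked_group_map(gmap, cmask)
            binarized[label] = BinaryMask(
                grid=grid, data=binarize_positive(gmap, config.alpha).data & cmask.data)
            written += iomod.save_statmap_nifti(masked_maps[label], out / f"map_{label}")
            iomod.save_volume_nifti(counts[li], grid, out / f"map_{label}_counts.nii")
            written.append(out / f"map_{label}_counts.nii")

        stage = "matrix"
        matrix = seed_matrix(cohort, rois, alpha=config.alpha)
        written += iomod.save_matrix_tsv(matrix, out / "matrix")

        stage = "aggregate"
        solutions = {}
        for name, labels in (("cortical", rois.cortical_labels),
                             ("subcortical", rois.subcortical_labels)):
            if len(labels) < 3:
                continue
            idx = [rois.labels.index(l) for l in labels]
            maps = np.stack([group_maps[l].t for l in labels])
            sim = similarity_matrix(maps, labels)
            pd.DataFrame(sim.values, index=labels, columns=labels).to_csv(
                out / f"similarity_{name}.tsv", sep="\t")
            written.append(out / f"similarity_{name}.tsv")
            k_lo, k_hi = config.k_range
            ks = range(k_lo, min(k_hi, len(labels) - 1) + 1)
            sol = kmeans_over_k(sim, ks, restarts=config.restarts,
                                max_iter=config.kmeans_max_iter, rng_seed=cluster_seed)
            solutions[name] = sol
            iomod.save_json(
                {"chosen_k": sol.chosen_k, "labels": sol.labels,
                 "ch_scores": {str(k): v for k, v in sol.ch_scores.items()}},
                out / f"clusters_{name}.json")
            written.append(out / f"clusters_{name}.json")
            logger.info("%s clustering: chosen k=%d (CH=%s)", name, sol.chosen_k,
                        {k: round(v, 2) for k, v in sol.ch_scores.items()})
            cmaps = cluster_conjunctions({l: binarized[l] for l in labels}, sol.labels)
            for cid, cmask in cmaps.items():
                iomod.save_mask_nifti(cmask, out / f"cluster_{name}_{cid}_conjunction.nii")
                written.append(out / f"cluster_{name}_{cid}_conjunction.nii")
            conj = conjunction([binarized[l] for l in labels])
            iomod.save_volume_nifti(conj.counts, grid, out / f"conjunction_{name}.nii")
            written.append(out / f"conjunction_{name}.nii")
            hub = connecting_regions(conj, min_overlap=max(2, len(labels) // 2))
            iomod.save_mask_nifti(hub, out / f"connecting_{name}.nii")
            written.append(out / f"connecting_{name}.nii")

        stage = "verify"
        evidence = {}
        for _, row in edges.iterrows():
            pair = (row["seed_a"], row["seed_b"])
            evidence[tuple(sorted(pair))] = edge_confirmed(
                pair, matrix, binarized, rois, rule=config.verification_rule,
                min_voxel_fraction=config.min_voxel_fraction)
        report = verification_summary(edges, evidence)
        report.per_edge.to_csv(out / "verification_edges.tsv", sep="\t", index=False)
        written.append(out / "verification_edges.tsv")
        iomod.save_json(
            {"overall_percent": report.overall_percent,
             "overall_fraction": report.overall_fraction,
             "per_category": report.per_category.to_dict(orient="records")},
            out / "verification_summary.json")
        written.append(out / "verification_summary.json")
        for _, row in report.per_category.iterrows():
            logger.info("verification %s: %d/%d confirmed (%.0f%%)", row["category"],
                        row["n_confirmed"], row["n_edges"], row["percent_confirmed"])

        stage = "manifest"
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        written.append(out / "config.yaml")
        import sklearn
        import scipy

        from interomap import __version__

        manifest = {
            "rng_seed": config.rng_seed,
            "versions": {
                "interomap": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-learn": sklearn.__version__,
                "pandas": pd.__version__,
            },
            "stage_seeds": {"cohort": cohort_seed, "bootstrap": boot_seed,
                            "clustering": cluster_seed},
            "elapsed_s": round(time.time() - t0, 2),
            "outputs": {
                str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(set(written))
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        logger.info("run complete in %.1f s; %d outputs", time.time() - t0, len(manifest["outputs"]))
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        handler.close()
        logger.removeHandler(handler)

    results.update(
        grid=grid, rois=rois, ground_truth=gt, matrix=matrix, group_maps=group_maps,
        masked_maps=masked_maps, binarized_maps=binarized, cluster_solutions=solutions,
        report=report, manifest=manifest, out_dir=out,
    )
    return results
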