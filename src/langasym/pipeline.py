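"""End-to-end orchestration: simulate -> gradients -> asymmetry ->
trajectories -> cluster -> brain-behavior CCA.

Each stage reads its inputs from, and writes its artifacts to, a single
working directory, so stages can be run individually (CLI) or chained by
:func:`run_pipeline`.  A manifest records the configuration hash; re-runs
with an unchanged configuration are skipped unless forced.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .asymmetry import asymmetry_long_to_wide, gradient_asymmetry, volume_asymmetry
from .atlas import pairs_of_interest
from .brain_behavior import pca_reduce, permutation_inference, residualize
from .clustering import cluster_trajectories
from .config import RunConfig
from .gradients import GradientPipeline
from .io import read_cohort, write_cohort
from .simulate import simulate_cohort
from .trajectories import fit_all_pairs, trajectory_curves

log = logging.getLogger("langasym")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


# ---------------------------------------------------------------------------
# stages (file-based contracts)


def stage_simulate(config: RunConfig, workdir: Path) -> None:
    with _timed("simulate"):
        data = simulate_cohort(config.cohort)
        write_cohort(data, workdir)


def _planted_template(data) -> np.ndarray | None:
    """Planted base gradient position per region — the synthetic analogue
    of a published template gradient used to orient the group reference."""
    gt = data.ground_truth
    if gt is None:
        return None
    return np.array([gt.pair_positions[p] for p in data.atlas["pair_id"]])


def stage_gradients(config: RunConfig, workdir: Path) -> None:
    with _timed("gradients"):
        data = read_cohort(workdir)
        if not data.timeseries:
            raise PipelineError("gradients", "no time series in working directory")
        region_ids = list(data.atlas["region_id"])
        anchors: list[int] | None = None
        template = None
        if config.anchor_regions:
            anchors = [region_ids.index(r) for r in config.anchor_regions]
        elif config.use_planted_template:
            template = _planted_template(data)
        pipe = GradientPipeline(
            density=config.density,
            n_components=config.n_components,
            alpha=config.alpha,
            n_align_iter=config.align_iters,
            anchor_regions=anchors,
            template=template,
            reference_mode=config.reference_mode,
        )
        g1 = pipe.fit_transform(data.timeseries)
        g1.rename_axis("subject_id").to_csv(workdir / "gradients_g1.csv")
        ref = pd.DataFrame(
            pipe.reference_gradients_,
            index=pd.Index(region_ids, name="region_id"),
            columns=[f"g{i + 1}" for i in range(pipe.reference_gradients_.shape[1])],
        )
        ref.to_csv(workdir / "gradients_reference.csv")
        meta = {
            "reference_eigenvalues": pipe.reference_eigenvalues_.tolist(),
            "reference_variance_explained": pipe.reference_variance_explained_.tolist(),
            "subject_variance_explained_g1": pipe.variance_explained_g1_.round(6).to_dict(),
        }
        (workdir / "gradients_meta.json").write_text(
            json.dumps(meta, sort_keys=True, indent=1)
        )


def stage_asymmetry(config: RunConfig, workdir: Path, measure: str = "both") -> None:
    with _timed("asymmetry"):
        data = read_cohort(workdir)
        frames = []
        if measure in ("gradient", "both"):
            g1 = pd.read_csv(workdir / "gradients_g1.csv", index_col="subject_id")
            frames.append(gradient_asymmetry(g1, data.atlas))
        if measure in ("volume", "both"):
            frames.append(
                volume_asymmetry(data.volumes, data.atlas, method=config.volume_measure)
            )
        pd.concat(frames, ignore_index=True).to_csv(
            workdir / "asymmetry.csv", index=False
        )


def stage_trajectories(config: RunConfig, workdir: Path) -> None:
    with _timed("trajectories"):
        data = read_cohort(workdir)
        g1 = pd.read_csv(workdir / "gradients_g1.csv", index_col="subject_id")
        pair_ids = pairs_of_interest(data.atlas)
        fits, summary = fit_all_pairs(
            g1,
            data.atlas,
            data.phenotype,
            pair_ids,
            k=config.knots,
            fdr_alpha=config.fdr_alpha,
            grid_size=config.grid_size,
        )
        summary.to_csv(workdir / "trajectory_summary.csv", index=False)
        trajectory_curves(fits).to_csv(workdir / "trajectory_curves.csv", index=False)


def stage_cluster(config: RunConfig, workdir: Path) -> dict:
    with _timed("cluster"):
        summary = pd.read_csv(workdir / "trajectory_summary.csv")
        curves = pd.read_csv(workdir / "trajectory_curves.csv")
        sig = summary.loc[summary["significant"], "pair_id"].tolist()
        out: dict = {"n_significant": len(sig)}
        if len(sig) < 3:
            log.warning(
                "cluster stage skipped: %d significant pair(s), need >= 3",
                len(sig),
            )
            out["skipped"] = f"only {len(sig)} significant pairs (need >= 3)"
            (workdir / "cluster_summary.json").write_text(
                json.dumps(out, sort_keys=True, indent=1)
            )
            return out
        wide = curves.pivot(index="age", columns="pair_id", values="asymmetry")[sig]
        solution = cluster_trajectories(wide, k_min=config.k_min, k_max=config.k_max)
        labels = pd.DataFrame(
            {
                "pair_id": solution.labels.index,
                "cluster": solution.labels.to_numpy(),
            }
        )
        labels.to_csv(workdir / "cluster_labels.csv", index=False)
        out.update(
            {
                "k": solution.k,
                "mean_silhouette": round(solution.mean_silhouette, 6),
                "silhouette_by_k": {
                    str(k): round(v, 6) for k, v in solution.silhouette_by_k.items()
                },
                "medoids": solution.medoids,
                "crossover_age": None
                if solution.crossover_age is None
                else round(solution.crossover_age, 4),
                "crossover_found": solution.crossover_found,
                "crossover_clusters": [int(c) for c in solution.crossover_clusters],
            }
        )
        (workdir / "cluster_summary.json").write_text(
            json.dumps(out, sort_keys=True, indent=1)
        )
        return out


def stage_cca(config: RunConfig, workdir: Path) -> dict:
    """Per-cluster brain-behavior CCA.

    The brain set of a cluster holds that cluster's gradient and
    normalized-volume asymmetries (subjects x pairs), PCA-reduced at the
    elbow; both sets are residualized on sex, age and MMSE.
    """
    with _timed("cca"):
        data = read_cohort(workdir)
        if data.behavior.empty:
            raise PipelineError("cca", "no behavior table in working directory")
        labels_path = workdir / "cluster_labels.csv"
        if not labels_path.exists():
            raise PipelineError("cca", "no cluster labels (run cluster stage first)")
        labels = pd.read_csv(labels_path)
        asym = pd.read_csv(workdir / "asymmetry.csv")
        grad_wide = asymmetry_long_to_wide(asym, "gradient")
        vol_wide = asymmetry_long_to_wide(asym, "normalized_volume")
        behavior = data.behavior.set_index("subject_id")
        pheno = data.phenotype.set_index("subject_id")
        subjects = grad_wide.index.intersection(behavior.index)
        covars = pheno.loc[subjects, ["sex", "age", "mmse"]]
        report: dict = {}
        for cluster_id, grp in labels.groupby("cluster"):
            pairs = grp["pair_id"].tolist()
            brain = pd.concat(
                [
                    grad_wide.loc[subjects, pairs].add_prefix("grad_"),
                    vol_wide.loc[subjects, pairs].add_prefix("vol_"),
                ],
                axis=1,
            )
            scores, evr, retained = pca_reduce(brain)
            brain_r = residualize(scores, covars)
            behav_r = residualize(behavior.loc[subjects], covars)
            res = permutation_inference(
                brain_r, behav_r, n_perm=config.n_perm, seed=config.cca_seed
            )
            key = f"cluster{cluster_id + 1}"
            res.x_loadings.round(6).to_csv(workdir / f"cca_{key}_brain_loadings.csv")
            res.y_loadings.round(6).to_csv(workdir / f"cca_{key}_behavior_loadings.csv")
            res.x_scores.round(6).to_csv(workdir / f"cca_{key}_brain_scores.csv")
            report[key] = {
                "n_subjects": int(len(subjects)),
                "n_brain_variables": int(brain.shape[1]),
                "n_components_retained": int(retained),
                "correlations": [round(float(r), 6) for r in res.correlations],
                "p_values": [round(float(p), 6) for p in res.p_values],
                "p_fwer": [round(float(p), 6) for p in res.p_fwer],
                "variance_explained_brain": [
                    round(float(v), 4) for v in res.variance_explained_x
                ],
                "variance_explained_behavior": [
                    round(float(v), 4) for v in res.variance_explained_y
                ],
            }
        (workdir / "cca_report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1)
        )
        return report


# ---------------------------------------------------------------------------
# orchestrator


def run_pipeline(
    config: RunConfig, out_dir: str | Path, force: bool = False
) -> dict:
    """Run every stage on a synthetic cohort and write ``summary.json``.

    The summary carries the configuration hash; an existing run with the
    same hash is returned as-is unless ``force`` is set.
    """
    workdir = Path(out_dir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    summary_path = workdir / "summary.json"
    if summary_path.exists() and not force:
        previous = json.loads(summary_path.read_text())
        if previous.get("config_hash") == cfg_hash:
            log.info("unchanged config hash %s: reusing existing results", cfg_hash)
            return previous
    stage_simulate(config, workdir)
    stage_gradients(config, workdir)
    stage_asymmetry(config, workdir)
    stage_trajectories(config, workdir)
    cluster_out = stage_cluster(config, workdir)
    summary: dict = {
        "config_hash": cfg_hash,
        "n_subjects": config.cohort.n_subjects,
        "n_regions": config.cohort.n_regions,
        "n_pairs_of_interest": config.cohort.n_pairs_of_interest,
        "cluster": cluster_out,
    }
    if "skipped" not in cluster_out:
        summary["cca"] = stage_cca(config, workdir)
    g1_meta = json.loads((workdir / "gradients_meta.json").read_text())
    var_g1 = list(g1_meta["subject_variance_explained_g1"].values())
    summary["mean_variance_explained_g1"] = round(float(np.mean(var_g1)), 6)
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=1))
    return summary
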