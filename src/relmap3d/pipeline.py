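"""End-to-end orchestration: simulate -> residualize -> train -> relevance ->
occlude -> evaluate, with a JSON run config, per-stage seeding, and a manifest
recording seeds, wall times and content hashes of every artifact."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, io_preproc, network as net_mod, evaluation
from .analysis import group_mean_map, occlusion_scan, region_volume_ml
from .io_preproc import GrayMatterVolume, write_volume
from .lrp import LRPConfig, compute_relevance_map, conservation_error
from .network import NetworkSpec, TrainConfig

STAGES = ("simulate", "residualize", "train", "relevance", "occlude", "evaluate")

_KNOWN_KEYS = {
    "out_dir", "mode", "seed", "n_control", "n_mci", "n_ad", "grid_shape",
    "noise_sd", "atrophy_regions", "k_folds", "epochs", "augment",
    "learning_rate", "batch_size", "occlusion_stride", "occlusion_edge",
    "occlusion_attenuation", "relevance_models",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (JSON-serializable; unknown keys error)."""

    out_dir: str = "run"
    mode: str = "residualized"  # or "raw"
    seed: int = 0
    n_control: int = 100
    n_mci: int = 50
    n_ad: int = 50
    grid_shape: tuple = (40, 40, 48)
    noise_sd: float = 0.05
    atrophy_regions: dict = field(default_factory=synthetic.default_atrophy_regions)
    k_folds: int = 10
    epochs: int | None = None  # default: 10 residualized / 20 raw (CV protocol)
    augment: bool = False      # translation augmentation is tied to the full grid
    learning_rate: float = 1e-4
    batch_size: int = 20
    occlusion_stride: int = 8
    occlusion_edge: int = 20
    occlusion_attenuation: float = 0.5
    relevance_models: int = 1  # how many fold models to run relevance maps with

    def __post_init__(self) -> None:
        if self.mode not in ("residualized", "raw"):
            raise ValueError(f"mode must be 'residualized' or 'raw', got {self.mode!r}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.epochs is None:
            self.epochs = 10 if self.mode == "residualized" else 20

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed fan-out from the global seed."""
        return int(
            np.random.SeedSequence([self.seed, STAGES.index(stage)]).generate_state(1)[0]
            % (2**31)
        )


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineRun:
    """Executes pipeline stages in order, writing artifacts and a manifest.

    A completed stage (marker file present) is skipped on re-run, making any
    stage resumable.
    """

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"config": self._config_dict(), "stages": {}}
        )
        self._cache: dict = {}

    def _config_dict(self) -> dict:
        d = asdict(self.config)
        d["grid_shape"] = list(self.config.grid_shape)
        return d

    def _record(self, stage: str, elapsed: float, outputs: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "seed": self.config.stage_seed(stage),
            "wall_time_s": round(elapsed, 3),
            "outputs": {str(p.relative_to(self.out)): _hash_file(p) for p in outputs},
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _done(self, stage: str) -> bool:
        return (self.out / f".{stage}.done").exists()

    def _mark(self, stage: str) -> None:
        (self.out / f".{stage}.done").touch()

    # -- stages ------------------------------------------------------------

    def run(self) -> dict:
        for stage in STAGES:
            if self._done(stage):
                continue
            t0 = time.perf_counter()
            outputs = getattr(self, f"_stage_{stage}")()
            self._record(stage, time.perf_counter() - t0, outputs)
            self._mark(stage)
        return self.manifest

    def _cohort(self):
        if "cohort" not in self._cache:
            cfg = self.config
            spec = synthetic.CohortSpec(
                n_control=cfg.n_control, n_mci=cfg.n_mci, n_ad=cfg.n_ad,
                grid_shape=cfg.grid_shape, noise_sd=cfg.noise_sd,
                atrophy_regions=cfg.atrophy_regions, seed=cfg.stage_seed("simulate"),
            )
            self._cache["cohort"] = synthetic.simulate_cohort(spec)
            self._cache["spec"] = spec
        return self._cache["cohort"]

    def _stage_simulate(self):
        volumes, records, atlas = self._cohort()
        vol_dir = self.out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for v in volumes:
            write_volume(v, vol_dir / f"{v.subject_id}.nii.gz")
        cov_path = self.out / "covariates.tsv"
        synthetic.write_covariates(records, cov_path)
        synthetic.write_atlas(atlas, self.out / "atlas.nii.gz", self.out / "atlas_names.json")
        self._cache["spec"].to_json(self.out / "cohort_spec.json")
        return [cov_path, self.out / "atlas.nii.gz", self.out / "cohort_spec.json"]

    def _stage_residualize(self):
        volumes, records, atlas = self._cohort()
        if self.config.mode == "raw":
            self._cache["inputs"] = [v.values for v in volumes]
            return []
        model = io_preproc.fit_residualizer_on_controls(volumes, records)
        residuals = io_preproc.residualize_volumes(volumes, records, model)
        io_preproc.save_residual_model(
            model, self.out / "residual_model.nii.gz", self.out / "residual_model.json"
        )
        self._cache["inputs"] = [r.values for r in residuals]
        return [self.out / "residual_model.nii.gz", self.out / "residual_model.json"]

    def _inputs(self):
        if "inputs" not in self._cache:
            self._stage_residualize()
        return self._cache["inputs"]

    def _stage_train(self):
        volumes, records, atlas = self._cohort()
        inputs = self._inputs()
        cfg = self.config
        spec = NetworkSpec(input_shape=cfg.grid_shape)
        tc = TrainConfig(
            learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
            epochs=cfg.epochs, augment=cfg.augment, seed=cfg.stage_seed("train"),
        )
        diagnoses = [r.diagnosis for r in records]
        models, metrics, folds = net_mod.cross_validate(
            inputs, diagnoses, spec, tc, k=cfg.k_folds
        )
        model_dir = self.out / "models"
        for m in models:
            net_mod.save_network(m, model_dir / f"fold{m.fold_id:02d}")
        pd.DataFrame(metrics).to_csv(self.out / "cv_metrics.tsv", sep="\t", index=False)
        np.savetxt(self.out / "fold_assignment.txt", folds, fmt="%d")
        self._cache["models"] = models
        self._cache["folds"] = folds
        return [self.out / "cv_metrics.tsv", self.out / "fold_assignment.txt"]

    def _models(self):
        if "models" not in self._cache:
            model_dir = self.out / "models"
            self._cache["models"] = [
                net_mod.load_network(d) for d in sorted(model_dir.iterdir())
            ]
            self._cache["folds"] = np.loadtxt(
                self.out / "fold_assignment.txt", dtype=int
            )
        return self._cache["models"]

    def _stage_relevance(self):
        volumes, records, atlas = self._cohort()
        inputs = self._inputs()
        models = self._models()[: self.config.relevance_models]
        maps_by_group: dict[str, list] = {"CN": [], "MCI": [], "AD": []}
        conservation = []
        rel_rows = []
        for model in models:
            for rec, x in zip(records, inputs):
                rmap = compute_relevance_map(model, x, target_class=1)
                maps_by_group[rec.diagnosis].append(rmap.values)
                conservation.append(conservation_error(rmap))
                rel_rows.append(
                    {
                        "model": model.fold_id,
                        "subject_id": rec.subject_id,
                        "diagnosis": rec.diagnosis,
                        "hippocampus_relevance": float(
                            rmap.values[atlas.mask("hippocampus")].sum()
                        ),
                        "total_relevance": float(rmap.values.sum()),
                    }
                )
        outputs = []
        for group, maps in maps_by_group.items():
            if maps:
                mean_map = GrayMatterVolume(
                    group_mean_map(maps), atlas.voxel_size_mm, "relevance"
                )
                p = self.out / f"mean_relevance_{group}.nii.gz"
                write_volume(mean_map, p)
                outputs.append(p)
        rel_path = self.out / "relevance_table.tsv"
        pd.DataFrame(rel_rows).to_csv(rel_path, sep="\t", index=False)
        (self.out / "conservation.json").write_text(
            json.dumps({"max_relative_error": max(conservation), "n_maps": len(conservation)})
        )
        return outputs + [rel_path, self.out / "conservation.json"]

    def _stage_occlude(self):
        volumes, records, atlas = self._cohort()
        inputs = self._inputs()
        model = self._models()[0]
        cn_idx = next(i for i, r in enumerate(records) if r.diagnosis == "CN")
        cfg = self.config
        # occlusion simulates atrophy on the gray-matter map; the network input
        # (residual) is recomputed from the occluded map
        raw = volumes[cn_idx].values
        predicted = raw - inputs[cn_idx]
        vol = GrayMatterVolume(raw, atlas.voxel_size_mm, "gray-matter")
        result = occlusion_scan(
            model, vol, cube_edge=cfg.occlusion_edge,
            attenuation=cfg.occlusion_attenuation, stride=cfg.occlusion_stride,
            compute_relevance=False, preprocess=lambda occ: occ - predicted,
        )
        p = self.out / "occlusion_probability.nii.gz"
        write_volume(GrayMatterVolume(result.probability_grid, 1.0, "occlusion"), p)
        (self.out / "occlusion_meta.json").write_text(
            json.dumps(
                {
                    "cube_edge_voxels": result.cube_edge_voxels,
                    "cube_edge_mm": result.cube_edge_mm,
                    "attenuation": result.attenuation,
                    "stride": result.stride,
                    "baseline_probability": result.baseline_probability,
                    "subject": records[cn_idx].subject_id,
                }
            )
        )
        return [p, self.out / "occlusion_meta.json"]

    def _stage_evaluate(self):
        volumes, records, atlas = self._cohort()
        if "folds" not in self._cache:
            self._cache["folds"] = np.loadtxt(self.out / "fold_assignment.txt", dtype=int)
        folds = self._cache["folds"]
        mask = atlas.mask("hippocampus")
        hippo_ml = np.array([region_volume_ml(v, mask) for v in volumes])
        covs = np.stack([r.covariate_vector for r in records])
        control = np.array([r.diagnosis == "CN" for r in records])
        residuals, _ = io_preproc.residualize_scalar(hippo_ml, covs, control)
        binary = np.array([r.diagnosis != "CN" for r in records], int)
        rows = []
        for fold_id in sorted(set(folds)):
            te = folds == fold_id
            roc = evaluation.volumetric_baseline(
                residuals[~te], binary[~te], residuals[te], binary[te]
            )
            rows.append(
                {
                    "fold": fold_id,
                    "baseline_auc": roc.auc,
                    "baseline_balanced_accuracy": roc.balanced_accuracy,
                    "baseline_threshold_ml": -roc.threshold,
                }
            )
        baseline = pd.DataFrame(rows)
        cv = pd.read_csv(self.out / "cv_metrics.tsv", sep="\t")
        summary = {
            "cnn_balanced_accuracy_mean": float(cv["balanced_accuracy"].mean()),
            "cnn_balanced_accuracy_sd": float(cv["balanced_accuracy"].std(ddof=1)),
            "cnn_auc_mean": float(cv["auc"].mean()),
            "cnn_auc_sd": float(cv["auc"].std(ddof=1)),
            "baseline_auc_mean": float(baseline["baseline_auc"].mean()),
            "baseline_balanced_accuracy_mean": float(
                baseline["baseline_balanced_accuracy"].mean()
            ),
        }
        baseline.to_csv(self.out / "baseline_metrics.tsv", sep="\t", index=False)
        (self.out / "summary.json").write_text(json.dumps(summary, indent=2))
        return [self.out / "baseline_metrics.tsv", self.out / "summary.json"]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest."""
    return PipelineRun(config).run()


def make_report(run_dir) -> str:
    """Human-readable summary of a completed run (markdown text)."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    lines = ["# Pipeline run report", ""]
    missing = [s for s in STAGES if s not in manifest["stages"]]
    if missing:
        lines.append(f"**Warning: incomplete run; missing stages: {', '.join(missing)}**")
        lines.append("")
    summary_path = run_dir / "summary.json"
    if summary_path.exists():
        s = json.loads(summary_path.read_text())
        lines += [
            "## Group separation (mean +/- SD over folds)",
            "",
            "| classifier | balanced accuracy | AUC |",
            "|---|---|---|",
            (
                f"| 3D CNN | {s['cnn_balanced_accuracy_mean']:.3f} +/- "
                f"{s['cnn_balanced_accuracy_sd']:.3f} | {s['cnn_auc_mean']:.3f} +/- "
                f"{s['cnn_auc_sd']:.3f} |"
            ),
            (
                f"| hippocampus volume (residuals) | "
                f"{s['baseline_balanced_accuracy_mean']:.3f} | "
                f"{s['baseline_auc_mean']:.3f} |"
            ),
            "",
        ]
    rel_path = run_dir / "relevance_table.tsv"
    if rel_path.exists():
        rel = pd.read_csv(rel_path, sep="\t")
        lines.append("## Hippocampus relevance by group (mean)")
        lines.append("")
        for group, sub in rel.groupby("diagnosis"):
            lines.append(f"- {group}: {sub['hippocampus_relevance'].mean():.4f}")
        lines.append("")
    lines.append("## Stage timings")
    lines.append("")
    for stage, info in manifest["stages"].items():
        lines.append(f"- {stage}: {info['wall_time_s']} s (seed {info['seed']})")
    text = "\n".join(lines) + "\n"
    (run_dir / "report.md").write_text(text)
    return text
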