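"""End-to-end orchestration of the two-stage clustering pipeline.

Stages: preprocess → ZINB pretrain + DEC cluster-train → [contrastive]
→ Leiden pseudo-labels + density + anchors → [teacher/student distillation]
→ evaluation (when ground truth is available). The three ablation switches
(`use_contrastive`, `use_mlp_head`, `use_self_kd`) reproduce the reduced
variants; with everything off the pipeline degenerates to Leiden on the
ZINB-stage embeddings.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io_preprocess
from .anchor_selection import (
    AnchorSplit,
    compute_density,
    leiden_cluster,
    leiden_cluster_auto,
    select_anchors,
)
from .contrastive import ContrastiveConfig, train_contrastive
from .distillation import ClusterAssignment, KDConfig, train_student, train_teacher
from .io_preprocess import CountMatrix
from .metrics import EvalReport, evaluate
from .synthetic_data import preset, simulate_counts
from .zinb_autoencoder import EncoderConfig, ZINBAutoencoder

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    # preprocessing
    min_cells: int = 3
    scale: float = 1e4
    n_top_genes: int = 2000
    # stage 1
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    # stage lengths are optimisation-step budgets: wall time and convergence
    # then depend on the step count, not on dataset size
    pretrain_steps: int = 500
    cluster_steps: int = 150
    contrastive_steps: int = 150
    student_steps: int = 250
    n_clusters: Optional[int] = None  # None: inferred by Leiden on pretrained space
    contrastive: ContrastiveConfig = field(default_factory=ContrastiveConfig)
    # stage 2
    leiden_neighbors: int = 15
    leiden_resolution: Optional[float] = None  # None: silhouette-selected
    density_k: int = 5
    anchor_fraction: float = 0.4
    kd: KDConfig = field(default_factory=KDConfig)
    # ablation switches
    use_contrastive: bool = True
    use_mlp_head: bool = True
    use_self_kd: bool = True
    # bookkeeping
    seed: int = 0
    output_dir: Optional[str] = None


@dataclass
class PipelineResult:
    assignment: ClusterAssignment
    anchors: AnchorSplit
    embeddings: np.ndarray
    report: Optional[EvalReport]
    manifest: dict


def _stage(manifest: dict, name: str, t0: float) -> float:
    t1 = time.perf_counter()
    manifest["stage_seconds"][name] = round(t1 - t0, 3)
    return t1


def run_pipeline(cfg: PipelineConfig, counts: Optional[CountMatrix] = None,
                 input_path: Optional[str] = None,
                 simulate: Optional[str] = None) -> PipelineResult:
    """Run the full pipeline on `counts`, a file, or a simulation preset."""
    if counts is None:
        if simulate is not None:
            counts = simulate_counts(preset(simulate, seed=cfg.seed))
        elif input_path is not None:
            counts = io_preprocess.load_counts(input_path)
        else:
            raise ValueError("provide counts, input_path or a simulation preset")
    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "n_cells": counts.n_cells,
        "n_genes": counts.n_genes,
        "stage_seconds": {},
    }
    t0 = time.perf_counter()

    expr, raw = io_preprocess.preprocess(
        counts, min_cells=cfg.min_cells, scale=cfg.scale, n_top=cfg.n_top_genes
    )
    t0 = _stage(manifest, "preprocess", t0)

    enc_cfg = dataclasses.replace(cfg.encoder)
    model = ZINBAutoencoder(expr.values.shape[1], enc_cfg, seed=cfg.seed)
    steps_per_epoch = max(1, -(-expr.n_cells // enc_cfg.batch_size))
    model.pretrain(expr, raw, epochs=_epochs(cfg.pretrain_steps, steps_per_epoch),
                   seed=cfg.seed)
    t0 = _stage(manifest, "zinb_pretrain", t0)

    if cfg.n_clusters is None:
        pre_labels, _ = _leiden(model.embed(expr.values), cfg, expr.n_cells)
        enc_cfg.n_clusters = int(pre_labels.max()) + 1
    else:
        enc_cfg.n_clusters = cfg.n_clusters
    manifest["n_clusters_stage1"] = enc_cfg.n_clusters
    Z, _ = model.train_cluster(expr, raw, epochs=_epochs(cfg.cluster_steps, steps_per_epoch),
                               seed=cfg.seed)
    t0 = _stage(manifest, "zinb_cluster", t0)

    loss_log = list(model.loss_log)
    stage2_encoder = model.encoder
    if cfg.use_contrastive:
        ccfg = dataclasses.replace(
            cfg.contrastive,
            seed=cfg.seed,
            use_mlp_head=cfg.use_mlp_head,
            epochs=_epochs(cfg.contrastive_steps,
                           max(1, -(-expr.n_cells // cfg.contrastive.batch_size))),
        )
        Z, state = train_contrastive(
            expr.values, ccfg, init_encoder=model.encoder, loss_log=loss_log
        )
        stage2_encoder = state.query_encoder
        t0 = _stage(manifest, "contrastive", t0)

    pseudo, used_resolution = _leiden(Z, cfg, expr.n_cells)
    manifest["leiden_resolution"] = used_resolution
    density = compute_density(Z, k=min(cfg.density_k, expr.n_cells - 1))
    anchors = select_anchors(pseudo, density, anchor_fraction=cfg.anchor_fraction)
    manifest["n_pseudo_clusters"] = int(pseudo.max()) + 1
    t0 = _stage(manifest, "anchors", t0)

    if cfg.use_self_kd:
        kcfg = dataclasses.replace(
            cfg.kd,
            seed=cfg.seed,
            epochs_student=_epochs(cfg.student_steps,
                                   max(1, -(-expr.n_cells // cfg.kd.batch_size))),
        )
        teacher = train_teacher(stage2_encoder, anchors, expr.values, kcfg)
        assignment, _student = train_student(
            teacher, anchors, expr.values, kcfg, init_encoder=teacher.encoder
        )
        t0 = _stage(manifest, "distillation", t0)
    else:
        n_classes = int(pseudo.max()) + 1
        probs = np.zeros((expr.n_cells, n_classes))
        probs[np.arange(expr.n_cells), pseudo] = 1.0
        assignment = ClusterAssignment(hard_labels=pseudo, soft_probs=probs)

    report = None
    if raw.labels is not None:
        report = evaluate(assignment.hard_labels, np.asarray(raw.labels))
        manifest["metrics"] = report.to_dict()
    result = PipelineResult(
        assignment=assignment,
        anchors=anchors,
        embeddings=Z,
        report=report,
        manifest=manifest,
    )
    if cfg.output_dir is not None:
        _write_artifacts(result, expr, loss_log, Path(cfg.output_dir))
    return result


def _epochs(step_budget: int, steps_per_epoch: int) -> int:
    return max(1, round(step_budget / steps_per_epoch))


def _leiden(Z, cfg: PipelineConfig, n_cells: int):
    n_neighbors = min(cfg.leiden_neighbors, n_cells - 1)
    if cfg.leiden_resolution is None:
        return leiden_cluster_auto(Z, n_neighbors=n_neighbors, seed=cfg.seed)
    labels = leiden_cluster(
        Z, n_neighbors=n_neighbors, resolution=cfg.leiden_resolution, seed=cfg.seed
    )
    return labels, cfg.leiden_resolution


def _config_dict(cfg) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        return obj

    return conv(cfg)


def _write_artifacts(result: PipelineResult, expr, loss_log, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    pd.DataFrame(loss_log).to_csv(outdir / "loss_log.csv", index=False)
    n_classes = result.assignment.soft_probs.shape[1]
    table = pd.DataFrame(
        {
            "cell_id": expr.cell_ids,
            "pseudo_label": result.anchors.pseudo_labels,
            "density": result.anchors.density,
            "is_anchor": result.anchors.is_anchor,
            "final_label": result.assignment.hard_labels,
            "max_prob": result.assignment.soft_probs.max(axis=1),
        }
    )
    for c in range(n_classes):
        table[f"prob_{c}"] = result.assignment.soft_probs[:, c]
    table.to_csv(outdir / "assignments.csv", index=False)
    if result.report is not None:
        (outdir / "report.json").write_text(json.dumps(result.report.to_dict(), indent=2))
        pd.DataFrame(
            result.report.confusion,
            index=result.report.truth_classes,
            columns=result.report.pred_clusters,
        ).to_csv(outdir / "confusion.csv")
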