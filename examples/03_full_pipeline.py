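"""Run the full two-stage clustering pipeline on a synthetic preset.

Stage 1: ZINB denoising autoencoder + deep-embedded-clustering self-training,
then neighbourhood-enhanced momentum contrastive refinement. Stage 2: Leiden
pseudo-labels, density-ranked anchor cells, teacher-student self-distillation.
Prints the agreement between the final labels and the simulated ground truth.
"""

from scdistill import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n_clusters=3)
result = run_pipeline(cfg, simulate="easy3")

print("pseudo-clusters found by Leiden:", result.manifest["n_pseudo_clusters"])
print("anchors used for distillation:", int(result.anchors.is_anchor.sum()),
      "of", len(result.anchors.is_anchor), "cells")
rep = result.report.to_dict()
print(f"ARI {rep['ari']:.3f}  NMI {rep['nmi']:.3f}  AMI {rep['ami']:.3f}")
# ARI/NMI/AMI of 1.0 mean the recovered labelling matches the simulated cell
# types exactly up to renaming; the soft probabilities in
# result.assignment.soft_probs quantify per-cell confidence.
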