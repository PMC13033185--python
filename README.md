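# scdistill

Two-stage self-supervised clustering of single-cell RNA-seq count matrices,
for computational biologists who need cluster labels — including rare
subpopulations — from raw counts without annotation.

**Stage 1 — representation learning.** A denoising autoencoder reconstructs
the raw counts under a zero-inflated negative binomial likelihood

    ZINB(x | π, μ, θ) = π·δ₀(x) + (1−π)·NB(x | μ, θ),

with the decoder emitting the mean μ (scaled by per-cell size factors), the
dispersion θ and the dropout probability π. Deep-embedded-clustering
self-training sharpens the bottleneck: soft assignments
q_ij ∝ (1+‖z_i−c_j‖²)⁻¹ are pulled toward the target p_ij ∝ q_ij²/f_j via
L = L_ZINB + γ·KL(P‖Q). A momentum contrastive stage then refines the
embedding: a query encoder is trained against a slowly-moving key encoder
with a hybrid InfoNCE loss whose positives are both the cell's corrupted
view and the key embeddings of its k nearest expression-space neighbours,
plus an L1 sparsity term on the query representation.

**Stage 2 — label refinement.** Leiden community detection on the embedding
yields pseudo-labels; within each pseudo-cluster the top 40% of cells by
latent cosine density become anchor cells. A teacher (the trained encoder +
linear head, fitted on anchors by cross-entropy) supervises an identically
shaped student through the distillation loss
α·H(p, softmax(z_s/τ₁)) + (1−α)·τ₂²·KL(softmax(z_t/τ₂)‖softmax(z_s/τ₂));
the student's softmax is the final probabilistic cluster assignment.

Evaluation ships with the package: ARI, NMI, AMI and Hungarian-matched
per-class F1, plus a ZINB simulator with configurable rare subpopulations
that serves as the test substrate. See `docs/methods.md` for the full model
description and design rationale.

## Worked example

```python
from scdistill import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1, n_clusters=3), simulate="easy3")
rep = result.report.to_dict()
print(f"ARI {rep['ari']:.3f}  NMI {rep['nmi']:.3f}  AMI {rep['ami']:.3f}")
```

On the `easy3` preset (1,000 simulated cells, three balanced types, strong
markers, 30% dropout) this prints

```
ARI 1.000  NMI 1.000  AMI 1.000
```

meaning the recovered labels match the simulated cell types exactly up to
renaming. `result.assignment.soft_probs` holds per-cell class
probabilities, `result.anchors` the pseudo-labels, densities and the
anchor/refinement split. The scripts in `examples/` walk through each
capability (preprocessing, the ZINB likelihood, the full pipeline, rare-type
detection, ablations) and print what the numbers mean.

The same pipeline is available from a shell:

```bash
scdistill simulate --preset rare5 --seed 1 --out data/
scdistill run --input data/matrix.mtx --n-clusters 5 --out runs/rare5
scdistill run --simulate easy3 --no-contrastive --out runs/ablation
```

Input formats: MatrixMarket (genes × cells, with barcodes/features sidecars),
CSV (header = gene ids, first column = cell ids), or dense text. Ablation
switches (`--no-contrastive`, `--no-mlp-head`, `--no-self-kd`) remove the
corresponding stage; with everything off the pipeline reduces to Leiden on
the ZINB-autoencoder embedding.

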