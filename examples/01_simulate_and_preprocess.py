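"""Simulate a labelled scRNA-seq count matrix and run the preprocessing recipe.

Builds a 1,000-cell, 3-cluster ZINB count matrix, then applies the standard
recipe: drop genes seen in fewer than 3 cells, depth-normalise to 10,000
counts per cell with log1p, and keep the most variable genes.
"""

import numpy as np

from scdistill import preprocess, preset, simulate_counts

counts = simulate_counts(preset("easy3", seed=1))
zero_frac = 1 - np.count_nonzero(counts.dense()) / counts.dense().size
print(f"simulated {counts.n_cells} cells x {counts.n_genes} genes, "
      f"{zero_frac:.0%} zeros (dropout + sampling)")

expr, raw = preprocess(counts)
print(f"model input: {expr.values.shape[0]} cells x {expr.values.shape[1]} genes, "
      f"median size factor {np.median(expr.size_factors):.3f}")
# The size factor is each cell's library size over 10,000; the expression
# values are log1p of depth-corrected counts — the encoder's input space.
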