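"""Clean the count matrix: low-count filter, variance-stabilizing transform,
surrogate variables and covariate residualization.  The surrogate variables
should capture the simulated technical nuisance (batch, depth) so that
regressing them out leaves the biological module structure intact."""

import numpy as np
from common import example_config

from afcerna import (
    ExpressionDataset,
    estimate_svs,
    filter_low_counts,
    generate_dataset,
    preprocess_pipeline,
    vst_transform,
)

ds = generate_dataset(example_config(batch_effect_sd=2.0, depth_effect_sd=0.0))
full = ExpressionDataset(ds.train_counts, ds.biotypes, ds.phenotypes)

filtered = filter_low_counts(ds.train_counts, min_count=10, max_low_fraction=0.8)
print(f"low-count filter: {ds.train_counts.shape[0]} -> {filtered.shape[0]} genes")

vst = vst_transform(filtered)
svs = estimate_svs(vst, ds.phenotypes, n_sv=2)
batch = np.asarray(ds.truth["batch_indicator"])
r = np.corrcoef(svs[:, 0], batch)[0, 1]
print(f"|cor(SV1, simulated batch)| = {abs(r):.3f}  (close to 1: SV1 found the batch)")

cleaned, info = preprocess_pipeline(full, top_k=300)
print("cleaned matrix:", cleaned.matrix.shape,
      "| SVs regressed out:", info["n_sv"])
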