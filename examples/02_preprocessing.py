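"""Run the four-step missing-value pipeline on data with injected gaps.

One sample is given 60% missingness (an array failure), one CpG is masked
everywhere, and the rest of the matrix loses 2% of entries at random.  The
pipeline drops the dead CpG, removes the outlier sample chunk-wise via the
Tukey fence on missing counts, and median-imputes what remains.
"""

import methgen as mg

spec = mg.SyntheticSpec(
    n_conditions=3, n_cpgs=200, n_samples_per_condition=20, seed=7,
    mean_separation=0.2,
)
matrix, labels, _ = mg.generate_ground_truth(spec)
masked, mask = mg.inject_missing(
    matrix, missing_rate=0.02, outlier_samples=1, outlier_rate=0.6,
    seed=8, n_all_missing_cpgs=1,
)
print(f"injected: {mask.mask.sum()} missing entries; "
      f"outlier sample {mask.outlier_sample_ids}, "
      f"dead CpG {mask.all_missing_cpg_ids}")

chunked, chunk_labels, report = mg.preprocess_pipeline(masked, labels,
                                                       chunk_size=80)
print(f"chunks: {[c.n_cpgs for c in chunked.chunks]} CpGs each")
print(f"step 1 removed CpGs: {report.removed_cpgs}")
print(f"step 3 removed samples per chunk: "
      f"{[len(r) for r in report.removed_samples_per_chunk]}")
print(f"step 4 imputed values per chunk: {report.imputed_count_per_chunk}")
import numpy as np  # noqa: E402

print("no missing values remain:",
      not any(np.isnan(c.values).any() for c in chunked.chunks))
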