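"""Four-step missing-value preprocessing for 450K beta-value matrices.

High missingness biases generative-model training, so before any model is
fit the matrix passes through four steps, in order:

1. drop CpG sites missing in *all* samples;
2. split the remaining CpGs into consecutive chunks (default 10,000 CpGs)
   so that a sample missing values only in some chunks is still usable in
   the others;
3. within each chunk, discard samples whose missing-value count is a Tukey
   upper-fence outlier (count > Q3 + 1.5 * IQR of the per-sample counts);
4. impute every remaining missing entry with the median of its CpG's
   observed values within the chunk.

After the pipeline no chunk contains a missing value.  Non-missing entries
of retained cells are never altered.  Every removal and imputation is
recorded in a :class:`PreprocessReport`.

Notes on conventions (the method names only "the IQR method"): the fence is
one-sided — low missingness is not a defect — with the canonical whisker
1.5; quantiles use linear interpolation between order statistics (NumPy's
default, the "type 7" rule).  Median imputation pools all retained samples
of the chunk; per-condition (stratified) imputation is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BetaMatrix, ConditionVector

__all__ = [
    "ChunkedDataset",
    "PreprocessReport",
    "PreprocessError",
    "drop_all_missing_cpgs",
    "chunk_cpgs",
    "remove_outlier_samples_iqr",
    "impute_median",
    "preprocess_pipeline",
]


class PreprocessError(ValueError):
    pass


@dataclass
class ChunkedDataset:
    """Ordered disjoint consecutive CpG blocks, each its own BetaMatrix.

    All chunks except possibly the last hold exactly ``chunk_size`` CpGs.
    Sample sets may differ between chunks once outlier removal has run.
    """

    chunks: list[BetaMatrix]
    chunk_size: int

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise PreprocessError("chunk_size must be >= 1")
        for k, c in enumerate(self.chunks[:-1]):
            if c.n_cpgs != self.chunk_size:
                raise PreprocessError(
                    f"chunk {k} has {c.n_cpgs} CpGs, expected {self.chunk_size}"
                )
        if self.chunks and self.chunks[-1].n_cpgs > self.chunk_size:
            raise PreprocessError("last chunk exceeds chunk_size")

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)

    @property
    def cpg_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.chunks:
            out.extend(c.cpg_ids)
        return out


@dataclass
class PreprocessReport:
    """Audit trail of the four preprocessing steps."""

    removed_cpgs: list[str] = field(default_factory=list)
    removed_samples_per_chunk: list[list[str]] = field(default_factory=list)
    imputed_count_per_chunk: list[int] = field(default_factory=list)
    chunk_size: int = 10000
    whisker: float = 1.5

    @property
    def total_imputed(self) -> int:
        return sum(self.imputed_count_per_chunk)

    def to_dict(self) -> dict:
        return {
            "removed_cpgs": self.removed_cpgs,
            "removed_samples_per_chunk": self.removed_samples_per_chunk,
            "imputed_count_per_chunk": self.imputed_count_per_chunk,
            "chunk_size": self.chunk_size,
            "whisker": self.whisker,
        }


def drop_all_missing_cpgs(m: BetaMatrix) -> tuple[BetaMatrix, list[str]]:
    """Remove CpG columns whose entries are missing in every sample."""
    all_missing = np.isnan(m.values).all(axis=0) if m.n_samples else np.zeros(
        m.n_cpgs, dtype=bool
    )
    removed = [c for c, bad in zip(m.cpg_ids, all_missing) if bad]
    if len(removed) == m.n_cpgs and m.n_cpgs > 0:
        raise PreprocessError("no CpGs remain after removing all-missing sites")
    keep = np.flatnonzero(~all_missing)
    return m.subset_cpgs(keep), removed


def chunk_cpgs(m: BetaMatrix, chunk_size: int = 10000) -> ChunkedDataset:
    """Split CpG columns into consecutive blocks of ``chunk_size`` (input order)."""
    if chunk_size < 1:
        raise PreprocessError("chunk_size must be >= 1")
    chunks = [
        m.subset_cpgs(range(start, min(start + chunk_size, m.n_cpgs)))
        for start in range(0, m.n_cpgs, chunk_size)
    ]
    return ChunkedDataset(chunks, chunk_size)


def remove_outlier_samples_iqr(
    chunk: BetaMatrix, whisker: float = 1.5
) -> tuple[BetaMatrix, list[str]]:
    """Drop samples with outlying missing-value counts (Tukey upper fence).

    A sample is removed iff its within-chunk missing count exceeds
    ``Q3 + whisker * IQR`` of the per-sample counts (linear-interpolation
    quantiles).  With IQR = 0 the fence equals Q3, so only counts strictly
    above it go.
    """
    counts = np.isnan(chunk.values).sum(axis=1).astype(float)
    if counts.size == 0:
        return chunk.copy(), []
    q1, q3 = np.percentile(counts, [25, 75])
    fence = q3 + whisker * (q3 - q1)
    out = counts > fence
    if out.all():
        raise PreprocessError("no samples remain in chunk after IQR removal")
    removed = [s for s, bad in zip(chunk.sample_ids, out) if bad]
    return chunk.subset_samples(np.flatnonzero(~out)), removed


def impute_median(chunk: BetaMatrix) -> tuple[BetaMatrix, int]:
    """Replace each missing entry by its CpG's within-chunk observed median."""
    vals = chunk.values.copy()
    nan_mask = np.isnan(vals)
    n_imputed = int(nan_mask.sum())
    if n_imputed:
        if nan_mask.all(axis=0).any():
            bad = chunk.cpg_ids[int(np.flatnonzero(nan_mask.all(axis=0))[0])]
            raise PreprocessError(
                f"CpG {bad!r} has no observed values in this chunk; "
                "run drop_all_missing_cpgs / chunking first"
            )
        med = np.nanmedian(vals, axis=0)
        vals[nan_mask] = np.broadcast_to(med, vals.shape)[nan_mask]
    return BetaMatrix(list(chunk.sample_ids), list(chunk.cpg_ids), vals), n_imputed


def preprocess_pipeline(
    m: BetaMatrix,
    labels: ConditionVector,
    chunk_size: int = 10000,
    whisker: float = 1.5,
    stratify_imputation: bool = False,
) -> tuple[ChunkedDataset, list[ConditionVector], PreprocessReport]:
    """Run the full four-step pipeline; returns per-chunk data, labels, report.

    ``labels`` must align with ``m.sample_ids``; each returned chunk carries
    a ConditionVector restricted to its retained samples (shared vocabulary).

    Idempotent: a second run on the output changes nothing, because no
    missing values remain to trigger any step.
    """
    if labels.n_samples != m.n_samples:
        raise PreprocessError(
            f"labels ({labels.n_samples}) not aligned to matrix ({m.n_samples})"
        )
    filtered, removed_cpgs = drop_all_missing_cpgs(m)
    chunked = chunk_cpgs(filtered, chunk_size)
    report = PreprocessReport(
        removed_cpgs=removed_cpgs, chunk_size=chunk_size, whisker=whisker
    )
    out_chunks: list[BetaMatrix] = []
    out_labels: list[ConditionVector] = []
    for k, chunk in enumerate(chunked.chunks):
        try:
            kept, removed_samples = remove_outlier_samples_iqr(chunk, whisker)
            if stratify_imputation:
                keep_idx = [m.sample_ids.index(s) for s in kept.sample_ids]
                sub = labels.subset(keep_idx)
                kept, n_imp = _impute_median_stratified(kept, sub)
            else:
                kept, n_imp = impute_median(kept)
        except PreprocessError as e:
            raise PreprocessError(f"chunk {k}: {e}") from e
        keep_idx = [m.sample_ids.index(s) for s in kept.sample_ids]
        out_chunks.append(kept)
        out_labels.append(labels.subset(keep_idx))
        report.removed_samples_per_chunk.append(removed_samples)
        report.imputed_count_per_chunk.append(n_imp)
    return ChunkedDataset(out_chunks, chunk_size), out_labels, report


def _impute_median_stratified(
    chunk: BetaMatrix, labels: ConditionVector
) -> tuple[BetaMatrix, int]:
    # per-condition medians; falls back to the pooled median when a
    # condition has no observed value at a CpG
    vals = chunk.values.copy()
    nan_mask = np.isnan(vals)
    n_imputed = int(nan_mask.sum())
    if n_imputed == 0:
        return chunk.copy(), 0
    pooled = np.nanmedian(np.where(nan_mask, np.nan, vals), axis=0)
    if np.isnan(pooled).any():
        bad = chunk.cpg_ids[int(np.flatnonzero(np.isnan(pooled))[0])]
        raise PreprocessError(f"CpG {bad!r} has no observed values in this chunk")
    idx = labels.indices()
    for c in range(labels.n_conditions):
        rows = np.flatnonzero(idx == c)
        if rows.size == 0:
            continue
        block = vals[rows, :]
        bmask = nan_mask[rows, :]
        with np.errstate(all="ignore"):
            med = np.nanmedian(np.where(bmask, np.nan, block), axis=0)
        med = np.where(np.isnan(med), pooled, med)
        block[bmask] = np.broadcast_to(med, block.shape)[bmask]
        vals[rows, :] = block
    return BetaMatrix(list(chunk.sample_ids), list(chunk.cpg_ids), vals), n_imputed
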