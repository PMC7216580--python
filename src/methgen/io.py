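"""Reading, writing and validation of methylation beta-value matrices and labels.

The exchange type throughout the package is :class:`BetaMatrix` — a
samples x CpG-sites grid of beta values in [0, 1], stored as float64 with
``NaN`` marking missing entries — together with :class:`ConditionVector`,
the per-sample categorical condition (cancer type) with a fixed vocabulary.

Files are plain delimited text (TSV by default, CSV by extension or flag)
with one header row of CpG IDs and one leading column of sample IDs.
Values are kept at full double precision; clipping or imputation is never
done at I/O time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "ConditionVector",
    "BetaMatrixError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_labels",
    "write_labels",
]

DEFAULT_MISSING_TOKENS = frozenset({"NA", "NaN", "nan", ""})

#: slack allowed before a value outside [0, 1] is rejected
RANGE_TOLERANCE = 1e-9


class BetaMatrixError(ValueError):
    """Malformed or invalid beta-value data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise BetaMatrixError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class BetaMatrix:
    """Samples x CpGs methylation beta values; NaN marks a missing entry.

    Parameters
    ----------
    sample_ids : ordered unique sample identifiers (rows).
    cpg_ids : ordered unique CpG identifiers (columns).
    values : float64 array of shape ``(n_samples, n_cpgs)`` with every
        non-missing entry in ``[0, 1]``.
    """

    sample_ids: list[str]
    cpg_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.cpg_ids = list(self.cpg_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise BetaMatrixError("values must be a 2-D array")
        if self.values.shape != (len(self.sample_ids), len(self.cpg_ids)):
            raise BetaMatrixError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.cpg_ids)} CpGs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.cpg_ids, "CpG")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (
            finite.min() < -RANGE_TOLERANCE or finite.max() > 1 + RANGE_TOLERANCE
        ):
            bad = finite[(finite < -RANGE_TOLERANCE) | (finite > 1 + RANGE_TOLERANCE)]
            raise BetaMatrixError(
                f"beta values must lie in [0, 1]; found {bad[0]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(list(self.sample_ids), list(self.cpg_ids), self.values.copy())

    def subset_samples(self, keep: Sequence[int]) -> "BetaMatrix":
        keep = list(keep)
        return BetaMatrix(
            [self.sample_ids[i] for i in keep], list(self.cpg_ids), self.values[keep, :]
        )

    def subset_cpgs(self, keep: Sequence[int]) -> "BetaMatrix":
        keep = list(keep)
        return BetaMatrix(
            list(self.sample_ids), [self.cpg_ids[j] for j in keep], self.values[:, keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)


@dataclass
class ConditionVector:
    """Per-sample condition labels with a fixed, sorted vocabulary.

    ``one_hot`` rows are indicator encodings over ``vocabulary`` and each
    sums to exactly 1.
    """

    labels: list[str]
    vocabulary: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if self.vocabulary is None:
            self.vocabulary = sorted(set(self.labels))
        else:
            self.vocabulary = list(self.vocabulary)
        _check_unique(self.vocabulary, "condition")
        vocab = set(self.vocabulary)
        for lab in self.labels:
            if lab not in vocab:
                raise BetaMatrixError(
                    f"label {lab!r} not in vocabulary {self.vocabulary}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def n_conditions(self) -> int:
        return len(self.vocabulary)

    @property
    def one_hot(self) -> np.ndarray:
        idx = {c: k for k, c in enumerate(self.vocabulary)}
        out = np.zeros((len(self.labels), len(self.vocabulary)))
        for i, lab in enumerate(self.labels):
            out[i, idx[lab]] = 1.0
        return out

    def indices(self) -> np.ndarray:
        idx = {c: k for k, c in enumerate(self.vocabulary)}
        return np.array([idx[lab] for lab in self.labels], dtype=int)

    def encode(self, condition: str) -> np.ndarray:
        """One-hot vector for a single condition."""
        if condition not in self.vocabulary:
            raise BetaMatrixError(
                f"unknown condition {condition!r}; vocabulary: {self.vocabulary}"
            )
        vec = np.zeros(len(self.vocabulary))
        vec[self.vocabulary.index(condition)] = 1.0
        return vec

    @staticmethod
    def decode(one_hot: np.ndarray, vocabulary: Sequence[str]) -> list[str]:
        return [vocabulary[int(k)] for k in np.asarray(one_hot).argmax(axis=1)]

    def subset(self, keep: Sequence[int]) -> "ConditionVector":
        return ConditionVector([self.labels[i] for i in keep], list(self.vocabulary))


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_beta_matrix(
    path: str | Path,
    orientation: str = "samples-as-rows",
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    sep: str | None = None,
) -> BetaMatrix:
    """Read a delimited beta-value matrix into canonical samples-as-rows form.

    Parameters
    ----------
    orientation : ``"samples-as-rows"`` (the canonical layout) or
        ``"cpgs-as-rows"`` (transposed on read).
    missing_tokens : cell strings treated as missing (default NA/NaN/empty).

    Raises
    ------
    BetaMatrixError
        On a malformed numeric cell (naming its row and column), a value
        outside [0, 1] beyond 1e-9, or a duplicate ID.
    """
    path = Path(path)
    if orientation not in ("samples-as-rows", "cpgs-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    delim = _sep_for(path, sep)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delim)[1:]
    _check_unique(header, "header")  # pandas silently mangles duplicates
    df = pd.read_csv(path, sep=delim, index_col=0, dtype=str, keep_default_na=False)
    df.columns = header
    if orientation == "cpgs-as-rows":
        df = df.T
    missing = set(missing_tokens)
    values = np.empty(df.shape, dtype=np.float64)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell in missing:
                values[i, j] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise BetaMatrixError(
                    f"malformed numeric cell {cell!r} at sample "
                    f"{df.index[i]!r}, CpG {df.columns[j]!r} in {path}"
                ) from None
            if not math.isfinite(v) or v < -RANGE_TOLERANCE or v > 1 + RANGE_TOLERANCE:
                raise BetaMatrixError(
                    f"value {cell} outside [0, 1] at sample "
                    f"{df.index[i]!r}, CpG {df.columns[j]!r} in {path}"
                )
            values[i, j] = min(max(v, 0.0), 1.0)
    return BetaMatrix([str(s) for s in df.index], [str(c) for c in df.columns], values)


def write_beta_matrix(m: BetaMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write a matrix as delimited text, sample rows x CpG columns, missing as NA.

    Values are written at full round-trip precision.
    """
    path = Path(path)
    m.to_frame().to_csv(path, sep=_sep_for(path, sep), na_rep="NA")


def read_labels(
    path: str | Path, samples: Sequence[str], sep: str | None = None
) -> ConditionVector:
    """Read a two-column sample->condition mapping aligned to ``samples``.

    The vocabulary is the sorted set of conditions seen in the mapping.
    An optional header line ("sample<TAB>condition" or similar) is skipped.

    Raises
    ------
    BetaMatrixError
        If any requested sample is absent from the mapping (all missing
        IDs are listed).
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path, sep), header=None, dtype=str, keep_default_na=False
    )
    if df.shape[1] < 2:
        raise BetaMatrixError(f"label file {path} must have two columns")
    rows = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if rows and rows[0][0].lower() in ("sample", "sample_id", "id"):
        rows = rows[1:]
    mapping = {s.strip(): c.strip() for s, c in rows}
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise BetaMatrixError(f"samples missing from label mapping: {missing}")
    labels = [mapping[s] for s in samples]
    return ConditionVector(labels, sorted(set(mapping.values())))


def write_labels(labels: ConditionVector, sample_ids: Sequence[str],
                 path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    pd.DataFrame({"sample": list(sample_ids), "condition": labels.labels}).to_csv(
        path, sep=_sep_for(path, sep), index=False, header=False
    )
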