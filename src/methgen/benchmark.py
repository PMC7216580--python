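"""Per-CpG beta-distribution benchmark generator.

Beta values of a CpG site within one cancer type are modelled as draws
from a Beta(alpha, beta) distribution.  Fitting one (alpha, beta) pair per
(CpG, cancer type) cell gives a simple parametric generator to compare the
CVAE against: simulated samples are drawn cell-wise independently from the
fitted distributions.

Estimation is by the method of moments — closed form, fast over millions
of cells, and self-checking through the moment identities (the fitted
distribution's analytic mean and variance reproduce the clipped sample
moments exactly).  Maximum likelihood is available behind a flag.  Cells
where the moments are infeasible (v >= m(1-m)) or degenerate (v = 0), or
with fewer than ``min_n`` observations, receive a mean-preserving
high-concentration fallback Beta(m*kappa, (1-m)*kappa) and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, ConditionVector
from .preprocess import ChunkedDataset

__all__ = [
    "BetaParamTable",
    "BetaFitError",
    "DegenerateDistributionError",
    "MomentInfeasibleError",
    "fit_beta_mom",
    "fit_beta_mle",
    "fit_table",
    "sample_benchmark",
]

CLIP_EPS = 1e-6
FALLBACK_KAPPA = 1000.0


class BetaFitError(ValueError):
    pass


class DegenerateDistributionError(BetaFitError):
    """Zero sample variance: all observations identical."""


class MomentInfeasibleError(BetaFitError):
    """Sample variance >= m(1-m): no beta distribution matches the moments."""


@dataclass
class BetaParamTable:
    """Fitted Beta(alpha, beta) per (CpG, condition) with fit diagnostics.

    Backed by a DataFrame with columns cpg_id, condition, alpha, beta,
    n_obs, fit_method, fallback_used.
    """

    table: pd.DataFrame

    REQUIRED = ("cpg_id", "condition", "alpha", "beta", "n_obs",
                "fit_method", "fallback_used")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise BetaFitError(f"parameter table missing column {col!r}")
        if (self.table["alpha"] <= 0).any() or (self.table["beta"] <= 0).any():
            raise BetaFitError("alpha and beta must be strictly positive")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    @property
    def cpg_ids(self) -> list[str]:
        # first-appearance order
        return list(dict.fromkeys(self.table["cpg_id"]))

    def get(self, cpg_id: str, condition: str) -> tuple[float, float]:
        sub = self.table[
            (self.table["cpg_id"] == cpg_id) & (self.table["condition"] == condition)
        ]
        if sub.empty:
            raise KeyError((cpg_id, condition))
        row = sub.iloc[0]
        return float(row["alpha"]), float(row["beta"])

    def params_for(self, condition: str) -> pd.DataFrame:
        """alpha/beta rows of one condition, indexed by cpg_id, CpG order kept."""
        if condition not in set(self.table["condition"]):
            raise BetaFitError(
                f"unknown condition {condition!r}; table covers {self.conditions}"
            )
        sub = self.table[self.table["condition"] == condition].set_index("cpg_id")
        return sub.loc[self.cpg_ids]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BetaParamTable":
        return cls(pd.read_csv(path, sep="\t"))


def fit_beta_mom(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Method-of-moments Beta fit of observed values (clipped to (0, 1)).

    With sample mean m and variance v (ddof=1):
    ``alpha = m * (m(1-m)/v - 1)``, ``beta = (1-m) * (m(1-m)/v - 1)``.

    Raises
    ------
    DegenerateDistributionError
        If the sample variance is zero.
    MomentInfeasibleError
        If ``v >= m(1-m)`` so no beta distribution has these moments.
    """
    x = np.clip(np.asarray(values, dtype=np.float64), CLIP_EPS, 1.0 - CLIP_EPS)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise BetaFitError("need at least 2 observed values")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if v == 0.0:
        raise DegenerateDistributionError("zero sample variance")
    if v >= m * (1.0 - m):
        raise MomentInfeasibleError(
            f"variance {v:.4g} >= m(1-m) = {m * (1 - m):.4g}"
        )
    conc = m * (1.0 - m) / v - 1.0
    return m * conc, (1.0 - m) * conc


def fit_beta_mle(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta fit (location 0, scale 1 fixed)."""
    x = np.clip(np.asarray(values, dtype=np.float64), CLIP_EPS, 1.0 - CLIP_EPS)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise BetaFitError("need at least 2 observed values")
    a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    if not (a > 0 and b > 0):
        raise BetaFitError("MLE produced non-positive parameters")
    return float(a), float(b)


def _fallback_params(m: float) -> tuple[float, float]:
    m = min(max(m, CLIP_EPS), 1.0 - CLIP_EPS)
    return m * FALLBACK_KAPPA, (1.0 - m) * FALLBACK_KAPPA


def fit_table(
    data: BetaMatrix | ChunkedDataset,
    labels: ConditionVector | Sequence[ConditionVector],
    min_n: int = 3,
    method: str = "mom",
) -> BetaParamTable:
    """Fit one Beta(alpha, beta) entry per (CpG, condition) cell.

    Missing entries are excluded per cell (preprocessed data has none).
    Cells with < ``min_n`` observations, zero variance or infeasible
    moments get the mean-preserving fallback and ``fallback_used=True``.
    """
    if isinstance(data, ChunkedDataset):
        if isinstance(labels, ConditionVector):
            labels = [labels] * data.n_chunks
        frames = [
            _fit_matrix(chunk, lab, min_n, method)
            for chunk, lab in zip(data.chunks, labels)
        ]
        return BetaParamTable(pd.concat(frames, ignore_index=True))
    assert isinstance(labels, ConditionVector)
    return BetaParamTable(_fit_matrix(data, labels, min_n, method))


def _fit_matrix(
    m: BetaMatrix, labels: ConditionVector, min_n: int, method: str
) -> pd.DataFrame:
    if labels.n_samples != m.n_samples:
        raise BetaFitError("labels not aligned to matrix")
    if method not in ("mom", "mle"):
        raise BetaFitError(f"unknown fit method {method!r}")
    idx = labels.indices()
    rows: dict[str, list] = {c: [] for c in BetaParamTable.REQUIRED}
    for ci, cond in enumerate(labels.vocabulary):
        sel = np.flatnonzero(idx == ci)
        if sel.size == 0:
            raise BetaFitError(f"condition {cond!r} has zero samples")
        block = np.clip(m.values[sel, :], CLIP_EPS, 1.0 - CLIP_EPS)
        block[np.isnan(m.values[sel, :])] = np.nan
        n_obs = (~np.isnan(block)).sum(axis=0)
        with np.errstate(all="ignore"):
            mean = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=0)
            var = np.nanvar(block, axis=0, ddof=1)
        mean = np.where(np.isnan(mean), 0.5, mean)
        feasible = (
            (n_obs >= max(min_n, 2))
            & (var > 0)
            & ~np.isnan(var)
            & (var < mean * (1.0 - mean))
        )
        if method == "mom":
            with np.errstate(all="ignore"):
                conc = mean * (1.0 - mean) / var - 1.0
            alpha = np.where(feasible, mean * conc, 0.0)
            beta = np.where(feasible, (1.0 - mean) * conc, 0.0)
        else:
            alpha = np.zeros(m.n_cpgs)
            beta = np.zeros(m.n_cpgs)
            for j in np.flatnonzero(feasible):
                col = block[:, j]
                alpha[j], beta[j] = fit_beta_mle(col[~np.isnan(col)])
        fb_a, fb_b = np.vectorize(_fallback_params)(mean)
        alpha = np.where(feasible, alpha, fb_a)
        beta = np.where(feasible, beta, fb_b)
        rows["cpg_id"].extend(m.cpg_ids)
        rows["condition"].extend([cond] * m.n_cpgs)
        rows["alpha"].extend(alpha.tolist())
        rows["beta"].extend(beta.tolist())
        rows["n_obs"].extend(n_obs.astype(int).tolist())
        rows["fit_method"].extend(
            [method if ok else "fallback" for ok in feasible]
        )
        rows["fallback_used"].extend((~feasible).tolist())
    return pd.DataFrame(rows)


def sample_benchmark(
    table: BetaParamTable, condition: str, n_samples: int, seed: int = 0
) -> BetaMatrix:
    """Draw simulated methylomes cell-wise from the fitted beta table.

    Each entry is an independent Beta(alpha, beta) draw for its
    (CpG, condition) cell; reproducible under ``seed``.  ``n_samples=0``
    yields an empty matrix with the full CpG header.
    """
    params = table.params_for(condition)
    cpgs = list(params.index)
    alpha = params["alpha"].to_numpy(dtype=np.float64)
    beta = params["beta"].to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)
    if n_samples == 0:
        values = np.empty((0, len(cpgs)))
    else:
        values = rng.beta(alpha, beta, size=(n_samples, len(cpgs)))
        # keep the open interval even when tiny shapes round to 0/1
        values = np.clip(values, 1e-12, 1.0 - 1e-12)
    ids = [f"{condition}_bench_{k}" for k in range(n_samples)]
    return BetaMatrix(ids, cpgs, values)
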