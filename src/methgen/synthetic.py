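"""Ground-truth synthetic methylome datasets for testing and benchmarking.

Emulates the statistical structure of a multi-cancer 450K beta-value
matrix: every (CpG, condition) cell has its own generating Beta(alpha,
beta); *informative* CpGs give the conditions well-separated means while
uninformative CpGs share identical parameters across conditions.  Optional
missingness injection reproduces exactly what the preprocessing pipeline
targets: sporadic missing-completely-at-random entries, designated
high-missingness outlier samples, and all-missing CpG sites.

Generating parameters are built mean-first: a mean m and a concentration
c = alpha + beta are chosen, then alpha = m*c, beta = (1-m)*c, which makes
the mean separation between conditions directly controllable.  At an
informative CpG the conditions receive a random permutation of equally
spaced mean levels ``start + j * mean_separation``, so every pair of
conditions is separated by at least ``mean_separation`` there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .benchmark import BetaParamTable
from .io import BetaMatrix, ConditionVector

__all__ = ["SyntheticSpec", "MissingnessMask", "SyntheticError",
           "generate_ground_truth", "inject_missing"]

#: distance kept between the extreme mean levels and the [0, 1] boundary
MEAN_MARGIN = 0.02


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Design of a synthetic multi-condition methylome dataset.

    ``n_samples_per_condition`` may be one integer or a per-condition
    sequence (unequal class sizes).  ``mean_separation`` is the pairwise
    separation of condition means at informative CpGs;
    ``concentration_range`` bounds alpha + beta of the generating betas
    (larger = less noisy values).
    """

    n_conditions: int = 4
    n_cpgs: int = 200
    n_samples_per_condition: int | tuple[int, ...] = 150
    mean_separation: float = 0.3
    frac_informative: float = 1.0
    concentration_range: tuple[float, float] = (10.0, 50.0)
    missing_rate: float = 0.0
    outlier_samples: int = 0
    outlier_rate: float = 0.6
    seed: int = 0
    condition_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_conditions < 1 or self.n_cpgs < 0:
            raise SyntheticError("counts must be nonnegative, >=1 condition")
        if not (0.0 <= self.mean_separation <= 1.0):
            raise SyntheticError("mean_separation must lie in [0, 1]")
        if not (0.0 <= self.frac_informative <= 1.0):
            raise SyntheticError("frac_informative must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SyntheticError("missing_rate must lie in [0, 1)")
        lo, hi = self.concentration_range
        if lo <= 0 or hi < lo:
            raise SyntheticError("concentration_range must be positive and ordered")
        span = (self.n_conditions - 1) * self.mean_separation
        if self.frac_informative > 0 and span > 1.0 - 2 * MEAN_MARGIN:
            raise SyntheticError(
                f"mean_separation {self.mean_separation} infeasible for "
                f"{self.n_conditions} conditions: level span {span:.3f} exceeds "
                f"the unit interval"
            )

    @property
    def samples_per_condition(self) -> list[int]:
        if isinstance(self.n_samples_per_condition, int):
            return [self.n_samples_per_condition] * self.n_conditions
        counts = list(self.n_samples_per_condition)
        if len(counts) != self.n_conditions:
            raise SyntheticError("per-condition sample counts length mismatch")
        return counts

    @property
    def conditions(self) -> list[str]:
        if self.condition_names is not None:
            if len(self.condition_names) != self.n_conditions:
                raise SyntheticError("condition_names length mismatch")
            return list(self.condition_names)
        return [f"C{k:02d}" for k in range(self.n_conditions)]


@dataclass
class MissingnessMask:
    """Which entries were masked, and why — for oracle tests."""

    mask: np.ndarray  # boolean, samples x CpGs
    outlier_sample_ids: list[str] = field(default_factory=list)
    all_missing_cpg_ids: list[str] = field(default_factory=list)


def generate_ground_truth(
    spec: SyntheticSpec,
) -> tuple[BetaMatrix, ConditionVector, BetaParamTable]:
    """Draw a full dataset plus the true per-cell parameter table.

    The returned :class:`BetaParamTable` rows carry
    ``fit_method="ground_truth"`` and an ``informative`` column marking
    CpGs whose means were separated between conditions.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    conds = spec.conditions
    C, P = spec.n_conditions, spec.n_cpgs

    n_informative = int(round(spec.frac_informative * P))
    informative = np.zeros(P, dtype=bool)
    informative[rng.choice(P, size=n_informative, replace=False)] = True

    means = np.empty((C, P))
    span = (C - 1) * spec.mean_separation
    for j in range(P):
        if informative[j] and spec.mean_separation > 0:
            start = rng.uniform(MEAN_MARGIN, 1.0 - MEAN_MARGIN - span)
            levels = start + spec.mean_separation * np.arange(C)
            means[:, j] = levels[rng.permutation(C)]
        else:
            means[:, j] = rng.uniform(0.05, 0.95)
    conc = rng.uniform(*spec.concentration_range, size=P)
    alpha = means * conc  # (C, P)
    beta = (1.0 - means) * conc

    counts = spec.samples_per_condition
    sample_ids: list[str] = []
    labels: list[str] = []
    blocks = []
    for ci, cond in enumerate(conds):
        n = counts[ci]
        blocks.append(rng.beta(alpha[ci], beta[ci], size=(n, P)))
        sample_ids.extend(f"{cond}_s{k}" for k in range(n))
        labels.extend([cond] * n)
    values = (
        np.concatenate(blocks, axis=0) if blocks else np.empty((0, P))
    )
    values = np.clip(values, 1e-12, 1.0 - 1e-12)
    cpg_ids = [f"cg{j:06d}" for j in range(P)]
    matrix = BetaMatrix(sample_ids, cpg_ids, values)
    cond_vec = ConditionVector(labels, sorted(conds))

    table = pd.DataFrame(
        {
            "cpg_id": cpg_ids * C,
            "condition": np.repeat(conds, P),
            "alpha": alpha.ravel(),
            "beta": beta.ravel(),
            "n_obs": np.repeat(counts, P),
            "fit_method": "ground_truth",
            "fallback_used": False,
            "informative": np.tile(informative, C),
        }
    )
    return matrix, cond_vec, BetaParamTable(table)


def inject_missing(
    m: BetaMatrix,
    missing_rate: float,
    outlier_samples: int = 0,
    outlier_rate: float = 0.6,
    seed: int = 0,
    n_all_missing_cpgs: int = 0,
) -> tuple[BetaMatrix, MissingnessMask]:
    """Mask entries at random; optionally create outlier samples and
    all-missing CpG sites.

    Ordinary samples lose entries uniformly at ``missing_rate``; the
    ``outlier_samples`` randomly chosen samples lose them at the higher
    ``outlier_rate`` (exercising the IQR removal step);
    ``n_all_missing_cpgs`` randomly chosen CpGs are masked in every sample
    (exercising the all-missing drop).  Returns the masked matrix and the
    exact mask for oracle comparisons.
    """
    if not (0.0 <= missing_rate < 1.0) or not (0.0 <= outlier_rate < 1.0):
        raise SyntheticError("rates must lie in [0, 1)")
    if outlier_samples > 0 and outlier_rate <= missing_rate:
        raise SyntheticError("outlier_rate must exceed missing_rate")
    if outlier_samples > m.n_samples:
        raise SyntheticError(
            f"outlier_samples {outlier_samples} exceeds sample count {m.n_samples}"
        )
    if n_all_missing_cpgs > m.n_cpgs:
        raise SyntheticError("n_all_missing_cpgs exceeds CpG count")
    rng = np.random.default_rng(seed)
    rates = np.full(m.n_samples, missing_rate)
    out_idx = rng.choice(m.n_samples, size=outlier_samples, replace=False)
    rates[out_idx] = outlier_rate
    mask = rng.random((m.n_samples, m.n_cpgs)) < rates[:, None]
    cpg_idx = rng.choice(m.n_cpgs, size=n_all_missing_cpgs, replace=False)
    mask[:, cpg_idx] = True
    values = m.values.copy()
    values[mask] = np.nan
    return (
        BetaMatrix(list(m.sample_ids), list(m.cpg_ids), values),
        MissingnessMask(
            mask=mask,
            outlier_sample_ids=[m.sample_ids[i] for i in sorted(out_idx)],
            all_missing_cpg_ids=[m.cpg_ids[j] for j in sorted(cpg_idx)],
        ),
    )
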