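"""Independent oracles: naive reimplementations used only to check methgen.

Everything here is deliberately written from the rule statements, not from
the package code — plain loops, no shared helpers — so agreement between
the two is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, stats


def kl_quadrature(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL[N(mu, diag exp(logvar)) || N(0, I)] by numerical integration.

    The divergence separates over coordinates; each 1-D term is
    integrated as E_q[log q(x) - log p(x)].
    """
    total = 0.0
    for m, lv in zip(np.atleast_1d(mu), np.atleast_1d(logvar)):
        s = math.sqrt(math.exp(lv))
        q = stats.norm(m, s)
        p = stats.norm(0.0, 1.0)

        def integrand(x, q=q, p=p):
            return q.pdf(x) * (q.logpdf(x) - p.logpdf(x))

        val, _ = integrate.quad(integrand, m - 12 * s, m + 12 * s, limit=200)
        total += val
    return total


def _quantile_type7(sorted_vals: list[float], q: float) -> float:
    """Linear interpolation between order statistics (R type 7)."""
    n = len(sorted_vals)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def naive_preprocess(
    values: np.ndarray,
    sample_ids: list[str],
    cpg_ids: list[str],
    chunk_size: int,
    whisker: float = 1.5,
):
    """Direct four-rule implementation on a raw value grid (NaN = missing).

    Returns (removed_cpg_ids, per-chunk dicts with kept sample ids, the
    imputed chunk value grid and the list of kept cpg ids).
    """
    n_samples, n_cpgs = values.shape
    # rule 1: drop CpGs missing everywhere
    removed_cpgs = []
    kept_cols = []
    for j in range(n_cpgs):
        if all(math.isnan(values[i, j]) for i in range(n_samples)):
            removed_cpgs.append(cpg_ids[j])
        else:
            kept_cols.append(j)
    # rule 2: consecutive chunks of chunk_size
    chunks = []
    for start in range(0, len(kept_cols), chunk_size):
        cols = kept_cols[start : start + chunk_size]
        # rule 3: Tukey upper fence on per-sample missing counts
        counts = [
            sum(math.isnan(values[i, j]) for j in cols) for i in range(n_samples)
        ]
        sc = sorted(float(c) for c in counts)
        q1 = _quantile_type7(sc, 0.25)
        q3 = _quantile_type7(sc, 0.75)
        fence = q3 + whisker * (q3 - q1)
        kept_rows = [i for i in range(n_samples) if counts[i] <= fence]
        removed_rows = [sample_ids[i] for i in range(n_samples) if counts[i] > fence]
        # rule 4: per-CpG median imputation over kept samples
        grid = np.empty((len(kept_rows), len(cols)))
        for cj, j in enumerate(cols):
            observed = sorted(
                values[i, j] for i in kept_rows if not math.isnan(values[i, j])
            )
            med = _quantile_type7(observed, 0.5)
            for ri, i in enumerate(kept_rows):
                v = values[i, j]
                grid[ri, cj] = med if math.isnan(v) else v
        chunks.append(
            {
                "sample_ids": [sample_ids[i] for i in kept_rows],
                "removed_sample_ids": removed_rows,
                "cpg_ids": [cpg_ids[j] for j in cols],
                "values": grid,
            }
        )
    return removed_cpgs, chunks


def auc_pair_counting(pos_scores, neg_scores) -> float:
    """AUC by exhaustive positive-negative pair comparison (ties = 1/2)."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
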