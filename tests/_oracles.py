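"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths (cumulative sums,
searchsorted windows, statsmodels GLM) so agreement is informative.
"""

from __future__ import annotations

import numpy as np


def brute_force_window_score(
    positions: np.ndarray,
    het_values: np.ndarray,
    focal_pos: int,
    half_width: int,
) -> float:
    """Scan every SNP on the contig; sum 2p(1-p) inside the window,
    excluding the focal position itself."""
    total = 0.0
    for p, h in zip(positions, het_values):
        if p == focal_pos:
            continue
        if abs(int(p) - int(focal_pos)) <= half_width:
            total += float(h)
    return total


def brute_force_indel_proximity(
    snp_positions: list[int], indel_positions: list[int], distance: int
) -> float:
    """All-pairs distance scan."""
    if not snp_positions:
        raise ValueError("no SNPs")
    near = 0
    for s in snp_positions:
        if any(abs(s - i) <= distance for i in indel_positions):
            near += 1
    return near / len(snp_positions)


def irls_logit_fit(
    bins: np.ndarray,
    successes: np.ndarray,
    trials: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 500,
) -> tuple[float, float]:
    """Hand-written Newton-Raphson IRLS for the binomial-logit regression of
    successes/trials on bin index. Returns (intercept, slope)."""
    X = np.column_stack([np.ones_like(bins, dtype=float), bins.astype(float)])
    y = successes.astype(float)
    n = trials.astype(float)
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - n * mu) / w
        xtw = X.T * w
        new = np.linalg.solve(xtw @ X, xtw @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return float(beta[0]), float(beta[1])


def random_nondegenerate_table(
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A small random (bins, successes, trials) table with a well-defined,
    non-separated MLE."""
    while True:
        n_bins = int(rng.integers(3, 11))
        bins = np.sort(rng.choice(np.arange(1, 31), n_bins, replace=False))
        trials = rng.integers(50, 500, n_bins)
        slope = rng.uniform(-0.15, 0.15)
        intercept = rng.uniform(-4.0, -1.0)
        p = 1.0 / (1.0 + np.exp(-(intercept + slope * bins)))
        successes = rng.binomial(trials, p)
        total_s = successes.sum()
        if total_s == 0 or (successes == trials).all():
            continue
        if (successes == 0).sum() > n_bins - 2:
            continue
        return bins, successes, trials
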