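"""Weighted beta-binomial estimation of sequencing proportions and the base t-test.

The sequencing proportion p of an RNA species is modelled as beta
distributed, Beta(α, β); the observed per-replicate proportion p_j adds
binomial sampling noise whose size depends on the replicate's library
count n_j.  The estimator combines replicates with weights w_j (Σw_j = 1)
chosen inversely proportional to each replicate's total variance

    V_j = σ_b² + p(1−p)/n_j

where σ_b² = p(1−p)/(α+β+1) is the between-replicate (beta) variance.
Weights, mean, variance components and method-of-moments (α, β) are
iterated to a fixed point; the converged weights are exactly the
variance-minimizing weights for the converged V_j on the simplex.

Small counts make replicate proportions nearly identical, collapsing the
estimated variance and inflating t.  A closed-form floor (a binomial
variance at a +1-shifted proportion) bounds the final variance from
below; the reported variance is the larger of the iterated estimate and
the floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BetaBinomialEstimate",
    "estimate_weighted",
    "estimate_weighted_many",
    "variance_floor",
    "final_variance",
    "t_statistic",
    "p_value",
]

_AB_DEGENERATE = 1e12  # alpha+beta when the between-replicate variance is 0


@dataclass
class BetaBinomialEstimate:
    """Per-feature, per-condition weighted beta-binomial estimate."""

    p_hat: float
    v_hat: float
    alpha_hat: float
    beta_hat: float
    weights: np.ndarray
    n_iter: int
    converged: bool
    sigma_b2: float = 0.0
    rep_variances: np.ndarray | None = None


def estimate_weighted_many(
    props: np.ndarray,
    library_sizes: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict[str, np.ndarray]:
    """Vectorized weighted estimation for many features at once.

    Parameters
    ----------
    props : (F, m) per-replicate proportions in [0, 1]
    library_sizes : (F, m) or (m,) positive totals behind each proportion

    Returns a dict of arrays: ``p_hat, v_hat, alpha_hat, beta_hat (F,)``,
    ``weights, rep_variances (F, m)``, ``sigma_b2, n_iter (F,)``,
    ``converged (F,) bool``.
    """
    P = np.atleast_2d(np.asarray(props, dtype=float))
    F, m = P.shape
    if m < 2:
        raise ValueError("need >= 2 replicates")
    if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
        raise ValueError("proportions must lie in [0, 1]")
    P = np.clip(P, 0.0, 1.0)
    N = np.broadcast_to(np.asarray(library_sizes, dtype=float), P.shape).copy()
    N = np.maximum(N, 1.0)

    w = np.full((F, m), 1.0 / m)
    n_iter = np.zeros(F, dtype=int)
    converged = np.zeros(F, dtype=bool)

    def _components(w: np.ndarray):
        p_hat = (w * P).sum(axis=1)
        denom = 1.0 - (w**2).sum(axis=1)
        denom = np.where(denom <= 1e-12, 1e-12, denom)
        s2 = (w * (P - p_hat[:, None]) ** 2).sum(axis=1) / denom
        b = (p_hat * (1.0 - p_hat))[:, None] / N
        sigma_b2 = np.maximum(s2 - (w * b).sum(axis=1), 0.0)
        V = sigma_b2[:, None] + b
        return p_hat, s2, b, sigma_b2, V

    for it in range(1, max_iter + 1):
        p_hat, s2, b, sigma_b2, V = _components(w)
        with np.errstate(divide="ignore"):
            inv = np.where(V > 0, 1.0 / np.where(V > 0, V, 1.0), 0.0)
        tot = inv.sum(axis=1, keepdims=True)
        w_new = np.where(tot > 0, inv / np.where(tot > 0, tot, 1.0), 1.0 / m)
        delta = np.abs(w_new - w).max(axis=1)
        newly = (~converged) & (delta < tol)
        n_iter[newly] = it
        converged |= newly
        w = np.where(converged[:, None], w, w_new)
        if converged.all():
            break
    n_iter[~converged] = max_iter

    # fall back to equal weights + plain unbiased estimates where not converged
    if not converged.all():
        w[~converged] = 1.0 / m
    p_hat, s2, b, sigma_b2, V = _components(w)
    v_hat = (w**2 * V).sum(axis=1)
    plain_v = s2 / m  # variance of the unweighted mean
    v_hat = np.where(converged, v_hat, plain_v)
    # identical proportions: zero variance; the Eq-floor takes over downstream
    degenerate = s2 <= 0.0
    v_hat = np.where(degenerate, 0.0, v_hat)

    pq = p_hat * (1.0 - p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(sigma_b2 > 0, pq / np.where(sigma_b2 > 0, sigma_b2, 1.0) - 1.0, _AB_DEGENERATE)
    ab = np.clip(ab, 1e-8, _AB_DEGENERATE)
    alpha_hat = np.clip(p_hat * ab, 1e-12, None)
    beta_hat = np.clip((1.0 - p_hat) * ab, 1e-12, None)

    return {
        "p_hat": p_hat,
        "v_hat": v_hat,
        "alpha_hat": alpha_hat,
        "beta_hat": beta_hat,
        "weights": w,
        "rep_variances": V,
        "sigma_b2": sigma_b2,
        "n_iter": n_iter,
        "converged": converged,
    }


def estimate_weighted(
    props: np.ndarray,
    library_sizes: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> BetaBinomialEstimate:
    """Weighted beta-binomial estimate for a single feature in one condition."""
    out = estimate_weighted_many(
        np.atleast_2d(props), library_sizes, tol=tol, max_iter=max_iter
    )
    return BetaBinomialEstimate(
        p_hat=float(out["p_hat"][0]),
        v_hat=float(out["v_hat"][0]),
        alpha_hat=float(out["alpha_hat"][0]),
        beta_hat=float(out["beta_hat"][0]),
        weights=out["weights"][0],
        n_iter=int(out["n_iter"][0]),
        converged=bool(out["converged"][0]),
        sigma_b2=float(out["sigma_b2"][0]),
        rep_variances=out["rep_variances"][0],
    )


def variance_floor(X_gi: float, X_g: float) -> float:
    """Lower bound for the proportion variance of one feature.

    ``(1/X_g) * q * (1 - q)`` with ``q = (1 + X_gi)/X_g``, where X_gi is
    the feature's total count and X_g the gene's total count in the
    condition.  At X_gi = 0 this equals ``(1/X_g²)(1 − 1/X_g)``, strictly
    positive for X_g ≥ 2, so floored variances never vanish.
    """
    if X_g <= 0:
        raise ValueError("X_g must be >= 1 (all-zero gene should be excluded)")
    if X_gi < 0 or X_gi > X_g:
        raise ValueError("require 0 <= X_gi <= X_g")
    q = (1.0 + X_gi) / X_g
    return (q * (1.0 - q)) / X_g


def variance_floor_many(X_gi: np.ndarray, X_g: float) -> np.ndarray:
    """Vectorized :func:`variance_floor` for all features of one gene."""
    if X_g <= 0:
        raise ValueError("X_g must be >= 1")
    q = (1.0 + np.asarray(X_gi, dtype=float)) / X_g
    return q * (1.0 - q) / X_g


def final_variance(est: BetaBinomialEstimate, floor: float) -> float:
    """The larger of the iterated variance estimate and the closed-form floor."""
    return max(est.v_hat, floor)


def t_statistic(estA: BetaBinomialEstimate, estB: BetaBinomialEstimate) -> float:
    """Baggerly-style t: (p̂_A − p̂_B)/sqrt(V̂_A + V̂_B).

    Variances should already be floored; both zero is impossible once
    the floor applies (it is positive for any gene with total count ≥ 2).
    """
    denom = np.sqrt(estA.v_hat + estB.v_hat)
    if denom == 0:
        raise ValueError("zero combined variance; apply the variance floor first")
    return float((estA.p_hat - estB.p_hat) / denom)


def p_value(t: float, m_A: int, m_B: int) -> float:
    """Two-sided Student-t tail probability with df = m_A + m_B − 2."""
    df = m_A + m_B - 2
    if df < 1:
        raise ValueError(f"degrees of freedom {df} < 1")
    return float(2.0 * stats.t.sf(np.abs(t), df))
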