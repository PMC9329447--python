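"""Calibration of the null threshold ω_α by repeated null simulation.

ω_α answers: how large does ρ get by chance among the features a plain
beta t-test would (falsely) call significant at level α?  It is
estimated by

1. refitting each feature's counts with a moment-matched negative
   binomial on the pooled (both-condition) data and drawing a fresh
   null table with the same layout and no condition effect;
2. running the un-inflated beta t-test (ρ = ω = 1) on the null table;
3. collecting the ρ values of the K features with p < α;
4. taking the 85 % point of those ρ sorted ascending (k′/K ≥ 0.85),
   their mean when 0 < K < 7, or the maximum ρ over all features when
   K = 0;
5. averaging over s independent null simulations.

Dividing an observed ρ by ω_α therefore shrinks everything a null
experiment could plausibly produce and inflates only stronger signals.
ω grows as replicate counts shrink, mirroring the rising chance of
spurious data gaps in small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .count_model import CountTable
from .differential import base_statistics

__all__ = [
    "OmegaEstimate",
    "simulate_null_like",
    "select_rho_alpha",
    "rho_alpha_one_sim",
    "estimate_omega",
]

_POISSON_SIZE = 1e6  # NB size used when the moment fit is under-dispersed


@dataclass
class OmegaEstimate:
    omega: float
    alpha: float
    s: int
    rho_alpha_per_sim: np.ndarray
    quantile_rule: list[str] = field(default_factory=list)
    level: str = "isoform"


def simulate_null_like(
    table: CountTable, seed: int | np.random.Generator | None = None
) -> CountTable:
    """Draw a no-effect count table shaped like the input.

    Per feature, a negative binomial is moment-matched on the pooled
    counts of both conditions (mean μ̂; size μ̂²/(v̂ − μ̂)); fresh counts
    are drawn for every sample from that single null distribution.
    Under-dispersed fits (v̂ ≤ μ̂) fall back to a near-Poisson draw
    (size 10⁶); all-zero features stay all-zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.counts
    mu = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        size = np.where(var > mu, mu**2 / np.where(var > mu, var - mu, 1.0), _POISSON_SIZE)
    size = np.clip(size, 1e-8, _POISSON_SIZE)
    p = size / (size + np.maximum(mu, 1e-12))
    n_samples = counts.shape[1]
    out = rng.negative_binomial(
        size[:, None], p[:, None], size=(counts.shape[0], n_samples)
    ).astype(float)
    out[mu == 0] = 0.0
    return CountTable(
        table.gene_ids,
        table.feature_ids,
        out,
        table.samples,
        table.sample_condition,
        table.feature_kind,
    )


def select_rho_alpha(rho: np.ndarray, significant: np.ndarray) -> tuple[float, str]:
    """Apply the K-dependent selection rule to one null run's ρ values.

    ``significant`` flags the features with p < α from the un-inflated
    test.  K ≥ 7: the ρ at the smallest order index k′ with
    k′/K ≥ 0.85 among the significant features sorted ascending;
    0 < K < 7: their mean; K = 0: the maximum ρ over all features.
    """
    rho = np.asarray(rho, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    if rho.size == 0:
        raise ValueError("empty table")
    K = int(significant.sum())
    if K == 0:
        return float(rho.max()), "max_when_empty"
    if K < 7:
        return float(rho[significant].mean()), "mean_small_K"
    ordered = np.sort(rho[significant])
    k_prime = int(np.ceil(0.85 * K))  # smallest k' with k'/K >= 0.85
    return float(ordered[k_prime - 1]), "q85"


def rho_alpha_one_sim(
    null_table: CountTable,
    alpha: float = 0.05,
    level: str = "isoform",
    variance_mode: str = "sample",
    zeta_transform: str = "none",
) -> tuple[float, str]:
    """Null ρ(α) from one simulated table; returns ``(rho_alpha, rule)``.

    ``rule`` records which branch applied: ``"q85"`` (K ≥ 7, 85 %
    order statistic), ``"mean_small_K"`` (0 < K < 7) or
    ``"max_when_empty"`` (K = 0, maximum ρ over all features).
    """
    if null_table.n_features == 0:
        raise ValueError("empty table")
    base = base_statistics(null_table, level, variance_mode, zeta_transform)
    return select_rho_alpha(
        base["rho"].to_numpy(), base["p_raw"].to_numpy() < alpha
    )


def estimate_omega(
    table: CountTable,
    alpha: float = 0.05,
    s: int = 10,
    seed: int | None = None,
    level: str = "isoform",
    variance_mode: str = "sample",
    zeta_transform: str = "none",
) -> OmegaEstimate:
    """ω_α as the mean of ρ(α) over ``s`` independent null simulations.

    Per-simulation generators are spawned from ``seed`` so a fixed seed
    reproduces ω exactly while simulations stay mutually independent.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    children = np.random.SeedSequence(seed).spawn(s)
    rhos = np.empty(s)
    rules: list[str] = []
    for r, child in enumerate(children):
        null_table = simulate_null_like(table, np.random.default_rng(child))
        rhos[r], rule = rho_alpha_one_sim(
            null_table, alpha, level, variance_mode, zeta_transform
        )
        rules.append(rule)
    return OmegaEstimate(
        omega=float(rhos.mean()),
        alpha=alpha,
        s=s,
        rho_alpha_per_sim=rhos,
        quantile_rule=rules,
        level=level,
    )
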