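"""Negative-binomial scenario generators and small-sample experiments.

All generators parameterize the negative binomial by (mean μ, size s),
i.e. variance μ + μ²/s — the convention of R's ``rnbinom(mu=, size=)``.

``simulate_counts`` builds a two-condition count table with planted
effects: an affected feature's mean is shifted by τ = U·A (U uniform on
(0, 1], A the effect level, e.g. 100 or 300) in one randomly chosen
condition, so effect sizes are linearly distributed from just above 0 up
to A.  Technical outliers are injected afterwards by multiplying
selected cells by a Uniform[5, 10] factor.

``gap_experiment`` and ``variance_experiment`` reproduce the two
small-sample pathologies that motivate the ρ statistic: the probability
of a spurious range gap between conditions, and the erratic variance of
tiny replicate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .count_model import CountTable

__all__ = [
    "Scenario",
    "SimulatedDataset",
    "VarianceSummary",
    "simulate_counts",
    "inject_outliers",
    "gap_experiment",
    "variance_experiment",
]


@dataclass
class Scenario:
    """Design of one simulated two-condition experiment.

    Defaults mirror the standard benchmark conditions: 3 replicates per
    condition, 10 % affected features at effect level A = 100, 30 %
    outlier cells.  ``features_per_gene`` may be an int or an inclusive
    ``(low, high)`` range sampled uniformly per gene.  ``baseline`` is
    an optional sequence of per-feature (μ, size) pairs; absent a
    template, μ ~ LogUniform[10, 5000] and size ~ Uniform[5, 100].
    """

    n_genes: int = 1000
    features_per_gene: int | tuple[int, int] = 2
    baseline: list[tuple[float, float]] | None = None
    effect_level: float = 100.0
    affected_fraction: float = 0.1
    outlier_fraction: float = 0.3
    outlier_mode: str = "feature"
    reps_per_condition: int | tuple[int, int] = 3
    feature_kind: str = "isoform"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must lie in [0, 1]")
        if self.effect_level <= 0:
            raise ValueError("effect_level must be positive")
        if self.outlier_mode not in ("feature", "cell"):
            raise ValueError("outlier_mode must be 'feature' or 'cell'")


@dataclass
class SimulatedDataset:
    """A simulated table plus its ground truth (affected flag, signed τ)."""

    table: CountTable
    truth: pd.DataFrame  # gene_id, feature_id, affected, tau, shifted_condition
    outlier_mask: np.ndarray | None = field(default=None, repr=False)


@dataclass
class VarianceSummary:
    fraction_small_sample_smaller: float
    sorted_variances_small: np.ndarray
    sorted_variances_large: np.ndarray
    n_experiments: int


def _nb_draw(rng: np.random.Generator, mu, size, shape) -> np.ndarray:
    mu = np.broadcast_to(np.asarray(mu, dtype=float), shape)
    size = np.broadcast_to(np.asarray(size, dtype=float), shape)
    p = size / (size + np.maximum(mu, 1e-12))
    out = rng.negative_binomial(size, p, size=shape).astype(float)
    return np.where(mu == 0, 0.0, out)


def simulate_counts(scenario: Scenario) -> SimulatedDataset:
    """Generate a two-condition dataset with planted differential features.

    Unaffected features are NB(μ, s) in both conditions; each affected
    feature is NB(μ + τ, s) in one fair-coin-chosen condition with
    τ = U·A.  Outliers are injected afterwards into
    ``outlier_fraction`` of feature × replicate cells.
    """
    rng = np.random.default_rng(scenario.seed)
    if isinstance(scenario.features_per_gene, tuple):
        lo, hi = scenario.features_per_gene
        n_per_gene = rng.integers(lo, hi + 1, scenario.n_genes)
    else:
        n_per_gene = np.full(scenario.n_genes, scenario.features_per_gene, dtype=int)
    F = int(n_per_gene.sum())
    gene_ids = np.repeat([f"g{i}" for i in range(scenario.n_genes)], n_per_gene)
    feature_ids = np.concatenate(
        [[f"g{i}.f{k}" for k in range(n)] for i, n in enumerate(n_per_gene)]
    )

    if scenario.baseline is not None:
        base = np.asarray(scenario.baseline, dtype=float)
        if base.shape != (F, 2):
            raise ValueError(f"baseline must provide (mu, size) for all {F} features")
        mu, size = base[:, 0], base[:, 1]
    else:
        mu = np.exp(rng.uniform(np.log(10.0), np.log(5000.0), F))
        size = rng.uniform(5.0, 100.0, F)

    if isinstance(scenario.reps_per_condition, tuple):
        m_A, m_B = scenario.reps_per_condition
    else:
        m_A = m_B = scenario.reps_per_condition

    affected = rng.random(F) < scenario.affected_fraction
    tau = np.where(affected, rng.uniform(0.0, 1.0, F) * scenario.effect_level, 0.0)
    tau = np.where(affected & (tau == 0.0), scenario.effect_level * 1e-9, tau)  # U in (0,1]
    shift_in_A = rng.random(F) < 0.5

    mu_A = mu + np.where(affected & shift_in_A, tau, 0.0)
    mu_B = mu + np.where(affected & ~shift_in_A, tau, 0.0)
    counts = np.hstack(
        [
            _nb_draw(rng, mu_A[:, None], size[:, None], (F, m_A)),
            _nb_draw(rng, mu_B[:, None], size[:, None], (F, m_B)),
        ]
    )
    samples = [f"A{j + 1}" for j in range(m_A)] + [f"B{j + 1}" for j in range(m_B)]
    design = {s: s[0] for s in samples}
    table = CountTable(gene_ids, feature_ids, counts, samples, design, scenario.feature_kind)

    mask = None
    if scenario.outlier_fraction > 0:
        table, mask = inject_outliers(
            table, scenario.outlier_fraction, rng, mode=scenario.outlier_mode
        )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "feature_id": feature_ids,
            "affected": affected,
            "tau": np.where(shift_in_A, tau, -tau) * affected,
            "shifted_condition": np.where(affected, np.where(shift_in_A, "A", "B"), ""),
        }
    )
    return SimulatedDataset(table=table, truth=truth, outlier_mask=mask)


def inject_outliers(
    table: CountTable,
    fraction: float,
    seed: int | np.random.Generator | None = None,
    mode: str = "cell",
) -> tuple[CountTable, np.ndarray]:
    """Multiply selected cells by Uniform[5, 10], rounded.

    ``mode="cell"`` selects a random ``fraction`` of all feature ×
    replicate cells independently.  ``mode="feature"`` — the technical-
    outlier model used by the benchmark scenarios — selects a
    ``fraction`` of features and corrupts exactly one randomly chosen
    replicate cell in each, mimicking a single aberrant library
    measurement.  Returns the modified table and the boolean selection
    mask; positive counts in selected cells strictly increase.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "feature":
        F, S = table.counts.shape
        mask = np.zeros((F, S), dtype=bool)
        rows = np.where(rng.random(F) < fraction)[0]
        mask[rows, rng.integers(0, S, rows.size)] = True
    elif mode == "cell":
        mask = rng.random(table.counts.shape) < fraction if fraction < 1 else np.ones(
            table.counts.shape, dtype=bool
        )
    else:
        raise ValueError("mode must be 'cell' or 'feature'")
    factors = rng.uniform(5.0, 10.0, table.counts.shape)
    counts = np.where(mask, np.round(table.counts * factors), table.counts)
    return (
        CountTable(
            table.gene_ids,
            table.feature_ids,
            counts,
            table.samples,
            table.sample_condition,
            table.feature_kind,
        ),
        mask,
    )


def gap_experiment(
    n_experiments: int,
    reps: int,
    E: float,
    mu: float = 100.0,
    size: float = 50.0,
    seed: int | None = None,
) -> float:
    """Fraction of experiments with a strict range gap between conditions.

    Each experiment draws ``reps`` counts from NB(μ, size) for one
    condition and NB(μ + E, size) for the other (which condition carries
    the shift is a fair coin); a gap means one sample's maximum falls
    strictly below the other's minimum.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    base = _nb_draw(rng, mu, size, (n_experiments, reps))
    shifted = _nb_draw(rng, mu + E, size, (n_experiments, reps))
    flip = rng.random(n_experiments) < 0.5
    A = np.where(flip[:, None], shifted, base)
    B = np.where(flip[:, None], base, shifted)
    gap = (A.max(axis=1) < B.min(axis=1)) | (B.max(axis=1) < A.min(axis=1))
    return float(gap.mean())


def variance_experiment(
    n_experiments: int,
    mu: float = 100.0,
    size: float = 50.0,
    seed: int | None = None,
    reps_small: int = 4,
    reps_large: int = 15,
) -> VarianceSummary:
    """Compare sample variances of small vs large replicate sets.

    Draws paired samples of ``reps_small`` and ``reps_large`` replicates
    from the same NB(μ, size) and reports the fraction of pairs where
    the small sample's variance is the smaller one, plus sorted variance
    curves for plotting.  For right-skewed counts that fraction sits
    well above 1/2 — small samples usually understate the variance and
    occasionally overshoot it badly, which is what inflates or shrinks
    small-sample t-statistics.
    """
    rng = np.random.default_rng(seed)
    small = _nb_draw(rng, mu, size, (n_experiments, reps_small)).var(axis=1, ddof=1)
    large = _nb_draw(rng, mu, size, (n_experiments, reps_large)).var(axis=1, ddof=1)
    return VarianceSummary(
        fraction_small_sample_smaller=float((small < large).mean()),
        sorted_variances_small=np.sort(small),
        sorted_variances_large=np.sort(large),
        n_experiments=n_experiments,
    )
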