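"""Inflation-shrinkage statistics: gap statistic φ, homogeneity ζ, and ρ.

Small-sample count experiments frequently show a *data gap* — the closed
ranges of the two conditions' replicates are disjoint — and either
unusually small or unusually large within-condition variances.  Both
effects distort a plain t-statistic.  The statistic ρ = sqrt(φ·ζ)
quantifies them jointly:

* φ compares the closest points of the two replicate ranges,
  ``max[(min A + 1)/(max B + 1), (min B + 1)/(max A + 1)]``; the +1
  guards against zero counts.  φ > 1 exactly when the ranges are
  strictly disjoint, and φ behaves like a conservative fold change.
* ζ is an F-like homogeneity statistic,
  ``ln((X̄·σ² + 1)/(X̄_A·σ_A² + X̄_B·σ_B² + 1))`` with X̄ = X̄_A + X̄_B,
  comparing the pooled variance against the mean-weighted
  within-condition variances (a log variance-ratio, ≈ 0 for pure noise);
  large ζ means replicates are consistent within conditions, negative
  raw values (noisy, overlapping data) are clamped to 0.

ρ multiplies the t-statistic (scaled by the null threshold ω): separated,
homogeneous data get inflated, overlapping noisy data get shrunk toward 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional
import warnings

import numpy as np

from .count_model import GeneSubMatrix

__all__ = [
    "RhoComponents",
    "phi",
    "zeta",
    "rho",
    "rho_components",
    "gene_rho",
    "has_gap",
]


@dataclass
class RhoComponents:
    """(φ, ζ_raw, ζ, ρ) for one feature or one gene."""

    phi: float
    zeta_raw: float
    zeta: float
    rho: float
    level: str = "feature"  # or "gene"


def phi(xA: np.ndarray, xB: np.ndarray) -> float:
    """Gap/fold statistic between two replicate sets.

    Returns ``max[(min(xA)+1)/(max(xB)+1), (min(xB)+1)/(max(xA)+1)]``.
    The result exceeds 1 iff the closed ranges of ``xA`` and ``xB`` are
    strictly disjoint; the +1 terms keep the ratio finite at zero counts.
    """
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    if xA.size == 0 or xB.size == 0:
        raise ValueError("empty replicate vector")
    return max(
        (xA.min() + 1.0) / (xB.max() + 1.0),
        (xB.min() + 1.0) / (xA.max() + 1.0),
    )


def zeta(
    xA: np.ndarray,
    xB: np.ndarray,
    variance_mode: str = "sample",
) -> tuple[float, float]:
    """Homogeneity statistic; returns ``(zeta_raw, zeta)``.

    ``zeta_raw = ln((X̄·σ² + 1)/(X̄_A·σ_A² + X̄_B·σ_B² + 1))`` with
    X̄ = X̄_A + X̄_B the sum of the condition means, σ² the variance of
    the pooled data and σ_A², σ_B² the within-condition variances — a
    guarded log ratio of pooled to within-condition variance that sits
    near 0 for pure noise and grows when the conditions separate.
    ``zeta = max(zeta_raw, 0)``.  Exactly 0 when both conditions are
    all-zero.

    variance_mode : {"sample", "population"}
        Divisor n−1 (default) or n.  A single-replicate condition has
        its within variance taken as 0 with a warning.
    """
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    if xA.size == 0 or xB.size == 0:
        raise ValueError("empty replicate vector")
    if variance_mode not in ("sample", "population"):
        raise ValueError("variance_mode must be 'sample' or 'population'")
    ddof = 1 if variance_mode == "sample" else 0

    def _var(x: np.ndarray) -> float:
        if x.size <= ddof:
            warnings.warn(
                "single-replicate condition: within-condition variance taken as 0",
                stacklevel=3,
            )
            return 0.0
        return float(np.var(x, ddof=ddof))

    mean_a = float(xA.mean())
    mean_b = float(xB.mean())
    if mean_a == 0.0 and mean_b == 0.0:
        return 0.0, 0.0
    grand_mean = mean_a + mean_b
    pooled = np.concatenate([xA, xB])
    pooled_var = float(np.var(pooled, ddof=ddof)) if pooled.size > ddof else 0.0
    raw = float(
        np.log(
            (grand_mean * pooled_var + 1.0)
            / (mean_a * _var(xA) + mean_b * _var(xB) + 1.0)
        )
    )
    return raw, max(raw, 0.0)


def rho(phi_value: float, zeta_value: float) -> float:
    """Geometric mean ``sqrt(phi * zeta)`` of the gap and homogeneity terms."""
    if phi_value <= 0:
        raise ValueError("phi must be positive")
    if zeta_value < 0:
        raise ValueError("zeta must be non-negative")
    return float(np.sqrt(phi_value * zeta_value))


Transform = Optional[Callable[[np.ndarray], np.ndarray]]


def rho_components(
    xA: np.ndarray,
    xB: np.ndarray,
    variance_mode: str = "sample",
    transform: Transform = None,
    level: str = "feature",
) -> RhoComponents:
    """φ, ζ and ρ for one feature (or one gene's summed counts).

    ``transform``, if given, is applied to both vectors before ζ is
    computed (e.g. log2 or a proportion transform); φ is always computed
    on the untransformed counts so the gap predicate is unchanged.
    """
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    p = phi(xA, xB)
    if transform is not None:
        zA, zB = transform(xA), transform(xB)
    else:
        zA, zB = xA, xB
    raw, z = zeta(zA, zB, variance_mode=variance_mode)
    return RhoComponents(phi=p, zeta_raw=raw, zeta=z, rho=rho(p, z), level=level)


def gene_rho(
    sub: GeneSubMatrix,
    variance_mode: str = "sample",
    transform: Transform = None,
) -> RhoComponents:
    """Gene-wise ρ computed on the per-gene column sums (one value per replicate).

    Used for sgRNA tests (all sgRNAs of a gene share ρ_g) and for the
    gene-level test.  An all-zero gene gets ρ = 0 (ζ = 0 by convention).
    """
    sums_a = sub.counts_A.sum(axis=0)
    sums_b = sub.counts_B.sum(axis=0)
    return rho_components(
        sums_a, sums_b, variance_mode=variance_mode, transform=transform, level="gene"
    )


def has_gap(xA: np.ndarray, xB: np.ndarray) -> bool:
    """True iff the closed ranges of the two replicate sets are strictly disjoint.

    A shared boundary value counts as overlap (strict-gap convention),
    matching φ > 1 ⇔ gap under the +1 guards.
    """
    xA = np.asarray(xA, dtype=float)
    xB = np.asarray(xB, dtype=float)
    if xA.size == 0 or xB.size == 0:
        raise ValueError("empty replicate vector")
    return bool(xA.max() < xB.min() or xB.max() < xA.min())
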