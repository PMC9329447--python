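"""End-to-end NBB t-tests at isoform/exon, sgRNA and gene level.

The test statistic for unit *u* is ``t_u^α = (ρ_u / ω_α) · t_u`` where
t_u is the weighted beta-binomial t-statistic, ρ_u the inflation-
shrinkage statistic (feature-wise for isoforms/exons, gene-wise for
sgRNAs and genes) and ω_α a null threshold for ρ calibrated by
simulation.  Two-sided p-values are computed from t^α with
df = m_A + m_B − 2 — the inflated/shrunken statistic, not the raw t,
carries into inference — and adjusted by Benjamini–Hochberg across the
features retained after dropping all-zero rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .count_model import CountTable

__all__ = [
    "test_isoforms",
    "test_sgrnas",
    "test_genes",
    "bh_adjust",
    "base_statistics",
]

RESULT_COLUMNS = [
    "gene_id",
    "feature_id",
    "t",
    "rho",
    "t_alpha",
    "pvalue",
    "padj",
    "direction",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    ``p_(i) * n / i`` with a running minimum from the largest rank down,
    capped at 1.  Kept as an explicit implementation so library routines
    can serve as an independent cross-check.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# vectorized internals
# ---------------------------------------------------------------------------


def _group_sums(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Per-row matrix of the row's gene-wise column sums (F x S)."""
    df = pd.DataFrame(values)
    return df.groupby(pd.Series(gene_ids), sort=False).transform("sum").to_numpy()


def _rho_many(
    A: np.ndarray,
    B: np.ndarray,
    variance_mode: str = "sample",
    zA: np.ndarray | None = None,
    zB: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """φ, ζ and ρ for many rows at once.

    φ uses the raw counts ``A``/``B``; ζ uses ``zA``/``zB`` when a
    pre-transform (log2, proportion) is requested, else the raw counts.
    """
    ddof = 1 if variance_mode == "sample" else 0
    phi = np.maximum(
        (A.min(axis=1) + 1.0) / (B.max(axis=1) + 1.0),
        (B.min(axis=1) + 1.0) / (A.max(axis=1) + 1.0),
    )
    if zA is None:
        zA, zB = A, B
    mean_a, mean_b = zA.mean(axis=1), zB.mean(axis=1)
    var_a = zA.var(axis=1, ddof=ddof) if zA.shape[1] > ddof else np.zeros(len(zA))
    var_b = zB.var(axis=1, ddof=ddof) if zB.shape[1] > ddof else np.zeros(len(zB))
    pooled = np.hstack([zA, zB])
    var_p = pooled.var(axis=1, ddof=ddof)
    grand = mean_a + mean_b
    raw = np.log((grand * var_p + 1.0) / (mean_a * var_a + mean_b * var_b + 1.0))
    both_zero = (mean_a == 0) & (mean_b == 0)
    raw = np.where(both_zero, 0.0, raw)
    z = np.maximum(raw, 0.0)
    return {"phi": phi, "zeta_raw": raw, "zeta": z, "rho": np.sqrt(phi * z)}


def _zeta_inputs(
    counts: np.ndarray, props: np.ndarray, zeta_transform: str
) -> np.ndarray:
    if zeta_transform == "none":
        return counts
    if zeta_transform == "log2":
        return np.log2(counts + 1.0)
    if zeta_transform == "proportion":
        return props
    raise ValueError(f"unknown zeta_transform {zeta_transform!r}")


def _condition_estimates(
    counts: np.ndarray,
    props: np.ndarray,
    divisors: np.ndarray,
    gene_ids: np.ndarray,
    tol: float,
    max_iter: int,
) -> dict[str, np.ndarray]:
    """Weighted estimates + floored variances for one condition's columns."""
    from .beta_binomial import estimate_weighted_many

    est = estimate_weighted_many(props, divisors, tol=tol, max_iter=max_iter)
    X_gi = counts.sum(axis=1)  # feature total in this condition
    X_g = _group_sums(counts, gene_ids).sum(axis=1)  # gene total in this condition
    est["X_gi"], est["X_g"] = X_gi, X_g
    return est


def _floors(
    X_gi: np.ndarray, X_g: np.ndarray, X_g_pooled: np.ndarray
) -> np.ndarray:
    # fall back to the pooled gene total when the gene is silent in this
    # condition, so all-zero-in-one-condition features stay testable
    Xg = np.where(X_g > 0, X_g, X_g_pooled)
    q = (1.0 + X_gi) / Xg
    return np.maximum(q * (1.0 - q) / Xg, 0.0)


def _run_pipeline(
    table: CountTable,
    level: str,
    variance_mode: str = "sample",
    zeta_transform: str = "none",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Per-unit t, ρ and raw-t p-values; no ω applied yet.

    The returned frame has one row per retained feature (isoform/sgrna
    levels) or per gene (gene level), with columns ``gene_id,
    feature_id, t, rho, phi, zeta, p_raw``.
    """
    if level not in ("isoform", "sgrna", "gene"):
        raise ValueError(f"unknown level {level!r}")
    if level == "gene" and table.feature_kind != "gene":
        table = table.sum_to_genes()
    table = table.drop_all_zero()
    if table.n_features == 0:
        raise ValueError("no features with non-zero counts")

    mask_a, mask_b = table.condition_columns()
    A = table.counts[:, mask_a]
    B = table.counts[:, mask_b]
    m_A, m_B = A.shape[1], B.shape[1]
    gene_ids = table.gene_ids

    # proportion divisors per convention
    if level == "gene":
        div_a = np.broadcast_to(A.sum(axis=0), A.shape)
        div_b = np.broadcast_to(B.sum(axis=0), B.shape)
    else:
        tot_a = _group_sums(A, gene_ids)  # X_gj within condition A
        tot_b = _group_sums(B, gene_ids)
        if level == "sgrna":
            div_a = np.broadcast_to(tot_a.max(axis=1, keepdims=True), A.shape)
            div_b = np.broadcast_to(tot_b.max(axis=1, keepdims=True), B.shape)
        else:  # isoform / exon: per-column gene library
            div_a, div_b = tot_a, tot_b

    with np.errstate(divide="ignore", invalid="ignore"):
        P_A = np.where(div_a > 0, A / np.where(div_a > 0, div_a, 1.0), 0.0)
        P_B = np.where(div_b > 0, B / np.where(div_b > 0, div_b, 1.0), 0.0)

    est_a = _condition_estimates(A, P_A, np.maximum(div_a, 1.0), gene_ids, tol, max_iter)
    est_b = _condition_estimates(B, P_B, np.maximum(div_b, 1.0), gene_ids, tol, max_iter)
    pooled_gene_total = est_a["X_g"] + est_b["X_g"]
    v_a = np.maximum(est_a["v_hat"], _floors(est_a["X_gi"], est_a["X_g"], pooled_gene_total))
    v_b = np.maximum(est_b["v_hat"], _floors(est_b["X_gi"], est_b["X_g"], pooled_gene_total))

    diff = est_a["p_hat"] - est_b["p_hat"]
    denom = np.sqrt(v_a + v_b)
    t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)

    # ρ at the level the test uses
    if level == "isoform":
        zA = _zeta_inputs(A, P_A, zeta_transform)
        zB = _zeta_inputs(B, P_B, zeta_transform)
        comp = _rho_many(A, B, variance_mode, zA, zB)
        rho = comp["rho"]
        phi_v, zeta_v = comp["phi"], comp["zeta"]
    else:
        # gene-wise ρ on per-gene column sums, shared by the gene's rows
        first = ~pd.Series(gene_ids).duplicated().to_numpy()
        GA = _group_sums(A, gene_ids)[first]
        GB = _group_sums(B, gene_ids)[first]
        comp = _rho_many(GA, GB, variance_mode)
        lut = dict(zip(gene_ids[first], range(first.sum())))
        idx = np.array([lut[g] for g in gene_ids])
        rho = comp["rho"][idx]
        phi_v, zeta_v = comp["phi"][idx], comp["zeta"][idx]

    df_t = m_A + m_B - 2
    p_raw = 2.0 * stats.t.sf(np.abs(t), df_t)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "feature_id": table.feature_ids if level != "gene" else "",
            "t": t,
            "rho": rho,
            "phi": phi_v,
            "zeta": zeta_v,
            "p_raw": p_raw,
            "_df": df_t,
        }
    )


def base_statistics(
    table: CountTable,
    level: str,
    variance_mode: str = "sample",
    zeta_transform: str = "none",
) -> pd.DataFrame:
    """Un-inflated beta t-test (ρ = ω = 1) plus the ρ each unit would use.

    This is the Step-2/3 ingredient of the ω calibration: p-values come
    from the raw t while ρ is reported alongside.
    """
    return _run_pipeline(table, level, variance_mode, zeta_transform)


def _finalize(
    base: pd.DataFrame, omega: float, fdr_cutoff: float
) -> pd.DataFrame:
    if omega <= 0:
        raise ValueError("omega must be positive")
    t_alpha = base["rho"].to_numpy() / omega * base["t"].to_numpy()
    df_t = int(base["_df"].iloc[0])
    pvalue = 2.0 * stats.t.sf(np.abs(t_alpha), df_t)
    padj = bh_adjust(pvalue)
    sig = padj < fdr_cutoff
    direction = np.where(
        sig & (t_alpha > 0), "up", np.where(sig & (t_alpha < 0), "down", "none")
    )
    out = pd.DataFrame(
        {
            "gene_id": base["gene_id"],
            "feature_id": base["feature_id"],
            "t": base["t"],
            "rho": base["rho"],
            "t_alpha": t_alpha,
            "pvalue": pvalue,
            "padj": padj,
            "direction": direction,
        }
    )
    out.attrs["omega"] = omega
    return out


def _test(
    table: CountTable,
    level: str,
    alpha: float,
    omega: float | None,
    seed: int | None,
    sims: int,
    variance_mode: str,
    zeta_transform: str,
    fdr_cutoff: float,
) -> pd.DataFrame:
    from .omega import estimate_omega  # deferred: omega builds on this module

    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    base = _run_pipeline(table, level, variance_mode, zeta_transform)
    if omega is None:
        omega = estimate_omega(
            table,
            alpha=alpha,
            s=sims,
            seed=seed,
            level=level,
            variance_mode=variance_mode,
            zeta_transform=zeta_transform,
        ).omega
    return _finalize(base, omega, fdr_cutoff)


def test_isoforms(
    table: CountTable,
    alpha: float = 0.05,
    omega: float | None = None,
    seed: int | None = None,
    sims: int = 10,
    variance_mode: str = "sample",
    zeta_transform: str = "none",
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Differential test of RNA isoforms or exons.

    Per-gene library proportions, feature-wise ρ_gi, multiplier ρ_gi/ω_α.
    ω is calibrated internally from ``sims`` null simulations unless
    supplied.  Returns one row per retained feature.
    """
    if table.feature_kind not in ("isoform", "exon"):
        raise ValueError("test_isoforms expects feature_kind 'isoform' or 'exon'")
    return _test(
        table, "isoform", alpha, omega, seed, sims, variance_mode, zeta_transform, fdr_cutoff
    )


def test_sgrnas(
    table: CountTable,
    alpha: float = 0.05,
    omega: float | None = None,
    seed: int | None = None,
    sims: int = 10,
    variance_mode: str = "sample",
    zeta_transform: str = "none",
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Differential CRISPR screen test of individual sgRNAs.

    Proportions use the per-condition max gene total (the sgRNA set is
    fixed by design, so replicate-total differences are technical); the
    t multiplier uses the gene-wise ρ_g shared by all sgRNAs of a gene.
    """
    if table.feature_kind != "sgrna":
        raise ValueError("test_sgrnas expects feature_kind 'sgrna'")
    return _test(
        table, "sgrna", alpha, omega, seed, sims, variance_mode, zeta_transform, fdr_cutoff
    )


def test_genes(
    table: CountTable,
    alpha: float = 0.05,
    omega: float | None = None,
    seed: int | None = None,
    sims: int = 10,
    variance_mode: str = "sample",
    zeta_transform: str = "none",
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Gene-level differential expression or screen test.

    Features are first summed to genes; gene proportions are the gene's
    share of the per-sample grand total, and the multiplier is ρ_g/ω_α.
    """
    return _test(
        table, "gene", alpha, omega, seed, sims, variance_mode, zeta_transform, fdr_cutoff
    )
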