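"""Statistical machinery: rank-sum DE, Dirichlet regression, proximity
enrichment, and GMT over-representation.

* ``wilcoxon_de`` — two-sided Wilcoxon rank-sum tests per gene with the
  10%-expression filter applied to the tested group and Bonferroni
  correction over the genes actually tested. Small samples
  (n1 + n2 <= 12) use an exact tie-aware null distribution computed by
  convolution over doubled average ranks; larger samples use the
  tie-corrected normal approximation. log-FC is ln of the ratio of
  (linear mean + 1) between groups.
* ``dirichlet_regression`` — MLE for compositional outcomes with
  alpha_ij = exp(x_i' beta_j) (common parametrization), zeros shrunk by the
  standard (y (n-1) + 1/J) / n transform, and a likelihood-ratio test
  against the intercept-only model.
* ``genes_near_snps`` / ``fisher_gwas_enrichment`` — gene-to-SNP proximity
  within a base-pair window (BED half-open gene bodies, 1-based SNPs) and a
  one-sided Fisher test of trait-proximal vs reference-proximal genes
  against a training-response gene set.
* ``overrepresentation_gmt`` — hypergeometric over-representation of a gene
  list in GMT sets with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import digamma, gammaln
from statsmodels.stats.multitest import multipletests

from .matrix import LAYER_LOGNORM, ExpressionMatrix

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum DE
# ---------------------------------------------------------------------------


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p-value, tie-aware.

    The null distribution of the group-1 rank sum is built by convolving
    over the pooled (doubled, so integral) average ranks: f[j][s] counts the
    subsets of size j with doubled-rank sum s. Two-sided p is
    min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks2 = np.round(2 * sps.rankdata(pooled)).astype(int)  # doubled avg ranks
    w_obs = int(ranks2[:n1].sum())
    max_sum = int(ranks2.sum())
    # f[j, s]: number of size-j subsets with doubled-rank sum s
    f = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    f[0, 0] = 1.0
    for r in ranks2:
        for j in range(n1, 0, -1):
            f[j, r:] += f[j - 1, : max_sum + 1 - r]
    dist = f[n1]
    total = dist.sum()
    p_le = dist[: w_obs + 1].sum() / total
    p_ge = dist[w_obs:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _log_fold_change(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.log((np.expm1(x).mean() + 1.0) / (np.expm1(y).mean() + 1.0)))


def wilcoxon_de(
    matrix: ExpressionMatrix,
    group1,
    group2,
    min_pct: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene rank-sum DE between two disjoint cell groups.

    Genes expressed (non-zero) in fewer than ``min_pct`` of group-1 cells
    are skipped before testing; Bonferroni correction is over the genes
    tested. Returns a table sorted by p-value with columns gene_id, log_fc,
    p_value, p_adjusted, pct_group1, pct_group2.
    """
    if matrix.layer_tag != LAYER_LOGNORM:
        raise ValueError("wilcoxon_de expects a log-normalized matrix")
    g1 = matrix.cell_index(list(group1))
    g2 = matrix.cell_index(list(group2))
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError("both groups must be non-empty")
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")

    X1 = matrix.values[:, g1]
    X2 = matrix.values[:, g2]
    pct1 = (X1 > 0).mean(axis=1)
    pct2 = (X2 > 0).mean(axis=1)
    tested = np.flatnonzero(pct1 >= min_pct)
    if tested.size == 0:
        return pd.DataFrame(
            columns=["gene_id", "log_fc", "p_value", "p_adjusted", "pct_group1", "pct_group2"]
        )

    n1, n2 = len(g1), len(g2)
    if n1 + n2 <= EXACT_MAX_N:
        pvals = np.array([exact_ranksum_p(X1[i], X2[i]) for i in tested])
    else:
        res = sps.mannwhitneyu(
            X1[tested], X2[tested], axis=1, alternative="two-sided", method="asymptotic"
        )
        pvals = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
        # constant pooled values (zero rank variance) give NaN; no evidence
        const = (X1[tested].std(axis=1) == 0) & (X2[tested].std(axis=1) == 0) & (
            X1[tested, :1].ravel() == X2[tested, :1].ravel()
        )
        pvals = np.where(const, 1.0, pvals)

    logfc = np.array([_log_fold_change(X1[i], X2[i]) for i in tested])
    p_adj = np.minimum(1.0, pvals * tested.size)
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids[tested],
            "log_fc": logfc,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "pct_group1": pct1[tested],
            "pct_group2": pct2[tested],
        }
    )
    return out.sort_values(["p_value", "gene_id"]).reset_index(drop=True)


def tr_genes(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    labels: pd.Series,
    control_condition: str = "RPMI",
    subgroups=("MCI", "MC"),
    min_pct: float = 0.10,
    alpha: float = 0.05,
    per_stimulus: bool = True,
) -> dict:
    """Training-response genes: trained subgroup vs pooled controls.

    Runs ``wilcoxon_de`` per (subgroup, stimulus) stratum (or pooled across
    stimuli when ``per_stimulus`` is false) against all control-condition
    cells. Returns ``{"tables": {(subgroup, stimulus): DEResult}, "shared":
    DataFrame}`` where ``shared`` lists, per subgroup, genes Bonferroni-
    significant in at least two stimuli.
    """
    md = metadata.set_index("cell_id") if "cell_id" in metadata.columns else metadata
    md = md.reindex(matrix.cell_ids)
    labels = labels.reindex(matrix.cell_ids)
    control_cells = md.index[md["condition"] == control_condition]
    if len(control_cells) == 0:
        raise ValueError(f"no cells with control condition {control_condition!r}")

    stimuli = (
        sorted(md.loc[md["condition"] != control_condition, "condition"].dropna().unique())
        if per_stimulus
        else ["all"]
    )
    tables: dict = {}
    shared_rows = []
    for sg in subgroups:
        sig_by_stim = {}
        for stim in stimuli:
            mask = (labels == sg) & (md["condition"] != control_condition)
            if per_stimulus:
                mask &= md["condition"] == stim
            cells = md.index[mask]
            if len(cells) == 0:
                logger.warning("no %s cells for stimulus %s; stratum skipped", sg, stim)
                tables[(sg, stim)] = None
                continue
            de = wilcoxon_de(matrix, cells, control_cells, min_pct=min_pct)
            de["significant"] = de.p_adjusted < alpha
            de["direction"] = np.where(de.log_fc > 0, "up", "down")
            tables[(sg, stim)] = de
            sig_by_stim[stim] = set(de.loc[de.significant, "gene_id"])
        counts: dict = {}
        for genes in sig_by_stim.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        for g, c in sorted(counts.items()):
            if c >= 2:
                shared_rows.append({"subgroup": sg, "gene_id": g, "n_stimuli": c})
    shared = pd.DataFrame(shared_rows, columns=["subgroup", "gene_id", "n_stimuli"])
    return {"tables": tables, "shared": shared}


# ---------------------------------------------------------------------------
# Dirichlet regression
# ---------------------------------------------------------------------------


def _zero_shrink(Y: np.ndarray) -> np.ndarray:
    """Compositional zero handling: y' = (y (n - 1) + 1/J) / n."""
    n, J = Y.shape
    return (Y * (n - 1) + 1.0 / J) / n


def _dirichlet_nll_grad(beta_flat, X, Y, J):
    p = X.shape[1]
    beta = beta_flat.reshape(p, J)
    eta = X @ beta
    eta = np.clip(eta, -30, 30)
    alpha = np.exp(eta)
    a0 = alpha.sum(axis=1)
    logY = np.log(Y)
    ll = (gammaln(a0) - gammaln(alpha).sum(axis=1) + ((alpha - 1) * logY).sum(axis=1)).sum()
    inner = alpha * (digamma(a0)[:, None] - digamma(alpha) + logY)  # n x J
    grad = X.T @ inner  # p x J
    return -ll, -grad.ravel()


def _design_matrix(table: pd.DataFrame, covariates) -> tuple:
    X = [np.ones(len(table))]
    names = ["(Intercept)"]
    for cov in covariates:
        col = table[cov]
        if col.dtype.kind in "biufc":
            X.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # treatment coding, first level is reference
                X.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    return np.column_stack(X), names


def _fit_dirichlet(X: np.ndarray, Y: np.ndarray):
    n, J = Y.shape
    p = X.shape[1]
    beta0 = np.zeros((p, J))
    # moment-matched intercept start: alpha ~ mean proportions * precision
    mean_p = Y.mean(axis=0)
    v = Y.var(axis=0).mean()
    prec = max((mean_p.mean() * (1 - mean_p.mean())) / max(v, 1e-8) - 1.0, 1.0)
    beta0[0] = np.log(np.maximum(mean_p * prec, 1e-6))
    res = optimize.minimize(
        _dirichlet_nll_grad,
        beta0.ravel(),
        args=(X, Y, J),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    return res


def dirichlet_regression(
    table: pd.DataFrame,
    covariates=("group",),
    components=("MCI", "MC", "NT"),
) -> dict:
    """Dirichlet regression of composition rows on sample covariates.

    Fits alpha_ij = exp(x_i' beta_j) by maximum likelihood (analytic
    gradient, L-BFGS-B) and reports a likelihood-ratio test of the full
    model against the intercept-only null with chi-square reference on
    (p_full - 1) * J degrees of freedom.
    """
    components = list(components)
    if len(components) < 2:
        raise ValueError("a composition needs at least 2 components")
    covariates = [covariates] if isinstance(covariates, str) else list(covariates)
    Y = table[components].to_numpy(dtype=float)
    if np.abs(Y.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("composition rows must sum to 1")
    for cov in covariates:
        counts = table[cov].astype(str).value_counts()
        if (counts < 2).any():
            raise ValueError(f"every level of {cov!r} needs at least 2 samples")
    Y = _zero_shrink(Y)
    X_full, names = _design_matrix(table, covariates)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("degenerate design matrix")
    X_null = X_full[:, :1]
    J = Y.shape[1]

    fit_full = _fit_dirichlet(X_full, Y)
    fit_null = _fit_dirichlet(X_null, Y)
    ll_full, ll_null = -fit_full.fun, -fit_null.fun
    df = (X_full.shape[1] - 1) * J
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    p = float(sps.chi2.sf(lrt, df)) if df > 0 else 1.0

    coef = pd.DataFrame(fit_full.x.reshape(X_full.shape[1], J), index=names,
                        columns=components)
    if not fit_full.success:
        logger.warning("Dirichlet full-model fit did not converge: %s", fit_full.message)
    return {
        "coefficients": coef,
        "log_likelihood": float(ll_full),
        "log_likelihood_null": float(ll_null),
        "lrt_stat": float(lrt),
        "df": int(df),
        "p_value": p,
        "converged": bool(fit_full.success and fit_null.success),
        "grad_norm": float(np.max(np.abs(fit_full.jac))),
        "fitted_means": _fitted_means(coef, components),
    }


def _fitted_means(coef: pd.DataFrame, components) -> pd.Series:
    alpha = np.exp(coef.loc["(Intercept)"].to_numpy(dtype=float))
    return pd.Series(alpha / alpha.sum(), index=list(components))


# ---------------------------------------------------------------------------
# GWAS proximity enrichment
# ---------------------------------------------------------------------------


def genes_near_snps(
    gene_coords: pd.DataFrame,
    snps: pd.DataFrame,
    window: int = 250_000,
    mode: str = "body",
) -> list:
    """Genes whose body lies within ``window`` bp of any SNP.

    ``gene_coords`` uses BED conventions (0-based, half-open: chrom, start,
    end, gene_id); ``snps`` has 1-based positions (chrom, pos, snp_id). A
    SNP inside the gene body gives distance 0. ``mode='tss'`` measures from
    the interval start instead of the whole body.
    """
    if mode not in ("body", "tss"):
        raise ValueError("mode must be 'body' or 'tss'")
    hits = set()
    for chrom, genes_c in gene_coords.groupby("chrom"):
        pos0 = snps.loc[snps["chrom"] == chrom, "pos"].to_numpy(dtype=np.int64) - 1
        if pos0.size == 0:
            continue
        start = genes_c["start"].to_numpy(dtype=np.int64)
        end = genes_c["end"].to_numpy(dtype=np.int64)
        if mode == "tss":
            end = start + 1
        # distance from each SNP (cols) to each gene interval (rows)
        left = start[:, None] - pos0[None, :]
        right = pos0[None, :] - (end[:, None] - 1)
        dist = np.maximum(np.maximum(left, right), 0)
        near = (dist.min(axis=1) <= window)
        hits.update(genes_c.loc[near, "gene_id"])
    return sorted(hits)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: rows (trait-proximal, reference-proximal), cols (in TR, not)
    odds_ratio: float
    p_value: float
    gene_lists: dict


def hypergeom_sf_logspace(a: int, r1: int, r2: int, c1: int) -> float:
    """P(X >= a) for X ~ Hypergeom(N=r1+r2, K=r1, n=c1), summed in log space."""
    N = r1 + r2
    kmax = min(r1, c1)
    if a > kmax:
        return 0.0
    logs = []
    for k in range(max(a, max(0, c1 - r2)), kmax + 1):
        logs.append(
            gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
            + gammaln(r2 + 1) - gammaln(c1 - k + 1) - gammaln(r2 - (c1 - k) + 1)
            - (gammaln(N + 1) - gammaln(c1 + 1) - gammaln(N - c1 + 1))
        )
    if not logs:
        return 0.0
    logs = np.asarray(logs)
    mx = logs.max()
    return float(min(1.0, np.exp(mx + np.log(np.exp(logs - mx).sum()))))


def fisher_gwas_enrichment(tr_gene_set, trait_proximal, reference_proximal) -> EnrichmentResult:
    """One-sided Fisher test: are TR genes over-represented near trait SNPs?

    Contingency rows are the trait-proximal and reference-proximal gene
    sets, columns membership in the TR set; the one-sided (greater)
    hypergeometric p conditions on the table margins.
    """
    tr = set(tr_gene_set)
    trait = set(trait_proximal)
    ref = set(reference_proximal)
    a = len(trait & tr)
    b = len(trait - tr)
    c = len(ref & tr)
    d = len(ref - tr)
    if a + b == 0 or c + d == 0:
        logger.warning("empty proximal set; enrichment p fixed at 1")
        p = 1.0
    else:
        p = hypergeom_sf_logspace(a, a + b, c + d, a + c)
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = np.inf
    else:
        odds = np.nan  # 0/0: degenerate table carries no association information
    return EnrichmentResult(
        table=np.array([[a, b], [c, d]]),
        odds_ratio=float(odds),
        p_value=float(p),
        gene_lists={
            "trait_in_tr": sorted(trait & tr),
            "trait_not_tr": sorted(trait - tr),
            "reference_in_tr": sorted(ref & tr),
            "reference_not_tr": sorted(ref - tr),
        },
    )


# ---------------------------------------------------------------------------
# Over-representation on GMT sets
# ---------------------------------------------------------------------------


def overrepresentation_gmt(gene_list, gmt_sets, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each GMT set.

    Sets are intersected with ``universe`` first; ``gene_list`` must be a
    subset of the universe. BH step-up adjustment across sets.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene_list must be a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for sig in gmt_sets:
        members = set(sig.genes) & universe
        K = len(members)
        k = len(members & genes)
        expected = K * n / N if N else 0.0
        p = hypergeom_sf_logspace(k, K, N - K, n) if K else 1.0
        rows.append({"set_name": sig.name, "set_size": K, "overlap": k,
                     "expected": expected, "p_value": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    return out.sort_values(["p_value", "set_name"]).reset_index(drop=True)
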