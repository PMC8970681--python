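"""Cross-cell expression heterogeneity of TI marker genes.

Three statistics on log(TP10K+1) matrices:

* expressed-gene selection (mean log-normalized expression strictly above a
  threshold, default 0.5);
* per-gene variance and dispersion-index (D = var/mean) tables with a
  top-fraction high-variance/high-dispersion flag (default top 5%);
* pairwise Spearman co-expression where zeros are treated as missing
  (pairwise-complete non-zero observations), the convention for sparse
  single-cell data where a zero mostly means "not captured".
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .matrix import LAYER_LOGNORM, ExpressionMatrix


def _require_lognorm(matrix: ExpressionMatrix) -> None:
    if matrix.layer_tag != LAYER_LOGNORM:
        raise ValueError("expected a log-normalized matrix (run lognormalize)")


def expressed_genes(
    matrix: ExpressionMatrix,
    min_mean: float = 0.5,
    cells=None,
) -> list:
    """Genes whose mean log-normalized expression exceeds ``min_mean`` (strict).

    ``cells`` restricts the computation to a cell subset (e.g. one macrophage
    cluster). Returns gene ids in matrix order; an empty result is returned
    as an empty list, not raised.
    """
    _require_lognorm(matrix)
    v = matrix.values if cells is None else matrix.values[:, matrix.cell_index(cells)]
    means = v.mean(axis=1)
    return [g for g, m in zip(matrix.gene_ids, means) if m > min_mean]


def _variance_table(matrix: ExpressionMatrix, genes, cells=None) -> pd.DataFrame:
    _require_lognorm(matrix)
    if matrix.n_cells < 2 and cells is None:
        raise ValueError("need at least 2 cells for a sample variance")
    genes = list(matrix.gene_ids) if genes is None else list(genes)
    v = matrix.values[matrix.gene_index(genes)]
    if cells is not None:
        v = v[:, matrix.cell_index(cells)]
    mean = v.mean(axis=1)
    var = v.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    return pd.DataFrame(
        {"gene_id": genes, "mean_lognorm": mean, "variance": var, "dispersion_index": disp}
    )


def _flag_top(table: pd.DataFrame, stat: str, top_frac: float) -> pd.DataFrame:
    """Add percentile and a flag for exactly ceil(top_frac * n) genes.

    Boundary ties are broken lexicographically by gene id (ascending id wins),
    so the output is deterministic.
    """
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must lie in (0, 1]")
    n = len(table)
    n_top = math.ceil(top_frac * n)
    order = table.sort_values([stat, "gene_id"], ascending=[False, True]).index
    flag = pd.Series(False, index=table.index)
    flag.loc[order[:n_top]] = True
    pct = table[stat].rank(method="average", pct=True)
    out = table.copy()
    out["percentile"] = pct
    out["high"] = flag
    return out


def variance_ranking(
    matrix: ExpressionMatrix, genes=None, top_frac: float = 0.05, cells=None
) -> pd.DataFrame:
    """Per-gene variance of log-normalized expression with a top-5% flag.

    Sample variance (n-1 denominator). Exactly ``ceil(top_frac * n_genes)``
    genes receive ``high_variance=True``.
    """
    table = _flag_top(_variance_table(matrix, genes, cells), "variance", top_frac)
    return table.rename(columns={"percentile": "variance_percentile", "high": "high_variance"})


def dispersion_index(
    matrix: ExpressionMatrix, genes=None, top_frac: float = 0.05, cells=None
) -> pd.DataFrame:
    """Per-gene dispersion index D = var/mean with a top-5% flag.

    Computed on the same log-normalized scale as ``variance_ranking`` so the
    two tables are directly comparable on a shared gene set.
    """
    table = _flag_top(_variance_table(matrix, genes, cells), "dispersion_index", top_frac)
    return table.rename(
        columns={"percentile": "dispersion_percentile", "high": "high_dispersion"}
    )


def spearman_coexpression(
    matrix: ExpressionMatrix,
    focus_genes,
    partner_genes=None,
    cells=None,
    min_obs: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Spearman correlation with zeros treated as missing.

    For every (focus, partner) pair, cells where either gene is zero are
    dropped; rho and the two-sided t-approximation p-value are computed on
    the remaining observations (average ranks for ties). Pairs with fewer
    than ``min_obs`` complete observations are reported with NaN rho/p and
    ``significant=False`` rather than raised.
    """
    _require_lognorm(matrix)
    focus = list(focus_genes)
    partners = focus if partner_genes is None else list(partner_genes)
    vf = matrix.values[matrix.gene_index(focus)]
    vp = matrix.values[matrix.gene_index(partners)]
    if cells is not None:
        ci = matrix.cell_index(cells)
        vf, vp = vf[:, ci], vp[:, ci]
    rows = []
    for (i, a), (j, b) in product(enumerate(focus), enumerate(partners)):
        x, y = vf[i], vp[j]
        if a == b:
            n_used = int((x > 0).sum())
            rows.append((a, b, 1.0, 0.0, n_used, True))
            continue
        keep = (x > 0) & (y > 0)
        n_used = int(keep.sum())
        if n_used < min_obs:
            rows.append((a, b, np.nan, np.nan, n_used, False))
            continue
        res = sps.spearmanr(x[keep], y[keep])
        rho, p = float(res.statistic), float(res.pvalue)
        if not np.isfinite(rho):  # constant vector after filtering
            rows.append((a, b, np.nan, np.nan, n_used, False))
            continue
        rows.append((a, b, rho, p, n_used, bool(p < alpha)))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "rho", "p_value", "n_pairs_used", "significant"]
    )
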