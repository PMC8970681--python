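"""Rank-based recovery-curve AUC signature scoring and threshold assignment.

Scoring follows the AUCell idea: within each cell, all genes are ranked by
decreasing expression (ties, including the zero block, broken by a seeded
random permutation so sparse data does not bias the ranking), and the score
asks how strongly the signature genes are front-loaded within the top
``top_frac`` (default 3%) of the ranking.

With k = ceil(top_frac * n_genes) and R(i) the number of signature genes at
rank <= i, the raw AUC is the step-sum

    raw = sum_{i=1..k} R(i)

and the score is raw divided by its best case (all m detected signature
genes occupying ranks 1..m):

    max = sum_{i=1..k} min(i, m),      score = raw / max  in [0, 1].

A score of 1 means perfect front-loading; 0 means no signature gene inside
the top k.

The packaged signature fixtures are the 9-gene MCI set (IL1B, IL8, IL6,
PTGS2, IL1A, CCL2, TNF, CXCL3, CXCL1) and the 12-gene MC set (CXCL11,
CXCL10, CXCL9, TNFSF10, HLA-DQA1, FCN1, IGFBP4, HLA-DPB1, HLA-DQB1, FAM26F,
RGL1, CD4), with default assignment thresholds 0.544 (MCI) and 0.169 (MC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import LAYER_LOGNORM, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError("a signature needs at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


MCI_SIGNATURE = GeneSignature(
    "MCI", ("IL1B", "IL8", "IL6", "PTGS2", "IL1A", "CCL2", "TNF", "CXCL3", "CXCL1")
)
MC_SIGNATURE = GeneSignature(
    "MC",
    ("CXCL11", "CXCL10", "CXCL9", "TNFSF10", "HLA-DQA1", "FCN1", "IGFBP4",
     "HLA-DPB1", "HLA-DQB1", "FAM26F", "RGL1", "CD4"),
)

DEFAULT_THRESHOLDS = {"MCI": 0.544, "MC": 0.169}
UNASSIGNED = "unassigned"


@dataclass
class ScoreThresholds:
    """Per-signature assignment thresholds on the normalized AUC scale."""

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self):
        for name, t in self.thresholds.items():
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"threshold for {name!r} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def read_gmt(path) -> list:
    """Read gene signatures from GMT (name, description, genes...)."""
    sigs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sigs.append(GeneSignature(parts[0], tuple(parts[2:])))
    return sigs


def write_gmt(signatures, path, description: str = "tisig") -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, description, *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# AUC scoring
# ---------------------------------------------------------------------------


def _max_auc(k: int, m: int) -> int:
    # sum_{i=1..k} min(i, m)
    if m >= k:
        return k * (k + 1) // 2
    return m * (m + 1) // 2 + m * (k - m)


def auc_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    top_frac: float = 0.03,
    tie_seed: int = 0,
) -> pd.Series:
    """Normalized recovery-curve AUC of a signature, per cell.

    Signature genes absent from the matrix are dropped with a warning; an
    error is raised only when none remain. The tie permutation is derived
    from ``(tie_seed, cell index)``, so with a fixed seed scoring is fully
    deterministic and independent of cell order elsewhere.
    """
    if matrix.layer_tag != LAYER_LOGNORM:
        raise ValueError("auc_score expects a log-normalized matrix")
    if not (0.0 < top_frac <= 1.0):
        raise ValueError("top_frac must lie in (0, 1]")
    present = [g for g in signature.genes if g in set(matrix.gene_ids)]
    missing = sorted(set(signature.genes) - set(present))
    if missing:
        logger.warning("signature %s: %d gene(s) absent from matrix: %s",
                       signature.name, len(missing), missing)
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} present in the matrix")

    n = matrix.n_genes
    k = math.ceil(top_frac * n)
    m = len(present)
    sig_idx = matrix.gene_index(present)
    is_sig = np.zeros(n, dtype=bool)
    is_sig[sig_idx] = True
    denom = _max_auc(k, m)

    scores = np.empty(matrix.n_cells)
    for ci in range(matrix.n_cells):
        expr = matrix.values[:, ci]
        perm = np.random.default_rng([tie_seed, ci]).permutation(n)
        # decreasing expression, ties broken by the permutation
        order = np.lexsort((perm, -expr))
        ranks = np.empty(n, dtype=np.int64)
        ranks[order] = np.arange(1, n + 1)
        r = ranks[sig_idx]
        in_top = r <= k
        raw = int(np.sum(k - r[in_top] + 1))  # == sum_{i=1..k} R(i)
        scores[ci] = raw / denom
    return pd.Series(scores, index=pd.Index(matrix.cell_ids, name="cell_id"),
                     name=signature.name)


def score_signatures(
    matrix: ExpressionMatrix,
    signatures,
    top_frac: float = 0.03,
    tie_seed: int = 0,
) -> pd.DataFrame:
    """Cell x signature table of normalized AUC scores."""
    return pd.concat(
        [auc_score(matrix, sig, top_frac, tie_seed) for sig in signatures], axis=1
    )


# ---------------------------------------------------------------------------
# Signature derivation and threshold assignment
# ---------------------------------------------------------------------------


def derive_signatures(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    min_pct: float = 0.10,
    alpha: float = 0.05,
    exclude=("NT",),
) -> dict:
    """Subgroup signatures: upregulated genes, subgroup vs the rest.

    For each subgroup label (except ``exclude``), runs the rank-sum DE test
    against all other cells and keeps genes with positive log-FC,
    Bonferroni-adjusted p < ``alpha`` and at least ``min_pct`` expressing
    cells in the subgroup, ordered by adjusted p. Empty results are allowed
    (an empty tuple, not a GeneSignature).
    """
    from .stats import wilcoxon_de

    labels = labels.reindex(matrix.cell_ids)
    out = {}
    for name in [l for l in pd.unique(labels.dropna()) if l not in exclude]:
        cells_in = labels.index[labels == name]
        cells_out = labels.index[(labels != name) & labels.notna()]
        if len(cells_in) < 3:
            raise ValueError(f"subgroup {name!r} has fewer than 3 cells")
        if len(cells_out) < 3:
            raise ValueError(f"rest-of-cells group for {name!r} has fewer than 3 cells")
        de = wilcoxon_de(matrix, cells_in, cells_out, min_pct=min_pct)
        hits = de[(de.p_adjusted < alpha) & (de.log_fc > 0)].sort_values(
            ["p_adjusted", "p_value", "gene_id"]
        )
        genes = tuple(hits.gene_id)
        out[name] = GeneSignature(name, genes) if genes else genes
    return out


def assign_by_threshold(
    scores: pd.DataFrame,
    thresholds: ScoreThresholds | dict | None = None,
) -> pd.Series:
    """Assign each cell to the signature with the largest exceedance margin.

    A cell is a candidate for every signature whose score meets its
    threshold; among candidates the signature with the largest
    (score - threshold) margin wins; cells below every threshold are
    ``unassigned``.
    """
    if thresholds is None:
        thresholds = ScoreThresholds()
    if isinstance(thresholds, dict):
        thresholds = ScoreThresholds(dict(thresholds))
    th = thresholds.thresholds
    missing = [name for name in th if name not in scores.columns]
    if missing:
        raise ValueError(f"score columns missing for thresholds: {missing}")
    margins = scores[list(th)].sub(pd.Series(th))
    eligible = margins.ge(0)
    best = margins.idxmax(axis=1)
    labels = best.where(eligible.any(axis=1), UNASSIGNED)
    return labels.rename("assigned")
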