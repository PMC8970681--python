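"""Per-cell trained-immunity (TI) phenotypes and MCI/MC/NT subgrouping.

The TI phenotype of a restimulated cell is the vector of log-fold-changes of
the six TI marker genes — the proinflammatory cytokines IL1B, IL6, TNF and
the chemokines CXCL9, CXCL10, CXCL11 — relative to the average expression of
each marker in restimulated RPMI-control cells. Phenotypes are differences
of log(TP10K+1) values, i.e. natural-log fold changes.

Cells are grouped by complete-linkage hierarchical clustering (Euclidean
distance on the 6-D phenotype) cut into three branches, and branches are
named by their block means: both cytokine and chemokine blocks enhanced →
MCI; chemokines only → MC; otherwise nontrained (NT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .matrix import LAYER_LOGNORM, ExpressionMatrix

logger = logging.getLogger(__name__)

TI_CYTOKINES = ("IL1B", "IL6", "TNF")
TI_CHEMOKINES = ("CXCL9", "CXCL10", "CXCL11")

SUBGROUP_MCI = "MCI"
SUBGROUP_MC = "MC"
SUBGROUP_NT = "NT"


@dataclass(frozen=True)
class MarkerPanel:
    """The TI marker panel: disjoint cytokine and chemokine gene blocks."""

    cytokines: tuple = TI_CYTOKINES
    chemokines: tuple = TI_CHEMOKINES

    def __post_init__(self):
        if not self.cytokines or not self.chemokines:
            raise ValueError("both marker blocks must be non-empty")
        if set(self.cytokines) & set(self.chemokines):
            raise ValueError("cytokine and chemokine blocks must be disjoint")

    @property
    def genes(self) -> tuple:
        return tuple(self.cytokines) + tuple(self.chemokines)


@dataclass
class TIPhenotypeMatrix:
    """Cell x marker log-fold-change matrix with its control baseline."""

    values: pd.DataFrame  # cells x markers
    control_means: pd.Series
    panel: MarkerPanel

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("phenotype entries must be finite")
        if list(self.values.columns) != list(self.panel.genes):
            raise ValueError("marker order must match the panel")


@dataclass
class SubgroupAssignment:
    """Per-cell MCI/MC/NT labels plus the clustering evidence behind them."""

    labels: pd.Series  # index: cell_id; values in {MCI, MC, NT}
    raw_clusters: pd.Series
    linkage: np.ndarray
    block_means: pd.DataFrame  # raw cluster x (cytokine_mean, chemokine_mean)


def compute_ti_phenotype(
    trained: ExpressionMatrix,
    control: ExpressionMatrix,
    panel: MarkerPanel | None = None,
) -> TIPhenotypeMatrix:
    """Log-FC of each marker in each trained cell vs the control mean."""
    panel = panel or MarkerPanel()
    for m, name in ((trained, "trained"), (control, "control")):
        if m.layer_tag != LAYER_LOGNORM:
            raise ValueError(f"{name} matrix must be log-normalized")
    if control.n_cells == 0:
        raise ValueError("control population is empty")
    genes = list(panel.genes)
    t = trained.values[trained.gene_index(genes)]  # markers x cells
    c = control.values[control.gene_index(genes)]
    control_means = c.mean(axis=1)
    values = pd.DataFrame(
        (t - control_means[:, None]).T,
        index=pd.Index(trained.cell_ids, name="cell_id"),
        columns=genes,
    )
    return TIPhenotypeMatrix(values, pd.Series(control_means, index=genes), panel)


def cluster_ti_subgroups(phen: TIPhenotypeMatrix, k: int = 3):
    """Complete-linkage Euclidean clustering of phenotypes, cut to k branches.

    Returns ``(raw_labels, linkage_matrix)``; labels are 1..k in scipy's
    ``fcluster`` numbering.
    """
    X = phen.values.to_numpy()
    n = X.shape[0]
    if k > n:
        raise ValueError(f"cannot cut {n} cells into {k} clusters")
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(raw, index=phen.values.index, name="raw_cluster"), Z


def label_subgroups(
    raw_labels: pd.Series,
    phen: TIPhenotypeMatrix,
    activation_threshold: float = 0.0,
    linkage: np.ndarray | None = None,
) -> SubgroupAssignment:
    """Name raw clusters MCI/MC/NT from their marker-block mean log-FCs.

    A cluster is MCI when both block means exceed ``activation_threshold``,
    MC when only the chemokine block does, NT otherwise. If several clusters
    earn the same non-NT name, the one with the larger summed block means
    keeps it; a demoted claimant is re-evaluated against the remaining rules
    (an MCI loser whose chemokine block is enhanced becomes MC; anything
    else falls back to NT), so a near-zero cytokine mean cannot erase an
    otherwise clear chemokine-only cluster.
    """
    cyt = list(phen.panel.cytokines)
    chem = list(phen.panel.chemokines)
    rows = []
    for cl, idx in phen.values.groupby(raw_labels).groups.items():
        sub = phen.values.loc[idx]
        rows.append(
            {
                "raw_cluster": cl,
                "n_cells": len(idx),
                "cytokine_mean": float(sub[cyt].to_numpy().mean()),
                "chemokine_mean": float(sub[chem].to_numpy().mean()),
            }
        )
    block = pd.DataFrame(rows).set_index("raw_cluster").sort_index()

    def rule(row) -> str:
        if row.cytokine_mean > activation_threshold and row.chemokine_mean > activation_threshold:
            return SUBGROUP_MCI
        if row.chemokine_mean > activation_threshold:
            return SUBGROUP_MC
        return SUBGROUP_NT

    block["subgroup"] = [rule(r) for r in block.itertuples()]
    # tie rule: one cluster per non-NT name, the larger summed block means
    # wins; losers cascade to the next rule they satisfy
    for name in (SUBGROUP_MCI, SUBGROUP_MC):
        claimants = block.index[block["subgroup"] == name]
        if len(claimants) > 1:
            scores = block.loc[claimants, ["cytokine_mean", "chemokine_mean"]].sum(axis=1)
            for cl in claimants:
                if cl == scores.idxmax():
                    continue
                demoted = SUBGROUP_NT
                if name == SUBGROUP_MCI and block.loc[cl, "chemokine_mean"] > activation_threshold:
                    demoted = SUBGROUP_MC
                block.loc[cl, "subgroup"] = demoted

    labels = raw_labels.map(block["subgroup"]).rename("subgroup")
    return SubgroupAssignment(
        labels=labels,
        raw_clusters=raw_labels,
        linkage=linkage if linkage is not None else np.empty((0, 4)),
        block_means=block,
    )


def classify_ti_subgroups(
    trained: ExpressionMatrix,
    control: ExpressionMatrix,
    panel: MarkerPanel | None = None,
    k: int = 3,
    activation_threshold: float = 0.0,
) -> SubgroupAssignment:
    """Convenience wrapper: phenotype → cluster → label in one call."""
    phen = compute_ti_phenotype(trained, control, panel)
    raw, Z = cluster_ti_subgroups(phen, k=k)
    return label_subgroups(raw, phen, activation_threshold, linkage=Z)


def subgroup_proportions(
    assignment: SubgroupAssignment | pd.Series,
    metadata: pd.DataFrame,
    group_by,
) -> pd.DataFrame:
    """Per-group subgroup counts and proportions (rows sum to 1).

    ``metadata`` must carry ``cell_id``; ``group_by`` is a list of its
    columns. Groups without any labeled cell are omitted with a warning.
    """
    labels = assignment.labels if isinstance(assignment, SubgroupAssignment) else assignment
    md = metadata.set_index("cell_id") if "cell_id" in metadata.columns else metadata
    df = md.join(labels, how="left")
    n_unlabeled = int(df["subgroup"].isna().sum())
    if n_unlabeled:
        logger.warning("%d metadata cells have no subgroup label; omitted", n_unlabeled)
        df = df.dropna(subset=["subgroup"])
    group_by = [group_by] if isinstance(group_by, str) else list(group_by)
    counts = (
        df.groupby(group_by + ["subgroup"], observed=True)
        .size()
        .unstack("subgroup", fill_value=0)
    )
    for col in (SUBGROUP_MCI, SUBGROUP_MC, SUBGROUP_NT):
        if col not in counts.columns:
            counts[col] = 0
    counts = counts[[SUBGROUP_MCI, SUBGROUP_MC, SUBGROUP_NT]]
    props = counts.div(counts.sum(axis=1), axis=0)
    out = counts.join(props, lsuffix="_count", rsuffix="_prop")
    out.columns = [
        f"{c}" if c.endswith(("_count", "_prop")) else c for c in out.columns
    ]
    out["n_cells"] = counts.sum(axis=1)
    return out.reset_index()
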