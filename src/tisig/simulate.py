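"""Synthetic data with the statistical structure the analysis assumes.

Three generators, all fully determined by their seed:

* ``simulate_counts`` — negative-binomial UMI matrices for a restimulated
  (T2) experiment: an RPMI control population plus trained cells carrying
  latent MCI/MC/NT subgroups. The six TI markers (IL1B/IL6/TNF cytokines,
  CXCL9/10/11 chemokines) are boosted in their active subgroups with a
  bimodal strong/weak responder split (a ``marker_bimodality`` fraction of
  active cells in the strong state), which makes them over-dispersed
  relative to equally expressed genes and positively co-expressed within
  blocks while every active cell stays enhanced over control.
* ``simulate_gwas_fixture`` — a synthetic chromosome with spaced genes,
  trait SNPs planted near a designated DEG list, and reference SNPs placed
  at random, for proximity-enrichment testing.
* ``simulate_composition`` — per-sample Dirichlet subgroup proportions for
  two covariate groups, for composition regression testing.

The count model: gene weights are lognormal, per-cell library sizes are
gamma, donor effects are lognormal per (donor, gene), and counts are drawn
gamma-Poisson (negative binomial with dispersion ``nb_dispersion``, i.e.
var = mu + nb_dispersion * mu^2). Marker boosts multiply a cell's gene
weight by exp(effect) before the per-cell weight normalization, so boosting
markers slightly depresses the rest of the transcriptome, as in real
compositional UMI data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LAYER_RAW, ExpressionMatrix
from .phenotype import TI_CHEMOKINES, TI_CYTOKINES

TRAINED_CONDITIONS = ("BG", "UA", "oxLDL", "MDP")
CONTROL_CONDITION = "RPMI"
ENVIRONMENTS = ("M-MONO", "M-PBMC")

# observed T2 three-way composition used as the default latent mixture
DEFAULT_PROPORTIONS = (0.398, 0.222, 0.380)

# markers sit far out in the baseline weight distribution: cytokine and
# chemokine transcripts are individually ~1% of the transcriptome in
# LPS-restimulated macrophages, so their baseline counts are never zero
_MARKER_WEIGHT_QUANTILE_Z = 3.3


@dataclass
class SimulationConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_genes: int = 2000
    n_control_cells: int = 2000
    n_trained_cells: int = 5000
    subgroup_proportions: tuple = DEFAULT_PROPORTIONS
    baseline_log_mean_mu: float = 0.0
    baseline_log_mean_sd: float = 1.0
    nb_dispersion: float = 0.02
    library_size_mean: float = 10000.0
    library_size_shape: float = 20.0
    marker_effect_cytokine: float = 1.5
    marker_effect_chemokine: float = 1.5
    marker_bimodality: float = 0.7
    marker_contrast: float = 0.5
    n_donors: int = 3
    donor_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.subgroup_proportions, dtype=float)
        if p.shape != (3,) or (p < 0).any():
            raise ValueError("subgroup_proportions must be 3 non-negative values")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"subgroup_proportions must sum to 1 (got {p.sum()!r})")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not (0.0 <= self.marker_bimodality <= 1.0):
            raise ValueError("marker_bimodality must lie in [0, 1]")
        for name in ("marker_effect_cytokine", "marker_effect_chemokine", "donor_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Planted per-cell subgroups and per-gene marker flags."""

    cell_subgroup: np.ndarray  # 'MCI' / 'MC' / 'NT' / 'control'
    marker_genes: dict  # {'cytokine': [...], 'chemokine': [...]}
    gene_active: np.ndarray  # bool per gene


def simulate_counts(config: SimulationConfig | None = None):
    """Draw a raw count matrix plus metadata and ground truth.

    Returns ``(ExpressionMatrix, metadata DataFrame, GroundTruth)``. Control
    cells are condition RPMI; trained cells are split uniformly across
    BG/UA/oxLDL/MDP. All cells are timepoint T2.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    nc, nt = config.n_control_cells, config.n_trained_cells
    n_cells = nc + nt
    markers = list(TI_CYTOKINES) + list(TI_CHEMOKINES)
    if n_genes < len(markers):
        raise ValueError("n_genes must be at least the 6 marker genes")

    gene_ids = np.array(markers + [f"G{i:04d}" for i in range(1, n_genes - len(markers) + 1)],
                        dtype=object)
    mu, sd = config.baseline_log_mean_mu, config.baseline_log_mean_sd
    weights = rng.lognormal(mu, sd, size=n_genes)
    weights[: len(markers)] = np.exp(mu + _MARKER_WEIGHT_QUANTILE_Z * sd)

    subgroup = np.concatenate([
        np.full(nc, "control", dtype=object),
        rng.choice(["MCI", "MC", "NT"], size=nt, p=np.asarray(config.subgroup_proportions)),
    ])
    donors = rng.integers(0, config.n_donors, size=n_cells)
    donor_eff = np.exp(rng.normal(0.0, config.donor_sd, size=(config.n_donors, n_genes)))
    lib = rng.gamma(config.library_size_shape,
                    config.library_size_mean / config.library_size_shape, size=n_cells)

    W = weights[:, None] * donor_eff[donors].T  # genes x cells

    # Active-subgroup cells split into strong and weak responder states per
    # marker: strong (fraction marker_bimodality) at effect + (1-f)*gap,
    # weak at effect - f*gap with gap = marker_contrast * effect, so the
    # subgroup mean log-effect equals `effect` exactly. The two-state
    # mixture makes markers over-dispersed yet keeps every active cell
    # enhanced over control, so subgroup identity stays recoverable.
    cyt_active = np.isin(subgroup, ["MCI"])
    chem_active = np.isin(subgroup, ["MCI", "MC"])
    f = config.marker_bimodality
    for gi, gene in enumerate(markers):
        active = cyt_active if gene in TI_CYTOKINES else chem_active
        effect = (config.marker_effect_cytokine if gene in TI_CYTOKINES
                  else config.marker_effect_chemokine)
        gap = config.marker_contrast * effect
        strong = active & (rng.random(n_cells) < f)
        weak = active & ~strong
        W[gi, strong] *= np.exp(effect + (1.0 - f) * gap)
        W[gi, weak] *= np.exp(effect - f * gap)

    mean = W / W.sum(axis=0, keepdims=True) * lib
    if config.nb_dispersion > 0:
        lam = rng.gamma(1.0 / config.nb_dispersion, mean * config.nb_dispersion)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = np.array([f"C{i:05d}" for i in range(1, n_cells + 1)], dtype=object)
    condition = np.concatenate([
        np.full(nc, CONTROL_CONDITION, dtype=object),
        rng.choice(TRAINED_CONDITIONS, size=nt),
    ])
    environment = rng.choice(ENVIRONMENTS, size=n_cells)
    metadata = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor": np.array([f"D{d + 1}" for d in donors], dtype=object),
            "environment": environment,
            "condition": condition,
            "timepoint": np.full(n_cells, "T2", dtype=object),
        }
    )
    gene_active = np.zeros(n_genes, dtype=bool)
    gene_active[: len(markers)] = True
    truth = GroundTruth(
        cell_subgroup=subgroup,
        marker_genes={"cytokine": list(TI_CYTOKINES), "chemokine": list(TI_CHEMOKINES)},
        gene_active=gene_active,
    )
    return ExpressionMatrix(counts, gene_ids, cell_ids, LAYER_RAW), metadata, truth


# ---------------------------------------------------------------------------
# GWAS fixture
# ---------------------------------------------------------------------------

_GENE_LEN = 10_000
_GENE_GAP_PAD = 10_000


def simulate_gwas_fixture(
    n_genes: int,
    n_trait_snps: int,
    n_ref_snps: int,
    planted_overlap: float,
    window: int = 250_000,
    seed: int = 0,
):
    """Genes on one synthetic chromosome plus trait and reference SNPs.

    Half of the genes (chosen at random) form the designated DEG set;
    ``round(planted_overlap * n_deg)`` trait SNPs are planted in-window of
    distinct DEG genes and the remaining trait SNPs, like all reference
    SNPs, land near uniformly random genes. Genes are spaced more than two
    windows apart so a SNP can be proximal to at most one gene.

    Returns ``(genes_df, trait_df, ref_df, truth)`` where ``truth`` holds
    the DEG list and the exact proximal gene sets.
    """
    if not (0.0 <= planted_overlap <= 1.0):
        raise ValueError("planted_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    spacing = _GENE_LEN + 2 * window + _GENE_GAP_PAD
    starts = np.arange(n_genes, dtype=np.int64) * spacing + window + _GENE_GAP_PAD
    ends = starts + _GENE_LEN
    gene_ids = np.array([f"G{i:04d}" for i in range(1, n_genes + 1)], dtype=object)
    genes_df = pd.DataFrame(
        {"chrom": "chrS", "start": starts, "end": ends, "gene_id": gene_ids}
    )

    n_deg = n_genes // 2
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    n_planted = int(round(planted_overlap * n_deg))
    if n_planted > n_trait_snps:
        raise ValueError(
            f"geometry infeasible: {n_planted} planted hits need at least that many trait SNPs"
        )

    def _snp_near(gi: int) -> int:
        lo = max(1, int(starts[gi]) + 1 - window)
        hi = int(ends[gi]) + window  # 1-based inclusive
        return int(rng.integers(lo, hi + 1))

    planted_genes = rng.choice(deg_idx, size=n_planted, replace=False)
    trait_pos = [_snp_near(gi) for gi in planted_genes]
    trait_pos += [_snp_near(int(rng.integers(0, n_genes)))
                  for _ in range(n_trait_snps - n_planted)]
    ref_pos = [_snp_near(int(rng.integers(0, n_genes))) for _ in range(n_ref_snps)]

    trait_df = pd.DataFrame(
        {"chrom": "chrS", "pos": trait_pos,
         "snp_id": [f"rsT{i + 1}" for i in range(n_trait_snps)]}
    )
    ref_df = pd.DataFrame(
        {"chrom": "chrS", "pos": ref_pos,
         "snp_id": [f"rsR{i + 1}" for i in range(n_ref_snps)]}
    )

    from .stats import genes_near_snps  # local import to avoid cycle at import time

    truth = {
        "deg_genes": sorted(gene_ids[deg_idx]),
        "trait_proximal": sorted(genes_near_snps(genes_df, trait_df, window)),
        "reference_proximal": sorted(genes_near_snps(genes_df, ref_df, window)),
    }
    return genes_df, trait_df, ref_df, truth


def simulate_composition(
    n_samples_per_group: int,
    alpha_group1,
    alpha_group2,
    seed: int = 0,
    components=("MCI", "MC", "NT"),
) -> pd.DataFrame:
    """Per-sample Dirichlet proportions for two groups (rows sum to 1)."""
    a1 = np.asarray(alpha_group1, dtype=float)
    a2 = np.asarray(alpha_group2, dtype=float)
    if (a1 <= 0).any() or (a2 <= 0).any():
        raise ValueError("Dirichlet concentrations must be strictly positive")
    if len(a1) != len(components) or len(a2) != len(components):
        raise ValueError("alpha vectors must match the number of components")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, alpha in enumerate((a1, a2), start=1):
        props = rng.dirichlet(alpha, size=n_samples_per_group)
        for si in range(n_samples_per_group):
            row = {"sample_id": f"S{gi}_{si + 1}", "group": f"g{gi}"}
            row.update({c: props[si, j] for j, c in enumerate(components)})
            rows.append(row)
    return pd.DataFrame(rows)
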