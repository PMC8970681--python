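"""Stage orchestration: run the analysis end to end with provenance.

Stages (dependency order): simulate → qc → normalize → heterogeneity →
classify → score → de → compose → gwas-enrich → ora. ``run_pipeline``
executes a requested subset in order, erroring when an upstream artifact is
missing, and writes a machine-readable run report (config hash, seed,
package version, per-stage outputs) next to the outputs. ``demo`` is the
one-command synthetic end-to-end path.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .heterogeneity import dispersion_index, expressed_genes, spearman_coexpression, variance_ranking
from .matrix import QCParams, lognormalize, qc_filter, read_counts, read_metadata, write_counts
from .phenotype import MarkerPanel, classify_ti_subgroups, subgroup_proportions
from .signatures import (MC_SIGNATURE, MCI_SIGNATURE, ScoreThresholds, assign_by_threshold,
                         read_gmt, score_signatures)
from .simulate import CONTROL_CONDITION, SimulationConfig, simulate_counts
from .stats import dirichlet_regression, fisher_gwas_enrichment, genes_near_snps, \
    overrepresentation_gmt, tr_genes

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "normalize", "heterogeneity", "classify", "score",
          "de", "compose", "gwas-enrich", "ora")

_DEPENDS = {
    "qc": ("counts",),
    "normalize": ("qc_counts",),
    "heterogeneity": ("lognorm",),
    "classify": ("lognorm", "metadata"),
    "score": ("lognorm",),
    "de": ("lognorm", "metadata", "labels"),
    "compose": ("labels", "metadata"),
    "gwas-enrich": ("gene_coords", "trait_snps", "ref_snps", "tr_gene_set"),
    "ora": ("gene_sets", "gene_list"),
}


@dataclass
class PipelineConfig:
    """Paths, parameters and the single seed driving a run."""

    outdir: Path = Path("tisig_out")
    counts: Path | None = None
    metadata: Path | None = None
    signatures_gmt: Path | None = None
    gene_coords: Path | None = None
    trait_snps: Path | None = None
    ref_snps: Path | None = None
    qc: QCParams = field(default_factory=QCParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    top_frac: float = 0.03
    thresholds: dict = field(default_factory=lambda: dict(ScoreThresholds().thresholds))
    gwas_window: int = 250_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("counts", "metadata", "signatures_gmt", "gene_coords",
                    "trait_snps", "ref_snps"):
            if raw.get(key) is not None:
                p = Path(raw[key])
                if not p.exists():
                    raise FileNotFoundError(f"configured path does not exist: {p}")
                kwargs[key] = p
        if "qc" in raw:
            kwargs["qc"] = QCParams(**raw["qc"])
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        for key in ("top_frac", "thresholds", "gwas_window", "seed", "outdir"):
            if key in raw:
                kwargs[key] = Path(raw[key]) if key == "outdir" else raw[key]
        return cls(**kwargs)

    def digest(self) -> str:
        def _default(o):
            return str(o) if isinstance(o, Path) else o.__dict__
        return hashlib.sha256(
            json.dumps(self.__dict__, default=_default, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, stages) -> dict:
    """Execute the requested stages in dependency order; returns artifacts.

    Raises ``ValueError`` naming the missing upstream artifact when a stage
    is requested without its inputs (either from an earlier stage or from a
    configured file).
    """
    requested = list(stages)
    bad = [s for s in requested if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in set(requested)]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    art: dict = {}
    if config.counts is not None:
        art["counts"] = read_counts(config.counts)
    if config.metadata is not None:
        art["metadata"] = read_metadata(config.metadata)

    report = {"version": __version__, "seed": config.seed,
              "config_hash": config.digest(), "stages": stages, "outputs": {}}

    def _need(stage, *keys):
        for key in keys:
            if key not in art:
                raise ValueError(
                    f"stage {stage!r} needs artifact {key!r}; run its upstream stage "
                    f"or configure the corresponding input path"
                )

    def _save(stage, name, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        report["outputs"].setdefault(stage, []).append(str(path))

    for stage in stages:
        logger.info("stage %s", stage)
        if stage == "simulate":
            sim = SimulationConfig(**{**config.simulation.__dict__, "seed": config.seed})
            counts, metadata, truth = simulate_counts(sim)
            art.update(counts=counts, metadata=metadata, truth=truth)
            write_counts(counts, outdir / "sim_counts")
            metadata.to_csv(outdir / "sim_metadata.tsv", sep="\t", index=False)
            report["outputs"]["simulate"] = [str(outdir / "sim_counts"),
                                             str(outdir / "sim_metadata.tsv")]
        elif stage == "qc":
            _need(stage, "counts")
            art["qc_counts"], qc_report = qc_filter(art["counts"], config.qc)
            (outdir / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
            report["outputs"]["qc"] = [str(outdir / "qc_report.json")]
        elif stage == "normalize":
            if "qc_counts" not in art and "counts" in art:
                art["qc_counts"], _ = qc_filter(art["counts"], config.qc)
            _need(stage, "qc_counts")
            art["lognorm"] = lognormalize(art["qc_counts"])
        elif stage == "heterogeneity":
            _need(stage, "lognorm")
            ln = art["lognorm"]
            genes = expressed_genes(ln)
            panel = MarkerPanel()
            _save(stage, "variance_table.tsv", variance_ranking(ln, genes or None))
            _save(stage, "dispersion_table.tsv", dispersion_index(ln, genes or None))
            markers = [g for g in panel.genes if g in set(ln.gene_ids)]
            if markers:
                _save(stage, "coexpression.tsv", spearman_coexpression(ln, markers))
        elif stage == "classify":
            _need(stage, "lognorm", "metadata")
            ln, md = art["lognorm"], art["metadata"]
            ctrl = md.loc[md["condition"] == CONTROL_CONDITION, "cell_id"]
            trained = md.loc[md["condition"] != CONTROL_CONDITION, "cell_id"]
            ctrl = [c for c in ctrl if c in set(ln.cell_ids)]
            trained = [c for c in trained if c in set(ln.cell_ids)]
            assignment = classify_ti_subgroups(ln.subset(cells=trained), ln.subset(cells=ctrl))
            art["assignment"] = assignment
            art["labels"] = assignment.labels
            out = assignment.labels.to_frame().join(assignment.raw_clusters)
            _save(stage, "subgroup_assignment.tsv", out.reset_index())
            (outdir / "dendrogram.json").write_text(
                json.dumps(assignment.linkage.tolist()))
            report["outputs"]["classify"].append(str(outdir / "dendrogram.json"))
        elif stage == "score":
            _need(stage, "lognorm")
            sigs = (read_gmt(config.signatures_gmt) if config.signatures_gmt
                    else [MCI_SIGNATURE, MC_SIGNATURE])
            scores = score_signatures(art["lognorm"], sigs, top_frac=config.top_frac,
                                      tie_seed=config.seed)
            art["scores"] = scores
            assigned = assign_by_threshold(scores, {k: v for k, v in config.thresholds.items()
                                                    if k in scores.columns})
            _save(stage, "signature_scores.tsv",
                  scores.join(assigned).reset_index())
        elif stage == "de":
            _need(stage, "lognorm", "metadata", "labels")
            result = tr_genes(art["lognorm"], art["metadata"], art["labels"])
            art["tr"] = result
            frames = [t.assign(subgroup=sg, stimulus=st)
                      for (sg, st), t in result["tables"].items() if t is not None]
            if frames:
                _save(stage, "tr_genes.tsv", pd.concat(frames, ignore_index=True))
            _save(stage, "tr_genes_shared.tsv", result["shared"])
            art["tr_gene_set"] = sorted(set(result["shared"]["gene_id"])) or sorted(
                {g for f in frames for g in f.loc[f["significant"], "gene_id"]})
            art.setdefault("gene_list", art["tr_gene_set"])
        elif stage == "compose":
            _need(stage, "labels", "metadata")
            comp = subgroup_proportions(art["labels"], art["metadata"],
                                        ["donor", "environment", "condition"])
            comp = comp[comp["condition"] != CONTROL_CONDITION]
            _save(stage, "composition.tsv", comp)
            props = comp.rename(columns={"MCI_prop": "MCI", "MC_prop": "MC", "NT_prop": "NT"})
            levels = props["environment"].nunique()
            if levels >= 2 and props.groupby("environment").size().min() >= 2:
                fit = dirichlet_regression(props, covariates=["environment"])
                (outdir / "composition_test.json").write_text(json.dumps(
                    {k: v for k, v in fit.items()
                     if k in ("log_likelihood", "log_likelihood_null", "lrt_stat",
                              "df", "p_value", "converged")}, indent=2))
                report["outputs"]["compose"].append(str(outdir / "composition_test.json"))
        elif stage == "gwas-enrich":
            if config.gene_coords is not None:
                art["gene_coords"] = pd.read_csv(config.gene_coords, sep="\t", header=None,
                                                 names=["chrom", "start", "end", "gene_id"])
                art["trait_snps"] = pd.read_csv(config.trait_snps, sep="\t")
                art["ref_snps"] = pd.read_csv(config.ref_snps, sep="\t")
            _need(stage, "gene_coords", "trait_snps", "ref_snps", "tr_gene_set")
            trait_prox = genes_near_snps(art["gene_coords"], art["trait_snps"], config.gwas_window)
            ref_prox = genes_near_snps(art["gene_coords"], art["ref_snps"], config.gwas_window)
            enr = fisher_gwas_enrichment(art["tr_gene_set"], trait_prox, ref_prox)
            (outdir / "gwas_enrichment.json").write_text(json.dumps(
                {"table": enr.table.tolist(), "odds_ratio": enr.odds_ratio,
                 "p_value": enr.p_value, "gene_lists": enr.gene_lists},
                indent=2, default=str))
            report["outputs"]["gwas-enrich"] = [str(outdir / "gwas_enrichment.json")]
        elif stage == "ora":
            if config.signatures_gmt is not None:
                art["gene_sets"] = read_gmt(config.signatures_gmt)
            _need(stage, "gene_sets", "gene_list")
            universe = (list(art["lognorm"].gene_ids) if "lognorm" in art
                        else sorted({g for s in art["gene_sets"] for g in s.genes}
                                    | set(art["gene_list"])))
            _save(stage, "ora.tsv",
                  overrepresentation_gmt(art["gene_list"], art["gene_sets"], universe))

    (outdir / "run_report.json").write_text(json.dumps(report, indent=2))
    art["report"] = report
    return art


def demo(outdir, seed: int = 0, simulation: SimulationConfig | None = None) -> dict:
    """Synthetic end-to-end run: simulate → classify → score → de → compose."""
    config = PipelineConfig(outdir=Path(outdir), seed=seed,
                            simulation=simulation or SimulationConfig())
    return run_pipeline(config, ["simulate", "qc", "normalize", "heterogeneity",
                                 "classify", "score", "de", "compose"])
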