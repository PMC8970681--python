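"""Count-matrix container, standard-format I/O, QC filtering and normalization.

The working object is a gene x cell UMI matrix. Raw counts come in as
MatrixMarket triplets (``matrix.mtx`` + ``features.tsv``/``genes.tsv`` +
``barcodes.tsv``) or as dense TSV/CSV with gene rows and cell columns. After
quality control the matrix is normalized to log(TP10K + 1): per-cell counts
scaled to 10,000 total, natural-log transformed with a pseudocount of 1.

QC follows the order used for plate-based (SORT-seq style) data: genes
detected in fewer than ``min_cells_per_gene`` cells are removed first, then
cells are filtered on detected-gene count and on mitochondrial / ERCC
spike-in count fractions. Spike-in genes participate in the fraction
computation and are dropped from the output afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

LAYER_RAW = "raw"
LAYER_LOGNORM = "lognorm"

METADATA_COLUMNS = ("cell_id", "donor", "environment", "condition", "timepoint")

TP10K_SCALE = 10_000.0


def _check_unique(ids: np.ndarray, what: str) -> None:
    uniq, counts = np.unique(ids, return_counts=True)
    if len(uniq) != len(ids):
        dup = uniq[counts > 1][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class ExpressionMatrix:
    """Gene x cell expression matrix with identifiers and a layer tag.

    ``values`` holds non-negative integers for the ``raw`` layer and
    non-negative reals for the ``lognorm`` layer. Gene and cell identifiers
    are unique and ordered.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer_tag: str = LAYER_RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D gene x cell matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.layer_tag not in (LAYER_RAW, LAYER_LOGNORM):
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.values.size and self.values.min() < 0:
            raise ValueError("negative entries are not allowed")
        if self.layer_tag == LAYER_RAW:
            if self.values.size and not np.all(np.mod(self.values, 1) == 0):
                raise ValueError("raw layer requires integer counts")
            self.values = self.values.astype(np.int64, copy=False)
        else:
            self.values = self.values.astype(np.float64, copy=False)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"cells not in matrix: {missing}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def subset(self, genes=None, cells=None) -> "ExpressionMatrix":
        gi = slice(None) if genes is None else self.gene_index(genes)
        ci = slice(None) if cells is None else self.cell_index(cells)
        return ExpressionMatrix(
            self.values[gi][:, ci],
            self.gene_ids[gi],
            self.cell_ids[ci],
            self.layer_tag,
        )

    def totals(self) -> np.ndarray:
        """Per-cell total counts (column sums)."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def to_anndata(self):
        """Cell x gene AnnData view (scanpy orientation)."""
        import anndata

        return anndata.AnnData(
            X=np.asarray(self.values, dtype=np.float64).T.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.gene_ids.copy(), self.cell_ids.copy(), self.layer_tag
        )


@dataclass
class QCParams:
    """Cell/gene quality-control thresholds.

    Cells are kept when ``min_genes <= detected <= max_genes`` (bounds
    inclusive: the removal rules are strict "less than" / "more than"), the
    mitochondrial count fraction is <= ``max_mt_frac`` and the spike-in
    fraction is <= ``max_spikein_frac``.
    """

    min_genes: int = 100
    max_genes: int = 7000
    max_mt_frac: float = 0.25
    max_spikein_frac: float = 0.90
    min_cells_per_gene: int = 3
    mt_prefix: str = "MT-"
    spikein_prefix: str = "ERCC-"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_mt_frac <= 1.0 and 0.0 <= self.max_spikein_frac <= 1.0):
            raise ValueError("fraction thresholds must lie in [0, 1]")
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be smaller than max_genes")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MTX_MATRIX = "matrix.mtx"
_MTX_BARCODES = "barcodes.tsv"
_MTX_FEATURES = ("features.tsv", "genes.tsv")


def _resolve_mtx_dir(path: Path) -> Path:
    if path.is_dir():
        return path
    return path.parent


def read_counts(path, format: str | None = None) -> ExpressionMatrix:
    """Read a raw gene x cell count matrix from MTX triplet or dense TSV/CSV.

    ``format`` is ``"mtx"`` or ``"tsv"``; when omitted it is inferred from
    the path (a directory or ``.mtx`` file means MTX).
    """
    path = Path(path)
    if format is None:
        format = "mtx" if path.is_dir() or path.suffix == ".mtx" else "tsv"
    if format == "mtx":
        return _read_mtx(path)
    if format == "tsv":
        return _read_dense(path)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx(path: Path) -> ExpressionMatrix:
    d = _resolve_mtx_dir(path)
    mtx = path if path.suffix == ".mtx" else d / _MTX_MATRIX
    if not mtx.exists():
        raise FileNotFoundError(f"missing matrix file: {mtx}")
    features = next((d / f for f in _MTX_FEATURES if (d / f).exists()), None)
    if features is None:
        raise FileNotFoundError(f"missing sidecar file: {d / _MTX_FEATURES[0]}")
    barcodes = d / _MTX_BARCODES
    if not barcodes.exists():
        raise FileNotFoundError(f"missing sidecar file: {barcodes}")

    m = spio.mmread(mtx)
    values = np.asarray(m.todense() if sparse.issparse(m) else m)
    feat = pd.read_csv(features, sep="\t", header=None, dtype=str)
    gene_ids = feat.iloc[:, 0].to_numpy()
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None, dtype=str).iloc[:, 0].to_numpy()
    if values.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {values.shape} does not match sidecars "
            f"({len(gene_ids)} features, {len(cell_ids)} barcodes)"
        )
    if values.size and not np.all(np.mod(values, 1) == 0):
        raise ValueError("non-integer entries in raw MTX matrix")
    return ExpressionMatrix(values.astype(np.int64), gene_ids, cell_ids, LAYER_RAW)


def _read_dense(path: Path) -> ExpressionMatrix:
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    gene_ids = df.index.astype(str).to_numpy()
    _check_unique(gene_ids, "gene")
    values = df.to_numpy()
    if values.size and not np.all(np.mod(values, 1) == 0):
        raise ValueError(f"non-integer entries in raw matrix {path}")
    return ExpressionMatrix(
        values.astype(np.int64), gene_ids, df.columns.astype(str).to_numpy(), LAYER_RAW
    )


def write_counts(matrix: ExpressionMatrix, path, format: str | None = None) -> None:
    """Write a raw matrix so that ``read_counts`` recovers it exactly."""
    if matrix.layer_tag != LAYER_RAW:
        raise ValueError("write_counts expects the raw layer")
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix in (".tsv", ".csv") else "mtx"
    if format == "mtx":
        d = path if path.suffix != ".mtx" else path.parent
        d.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(
            str(d / _MTX_MATRIX),
            sparse.coo_matrix(matrix.values),
            field="integer",
        )
        # mmwrite may append .mtx twice on some names; normalise
        written = d / (_MTX_MATRIX + ".mtx")
        if written.exists():
            written.replace(d / _MTX_MATRIX)
        with open(d / _MTX_FEATURES[0], "w") as fh:
            for g in matrix.gene_ids:
                fh.write(f"{g}\t{g}\n")
        with open(d / _MTX_BARCODES, "w") as fh:
            for c in matrix.cell_ids:
                fh.write(f"{c}\n")
    elif format == "tsv":
        sep = "," if path.suffix == ".csv" else "\t"
        path.parent.mkdir(parents=True, exist_ok=True)
        matrix.to_frame().to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Read a per-cell metadata TSV; optionally validate against a matrix."""
    md = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing required columns: {missing_cols}")
    if matrix is not None:
        extra = set(md["cell_id"]) - set(matrix.cell_ids)
        if extra:
            raise ValueError(f"metadata cells absent from matrix: {sorted(extra)[:5]}")
    return md


# ---------------------------------------------------------------------------
# QC + normalization
# ---------------------------------------------------------------------------


def qc_filter(matrix: ExpressionMatrix, params: QCParams | None = None):
    """Apply gene- then cell-level QC; returns (filtered matrix, report).

    Rare genes (detected in fewer than ``min_cells_per_gene`` cells) are
    removed first. Detected-gene counts per cell are then computed on the
    remaining non-spike-in genes; MT and spike-in fractions are computed
    over all remaining counts. Spike-in genes are dropped from the output
    after the fractions are taken.
    """
    if matrix.layer_tag != LAYER_RAW:
        raise ValueError("qc_filter expects the raw layer")
    params = params or QCParams()

    v = matrix.values
    detected_cells = (v > 0).sum(axis=1)
    keep_gene = detected_cells >= params.min_cells_per_gene
    n_rare = int((~keep_gene).sum())
    v = v[keep_gene]
    genes = matrix.gene_ids[keep_gene]

    is_spike = np.array([str(g).startswith(params.spikein_prefix) for g in genes], dtype=bool)
    is_mt = np.array([str(g).startswith(params.mt_prefix) for g in genes], dtype=bool)

    totals = v.sum(axis=0).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    mt_frac = v[is_mt].sum(axis=0) / safe if is_mt.any() else np.zeros(v.shape[1])
    spike_frac = v[is_spike].sum(axis=0) / safe if is_spike.any() else np.zeros(v.shape[1])
    detected = (v[~is_spike] > 0).sum(axis=0)

    fail_min = detected < params.min_genes
    fail_max = detected > params.max_genes
    fail_mt = mt_frac > params.max_mt_frac
    fail_spike = spike_frac > params.max_spikein_frac
    keep_cell = ~(fail_min | fail_max | fail_mt | fail_spike)

    report = {
        "n_genes_in": int(matrix.n_genes),
        "n_cells_in": int(matrix.n_cells),
        "genes_removed_rare": n_rare,
        "genes_removed_spikein": int(is_spike.sum()),
        "cells_removed_min_genes": int(fail_min.sum()),
        "cells_removed_max_genes": int(fail_max.sum()),
        "cells_removed_mt_frac": int(fail_mt.sum()),
        "cells_removed_spikein_frac": int(fail_spike.sum()),
        "cells_removed_total": int((~keep_cell).sum()),
        "n_genes_out": int((~is_spike).sum()),
        "n_cells_out": int(keep_cell.sum()),
    }

    if report["n_genes_out"] == 0 or report["n_cells_out"] == 0:
        raise ValueError(f"QC removed every gene or cell (report: {report})")

    out = ExpressionMatrix(
        v[~is_spike][:, keep_cell],
        genes[~is_spike],
        matrix.cell_ids[keep_cell],
        LAYER_RAW,
    )
    return out, report


def lognormalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log(TP10K + 1): per-cell counts scaled to 10,000 total, then ln(1 + x)."""
    if matrix.layer_tag != LAYER_RAW:
        raise ValueError("lognormalize expects the raw layer")
    totals = matrix.totals().astype(float)
    if (totals <= 0).any():
        bad = matrix.cell_ids[totals <= 0][:5]
        raise ValueError(
            f"cells with zero total counts (e.g. {list(bad)}); run qc_filter first"
        )
    values = np.log1p(TP10K_SCALE * matrix.values / totals)
    return ExpressionMatrix(values, matrix.gene_ids.copy(), matrix.cell_ids.copy(), LAYER_LOGNORM)
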