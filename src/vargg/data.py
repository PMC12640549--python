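"""Spot-level data model, Visium-layout I/O, preprocessing, and PCA.

The central container is :class:`SpatialDataset`: a spots x genes expression
matrix with per-spot 2-D coordinates, plus optional morphology features and
ground-truth domain labels. Readers accept the 10x Genomics Visium directory
layout (matrix-market triplet + barcodes/features tables + tissue-positions
table, both the header-less "list" dialect and the headered one).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from sklearn.decomposition import PCA

from .errors import ConsistencyError, InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialDataset",
    "ProcessedMatrix",
    "read_visium",
    "read_generic",
    "write_dataset",
    "preprocess",
    "pca_reduce",
    "read_labels_tsv",
    "write_labels_tsv",
]


@dataclass
class SpatialDataset:
    """Spots x genes expression with spatial coordinates.

    Attributes
    ----------
    expression : (N, O) float array, non-negative before preprocessing
    coords : (N, 2) float array, (row_pixel, col_pixel) for Visium input
    spot_ids, gene_ids : unique string identifiers
    morphology : optional (N, F) float array of per-spot image features
    labels : optional (N,) integer array of ground-truth domains
    provenance : ordered record of preprocessing steps applied
    """

    expression: np.ndarray
    coords: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    morphology: np.ndarray | None = None
    labels: np.ndarray | None = None
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.expression = np.asarray(self.expression, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = np.asarray(self.spot_ids, dtype=str)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        n, o = self.expression.shape
        if n < 1 or o < 1:
            raise ParameterError("expression must be at least 1 spot x 1 gene")
        if self.coords.shape != (n, 2):
            raise ConsistencyError(
                f"coords shape {self.coords.shape} does not match {n} spots")
        if self.spot_ids.shape[0] != n:
            raise ConsistencyError("spot_ids length does not match expression rows")
        if self.gene_ids.shape[0] != o:
            raise ConsistencyError("gene_ids length does not match expression columns")
        if len(set(self.spot_ids.tolist())) != n:
            raise ConsistencyError("duplicate spot_ids")
        if len(set(self.gene_ids.tolist())) != o:
            raise ConsistencyError("duplicate gene_ids")
        if not np.all(np.isfinite(self.expression)):
            raise ConsistencyError("expression contains non-finite values")
        if self.morphology is not None:
            self.morphology = np.asarray(self.morphology, dtype=float)
            if self.morphology.shape[0] != n:
                raise ConsistencyError("morphology rows do not match spot count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape[0] != n:
                raise ConsistencyError("labels length does not match spot count")

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]


@dataclass
class ProcessedMatrix:
    """A derived spots x M matrix plus the record of how it was produced."""

    values: np.ndarray
    transform_log: list
    components: np.ndarray | None = None
    mean: np.ndarray | None = None
    explained_variance: np.ndarray | None = None

    def reconstruct(self) -> np.ndarray:
        """Map component scores back to the original feature space."""
        if self.components is None:
            raise ParameterError("no PCA components stored; cannot reconstruct")
        return self.values @ self.components + self.mean


# ---------------------------------------------------------------------------
# Visium-layout I/O
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col",
                     "pxl_row_in_fullres", "pxl_col_in_fullres"]


def _find_file(root: Path, stems: list[str]) -> Path:
    """Locate the first existing candidate file in root or one subdir level."""
    for stem in stems:
        for cand in [root / stem, *sorted(root.glob(f"*/{stem}"))]:
            if cand.is_file():
                return cand
    raise InputError(f"missing file: none of {stems} found under {root}")


def _read_table(path: Path, **kw) -> pd.DataFrame:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return pd.read_csv(fh, **kw)


def read_visium(path) -> SpatialDataset:
    """Read a 10x Visium-layout directory restricted to in-tissue spots.

    Coordinates are full-resolution pixel positions in (row, col) order and
    spot order follows the barcode table. A ``labels.tsv`` written by
    :func:`write_dataset` is picked up automatically when present.
    """
    root = Path(path)
    if not root.is_dir():
        raise InputError(f"missing file: {root} is not a directory")
    mtx_path = _find_file(root, ["matrix.mtx", "matrix.mtx.gz"])
    bc_path = _find_file(root, ["barcodes.tsv", "barcodes.tsv.gz"])
    ft_path = _find_file(root, ["features.tsv", "features.tsv.gz",
                                "genes.tsv", "genes.tsv.gz"])
    pos_path = _find_file(root, ["tissue_positions.csv",
                                 "tissue_positions_list.csv",
                                 "tissue_positions.csv.gz",
                                 "tissue_positions_list.csv.gz"])

    mat = scipy.io.mmread(str(mtx_path))  # genes x barcodes per 10x convention
    mat = scipy.sparse.csr_matrix(mat).T.toarray().astype(float)  # spots x genes
    barcodes = _read_table(bc_path, sep="\t", header=None)[0].astype(str).to_numpy()
    features = _read_table(ft_path, sep="\t", header=None)
    gene_ids = features[0].astype(str).to_numpy()
    if mat.shape != (len(barcodes), len(gene_ids)):
        raise ConsistencyError(
            f"matrix shape {mat.shape} does not match "
            f"{len(barcodes)} barcodes x {len(gene_ids)} features")

    first = _read_table(pos_path, header=None, nrows=1)
    headered = str(first.iloc[0, 0]).strip().lower() == "barcode"
    pos = _read_table(pos_path, header=0 if headered else None)
    pos.columns = _POSITION_COLUMNS[: pos.shape[1]]
    pos["barcode"] = pos["barcode"].astype(str)
    pos = pos.set_index("barcode")

    missing = [b for b in barcodes if b not in pos.index]
    if missing:
        raise ConsistencyError(
            f"barcodes absent from positions table: {missing}")
    pos = pos.loc[barcodes]
    in_tissue = pos["in_tissue"].to_numpy().astype(int) == 1
    coords = pos[["pxl_row_in_fullres", "pxl_col_in_fullres"]].to_numpy(float)

    labels = None
    keep = np.flatnonzero(in_tissue)
    spot_ids = barcodes[keep]
    lab_path = root / "labels.tsv"
    if lab_path.is_file():
        lab = read_labels_tsv(lab_path)
        labels = np.array([lab[s] for s in spot_ids if s in lab], dtype=int)
        if labels.shape[0] != spot_ids.shape[0]:
            raise ConsistencyError("labels.tsv does not cover all in-tissue spots")

    return SpatialDataset(
        expression=mat[keep],
        coords=coords[keep],
        spot_ids=spot_ids,
        gene_ids=gene_ids,
        labels=labels,
    )


def read_generic(expression_path, coords_path, labels_path=None) -> SpatialDataset:
    """Read a dense TSV expression matrix (spots x genes) plus a coordinate table.

    The coordinate table has columns (spot_id, x, y); expression rows are
    indexed by spot_id in the first column.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    coords = pd.read_csv(coords_path, sep="\t", index_col=0)
    coords.index = coords.index.astype(str)
    spot_ids = expr.index.astype(str).to_numpy()
    missing = [s for s in spot_ids if s not in coords.index]
    if missing:
        raise ConsistencyError(f"spots absent from coordinates table: {missing}")
    xy = coords.loc[spot_ids].iloc[:, :2].to_numpy(float)
    labels = None
    if labels_path is not None:
        lab = read_labels_tsv(labels_path)
        labels = np.array([lab[s] for s in spot_ids], dtype=int)
    return SpatialDataset(expr.to_numpy(float), xy, spot_ids,
                          expr.columns.astype(str).to_numpy(), labels=labels)


def write_dataset(ds: SpatialDataset, path) -> None:
    """Emit a Visium-layout directory readable by :func:`read_visium`.

    Integer counts round-trip losslessly. Labels, when present, are written
    as a two-column ``labels.tsv``.
    """
    if ds.n_genes == 0:
        raise ParameterError("cannot write a dataset with zero genes")
    root = Path(path)
    try:
        root.mkdir(parents=True, exist_ok=True)
        probe = root / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"unwritable path {root}: {exc}") from exc

    mat = ds.expression.T  # genes x barcodes on disk, 10x convention
    integral = np.allclose(mat, np.round(mat))
    sp = scipy.sparse.coo_matrix(np.round(mat).astype(np.int64) if integral else mat)
    scipy.io.mmwrite(str(root / "matrix.mtx"), sp)
    pd.Series(ds.spot_ids).to_csv(root / "barcodes.tsv", sep="\t",
                                  header=False, index=False)
    pd.DataFrame({0: ds.gene_ids, 1: ds.gene_ids,
                  2: "Gene Expression"}).to_csv(
        root / "features.tsv", sep="\t", header=False, index=False)
    pos = pd.DataFrame({
        "barcode": ds.spot_ids,
        "in_tissue": 1,
        "array_row": 0,
        "array_col": 0,
        "pxl_row_in_fullres": ds.coords[:, 0],
        "pxl_col_in_fullres": ds.coords[:, 1],
    })
    pos.to_csv(root / "tissue_positions.csv", index=False)
    if ds.labels is not None:
        write_labels_tsv(root / "labels.tsv", ds.spot_ids, ds.labels)


def read_labels_tsv(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise InputError(f"labels table {path} needs two columns (spot_id, domain)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


def write_labels_tsv(path, spot_ids, labels) -> None:
    pd.DataFrame({"spot_id": np.asarray(spot_ids, dtype=str),
                  "domain": np.asarray(labels, dtype=int)}).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(ds: SpatialDataset, target_sum: float | None = 1e4,
               log_transform: bool = True,
               n_hvg: int | None = 3000) -> SpatialDataset:
    """Library-size scaling, log1p, and highly-variable-gene restriction.

    Each step is skippable by passing ``None``/``False``. Spots with zero
    total count are left unscaled (and logged) rather than dropped, so spot
    indexing stays aligned with the coordinates.
    """
    X = ds.expression.copy()
    if np.any(X < 0):
        raise ParameterError("preprocess requires non-negative expression")
    log_steps = list(ds.provenance)
    gene_ids = ds.gene_ids
    if target_sum is not None:
        totals = X.sum(axis=1)
        zero = totals == 0
        if np.any(zero):
            logger.warning("%d spot(s) with zero total count left unscaled",
                           int(zero.sum()))
        scale = np.where(zero, 1.0, target_sum / np.where(zero, 1.0, totals))
        X = X * scale[:, None]
        log_steps.append(("normalize_total", float(target_sum)))
    if log_transform:
        X = np.log1p(X)
        log_steps.append(("log1p", True))
    if n_hvg is not None and n_hvg < X.shape[1]:
        var = X.var(axis=0)
        # stable selection: rank by (-variance, index), keep original order
        order = np.lexsort((np.arange(var.size), -var))
        keep = np.sort(order[:n_hvg])
        X = X[:, keep]
        gene_ids = gene_ids[keep]
        log_steps.append(("hvg", int(n_hvg)))
    return SpatialDataset(X, ds.coords.copy(), ds.spot_ids.copy(), gene_ids.copy(),
                          morphology=None if ds.morphology is None else ds.morphology.copy(),
                          labels=None if ds.labels is None else ds.labels.copy(),
                          provenance=log_steps)


def pca_reduce(X: np.ndarray, n_components: int) -> ProcessedMatrix:
    """PCA scores in decreasing explained-variance order with fixed signs.

    Each component's sign is fixed so that its largest-magnitude loading is
    positive, making the decomposition deterministic.
    """
    X = np.asarray(X, dtype=float)
    n, o = X.shape
    if n_components > min(n, o):
        raise ParameterError(
            f"n_components={n_components} exceeds min(N, O)={min(n, o)}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    return ProcessedMatrix(
        values=scores,
        transform_log=[("pca", int(n_components))],
        components=comps,
        mean=pca.mean_.copy(),
        explained_variance=pca.explained_variance_.copy(),
    )
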