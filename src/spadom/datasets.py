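"""Loading and preprocessing of spatial transcriptomics inputs.

A dataset couples a spot-by-gene expression matrix with 2-D spot
coordinates, optional histology-derived image features (one embedding
vector per spot, e.g. from a pretrained CNN applied to the patch under
each spot — computed upstream and supplied as a matrix), and optional
reference domain labels.

Three on-disk layouts are supported:

* ``tabular`` — expression CSV/TSV (first column spot IDs, header row gene
  names), a coordinate table with columns ``spot_id,x,y``, and optional
  image-feature / label tables keyed by spot ID.
* ``triplet`` — 10x-style MatrixMarket triple (``matrix.mtx`` +
  ``barcodes.tsv`` + ``features.tsv``) plus a coordinate table.
* ``h5ad`` — a single AnnData container with coordinates under
  ``obsm["spatial"]`` and image features under ``obsm["image_feats"]``.

All secondary tables are joined to the expression matrix's row order by
spot ID; a mismatch is an error that names the offending barcodes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpatialDataset",
    "DataValidationError",
    "SpotJoinError",
    "CapabilityError",
    "read_dataset",
    "write_dataset",
    "preprocess",
    "embed_image_features",
]


class DataValidationError(ValueError):
    """An input matrix violates a structural invariant (NaN, negative, shape)."""


class SpotJoinError(ValueError):
    """Spot IDs of a secondary table do not match the expression matrix."""


class CapabilityError(RuntimeError):
    """A requested optional capability (e.g. a CNN extractor) is unavailable."""


@dataclass
class SpatialDataset:
    """In-memory container for one slide.

    Attributes
    ----------
    expr
        ``(n_spots, n_genes)`` expression matrix. Raw counts on load;
        log-normalized after :func:`preprocess` with default flags.
    coords
        ``(n_spots, 2)`` planar spot coordinates, in whatever unit the
        input uses (radius calibration downstream adapts to the unit).
    gene_names, spot_ids
        Identifiers aligned to the columns / rows of ``expr``.
    image_feats
        Optional ``(n_spots, m)`` image-feature embedding.
    labels
        Optional per-spot categorical reference labels.
    expr_linear
        Linear-scale (library-normalized, pre-log) matrix retained by
        :func:`preprocess`; fold changes are ratios of means and only
        meaningful on this scale.
    """

    expr: np.ndarray
    coords: np.ndarray
    gene_names: np.ndarray
    spot_ids: np.ndarray
    image_feats: np.ndarray | None = None
    labels: np.ndarray | None = None
    expr_linear: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.gene_names = np.asarray(self.gene_names)
        self.spot_ids = np.asarray(self.spot_ids)
        n = self.expr.shape[0]
        if self.expr.ndim != 2:
            raise DataValidationError("expr must be a 2-D matrix")
        if self.coords.shape != (n, 2):
            raise DataValidationError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.gene_names) != self.expr.shape[1]:
            raise DataValidationError("gene_names length != n_genes")
        if len(self.spot_ids) != n:
            raise DataValidationError("spot_ids length != n_spots")
        if len(set(map(str, self.gene_names))) != len(self.gene_names):
            raise DataValidationError("gene_names are not unique")
        for name, arr in (("expr", self.expr), ("coords", self.coords)):
            if not np.all(np.isfinite(arr)):
                raise DataValidationError(f"{name} contains NaN/Inf")
        if self.image_feats is not None:
            self.image_feats = np.asarray(self.image_feats, dtype=float)
            if self.image_feats.shape[0] != n:
                raise DataValidationError("image_feats rows != n_spots")
            if not np.all(np.isfinite(self.image_feats)):
                raise DataValidationError("image_feats contains NaN/Inf")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise DataValidationError("labels length != n_spots")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def copy(self) -> "SpatialDataset":
        return replace(
            self,
            expr=self.expr.copy(),
            coords=self.coords.copy(),
            gene_names=self.gene_names.copy(),
            spot_ids=self.spot_ids.copy(),
            image_feats=None if self.image_feats is None else self.image_feats.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            expr_linear=None if self.expr_linear is None else self.expr_linear.copy(),
        )


def _read_table(path: str) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    # round_trip parser so written doubles reload bit-identically
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _join_by_spot(df: pd.DataFrame, spot_ids: np.ndarray, what: str) -> pd.DataFrame:
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    want = pd.Index(spot_ids.astype(str))
    missing = want.difference(df.index)
    extra = df.index.difference(want)
    if len(missing) or len(extra):
        raise SpotJoinError(
            f"{what}: spot IDs do not match expression matrix"
            + (f"; missing {sorted(missing)[:10]}" if len(missing) else "")
            + (f"; unmatched {sorted(extra)[:10]}" if len(extra) else "")
        )
    return df.loc[want]


def read_dataset(
    path_spec: Mapping[str, str] | str,
    format: str | None = None,
) -> SpatialDataset:
    """Load a dataset from disk.

    Parameters
    ----------
    path_spec
        For ``tabular``: a mapping with keys ``expr``, ``coords`` and
        optionally ``image_feats``, ``labels``. For ``triplet``: keys
        ``matrix``, ``barcodes``, ``features``, ``coords`` (+ optional
        ``image_feats``, ``labels``). For ``h5ad``: a single file path.
    format
        One of ``{"tabular", "triplet", "h5ad"}``; inferred from
        ``path_spec`` when omitted.
    """
    if format is None:
        if isinstance(path_spec, str):
            format = "h5ad"
        elif "matrix" in path_spec:
            format = "triplet"
        else:
            format = "tabular"

    if format == "h5ad":
        return _read_h5ad(str(path_spec))
    if not isinstance(path_spec, Mapping):
        raise ValueError(f"format {format!r} needs a mapping of file paths")
    for key in ({"matrix", "barcodes", "features", "coords"} if format == "triplet" else {"expr", "coords"}):
        if key not in path_spec:
            raise ValueError(f"path_spec missing required key {key!r}")
        if not os.path.exists(path_spec[key]):
            raise FileNotFoundError(path_spec[key])

    if format == "tabular":
        expr_df = _read_table(path_spec["expr"])
        expr_df = expr_df.set_index(expr_df.columns[0])
        spot_ids = expr_df.index.astype(str).to_numpy()
        gene_names = expr_df.columns.to_numpy()
        expr = expr_df.to_numpy(dtype=float)
    elif format == "triplet":
        mat = scipy.io.mmread(path_spec["matrix"])
        barcodes = pd.read_csv(path_spec["barcodes"], sep="\t", header=None)[0].astype(str).to_numpy()
        feats = pd.read_csv(path_spec["features"], sep="\t", header=None)
        gene_names = feats.iloc[:, -1 if feats.shape[1] == 1 else 1].to_numpy()
        dense = np.asarray(sp.csr_matrix(mat).todense(), dtype=float)
        # 10x convention stores genes as rows, spots as columns
        if dense.shape == (len(gene_names), len(barcodes)):
            dense = dense.T
        elif dense.shape != (len(barcodes), len(gene_names)):
            raise DataValidationError(
                f"matrix shape {dense.shape} matches neither orientation of "
                f"({len(barcodes)} barcodes, {len(gene_names)} features)"
            )
        expr, spot_ids = dense, barcodes
    else:
        raise ValueError(f"unknown format {format!r}")

    if np.any(expr < 0):
        raise DataValidationError("expression matrix has negative entries")

    coords_df = _join_by_spot(_read_table(path_spec["coords"]), spot_ids, "coords")
    coords = coords_df[["x", "y"]].to_numpy(dtype=float) if {"x", "y"} <= set(coords_df.columns) else coords_df.iloc[:, :2].to_numpy(dtype=float)

    image_feats = None
    if path_spec.get("image_feats"):
        img_df = _join_by_spot(_read_table(path_spec["image_feats"]), spot_ids, "image_feats")
        image_feats = img_df.to_numpy(dtype=float)
    labels = None
    if path_spec.get("labels"):
        lab_df = _join_by_spot(_read_table(path_spec["labels"]), spot_ids, "labels")
        labels = lab_df.iloc[:, 0].to_numpy()

    return SpatialDataset(
        expr=expr,
        coords=coords,
        gene_names=gene_names,
        spot_ids=spot_ids,
        image_feats=image_feats,
        labels=labels,
    )


def _read_h5ad(path: str) -> SpatialDataset:
    import anndata

    adata = anndata.read_h5ad(path)
    X = adata.X
    expr = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    if "spatial" not in adata.obsm:
        raise DataValidationError("h5ad container lacks obsm['spatial'] coordinates")
    coords = np.asarray(adata.obsm["spatial"], dtype=float)[:, :2]
    image_feats = None
    if "image_feats" in adata.obsm:
        image_feats = np.asarray(adata.obsm["image_feats"], dtype=float)
    labels = None
    for key in ("domain", "label", "ground_truth"):
        if key in adata.obs:
            labels = adata.obs[key].to_numpy()
            break
    if np.any(expr < 0):
        raise DataValidationError("expression matrix has negative entries")
    return SpatialDataset(
        expr=expr,
        coords=coords,
        gene_names=adata.var_names.to_numpy(),
        spot_ids=adata.obs_names.to_numpy(),
        image_feats=image_feats,
        labels=labels,
    )


def write_dataset(ds: SpatialDataset, outdir: str) -> dict[str, str]:
    """Write a dataset in the tabular dialect; returns the path mapping.

    Round-trips bit-identically with :func:`read_dataset` for values that
    survive decimal text representation (``repr`` precision is used).
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {"expr": os.path.join(outdir, "expr.csv"), "coords": os.path.join(outdir, "coords.csv")}
    expr_df = pd.DataFrame(ds.expr, index=ds.spot_ids, columns=ds.gene_names)
    expr_df.index.name = "spot_id"
    expr_df.to_csv(paths["expr"], float_format="%.17g")
    pd.DataFrame({"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}).to_csv(
        paths["coords"], index=False, float_format="%.17g"
    )
    if ds.image_feats is not None:
        paths["image_feats"] = os.path.join(outdir, "image_feats.csv")
        img = pd.DataFrame(ds.image_feats, index=ds.spot_ids)
        img.columns = [f"f{i}" for i in range(img.shape[1])]
        img.index.name = "spot_id"
        img.to_csv(paths["image_feats"], float_format="%.17g")
    if ds.labels is not None:
        paths["labels"] = os.path.join(outdir, "labels.csv")
        pd.DataFrame({"spot_id": ds.spot_ids, "label": ds.labels}).to_csv(paths["labels"], index=False)
    return paths


def preprocess(
    ds: SpatialDataset,
    n_hvg: int = 3000,
    normalize: bool = True,
    log1p: bool = True,
) -> SpatialDataset:
    """Normalize, log-transform and restrict to highly variable genes.

    Gene variability is ranked by the variance of log1p library-normalized
    expression (ties broken by lower gene index); the top ``n_hvg`` genes
    are kept (all genes when ``n_genes <= n_hvg``). When the flags are set,
    the output ``expr`` is per-spot library-size normalized to the median
    library size and then log(1+x)-transformed, in that order. The
    normalized pre-log matrix is always retained as ``expr_linear`` for
    downstream fold-change computations.
    """
    expr = np.asarray(ds.expr, dtype=float)
    if np.any(expr < 0):
        raise DataValidationError("preprocess requires non-negative expression")
    lib = expr.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        ids = [str(ds.spot_ids[i]) for i in zero[:10]]
        raise DataValidationError(f"all-zero spots cannot be normalized: {ids}")

    target = float(np.median(lib))
    normalized = expr * (target / lib)[:, None]

    # ranking always uses the log-normalized scale, independent of flags
    log_norm = np.log1p(normalized)
    variances = log_norm.var(axis=0)
    if ds.n_genes > n_hvg:
        order = np.argsort(-variances, kind="stable")  # stable → ties by lower index
        keep = np.sort(order[:n_hvg])
    else:
        keep = np.arange(ds.n_genes)

    out_linear = (normalized if normalize else expr)[:, keep]
    out = np.log1p(out_linear) if log1p else out_linear.copy()
    return replace(
        ds,
        expr=out,
        gene_names=ds.gene_names[keep],
        expr_linear=out_linear,
    )


def embed_image_features(
    patches_or_feats: np.ndarray | None,
    extractor: Callable[..., np.ndarray] | None = None,
    n_spots: int | None = None,
) -> np.ndarray:
    """Return the per-spot image-feature matrix.

    Precomputed features pass through unchanged after validation. If no
    matrix is given, an ``extractor`` callable (e.g. a CNN applied to
    histology patches) may be plugged in; the core pipeline never requires
    one.
    """
    if patches_or_feats is not None and not callable(patches_or_feats):
        feats = np.asarray(patches_or_feats, dtype=float)
        if feats.ndim != 2:
            raise DataValidationError("image features must be a 2-D matrix")
        if n_spots is not None and feats.shape[0] != n_spots:
            raise DataValidationError(
                f"image features have {feats.shape[0]} rows, expected {n_spots}"
            )
        return feats
    handle = extractor if extractor is not None else (patches_or_feats if callable(patches_or_feats) else None)
    if handle is None:
        raise CapabilityError(
            "no precomputed image features and no extractor plugin available; "
            "supply a spot-by-feature matrix or an extractor callable"
        )
    feats = np.asarray(handle(), dtype=float)
    if n_spots is not None and feats.shape[0] != n_spots:
        raise DataValidationError("extractor returned wrong number of rows")
    return feats
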