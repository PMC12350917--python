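"""Nuclei-anchored aggregation of 2×2 µm spatial expression bins.

High-resolution barcoded-capture data arrive as gene counts on a regular
grid of 2 µm bins.  To approximate single-cell counts, each bin is assigned
to the segmented nucleus whose label-mask region contains the bin's center;
counts are summed per nucleus, improperly segmented nuclei are filtered by
area and UMI total, and mitochondrial genes are removed before downstream
analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

__all__ = [
    "BinCountGrid",
    "NucleiLabelMask",
    "CellByGeneMatrix",
    "NucleiFilterConfig",
    "assign_bins_to_nuclei",
    "aggregate_to_cells",
    "filter_nuclei",
    "remove_mt_genes",
    "write_bin_grid",
    "read_bin_grid",
    "write_label_mask",
    "read_label_mask",
    "write_cell_matrix",
]


@dataclass
class BinCountGrid:
    """Sparse gene counts on a regular square-bin grid.

    Bin (row, col) covers the half-open square
    ``[x0 + col·pitch, x0 + (col+1)·pitch) × [y0 + row·pitch, y0 + (row+1)·pitch)``.
    Only occupied bins are stored: ``counts[i]`` is the gene-count vector of
    the bin at ``(rows[i], cols[i])``.
    """

    counts: sp.csr_matrix  # n_bins × n_genes, non-negative integers
    rows: np.ndarray
    cols: np.ndarray
    gene_index: list[str]
    pitch: float = 2.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.rows = np.asarray(self.rows, dtype=np.int64)
        self.cols = np.asarray(self.cols, dtype=np.int64)
        if self.counts.shape[0] != len(self.rows) or len(self.rows) != len(self.cols):
            raise ValueError("counts, rows and cols must agree in length")
        if self.counts.data.size and self.counts.data.min() < 0:
            raise ValueError("bin counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_centers(self) -> np.ndarray:
        """(n_bins, 2) array of bin-center coordinates in µm."""
        x = self.origin[0] + (self.cols + 0.5) * self.pitch
        y = self.origin[1] + (self.rows + 0.5) * self.pitch
        return np.column_stack([x, y])

    def total_counts(self) -> int:
        return int(self.counts.sum())

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()


@dataclass
class NucleiLabelMask:
    """Integer label raster: 0 = background, k > 0 = nucleus k."""

    labels: np.ndarray  # (ny, nx)
    pixel_size: float = 2.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.labels.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.pixel_size, y0 + ny * self.pixel_size)

    def label_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Label of the pixel containing each (x, y) point (µm)."""
        px = np.floor((np.asarray(x) - self.origin[0]) / self.pixel_size).astype(np.int64)
        py = np.floor((np.asarray(y) - self.origin[1]) / self.pixel_size).astype(np.int64)
        ny, nx = self.labels.shape
        if (px < 0).any() or (px >= nx).any() or (py < 0).any() or (py >= ny).any():
            raise ValueError("query points fall outside the mask extent")
        return self.labels[py, px]

    def nucleus_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas(self) -> pd.Series:
        """Per-nucleus area in µm² (pixel count × pixel_size²)."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return pd.Series(counts * self.pixel_size**2, index=ids, name="area_um2")

    def centroids(self) -> pd.DataFrame:
        """Per-nucleus centroid (µm) of the labelled pixels."""
        lab = self.labels
        ids = self.nucleus_ids()
        ys, xs = np.nonzero(lab)
        vals = lab[ys, xs]
        order = np.argsort(vals, kind="stable")
        vals, ys, xs = vals[order], ys[order], xs[order]
        bounds = np.searchsorted(vals, ids, side="left")
        bounds = np.append(bounds, len(vals))
        cx, cy = [], []
        for i in range(len(ids)):
            sl = slice(bounds[i], bounds[i + 1])
            cx.append(self.origin[0] + (xs[sl].mean() + 0.5) * self.pixel_size)
            cy.append(self.origin[1] + (ys[sl].mean() + 0.5) * self.pixel_size)
        return pd.DataFrame({"x": cx, "y": cy}, index=ids)


@dataclass
class CellByGeneMatrix:
    """Nucleus × gene count matrix with per-nucleus geometry."""

    counts: np.ndarray  # (n_nuclei, n_genes) non-negative integers
    nucleus_ids: np.ndarray
    areas: np.ndarray  # µm²
    centroids: np.ndarray  # (n_nuclei, 2) µm
    gene_index: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.nucleus_ids = np.asarray(self.nucleus_ids, dtype=np.int64)
        self.areas = np.asarray(self.areas, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.nucleus_ids) and (self.areas <= 0).any():
            raise ValueError("nucleus areas must be positive")

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[0]

    def umi_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.nucleus_ids, columns=self.gene_index)


@dataclass(frozen=True)
class NucleiFilterConfig:
    """Thresholds for removing improperly segmented nuclei.

    The upstream segmentation leaves debris (tiny labels), merged nuclei
    (oversized labels) and capture dropouts (low UMI).  Bounds are in µm²
    and deduplicated transcript counts.
    """

    min_area: float = 16.0
    max_area: float = 800.0
    min_umi: int = 10
    mt_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if not (0 < self.min_area < self.max_area):
            raise ValueError("require 0 < min_area < max_area")
        if self.min_umi < 0:
            raise ValueError("min_umi must be >= 0")


def assign_bins_to_nuclei(grid: BinCountGrid, mask: NucleiLabelMask) -> np.ndarray:
    """Assign each occupied bin to a nucleus by bin-center containment.

    Returns an integer array aligned with ``grid`` rows: the label of the
    nucleus whose mask region contains the bin's center, or 0 (background /
    unassigned).  Bin-center lookup is nearest-pixel after converting both
    frames to µm; masks are never resampled.

    Raises
    ------
    ValueError
        If any bin center falls outside the mask extent (mismatched frames);
        the message names both extents.
    """
    centers = grid.bin_centers()
    if grid.n_bins == 0:
        return np.zeros(0, dtype=np.int64)
    ext = mask.extent()
    cx, cy = centers[:, 0], centers[:, 1]
    if cx.min() < ext[0] or cy.min() < ext[1] or cx.max() >= ext[2] or cy.max() >= ext[3]:
        grid_ext = (cx.min(), cy.min(), cx.max(), cy.max())
        raise ValueError(
            f"grid bin centers (extent {grid_ext}) fall outside mask extent {ext}"
        )
    return mask.label_at(cx, cy).astype(np.int64)


def aggregate_to_cells(
    grid: BinCountGrid, assignment: np.ndarray, mask: NucleiLabelMask
) -> CellByGeneMatrix:
    """Sum bin counts per assigned nucleus into a cell-by-gene matrix.

    Unassigned bins (label 0) are excluded, so the per-gene column sums are
    bounded by the grid's per-gene totals, with equality when every bin is
    assigned.  Per-nucleus area and centroid come from the label mask; nuclei
    present in the mask but receiving no bins appear with zero counts.
    """
    assignment = np.asarray(assignment, dtype=np.int64)
    if len(assignment) != grid.n_bins:
        raise ValueError("assignment length does not match grid")
    ids = mask.nucleus_ids()
    id_to_row = {int(k): i for i, k in enumerate(ids)}
    n, g = len(ids), len(grid.gene_index)
    counts = np.zeros((n, g), dtype=np.int64)
    assigned = assignment > 0
    if assigned.any():
        rows = np.array([id_to_row[int(k)] for k in assignment[assigned]])
        dense = np.asarray(grid.counts[assigned].todense())
        np.add.at(counts, rows, dense)
    areas = mask.areas().reindex(ids).to_numpy()
    cents = mask.centroids().reindex(ids).to_numpy()
    return CellByGeneMatrix(
        counts=counts, nucleus_ids=ids, areas=areas, centroids=cents,
        gene_index=list(grid.gene_index),
    )


def filter_nuclei(
    matrix: CellByGeneMatrix, config: NucleiFilterConfig
) -> tuple[CellByGeneMatrix, pd.DataFrame]:
    """Drop improperly segmented nuclei by area bounds and minimum UMI.

    Keeps nuclei with ``min_area <= area <= max_area`` and
    ``UMI >= min_umi``, preserving order.  Returns the filtered matrix and a
    report of removed nuclei with a reason per nucleus (``small_area``,
    ``large_area`` or ``low_umi``; area reasons take precedence).
    """
    umi = matrix.umi_totals()
    small = matrix.areas < config.min_area
    large = matrix.areas > config.max_area
    low = umi < config.min_umi
    removed = small | large | low
    reasons = np.where(small, "small_area", np.where(large, "large_area", "low_umi"))
    report = pd.DataFrame(
        {
            "nucleus_id": matrix.nucleus_ids[removed],
            "area_um2": matrix.areas[removed],
            "total_umi": umi[removed],
            "reason": reasons[removed],
        }
    )
    keep = ~removed
    out = CellByGeneMatrix(
        counts=matrix.counts[keep],
        nucleus_ids=matrix.nucleus_ids[keep],
        areas=matrix.areas[keep],
        centroids=matrix.centroids[keep],
        gene_index=list(matrix.gene_index),
    )
    return out, report


def remove_mt_genes(obj, mt_prefix: str = "mt-"):
    """Remove mitochondrial genes by symbol prefix (case-insensitive).

    Works on either a :class:`BinCountGrid` or a :class:`CellByGeneMatrix`;
    all retained columns are unchanged.  An empty prefix is rejected — it
    would match (and drop) every gene.
    """
    if mt_prefix == "":
        raise ValueError("mt_prefix must be non-empty (empty prefix matches all genes)")
    pref = mt_prefix.lower()
    keep = [i for i, g in enumerate(obj.gene_index) if not g.lower().startswith(pref)]
    genes = [obj.gene_index[i] for i in keep]
    if isinstance(obj, BinCountGrid):
        return replace(obj, counts=obj.counts[:, keep], gene_index=genes)
    if isinstance(obj, CellByGeneMatrix):
        return replace(obj, counts=obj.counts[:, keep], gene_index=genes)
    raise TypeError(f"unsupported type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# I/O: MatrixMarket + bin_positions.csv, 16-bit label TIFF, cells.csv


def write_bin_grid(grid: BinCountGrid, directory: str | Path) -> None:
    """Write a grid as ``matrix.mtx`` + ``bin_positions.csv`` + ``features.tsv``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(grid.counts), field="integer")
    centers = grid.bin_centers()
    pd.DataFrame(
        {
            "bin_id": np.arange(grid.n_bins),
            "row": grid.rows,
            "col": grid.cols,
            "x_um": centers[:, 0],
            "y_um": centers[:, 1],
        }
    ).to_csv(d / "bin_positions.csv", index=False)
    (d / "features.tsv").write_text("".join(f"{g}\n" for g in grid.gene_index))
    (d / "grid_meta.csv").write_text(
        "pitch,origin_x,origin_y\n"
        f"{grid.pitch},{grid.origin[0]},{grid.origin[1]}\n"
    )


def read_bin_grid(directory: str | Path) -> BinCountGrid:
    d = Path(directory)
    counts = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx"))
    pos = pd.read_csv(d / "bin_positions.csv")
    genes = (d / "features.tsv").read_text().splitlines()
    meta = pd.read_csv(d / "grid_meta.csv")
    return BinCountGrid(
        counts=counts,
        rows=pos["row"].to_numpy(),
        cols=pos["col"].to_numpy(),
        gene_index=genes,
        pitch=float(meta.loc[0, "pitch"]),
        origin=(float(meta.loc[0, "origin_x"]), float(meta.loc[0, "origin_y"])),
    )


def write_label_mask(mask: NucleiLabelMask, path: str | Path) -> None:
    """Write a 16-bit single-channel label TIFF; origin/pixel-size go in the
    ImageDescription tag as ``key=value`` pairs."""
    desc = f"pixel_size={mask.pixel_size};origin_x={mask.origin[0]};origin_y={mask.origin[1]}"
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many nuclei for a 16-bit label mask")
    tifffile.imwrite(path, mask.labels.astype(np.uint16), description=desc)


def read_label_mask(path: str | Path) -> NucleiLabelMask:
    with tifffile.TiffFile(path) as tf:
        labels = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = dict(item.split("=") for item in desc.split(";") if "=" in item)
    return NucleiLabelMask(
        labels=labels,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        origin=(float(meta.get("origin_x", 0.0)), float(meta.get("origin_y", 0.0))),
    )


def write_cell_matrix(matrix: CellByGeneMatrix, directory: str | Path) -> None:
    """Write ``matrix.mtx`` + ``cells.csv`` (+ ``features.tsv``)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(d / "matrix.mtx", sp.coo_matrix(matrix.counts), field="integer")
    pd.DataFrame(
        {
            "cell_id": matrix.nucleus_ids,
            "area_um2": matrix.areas,
            "x": matrix.centroids[:, 0],
            "y": matrix.centroids[:, 1],
            "total_umi": matrix.umi_totals(),
        }
    ).to_csv(d / "cells.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    (d / "features.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_index))
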