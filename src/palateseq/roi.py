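"""Area-standardized ROIs and the ROI × gene transcript-density matrix.

Regions of interest are standardized by surface area (default 6400 µm² with
a ±100 µm² tolerance) and drawn three per side of the oronasal axis per
palatal shelf — twelve per section.  Transcripts passing a quality threshold
are counted inside each ROI polygon (boundary inclusive) and divided by the
ROI area to give transcript densities in µm⁻², the sampling unit of the
differential-expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon

from .partition import AxisLine, NASAL, ORAL

__all__ = [
    "ROI",
    "ROIConfig",
    "DensityMatrix",
    "generate_rois",
    "count_in_roi",
    "build_density_matrix",
    "write_roi_csv",
    "read_roi_csv",
]

ROI_CSV_COLUMNS = ["roi_id", "shelf", "domain", "area_um2", "gene", "count", "density_per_um2"]


@dataclass(frozen=True)
class ROIConfig:
    """ROI generation parameters."""

    target_area: float = 6400.0  # µm²
    area_tolerance: float = 100.0  # µm²
    n_per_domain_side: int = 3
    shape: str = "square"  # "square" | "circle"
    min_qv: float = 20.0
    seed: int = 0
    candidate_step: float = 20.0  # candidate-center grid spacing, µm

    def __post_init__(self) -> None:
        if self.target_area <= 0 or self.area_tolerance < 0 or self.n_per_domain_side < 1:
            raise ValueError("require target_area > 0, tolerance >= 0, n >= 1")
        if self.shape not in ("square", "circle"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")


@dataclass(frozen=True)
class ROI:
    """An area-standardized polygonal region tagged with shelf and domain."""

    polygon: Polygon
    shelf: str
    domain: str
    roi_id: str

    @property
    def area(self) -> float:
        return float(self.polygon.area)


def _roi_polygon(cx: float, cy: float, config: ROIConfig, angle_deg: float = 0.0) -> Polygon:
    """Candidate ROI polygon; squares are oriented along the shelf axis so
    placement does not depend on the section's orientation in the frame."""
    if config.shape == "square":
        half = np.sqrt(config.target_area) / 2.0
        square = shapely.box(cx - half, cy - half, cx + half, cy + half)
        if angle_deg:
            square = affinity.rotate(square, angle_deg, origin=(cx, cy))
        return square
    radius = np.sqrt(config.target_area / np.pi)
    return Point(cx, cy).buffer(radius, quad_segs=16)


def generate_rois(
    geometry,
    axes: dict[str, AxisLine],
    table: pd.DataFrame,
    config: ROIConfig | None = None,
    oral_refs: dict[str, tuple[float, float]] | None = None,
) -> list[ROI]:
    """Place ``n_per_domain_side`` non-overlapping ROIs per (shelf, domain).

    Candidate centers lie on a seed-jittered grid; a candidate is valid when
    its ROI polygon sits entirely inside the shelf polygon with every vertex
    on the correct side of the fitted axis.  Candidates are ranked by the
    number of quality-passing transcripts they contain and accepted greedily,
    skipping overlaps — a declared, reproducible substitute for hand-drawn
    ROI selection.  Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If a (shelf, domain) cannot host the requested number of
        non-overlapping ROIs; the message names the shelf and domain.
    """
    config = config or ROIConfig()
    rng = np.random.default_rng(config.seed)
    jitter = rng.uniform(0.0, config.candidate_step, size=2)
    ok_q = table["qv"].to_numpy() >= config.min_qv
    tx = table["x_location"].to_numpy(float)[ok_q]
    ty = table["y_location"].to_numpy(float)[ok_q]

    rois: list[ROI] = []
    for shelf in geometry.shelves:
        axis = axes[shelf.name]
        if oral_refs is not None:
            oral_ref = oral_refs[shelf.name]
        else:
            oral_ref = shelf.oral_reference()
        s_ref = float(axis.signed_distance(np.asarray(oral_ref))[0])
        xmin, ymin, xmax, ymax = shelf.polygon.bounds
        angle = float(np.degrees(np.arctan2(axis.direction[1], axis.direction[0])))
        for domain in (NASAL, ORAL):
            accepted: list[Polygon] = []
            # refine the candidate grid deterministically before giving up:
            # narrow feasible bands (e.g. circles in a shallow domain) may
            # fall between coarse grid lines
            step = config.candidate_step
            while len(accepted) < config.n_per_domain_side and step >= config.candidate_step / 8:
                gx = np.arange(xmin + jitter[0] % step, xmax, step)
                gy = np.arange(ymin + jitter[1] % step, ymax, step)
                xx, yy = np.meshgrid(gx, gy)
                centers = np.column_stack([xx.ravel(), yy.ravel()])
                cands = []
                for cx, cy in centers:
                    poly = _roi_polygon(cx, cy, config, angle)
                    if not poly.within(shelf.polygon):
                        continue
                    verts = np.asarray(poly.exterior.coords)
                    s = axis.signed_distance(verts)
                    if domain == ORAL:
                        on_side = (s * np.sign(s_ref) >= 0).all()
                    else:
                        on_side = (s * np.sign(s_ref) < 0).all()
                    if not on_side:
                        continue
                    pxmin, pymin, pxmax, pymax = poly.bounds
                    near = (tx >= pxmin) & (tx <= pxmax) & (ty >= pymin) & (ty <= pymax)
                    n_in = int(shapely.intersects_xy(poly, tx[near], ty[near]).sum())
                    cands.append((n_in, round(cy, 6), round(cx, 6), poly))
                # dense-first, deterministic tie-break by position
                cands.sort(key=lambda t: (-t[0], t[1], t[2]))
                accepted = []
                for n_in, cy, cx, poly in cands:
                    if len(accepted) == config.n_per_domain_side:
                        break
                    if any(poly.intersection(a).area > 1e-9 for a in accepted):
                        continue
                    accepted.append(poly)
                step /= 2.0
            if len(accepted) < config.n_per_domain_side:
                raise ValueError(
                    f"domain {domain} of shelf {shelf.name} cannot fit "
                    f"{config.n_per_domain_side} non-overlapping ROIs of "
                    f"{config.target_area} um^2"
                )
            for k, poly in enumerate(accepted, start=1):
                rois.append(
                    ROI(polygon=poly, shelf=shelf.name, domain=domain,
                        roi_id=f"{shelf.name}-{domain}-{k}")
                )
    return rois


def count_in_roi(
    table: pd.DataFrame,
    roi: ROI,
    min_qv: float = 20.0,
    gene_index: list[str] | None = None,
) -> pd.Series:
    """Per-gene transcript counts inside one ROI (boundary inclusive).

    Only transcripts with ``qv >= min_qv`` are counted.  Genes with no
    transcript in the ROI are reported as 0; the reported gene set is
    ``gene_index`` if given, else all genes in the table.
    """
    if gene_index is None:
        gene_index = sorted(table["feature_name"].unique())
    ok = table["qv"].to_numpy() >= min_qv
    x = table["x_location"].to_numpy(float)[ok]
    y = table["y_location"].to_numpy(float)[ok]
    genes = table["feature_name"].to_numpy()[ok]
    inside = shapely.intersects_xy(roi.polygon, x, y)
    counts = pd.Series(0, index=pd.Index(gene_index, name="gene"), dtype=np.int64)
    vc = pd.Series(genes[inside]).value_counts()
    common = vc.index.intersection(counts.index)
    counts.loc[common] = vc.loc[common].astype(np.int64)
    return counts


@dataclass
class DensityMatrix:
    """ROI × gene transcript densities with the underlying integer counts.

    ``counts`` is indexed by roi_id; ``meta`` carries shelf, domain and
    area_um2 per ROI; ``group`` is the comparison-group label of the ROI set.
    Densities are exactly ``counts / area``.
    """

    counts: pd.DataFrame  # roi × gene, integers
    meta: pd.DataFrame  # index roi_id; columns shelf, domain, area_um2
    group: str | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.meta["area_um2"].to_numpy() <= 0).any():
            raise ValueError("zero-area ROI")
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the roi_id index")

    @property
    def densities(self) -> pd.DataFrame:
        return self.counts.div(self.meta["area_um2"], axis=0)

    @property
    def gene_index(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, domain: str | None = None) -> "DensityMatrix":
        """Restrict to one domain ("NP" / "OP"); None returns self."""
        if domain is None:
            return self
        keep = self.meta["domain"] == domain
        return DensityMatrix(
            counts=self.counts.loc[keep], meta=self.meta.loc[keep], group=self.group
        )


def build_density_matrix(
    table: pd.DataFrame,
    rois: list[ROI],
    min_qv: float = 20.0,
    gene_index: list[str] | None = None,
    group: str | None = None,
) -> DensityMatrix:
    """Count quality-passing transcripts per ROI and divide by ROI area."""
    if not rois:
        raise ValueError("need at least one ROI")
    if gene_index is None:
        gene_index = sorted(table["feature_name"].unique())
    rows = {}
    meta = {}
    for roi in rois:
        if roi.area <= 0:
            raise ValueError(f"zero-area ROI {roi.roi_id}")
        rows[roi.roi_id] = count_in_roi(table, roi, min_qv=min_qv, gene_index=gene_index)
        meta[roi.roi_id] = {"shelf": roi.shelf, "domain": roi.domain, "area_um2": roi.area}
    counts = pd.DataFrame(rows).T.reindex(columns=gene_index)
    counts.index.name = "roi_id"
    meta_df = pd.DataFrame(meta).T
    meta_df.index.name = "roi_id"
    meta_df["area_um2"] = meta_df["area_um2"].astype(float)
    return DensityMatrix(counts=counts, meta=meta_df, group=group)


def write_roi_csv(matrix: DensityMatrix, path: str | Path) -> None:
    """Write a density matrix in the long ROI CSV schema
    (``roi_id,shelf,domain,area_um2,gene,count,density_per_um2`` plus a
    ``group`` column when the matrix carries a group label)."""
    recs = []
    dens = matrix.densities
    for roi_id in matrix.counts.index:
        m = matrix.meta.loc[roi_id]
        for gene in matrix.counts.columns:
            recs.append(
                {
                    "roi_id": roi_id,
                    "shelf": m["shelf"],
                    "domain": m["domain"],
                    "area_um2": m["area_um2"],
                    "gene": gene,
                    "count": int(matrix.counts.loc[roi_id, gene]),
                    "density_per_um2": dens.loc[roi_id, gene],
                }
            )
    df = pd.DataFrame(recs, columns=ROI_CSV_COLUMNS)
    if matrix.group is not None:
        df["group"] = matrix.group
    df.to_csv(path, index=False)


def read_roi_csv(path: str | Path | list) -> DensityMatrix:
    """Read one ROI CSV — or assemble several (e.g. legacy one-file-per-ROI
    exports) — back into a :class:`DensityMatrix`.

    Raises
    ------
    ValueError
        On a malformed header or a negative count, naming the offending file
        line (1-based, header = line 1).
    """
    paths = path if isinstance(path, (list, tuple)) else [path]
    frames = []
    for p in paths:
        df = pd.read_csv(p)
        missing = [c for c in ROI_CSV_COLUMNS if c not in df.columns and c != "density_per_um2"]
        if missing:
            raise ValueError(f"{p}: malformed header, missing columns {missing}")
        neg = df.index[df["count"] < 0]
        if len(neg):
            raise ValueError(f"{p}: negative count at line {int(neg[0]) + 2}")
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    counts = df.pivot_table(index="roi_id", columns="gene", values="count",
                            aggfunc="first", sort=True).astype(np.int64)
    counts.index.name = "roi_id"
    counts.columns.name = None
    meta = (
        df.drop_duplicates("roi_id")
        .set_index("roi_id")[["shelf", "domain", "area_um2"]]
        .reindex(counts.index)
    )
    group = None
    if "group" in df.columns:
        groups = df["group"].unique()
        if len(groups) == 1:
            group = str(groups[0])
    return DensityMatrix(counts=counts, meta=meta, group=group)
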