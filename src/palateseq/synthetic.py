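"""Seeded synthetic coronal palate sections with known ground truth.

The generator emulates the two data modalities of a sub-regional palate
study at desk scale:

* an imaging-based in situ point pattern (one decoded transcript per row,
  with µm coordinates and a quality score), drawn as an inhomogeneous
  Poisson point process over a two-shelf section geometry; and
* a barcoded-capture 2 µm bin grid with a segmented-nuclei label mask and
  per-nucleus ground-truth expression.

Each section holds two palatal shelves (PL left, PR right), modelled as
rotated rectangles.  A thin epithelial strip runs along one long edge (the
oral margin); the true oronasal axis is the shelf's long mid-line, so the
strip and the adjacent *Ptch1*-positive mesenchyme lie in the oral half.
Gene intensities are piecewise constant over three regions per shelf
(epithelial strip, oral mesenchyme, nasal mesenchyme), with per-gene
multipliers and a per-gene log2 fold change applied in condition "B"
relative to condition "A".

Coordinates are Cartesian µm with x rightward and y downward (image
convention), origin at the frame's top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry import Point, Polygon

from .binning import BinCountGrid, NucleiLabelMask
from .partition import AxisLine, NASAL, ORAL

__all__ = [
    "GeometryParams",
    "Shelf",
    "SectionGeometry",
    "GeneSpec",
    "GeneModel",
    "default_gene_model",
    "NucleiParams",
    "GroundTruth",
    "generate_section_geometry",
    "simulate_xenium_transcripts",
    "simulate_visium_hd",
    "write_transcripts_csv",
    "read_transcripts_csv",
    "geometry_to_dict",
    "geometry_from_dict",
]

CONDITIONS = ("A", "B")

EPITHELIUM = "epithelium"
ORAL_MES = "oral"
NASAL_MES = "nasal"


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class GeometryParams:
    """Section-geometry configuration (all lengths in µm)."""

    frame: tuple[float, float] = (1200.0, 900.0)
    shelf_length: tuple[float, float] = (380.0, 440.0)  # extent along the axis
    shelf_depth: tuple[float, float] = (240.0, 280.0)  # oronasal extent
    strip_thickness: float = 10.0


@dataclass(frozen=True)
class Shelf:
    """One palatal shelf with its ground-truth oronasal structure."""

    name: str  # "PL" | "PR"
    polygon: Polygon
    axis_truth: AxisLine
    epithelial_strip: Polygon
    oral_sign: float  # sign of axis signed distance on the oral side

    def domain_of(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth OP/NP label of points by side of the truth axis."""
        s = self.axis_truth.signed_distance(points)
        return np.where(s * self.oral_sign >= 0, ORAL, NASAL)

    def oral_reference(self) -> tuple[float, float]:
        c = self.epithelial_strip.centroid
        return (c.x, c.y)

    def region_polygons(self) -> dict[str, Polygon]:
        """Epithelial strip / oral mesenchyme / nasal mesenchyme partition."""
        ax = self.axis_truth
        ux, uy = ax.direction
        nx, ny = ax.normal
        cx, cy = ax.anchor
        big = 10 * max(self.polygon.bounds[2], self.polygon.bounds[3]) + 1.0
        s = self.oral_sign
        half = Polygon(
            [
                (cx - big * ux, cy - big * uy),
                (cx + big * ux, cy + big * uy),
                (cx + big * ux + s * big * nx, cy + big * uy + s * big * ny),
                (cx - big * ux + s * big * nx, cy - big * uy + s * big * ny),
            ]
        )
        oral_half = self.polygon.intersection(half)
        strip = self.epithelial_strip
        return {
            EPITHELIUM: strip,
            ORAL_MES: oral_half.difference(strip),
            NASAL_MES: self.polygon.difference(half),
        }


@dataclass(frozen=True)
class SectionGeometry:
    shelves: tuple[Shelf, Shelf]
    frame: tuple[float, float]
    params: GeometryParams = field(default_factory=GeometryParams)

    def shelf(self, name: str) -> Shelf:
        for s in self.shelves:
            if s.name == name:
                return s
        raise KeyError(name)

    def total_area(self) -> float:
        return sum(s.polygon.area for s in self.shelves)


def _make_shelf(name: str, center: np.ndarray, rng: np.random.Generator,
                params: GeometryParams) -> Shelf:
    length = rng.uniform(*params.shelf_length)
    depth = rng.uniform(*params.shelf_depth)
    theta = rng.uniform(0.0, np.pi)
    u = np.array([np.cos(theta), np.sin(theta)])
    n = np.array([-u[1], u[0]])
    oral_sign = float(rng.choice([-1.0, 1.0]))
    hl, hd = length / 2.0, depth / 2.0
    corners = [center + a * hl * u + b * hd * n
               for a, b in [(-1, -1), (1, -1), (1, 1), (-1, 1)]]
    polygon = Polygon([(p[0], p[1]) for p in corners])
    t = params.strip_thickness
    edge = oral_sign * hd
    inner = oral_sign * (hd - t)
    # band clipped to the shelf so the strip is robustly inside the polygon
    band = Polygon(
        [
            tuple(center - 2 * hl * u + inner * n),
            tuple(center + 2 * hl * u + inner * n),
            tuple(center + 2 * hl * u + edge * n),
            tuple(center - 2 * hl * u + edge * n),
        ]
    )
    strip = polygon.intersection(band)
    axis = AxisLine(anchor=(float(center[0]), float(center[1])),
                    direction=(float(u[0]), float(u[1])), shelf=name)
    return Shelf(name=name, polygon=polygon, axis_truth=axis,
                 epithelial_strip=strip, oral_sign=oral_sign)


def generate_section_geometry(
    seed: int, params: GeometryParams | None = None
) -> SectionGeometry:
    """Generate a two-shelf section geometry, deterministic per seed.

    Shelves are centred at 1/4 and 3/4 of the frame width with random
    orientation and size; the ground-truth oronasal axis is each shelf's
    long mid-line and the epithelial strip lies along the oral margin.

    Raises
    ------
    ValueError
        For a degenerate (zero-area) frame, or parameter combinations for
        which the shelves cannot fit in the frame without overlapping.
    """
    params = params or GeometryParams()
    fw, fh = params.frame
    if fw <= 0 or fh <= 0:
        raise ValueError(f"degenerate frame {params.frame}: must have positive area")
    rng = np.random.default_rng(seed)
    centers = {
        "PL": np.array([fw * 0.25, fh * 0.5]),
        "PR": np.array([fw * 0.75, fh * 0.5]),
    }
    shelves = tuple(_make_shelf(name, c, rng, params) for name, c in centers.items())
    frame_box = shapely.box(0, 0, fw, fh)
    for s in shelves:
        if not frame_box.contains(s.polygon):
            raise ValueError(
                f"shelf {s.name} does not fit inside the frame; "
                "enlarge the frame or shrink the shelves"
            )
    if shelves[0].polygon.intersects(shelves[1].polygon):
        raise ValueError("shelf polygons overlap; enlarge the frame")
    return SectionGeometry(shelves=shelves, frame=params.frame, params=params)


# ---------------------------------------------------------------------------
# gene model


@dataclass(frozen=True)
class GeneSpec:
    """Expression model of a single gene.

    ``base_intensity`` is in transcripts per µm²; the per-region multipliers
    scale it inside the epithelial strip, the oral mesenchyme and the nasal
    mesenchyme.  ``effect_lfc`` is the log2 fold change applied in condition
    "B" relative to condition "A".
    """

    base_intensity: float
    epithelium: float = 1.0
    oral: float = 1.0
    nasal: float = 1.0
    effect_lfc: float = 0.0
    mitochondrial: bool = False

    def __post_init__(self) -> None:
        if self.base_intensity < 0 or min(self.epithelium, self.oral, self.nasal) < 0:
            raise ValueError("intensities and multipliers must be >= 0")
        if not np.isfinite(self.effect_lfc):
            raise ValueError("effect_lfc must be finite")

    def intensity(self, region: str, condition: str) -> float:
        mult = {EPITHELIUM: self.epithelium, ORAL_MES: self.oral, NASAL_MES: self.nasal}[region]
        fold = 2.0 ** self.effect_lfc if condition == "B" else 1.0
        return self.base_intensity * mult * fold


@dataclass(frozen=True)
class GeneModel:
    genes: dict[str, GeneSpec]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene model must contain at least one gene")

    @property
    def gene_index(self) -> list[str]:
        return list(self.genes)

    def true_lfc(self) -> pd.Series:
        return pd.Series({g: s.effect_lfc for g, s in self.genes.items()}, name="true_lfc")

    def mt_genes(self) -> list[str]:
        return [g for g, s in self.genes.items() if s.mitochondrial]


def default_gene_model() -> GeneModel:
    """A palate-flavoured default panel.

    *Shh* is confined to the epithelial strip and *Ptch1* to the oral side,
    mirroring their roles as the oronasal landmark pair.  A handful of
    extracellular-matrix and patterning genes carry condition effects
    (``effect_lfc`` ≠ 0), *Fmod* only in the oral domain; the rest are null.
    Two mitochondrial genes exercise the mt-removal path.
    """
    g = {
        "Shh": GeneSpec(0.30, epithelium=1.0, oral=0.0, nasal=0.0),
        "Ptch1": GeneSpec(0.04, epithelium=0.3, oral=1.0, nasal=0.0),
        "Pax9": GeneSpec(0.02, oral=1.0, nasal=0.6),
        "Osr2": GeneSpec(0.02, oral=0.3, nasal=1.0),
        # condition-B effects
        "Col1a1": GeneSpec(0.015, effect_lfc=2.0),
        "Eln": GeneSpec(0.010, effect_lfc=1.5),
        "Tnn": GeneSpec(0.008, effect_lfc=3.0),
        "Fmod": GeneSpec(0.012, epithelium=0.0, oral=1.0, nasal=0.0, effect_lfc=2.5),
        "Wnt5a": GeneSpec(0.012, oral=0.4, nasal=1.0, effect_lfc=-1.5),
        # null background
        "Actb": GeneSpec(0.030),
        "Gapdh": GeneSpec(0.025),
        "Col2a1": GeneSpec(0.008),
        "Bgn": GeneSpec(0.008),
        "Prrx1": GeneSpec(0.010),
        "Alx1": GeneSpec(0.006),
        "Msx1": GeneSpec(0.008),
        "Lum": GeneSpec(0.006),
        "Ogn": GeneSpec(0.006),
        "Wif1": GeneSpec(0.005),
        "Dkk1": GeneSpec(0.004),
        "Runx2": GeneSpec(0.005),
        "Bmp4": GeneSpec(0.005),
        "Fgf10": GeneSpec(0.004),
        "mt-Co1": GeneSpec(0.020, mitochondrial=True),
        "mt-Nd1": GeneSpec(0.015, mitochondrial=True),
    }
    return GeneModel(genes=g)


@dataclass
class GroundTruth:
    """Known truth of a simulated section."""

    true_lfc: pd.Series
    transcript_domains: pd.Series | None = None  # per transcript_id, "OP"/"NP"
    nucleus_counts: pd.DataFrame | None = None  # nucleus × gene
    nucleus_meta: pd.DataFrame | None = None  # x, y, radius, area_um2, region


# ---------------------------------------------------------------------------
# in situ point-pattern simulation


def _sample_uniform_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points inside a polygon by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((n, 2))
    got = 0
    frac = max(poly.area / ((xmax - xmin) * (ymax - ymin)), 1e-3)
    while got < n:
        m = int((n - got) / frac * 1.2) + 16
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        ok = shapely.contains_xy(poly, xs, ys)
        take = min(int(ok.sum()), n - got)
        out[got : got + take, 0] = xs[ok][:take]
        out[got : got + take, 1] = ys[ok][:take]
        got += take
    return out


def simulate_xenium_transcripts(
    geometry: SectionGeometry,
    model: GeneModel,
    condition: str,
    seed: int,
    low_qv_fraction: float = 0.05,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw an in situ transcript point pattern for one section.

    Per shelf region R and gene g, the transcript count is
    ``Poisson(base(g) · mult(g, R) · 2^(lfc(g)·[condition=="B"]) · area(R))``
    with locations uniform in R.  Quality scores are uniform in [20, 40),
    except a ``low_qv_fraction`` of transcripts drawn with qv in [5, 20) to
    exercise quality filtering.  Deterministic per seed.

    Returns the transcript table (``transcript_id, feature_name, x_location,
    y_location, qv``) and the ground truth (per-gene true LFC, per-transcript
    OP/NP domain).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng(seed)
    rows_gene: list[str] = []
    rows_xy: list[np.ndarray] = []
    domains: list[np.ndarray] = []
    for shelf in geometry.shelves:
        regions = shelf.region_polygons()
        for region_name, poly in regions.items():
            area = poly.area
            if area <= 0:
                continue
            for gene, spec in model.genes.items():
                lam = spec.intensity(region_name, condition) * area
                n = int(rng.poisson(lam)) if lam > 0 else 0
                if n == 0:
                    continue
                pts = _sample_uniform_in_polygon(poly, n, rng)
                rows_gene.extend([gene] * n)
                rows_xy.append(pts)
                domains.append(shelf.domain_of(pts))
    if rows_xy:
        xy = np.vstack(rows_xy)
        dom = np.concatenate(domains)
    else:
        xy = np.empty((0, 2))
        dom = np.empty(0, dtype=object)
    n_total = len(rows_gene)
    qv = rng.uniform(20.0, 40.0, n_total)
    low = rng.random(n_total) < low_qv_fraction
    qv[low] = rng.uniform(5.0, 20.0, int(low.sum()))
    table = pd.DataFrame(
        {
            "transcript_id": np.arange(n_total, dtype=np.int64),
            "feature_name": rows_gene,
            "x_location": xy[:, 0],
            "y_location": xy[:, 1],
            "qv": qv,
        }
    )
    truth = GroundTruth(
        true_lfc=model.true_lfc(),
        transcript_domains=pd.Series(dom, index=table["transcript_id"], name="domain"),
    )
    return table, truth


# ---------------------------------------------------------------------------
# barcoded-capture bin-grid simulation


@dataclass(frozen=True)
class NucleiParams:
    """Nuclei placement and capture configuration."""

    n_nuclei: int = 150
    radius_range: tuple[float, float] = (4.0, 9.0)
    min_separation: float = 2.0
    extra_nuclear_fraction: float = 0.3
    pitch: float = 2.0  # bin edge and mask pixel size, µm
    max_attempts: int = 200_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.extra_nuclear_fraction < 1.0):
            raise ValueError("extra_nuclear_fraction must be in [0, 1)")
        if self.n_nuclei < 1 or self.pitch <= 0:
            raise ValueError("need n_nuclei >= 1 and pitch > 0")


def _place_nuclei(
    geometry: SectionGeometry, params: NucleiParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Dart-throwing placement of non-overlapping disks inside the shelves."""
    shelves = geometry.shelves
    areas = np.array([s.polygon.area for s in shelves])
    weights = areas / areas.sum()
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    regions: list[str] = []
    attempts = 0
    while len(centers) < params.n_nuclei:
        if attempts >= params.max_attempts:
            raise RuntimeError(
                f"could not place {params.n_nuclei} non-overlapping nuclei "
                f"within {params.max_attempts} attempts; reduce n_nuclei or radii"
            )
        attempts += 1
        shelf = shelves[int(rng.choice(len(shelves), p=weights))]
        r = rng.uniform(*params.radius_range)
        (x, y), = _sample_uniform_in_polygon(shelf.polygon, 1, rng)
        if shelf.polygon.exterior.distance(Point(x, y)) < r:
            continue
        ok = True
        for (px, py), pr in zip(centers, radii):
            if (x - px) ** 2 + (y - py) ** 2 < (r + pr + params.min_separation) ** 2:
                ok = False
                break
        if not ok:
            continue
        centers.append((x, y))
        radii.append(r)
        if bool(shapely.contains_xy(shelf.epithelial_strip, x, y)):
            regions.append(EPITHELIUM)
        elif shelf.domain_of(np.array([x, y]))[0] == ORAL:
            regions.append(ORAL_MES)
        else:
            regions.append(NASAL_MES)
    return pd.DataFrame(
        {
            "x": [c[0] for c in centers],
            "y": [c[1] for c in centers],
            "radius": radii,
            "region": regions,
        },
        index=pd.RangeIndex(1, len(centers) + 1, name="nucleus_id"),
    )


def _rasterize_disks(
    nuclei: pd.DataFrame, frame: tuple[float, float], pitch: float
) -> NucleiLabelMask:
    """Label pixels whose centers fall inside each disk (center-in-disk rule)."""
    nx = int(np.ceil(frame[0] / pitch))
    ny = int(np.ceil(frame[1] / pitch))
    labels = np.zeros((ny, nx), dtype=np.uint16)
    for nid, row in nuclei.iterrows():
        x, y, r = row["x"], row["y"], row["radius"]
        j0 = max(int(np.floor((x - r) / pitch)) - 1, 0)
        j1 = min(int(np.ceil((x + r) / pitch)) + 1, nx - 1)
        i0 = max(int(np.floor((y - r) / pitch)) - 1, 0)
        i1 = min(int(np.ceil((y + r) / pitch)) + 1, ny - 1)
        jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
        cx = (jj + 0.5) * pitch
        cy = (ii + 0.5) * pitch
        inside = (cx - x) ** 2 + (cy - y) ** 2 <= r * r
        if labels[ii[inside], jj[inside]].any():
            raise RuntimeError("nucleus rasterization collision")  # pragma: no cover
        labels[ii[inside], jj[inside]] = nid
    return NucleiLabelMask(labels=labels, pixel_size=pitch, origin=(0.0, 0.0))


def simulate_visium_hd(
    geometry: SectionGeometry,
    model: GeneModel,
    nuclei_params: NucleiParams | None = None,
    seed: int = 0,
    condition: str = "A",
) -> tuple[BinCountGrid, NucleiLabelMask, GroundTruth]:
    """Simulate a 2 µm bin-grid capture with a nuclei label mask.

    Nuclei are non-overlapping disks rasterized by the center-in-disk rule at
    the bin pitch.  Per-nucleus counts for gene g are
    ``Poisson(intensity_g(region) · area)`` with transcripts placed uniformly
    over the nucleus's rasterized footprint (so bin-center aggregation can
    recover the per-nucleus truth exactly).  An extra-nuclear fraction f of
    transcripts is placed uniformly in the shelves outside any labelled
    pixel: the extra-nuclear process has total rate f/(1−f) times the
    nuclear rate per gene.

    Returns the bin grid, the label mask, and ground truth (per-nucleus
    counts and metadata, per-gene true LFC).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    params = nuclei_params or NucleiParams()
    rng = np.random.default_rng(seed)
    nuclei = _place_nuclei(geometry, params, rng)
    mask = _rasterize_disks(nuclei, geometry.frame, params.pitch)

    genes = model.gene_index
    n_genes = len(genes)
    # pixel list per nucleus
    ys, xs = np.nonzero(mask.labels)
    labs = mask.labels[ys, xs]
    order = np.argsort(labs, kind="stable")
    labs, ys, xs = labs[order], ys[order], xs[order]
    ids = nuclei.index.to_numpy()
    starts = np.searchsorted(labs, ids, side="left")
    stops = np.searchsorted(labs, ids, side="right")
    areas = (stops - starts) * params.pitch**2

    lam = np.zeros((len(ids), n_genes))
    for gi, gene in enumerate(genes):
        spec = model.genes[gene]
        for k, nid in enumerate(ids):
            lam[k, gi] = spec.intensity(nuclei.loc[nid, "region"], condition) * areas[k]
    nuc_counts = rng.poisson(lam)

    bin_counts: dict[tuple[int, int], np.ndarray] = {}

    def _add(row: int, col: int, gi: int, c: int) -> None:
        key = (row, col)
        if key not in bin_counts:
            bin_counts[key] = np.zeros(n_genes, dtype=np.int64)
        bin_counts[key][gi] += c

    for k in range(len(ids)):
        px = xs[starts[k] : stops[k]]
        py = ys[starts[k] : stops[k]]
        for gi in range(n_genes):
            c = int(nuc_counts[k, gi])
            if c == 0:
                continue
            pick = rng.integers(0, len(px), c)
            picked, reps = np.unique(pick, return_counts=True)
            for p, rct in zip(picked, reps):
                _add(int(py[p]), int(px[p]), gi, int(rct))

    f = params.extra_nuclear_fraction
    if f > 0:
        lam_extra = lam.sum(axis=0) * f / (1.0 - f)
        extra = rng.poisson(lam_extra)
        shelf_polys = [s.polygon for s in geometry.shelves]
        shelf_areas = np.array([p.area for p in shelf_polys])
        w = shelf_areas / shelf_areas.sum()
        for gi in range(n_genes):
            need = int(extra[gi])
            while need > 0:
                poly = shelf_polys[int(rng.choice(len(shelf_polys), p=w))]
                (x, y), = _sample_uniform_in_polygon(poly, 1, rng)
                col = int(x // params.pitch)
                row = int(y // params.pitch)
                if mask.labels[row, col] != 0:
                    continue  # keep extra-nuclear transcripts off nuclei
                _add(row, col, gi, 1)
                need -= 1

    keys = sorted(bin_counts)
    rows = np.array([k[0] for k in keys], dtype=np.int64)
    cols = np.array([k[1] for k in keys], dtype=np.int64)
    data = np.vstack([bin_counts[k] for k in keys]) if keys else np.zeros((0, n_genes))
    grid = BinCountGrid(
        counts=sp.csr_matrix(data), rows=rows, cols=cols, gene_index=genes,
        pitch=params.pitch, origin=(0.0, 0.0),
    )
    meta = nuclei.copy()
    meta["area_um2"] = areas
    truth = GroundTruth(
        true_lfc=model.true_lfc(),
        nucleus_counts=pd.DataFrame(nuc_counts, index=ids, columns=genes),
        nucleus_meta=meta,
    )
    return grid, mask, truth


# ---------------------------------------------------------------------------
# I/O


def geometry_to_dict(geometry: SectionGeometry) -> dict:
    """JSON-serializable description of a section geometry."""
    return {
        "frame": list(geometry.frame),
        "shelves": [
            {
                "name": s.name,
                "polygon": [list(p) for p in s.polygon.exterior.coords[:-1]],
                "epithelial_strip": [list(p) for p in s.epithelial_strip.exterior.coords[:-1]],
                "axis_truth": s.axis_truth.to_dict(),
                "oral_sign": s.oral_sign,
            }
            for s in geometry.shelves
        ],
    }


def geometry_from_dict(d: dict) -> SectionGeometry:
    shelves = []
    for sd in d["shelves"]:
        ax = sd["axis_truth"]
        shelves.append(
            Shelf(
                name=sd["name"],
                polygon=Polygon(sd["polygon"]),
                epithelial_strip=Polygon(sd["epithelial_strip"]),
                axis_truth=AxisLine(anchor=tuple(ax["anchor"]),
                                    direction=tuple(ax["direction"]),
                                    shelf=ax.get("shelf", sd["name"])),
                oral_sign=float(sd["oral_sign"]),
            )
        )
    return SectionGeometry(shelves=tuple(shelves), frame=tuple(d["frame"]))


def write_transcripts_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write the transcript table in the decoded-transcripts CSV dialect."""
    cols = ["transcript_id", "feature_name", "x_location", "y_location", "qv"]
    table[cols].to_csv(path, index=False)


def read_transcripts_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    required = {"transcript_id", "feature_name", "x_location", "y_location", "qv"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"transcript CSV missing columns: {sorted(missing)}")
    return table
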