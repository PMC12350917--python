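"""Reproducible two-group comparison runs.

Orchestrates simulate → partition → ROI → density → DGE for a two-group
design (e.g. wild-type vs mutant, or two developmental stages), producing
three contrasts per run — whole shelves (all ROIs), nasal-domain-only and
oral-domain-only — each as a DGE table and a volcano table, plus a JSON
manifest recording the config, seed and per-stage record counts.

The reported log2 fold change is oriented as log2(group B / group A): the
second (test) group relative to the first (baseline).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dge import DGEConfig, run_dge, volcano_plot, volcano_table
from .binning import NucleiFilterConfig
from .partition import NASAL, ORAL, coexpression_field, fit_oronasal_axis, marker_density_mode
from .roi import ROIConfig, DensityMatrix, build_density_matrix, generate_rois, write_roi_csv
from .synthetic import (
    GeometryParams,
    default_gene_model,
    generate_section_geometry,
    simulate_xenium_transcripts,
)

__all__ = ["RunConfig", "run_comparison"]

SCOPES = {"whole": None, "nasal": NASAL, "oral": ORAL}


@dataclass
class RunConfig:
    """Declarative configuration of one comparison run."""

    seed: int = 0
    group_a: str = "A"  # baseline condition
    group_b: str = "B"  # test condition
    n_sections_per_group: int = 2
    marker_a: str = "Shh"
    marker_b: str = "Ptch1"
    bandwidth: float = 20.0
    grid_step: float = 5.0
    geometry: GeometryParams = field(default_factory=GeometryParams)
    roi: ROIConfig = field(default_factory=ROIConfig)
    dge: DGEConfig = field(default_factory=DGEConfig)
    nuclei_filter: NucleiFilterConfig = field(default_factory=NucleiFilterConfig)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML document whose keys mirror the field names;
        nested sections (geometry, roi, dge, nuclei_filter) are mappings.
        Keyword overrides (e.g. from CLI flags) win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        nested = {
            "geometry": GeometryParams,
            "roi": ROIConfig,
            "dge": DGEConfig,
            "nuclei_filter": NucleiFilterConfig,
        }
        kwargs = {}
        for k, v in data.items():
            if k in nested and isinstance(v, dict):
                v = {kk: tuple(vv) if isinstance(vv, list) else vv for kk, vv in v.items()}
                kwargs[k] = nested[k](**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _derive_seeds(seed: int, n: int) -> list[int]:
    import numpy as np

    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_comparison(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full comparison pipeline into ``out_dir``.

    Per group and section: generate a synthetic section, simulate
    transcripts under the group's condition, fit the oronasal axis of each
    shelf from marker co-expression (oral side disambiguated by the
    ``marker_a`` density mode), place ROIs, and build the density matrix.
    Pooled group matrices are then compared at three scopes (whole / nasal /
    oral), writing ``dge_<scope>.csv`` and ``volcano_<scope>.csv``.

    Outputs are fully determined by (config, seed); any stage failure aborts
    the run with the stage named and the manifest marked incomplete.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("palateseq.run")
    if not log.handlers:
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)

    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "lfc_orientation": f"log2({config.group_b}/{config.group_a})",
        "classification_p": "p_adj" if config.dge.use_adjusted_p_for_class else "p_raw",
        "stages": {},
        "status": "incomplete",
    }
    stage = "setup"
    try:
        model = default_gene_model()
        genes = model.gene_index
        n = config.n_sections_per_group
        seeds = _derive_seeds(config.seed, 2 * n * 3)
        matrices: dict[str, list[DensityMatrix]] = {config.group_a: [], config.group_b: []}
        counts_log = {}
        si = 0
        for group in (config.group_a, config.group_b):
            condition = "A" if group == config.group_a else "B"
            for k in range(n):
                t0 = time.perf_counter()
                stage = f"simulate[{group}:{k}]"
                geom = generate_section_geometry(seeds[si * 3])
                table, _truth = simulate_xenium_transcripts(
                    geom, model, condition=condition, seed=seeds[si * 3 + 1]
                )
                stage = f"partition[{group}:{k}]"
                axes, refs = {}, {}
                for shelf in geom.shelves:
                    xmin, ymin, xmax, ymax = shelf.polygon.bounds
                    pad = 2 * config.bandwidth
                    fld = coexpression_field(
                        table, config.marker_a, config.marker_b,
                        bandwidth=config.bandwidth, grid_step=config.grid_step,
                        bounds=(xmin - pad, ymin - pad, xmax + pad, ymax + pad),
                    )
                    axes[shelf.name] = fit_oronasal_axis(fld, shelf.polygon, shelf.name)
                    refs[shelf.name] = marker_density_mode(
                        table, config.marker_a, bandwidth=config.bandwidth,
                        grid_step=config.grid_step, within=shelf.polygon,
                    )
                stage = f"roi[{group}:{k}]"
                roi_cfg = dataclasses.replace(config.roi, seed=seeds[si * 3 + 2])
                rois = generate_rois(geom, axes, table, roi_cfg, oral_refs=refs)
                stage = f"density[{group}:{k}]"
                dm = build_density_matrix(
                    table, rois, min_qv=config.roi.min_qv, gene_index=genes, group=group
                )
                prefix = f"{group}{k + 1}-"
                dm = DensityMatrix(
                    counts=dm.counts.set_axis(prefix + dm.counts.index, axis=0),
                    meta=dm.meta.set_axis(prefix + dm.meta.index, axis=0),
                    group=group,
                )
                matrices[group].append(dm)
                counts_log[f"{group}:{k}"] = {
                    "transcripts": int(len(table)),
                    "rois": len(rois),
                }
                log.info("section %s:%d done in %.2fs (%d transcripts, %d ROIs)",
                         group, k, time.perf_counter() - t0, len(table), len(rois))
                si += 1
        manifest["stages"]["sections"] = counts_log

        pooled = {}
        for group, mats in matrices.items():
            pooled[group] = DensityMatrix(
                counts=pd.concat([m.counts for m in mats]),
                meta=pd.concat([m.meta for m in mats]),
                group=group,
            )
            write_roi_csv(pooled[group], out / f"density_{group}.csv")

        scope_counts = {}
        for scope, domain in SCOPES.items():
            stage = f"dge[{scope}]"
            t0 = time.perf_counter()
            sub_b = pooled[config.group_b].subset(domain)
            sub_a = pooled[config.group_a].subset(domain)
            res = run_dge(sub_b, sub_a, config.dge)  # lfc = log2(B/A)
            res.drop(columns=["degenerate"]).to_csv(out / f"dge_{scope}.csv", index=False)
            volcano_table(res, config.dge).to_csv(out / f"volcano_{scope}.csv", index=False)
            if config.make_plots:
                volcano_plot(res, out / f"volcano_{scope}.png", config.dge,
                             title=f"{config.group_b} vs {config.group_a} ({scope})")
            scope_counts[scope] = {
                "rois_per_group": [int(len(sub_a.counts)), int(len(sub_b.counts))],
                "genes": int(len(res)),
                "up": int((res["class"] == "up").sum()),
                "down": int((res["class"] == "down").sum()),
            }
            log.info("scope %s: %s (%.2fs)", scope, scope_counts[scope],
                     time.perf_counter() - t0)
        manifest["stages"]["dge"] = scope_counts
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
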