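"""Shared fixtures: a default synthetic section and its fitted partition."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from palateseq.partition import AxisLine, coexpression_field, fit_oronasal_axis
from palateseq.synthetic import (
    GeneModel,
    GeneSpec,
    SectionGeometry,
    Shelf,
    default_gene_model,
    generate_section_geometry,
    simulate_xenium_transcripts,
)

GEOM_SEED = 11
XENIUM_SEED = 23


@pytest.fixture(scope="session")
def geometry():
    return generate_section_geometry(GEOM_SEED)


@pytest.fixture(scope="session")
def gene_model():
    return default_gene_model()


@pytest.fixture(scope="session")
def xenium(geometry, gene_model):
    """Default condition-A section: (table, truth)."""
    return simulate_xenium_transcripts(geometry, gene_model, "A", XENIUM_SEED)


@pytest.fixture(scope="session")
def fitted_axes(geometry, xenium):
    table, _ = xenium
    axes = {}
    for shelf in geometry.shelves:
        xmin, ymin, xmax, ymax = shelf.polygon.bounds
        field = coexpression_field(
            table, "Shh", "Ptch1",
            bounds=(xmin - 40, ymin - 40, xmax + 40, ymax + 40),
        )
        axes[shelf.name] = fit_oronasal_axis(field, shelf.polygon, shelf.name)
    return axes


def square_shelf(side: float = 100.0, strip: float = 10.0) -> SectionGeometry:
    """A single axis-aligned square shelf, oral margin at the bottom edge."""
    poly = Polygon([(0, 0), (side, 0), (side, side), (0, side)])
    strip_poly = Polygon(
        [(0, side - strip), (side, side - strip), (side, side), (0, side)]
    )
    axis = AxisLine(anchor=(side / 2, side / 2), direction=(1.0, 0.0), shelf="PL")
    shelf = Shelf(name="PL", polygon=poly, axis_truth=axis,
                  epithelial_strip=strip_poly, oral_sign=1.0)
    return SectionGeometry(shelves=(shelf,), frame=(side, side))


def uniform_gene(intensity: float, lfc: float = 0.0) -> GeneModel:
    """One spatially uniform gene, for Poisson-law checks."""
    return GeneModel(genes={"G": GeneSpec(intensity, effect_lfc=lfc)})
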