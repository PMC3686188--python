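import pytest
from shapely.geometry import MultiPolygon, Polygon, box

from rangearc.range_geometry import RangeGeom
from rangearc.synthetic_data import make_prunellid_fixture


def square(taxon, x0, y0, side):
    """Axis-aligned square RangeGeom helper."""
    return RangeGeom(taxon, MultiPolygon([box(x0, y0, x0 + side, y0 + side)]))


def rect(taxon, x0, y0, x1, y1):
    return RangeGeom(taxon, MultiPolygon([box(x0, y0, x1, y1)]))


@pytest.fixture(scope="session")
def prunellid():
    """The packaged 15-tip accentor-like dataset (tree, ranges, coding)."""
    return make_prunellid_fixture()


@pytest.fixture
def l_shape():
    """An L-shaped simple polygon for rasterization oracle tests."""
    poly = Polygon([(0, 0), (10, 0), (10, 4), (4, 4), (4, 10), (0, 10)])
    return RangeGeom("L", MultiPolygon([poly]))
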