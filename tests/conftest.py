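import numpy as np
import pytest

from figprov.ingest import Panel, PanelBox
from figprov.synthetic import synth_panel


def make_panel(
    raster: np.ndarray,
    panel_id: str = "docA/fig0/p0",
    panel_type: str = "microscopy",
) -> Panel:
    doc_id, figure = panel_id.split("/")[0], "/".join(panel_id.split("/")[:2])
    h, w = raster.shape[:2]
    return Panel(panel_id, doc_id, figure, PanelBox((0, 0, w, h), panel_type), raster)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def textured_panel(rng):
    """A keypoint-rich microscopy-like panel."""
    return make_panel(synth_panel("microscopy", rng))


@pytest.fixture
def noise_panel_pair(rng):
    """Two unrelated random-texture panels."""
    a = make_panel(synth_panel("microscopy", rng), "docA/fig0/p0")
    b = make_panel(synth_panel("microscopy", rng), "docB/fig0/p0")
    return a, b
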