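import pytest

from tonoquant import synthetic
from tonoquant.prep import CellROI


@pytest.fixture(scope="session")
def optics():
    return synthetic.OpticsNoiseSpec()


@pytest.fixture(scope="session")
def optics_clean():
    """Noise-free, bleach-free optics for deterministic geometry checks."""
    return synthetic.OpticsNoiseSpec().noiseless()


@pytest.fixture(scope="session")
def one_compartment_cell():
    """A single consolidated cell with exactly one compartment."""
    cells = synthetic.generate_cell_population(8, "consolidated", seed=3)
    for c in cells:
        if c.n_compartments == 1:
            return c
    raise AssertionError("no 1-compartment cell drawn")


@pytest.fixture(scope="session")
def textured_frame(optics_clean):
    """Noiseless multi-compartment frame with enough structure to register."""
    cells = synthetic.generate_cell_population(
        1, "fragmented", seed=7,
        geometry=synthetic.GeometryParams(cell_width_px=(180, 180), cell_length_px=(180, 180)),
    )
    frame, _ = synthetic.render_frame(cells, optics_clean, seed=0)
    return frame


def roi_of(cell) -> CellROI:
    return CellROI(cell.cell_id, *cell.rect, condition_label=cell.condition_label)
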