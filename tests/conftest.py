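import numpy as np
import pytest

from ifishquant import synth


@pytest.fixture(scope="session")
def small_scene():
    """15 non-touching cells with 3 spots each; shared across tests."""
    spec = synth.SceneSpec(
        n_cells=15, height=400, width=400, seed=11, spots_per_cell=3
    )
    return spec, synth.generate_scene(spec)


@pytest.fixture(scope="session")
def two_population_scene():
    """Separable tumor/stroma phenotypes for classifier tests."""
    types = [
        synth.CellType(
            "tumor", 0.5, radius_scale=1.15, nuclear_level=0.5, membrane_level=0.7
        ),
        synth.CellType(
            "stroma", 0.5, radius_scale=0.8, nuclear_level=0.15, membrane_level=0.2
        ),
    ]
    spec = synth.SceneSpec(
        n_cells=40,
        height=600,
        width=600,
        seed=7,
        spots_per_cell=2,
        cell_types=types,
    )
    return spec, synth.generate_scene(spec)


@pytest.fixture(scope="session")
def measured_records(two_population_scene):
    """Fully measured cell records for the two-population scene."""
    from ifishquant import cell_features, io_background, membrane_seg, spot_detect

    spec, (stack, nuclei, cells, spots_t, recs) = two_population_scene
    mem = membrane_seg.membrane_segment(stack.channel("HER2"), nuclei)
    spots = spot_detect.detect_spots(stack.channel("HER2-FISH"), nuclei)
    records = cell_features.map_segments(
        nuclei, mem, spots, spot_channel="HER2-FISH"
    )
    backgrounds = {}
    for name in stack.names:
        ch = stack.channel(name)
        g = io_background.global_background(ch, nuclei == 0)
        est = io_background.ring_background(ch, nuclei)
        backgrounds[name] = io_background.BackgroundEstimate(
            global_mean=g, per_label=est.per_label
        )
    records = cell_features.measure_cells(
        records, stack, backgrounds, nuclei=nuclei, membranes=mem
    )
    truth = dict(zip(recs.label, recs.cell_type))
    return records, truth, nuclei, mem, stack


def disk_mask(shape, center, radius):
    rows, cols = np.mgrid[: shape[0], : shape[1]]
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
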