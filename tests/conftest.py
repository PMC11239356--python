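import numpy as np
import pytest

from stainlab import labeling, simulate


@pytest.fixture(scope="session")
def small_section():
    """A modest default-density section shared by read-only tests."""
    return simulate.generate_section(60, 0.2, (256, 256), seed=11)


def make_separated_section(seed, n_cells=25, canvas=(512, 512)):
    """Section with well-separated nuclei: far enough apart that the
    default CD3 blur tail from one cell cannot majority-cover any
    neighbouring nucleus."""
    return simulate.generate_section(
        n_cells, 0.2, canvas, seed=seed, min_dist=64.0
    )


@pytest.fixture
def separated_section():
    return make_separated_section(seed=3)


def truth_labels_of(section):
    return {c.id: c.label for c in section.cells}


def label_agreement(table, section):
    truth = truth_labels_of(section)
    return float(np.mean([truth[i] == l for i, l in zip(table["id"], table["label"])]))
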