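import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from morphovox.morphology import (
    MorphSample,
    Morphology,
    Section,
    SomaGeometry,
    Structure,
)

# 8-row SWC: soma + 3-sample chain bifurcating into two 2-sample chains
EIGHT_ROW_SWC = """\
# toy neuron
1 1 0 0 0 5.0 -1
2 3 6 0 0 1.5 1
3 3 12 0 0 1.4 2
4 3 18 0 0 1.3 3
5 3 24 4 0 1.0 4
6 3 30 8 0 0.9 5
7 3 24 -4 0 0.8 4
8 3 30 -8 0 0.7 7
"""


@pytest.fixture
def eight_row_swc(tmp_path):
    p = tmp_path / "eight.swc"
    p.write_text(EIGHT_ROW_SWC)
    return p


def make_sample(i, pos, radius=1.0, structure=Structure.BASAL_DENDRITE):
    return MorphSample(i, structure, np.asarray(pos, float), radius)


def chain_section(positions, radii, order=1, start_id=100, structure=Structure.BASAL_DENDRITE):
    samples = [
        make_sample(start_id + k, p, r, structure)
        for k, (p, r) in enumerate(zip(positions, radii))
    ]
    return Section(samples=samples, order=order)


def soma_only(radius=5.0):
    return Morphology(soma=SomaGeometry(centroid=np.zeros(3), mean_radius=radius))


@pytest.fixture
def straight_neurite_morph():
    """Soma (r=5) plus one straight first-order section along +x."""
    m = soma_only()
    sec = chain_section(
        [(5, 0, 0), (10, 0, 0), (15, 0, 0), (20, 0, 0)], [1.5, 1.4, 1.3, 1.2]
    )
    m.neurites.append(sec)
    return m
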