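import numpy as np
import pytest

from vffr.graph import VesselGraph, VesselNode, VesselSegment
from vffr.hemo import TerminalOutlet
from vffr.personalize import PatientRecord


@pytest.fixture
def single_tube():
    """Ostium -> terminal straight tube, D=3 mm, L=30 mm."""
    nodes = [
        VesselNode("n0", "ostium", (0.0, 0.0, 0.0)),
        VesselNode("n1", "terminal", (30.0, 0.0, 0.0)),
    ]
    segs = [VesselSegment("s0", "n0", "n1", 30.0, 3.0, 3.0, 12.0)]
    return VesselGraph.from_lists(nodes, segs, ["n0"])


@pytest.fixture
def y_tree():
    """Single bifurcation: trunk plus two unequal daughters."""
    nodes = [
        VesselNode("n0", "ostium", (0.0, 0.0, 0.0)),
        VesselNode("n1", "junction", (30.0, 0.0, 0.0)),
        VesselNode("n2", "terminal", (55.0, 10.0, 0.0)),
        VesselNode("n3", "terminal", (55.0, -10.0, 0.0)),
    ]
    segs = [
        VesselSegment("s0", "n0", "n1", 30.0, 3.5, 3.5, 12.0),
        VesselSegment("s1", "n1", "n2", 25.0, 2.8, 2.8, 12.0),
        VesselSegment("s2", "n1", "n3", 25.0, 2.4, 2.4, 12.0),
    ]
    return VesselGraph.from_lists(nodes, segs, ["n0"])


@pytest.fixture
def y_terminals():
    return {
        "n2": TerminalOutlet(resistance=20.0, p_out=8.0),
        "n3": TerminalOutlet(resistance=30.0, p_out=8.0),
    }


@pytest.fixture
def table1_record():
    """Cohort-mean hemodynamics of the study population."""
    return PatientRecord(id="mean", age=63.61, sbp=133.39, dbp=84.03, hr=65.19)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
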