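import pytest

from mcps.colored_graphs import BLACK, GRAY, ColoredGraph, LabeledGraph, Labeling
from mcps.synthetic import fixtures


@pytest.fixture()
def fx():
    return fixtures()


def make_circle(labels, gray_labels=None):
    """A labeled circle with r black edges in the given circular order.

    Vertices are 0..2r-1; black edge i spans (2i, 2i+1), the gray edge
    after it spans (2i+1, 2i+2 mod 2r).
    """
    r = len(labels)
    g = ColoredGraph()
    lab = Labeling()
    for i in range(r):
        eid = g.add_edge(BLACK, 2 * i, 2 * i + 1)
        lab.edge[eid] = labels[i]
    for i in range(r):
        eid = g.add_edge(GRAY, 2 * i + 1, (2 * i + 2) % (2 * r))
        if gray_labels is not None:
            lab.edge[eid] = gray_labels[i]
    return LabeledGraph(g, lab)
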