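import pytest

from sigreach.network_model import ProbabilisticNetwork


def make_net(edges, probs, sources, targets, extra=()):
    return ProbabilisticNetwork(
        edges=tuple(edges),
        probs=tuple(probs),
        sources=frozenset(sources),
        targets=frozenset(targets),
        extra_nodes=frozenset(extra),
    )


@pytest.fixture
def single_edge():
    """s -> t with existence probability 0.4."""
    return make_net([("s", "t")], [0.4], {"s"}, {"t"})


@pytest.fixture
def chain():
    """s -> a -> t, both edges at 0.5 (series motif, P_reach = 0.25)."""
    return make_net([("s", "a"), ("a", "t")], [0.5, 0.5], {"s"}, {"t"})


@pytest.fixture
def diamond():
    """Two parallel two-hop paths s->v->t and s->w->t, all edges at 0.5.

    P_reach = 1 - (1 - 0.25)^2 = 0.4375.
    """
    return make_net(
        [("s", "v"), ("v", "t"), ("s", "w"), ("w", "t")],
        [0.5] * 4,
        {"s"},
        {"t"},
    )


MINI_OBO = """\
format-version: 1.2
ontology: mini

[Term]
id: X:0000001
name: root

[Term]
id: X:0000002
name: level1
is_a: X:0000001 ! root

[Term]
id: X:0000003
name: level2 via part_of
relationship: part_of X:0000002 ! level1

[Term]
id: X:0000004
name: deep chain node
is_a: X:0000003

[Term]
id: X:0000005
name: diamond child (short path 2, long path 3)
is_a: X:0000002
is_a: X:0000004
"""


@pytest.fixture
def mini_obo(tmp_path):
    path = tmp_path / "mini.obo"
    path.write_text(MINI_OBO)
    return path
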