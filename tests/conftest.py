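"""Shared test configuration and helpers."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# deterministic property tests: fixed derandomized profile
settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_binary_tree(rng, labels, min_bl=0.05, max_bl=1.0):
    """Random rooted binary tree over the given labels (fusionscape Clade)."""
    from fusionscape.trees import Clade

    nodes = [Clade(name=l, length=float(rng.uniform(min_bl, max_bl))) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Clade(
            children=[a, b], length=float(rng.uniform(min_bl, max_bl))
        )
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


def path_distances(tree):
    """Leaf-to-leaf path-length matrix of a Clade as {frozenset({a,b}): d}."""
    out = {}

    def walk(node):
        if node.is_leaf:
            return {node.name: 0.0}
        depths = {}
        child_maps = []
        for child in node.children:
            m = walk(child)
            m = {k: v + (child.length or 0.0) for k, v in m.items()}
            child_maps.append(m)
            depths.update(m)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for a, da in child_maps[i].items():
                    for b, db in child_maps[j].items():
                        out[frozenset((a, b))] = da + db
        return depths

    walk(tree)
    return out
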