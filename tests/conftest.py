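import numpy as np
import pytest

from galton import LanguageTaxonomy, WorldConfig, make_world


@pytest.fixture(scope="session")
def toy_tree():
    """root -> A -> (a1 -> (L1, L2), L3); root -> B -> L4.

    Maximum root-to-tip depth is 3 edges, so the relative-MRCA-depth
    proximities are s(L1,L2)=2/3, s(L1,L3)=1/3, s(L1,L4)=0.
    """
    return LanguageTaxonomy.from_newick("(((L1,L2)a1,L3)A,(L4)B);")


@pytest.fixture(scope="session")
def small_world():
    return make_world(WorldConfig(n_nations=30, seed=11))


@pytest.fixture(scope="session")
def mid_world():
    return make_world(WorldConfig(n_nations=60, seed=5))


def random_tuple_tree(rng: np.random.Generator, n_tips: int):
    """Random rooted topology as nested tuples of string tips (test oracle input)."""
    nodes = [f"t{i}" for i in range(n_tips)]
    while len(nodes) > 1:
        k = 2 if len(nodes) == 2 else int(rng.integers(2, min(3, len(nodes)) + 1))
        picks = sorted(rng.choice(len(nodes), size=k, replace=False))[::-1]
        children = tuple(nodes[i] for i in picks)
        for i in picks:
            del nodes[i]
        nodes.append(children)
    return nodes[0]


def tuple_tree_newick(node) -> str:
    def render(nd):
        if isinstance(nd, str):
            return nd
        return "(" + ",".join(render(c) for c in nd) + ")"
    return render(node) + ";"


def brute_force_proximities(node):
    """Independent proximity oracle: enumerate root paths, intersect for the MRCA.

    Returns (tips, dict[(i, j)] -> s) with s = (n_r - n_i)/n_r, n_r the
    maximum root-to-tip edge count and n_i the maximum edge count from the
    MRCA down to any tip below it.
    """
    paths = {}

    def walk(nd, prefix):
        if isinstance(nd, str):
            paths[nd] = prefix
            return
        for ci, child in enumerate(nd):
            walk(child, prefix + (ci,))

    walk(node, ())
    tips = sorted(paths)
    n_r = max(len(p) for p in paths.values())
    out = {}
    for a in tips:
        for b in tips:
            pa, pb = paths[a], paths[b]
            d = 0
            while d < min(len(pa), len(pb)) and pa[d] == pb[d]:
                d += 1
            if a == b:
                out[(a, b)] = 1.0
                continue
            # n_i: deepest tip below the MRCA, in edges from the MRCA
            n_i = max(len(p) - d for t, p in paths.items() if p[:d] == pa[:d])
            out[(a, b)] = (n_r - n_i) / n_r
    return tips, out
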