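"""Shared fixtures and tree-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest
from skbio import TreeNode

from phylophen.genome import GenomeRecord


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.5,
                  gid: str = "g") -> GenomeRecord:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    seq = "".join("ACGT"[c] for c in codes)
    return GenomeRecord(id=gid, scaffolds=[("chr1", seq)])


def random_additive_tree(n: int, rng: np.random.Generator) -> TreeNode:
    """Random binary tree with uniform branch lengths (additive matrix source)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(TreeNode(children=[b, a]))
    for nd in nodes:
        nd.length = float(rng.uniform(0.05, 1.0))
    return TreeNode(children=nodes)


def clade_tree(rng: np.random.Generator, n_clades: int = 3, tips: int = 4,
               within: float = 0.001, between: float = 0.5) -> TreeNode:
    """Rooted tree with well-separated clades: short within-clade branches
    (~Exp(within)) and long between-clade branches (~Exp(between))."""
    clades = []
    for c in range(n_clades):
        nodes = [TreeNode(name=f"c{c}t{i}") for i in range(tips)]
        while len(nodes) > 1:
            a, b = nodes.pop(), nodes.pop()
            a.length = float(rng.exponential(within))
            b.length = float(rng.exponential(within))
            nodes.append(TreeNode(children=[a, b]))
        root = nodes[0]
        root.length = float(rng.exponential(between)) + between / 2
        clades.append(root)
    while len(clades) > 2:
        a, b = clades.pop(), clades.pop()
        p = TreeNode(children=[a, b])
        p.length = float(rng.exponential(between)) + between / 2
        clades.append(p)
    return TreeNode(children=clades)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
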