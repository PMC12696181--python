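"""Ward agglomerative clustering and distance-based (NJ/BIONJ) phylogenies.

Both operate on a validated square :class:`DistanceMatrix` and return
scikit-bio ``TreeNode`` objects, so Newick round-trips, midpoint rooting and
bipartition handling come from the standard tree container. Tie-breaking is
deterministic everywhere: among equally good candidate merges, the pair
whose (lexicographically smallest, largest) label pair sorts first wins.

The NJ tree here plays the role of an alignment-free phylogenomic tree
built directly on Mash distances; branch lengths stay on the D scale.
Negative NJ branch length estimates are clamped to zero with the deficit
moved to the sister branch, preserving path lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .genome import GenomeRecord
from .sketch import Sketch, jaccard_estimate, make_sketch, mash_distance

__all__ = [
    "DistanceMatrix",
    "ward_cluster",
    "nj_tree",
    "bootstrap_support",
    "read_newick",
    "write_newick",
    "tree_tip_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of non-negative distances with labels."""

    labels: list[str]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if np.any(np.abs(self.data - self.data.T) > 1e-12):
            raise ValueError("matrix is not symmetric (tolerance 1e-12)")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(self.data < 0):
            raise ValueError("distances must be non-negative")

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels=list(labels), data=self.data[np.ix_(idx, idx)])

    def to_phylip(self, path: str | Path | None = None) -> str:
        lines = [str(len(self.labels))]
        for label, row in zip(self.labels, self.data):
            lines.append(label + "\t" + "\t".join(f"{x:.10g}" for x in row))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_phylip(cls, path: str | Path) -> "DistanceMatrix":
        lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        return cls(labels=labels, data=np.array(rows))


# ---------------------------------------------------------------------------
# Ward clustering (Lance-Williams)


def ward_cluster(m: DistanceMatrix) -> tuple[TreeNode, list[tuple[str, str, float]]]:
    """Ward's-method agglomerative clustering of a distance matrix.

    Lance-Williams update on squared distances; merge heights are
    non-decreasing (Ward is reducible). Returns a rooted ultrametric
    dendrogram (tip-to-tip distance through a node equals its merge height)
    and the merge trace as ``(label_i, label_j, height)`` tuples.

    Deterministic: ties are broken by the lexicographically smallest label
    pair, where a cluster is identified by its smallest member label.
    """
    n = len(m.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    d2 = m.data.astype(float) ** 2
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    keys = {i: m.labels[i] for i in range(n)}  # smallest member label
    nodes = {i: TreeNode(name=m.labels[i], length=0.0) for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    merges: list[tuple[str, str, float]] = []
    next_id = n
    d2 = {i: {j: d2[i, j] for j in range(n) if j != i} for i in range(n)}

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dist = d2[i][j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                if best is None or dist < best[0] - 1e-15 or (
                    abs(dist - best[0]) <= 1e-15 and pair_key < best[1]
                ):
                    best = (dist, pair_key, i, j)
        _, _, i, j = best
        h = float(np.sqrt(max(d2[i][j], 0.0)))
        li, lj = sorted((keys[i], keys[j]))
        merges.append((li, lj, h))
        # new node at height h; children branch lengths fill the gap
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = h / 2.0 - heights[i] / 2.0
        child_j.length = h / 2.0 - heights[j] / 2.0
        parent = TreeNode(children=[child_i, child_j], length=0.0)
        u = next_id
        next_id += 1
        ni, nj = sizes[i], sizes[j]
        d2[u] = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            val = (
                (ni + nk) * d2[i][k] + (nj + nk) * d2[j][k] - nk * d2[i][j]
            ) / (ni + nj + nk)
            d2[u][k] = val
            d2[k][u] = val
            del d2[k][i], d2[k][j]
        del d2[i], d2[j]
        active = [k for k in active if k not in (i, j)] + [u]
        sizes[u] = ni + nj
        keys[u] = min(keys[i], keys[j])
        nodes[u] = parent
        heights[u] = h
    root = nodes[active[0]]
    root.length = None
    return root, merges


# ---------------------------------------------------------------------------
# Neighbor joining / BIONJ


def _cluster_key(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


def nj_tree(m: DistanceMatrix, method: str = "bionj") -> TreeNode:
    """Neighbor-joining (or BIONJ variance-weighted) tree from distances.

    Standard Q-criterion agglomeration; returns an unrooted tree (root is a
    trifurcation). Negative branch length estimates are clamped to 0 and the
    deficit is moved to the sister branch so the joined path length is
    preserved. Deterministic: ties on Q broken by smallest label pair.
    """
    if method not in ("nj", "bionj"):
        raise ValueError("method must be 'nj' or 'bionj'")
    n = len(m.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")

    nodes = [TreeNode(name=l) for l in m.labels]
    D = m.data.astype(float).copy()
    V = D.copy()  # variances (BIONJ); unused by plain NJ

    idx = list(range(n))  # active row indices into D/V
    while len(idx) > 3:
        k = len(idx)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        best = None
        for a in range(k):
            for b in range(a + 1, k):
                q = (k - 2) * sub[a, b] - r[a] - r[b]
                pair_key = tuple(
                    sorted((_cluster_key(nodes[idx[a]]), _cluster_key(nodes[idx[b]])))
                )
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and pair_key < best[1]
                ):
                    best = (q, pair_key, a, b)
        _, _, a, b = best
        i, j = idx[a], idx[b]
        dij = D[i, j]
        vi = 0.5 * dij + (r[a] - r[b]) / (2.0 * (k - 2))
        vj = dij - vi
        # clamp negatives, moving the deficit to the sister branch
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = vi
        child_j.length = vj
        parent = TreeNode(children=[child_i, child_j])

        if method == "bionj" and V[i, j] > 0:
            others = [idx[c] for c in range(k) if c not in (a, b)]
            lam = 0.5 + sum(V[j, o] - V[i, o] for o in others) / (
                2.0 * (k - 2) * V[i, j]
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        for c in range(k):
            o = idx[c]
            if o in (i, j):
                continue
            if method == "bionj":
                newd = lam * (D[i, o] - vi) + (1.0 - lam) * (D[j, o] - vj)
                newv = lam * V[i, o] + (1.0 - lam) * V[j, o] - lam * (1.0 - lam) * V[i, j]
            else:
                newd = 0.5 * (D[i, o] + D[j, o] - dij)
                newv = newd
            D[i, o] = D[o, i] = newd
            V[i, o] = V[o, i] = max(newv, 0.0)
        nodes[i] = parent
        idx.remove(j)

    # final three nodes: star with closed-form lengths
    i, j, o = idx
    vi = 0.5 * (D[i, j] + D[i, o] - D[j, o])
    vj = 0.5 * (D[i, j] + D[j, o] - D[i, o])
    vo = 0.5 * (D[i, o] + D[j, o] - D[i, j])
    for node, v in ((nodes[i], vi), (nodes[j], vj), (nodes[o], vo)):
        node.length = max(v, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[o]])
    return root


def tree_tip_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Path-length (patristic) distances between all tips of a tree."""
    tips = sorted(t.name for t in tree.tips())
    dm = tree.tip_tip_distances(endpoints=tips)
    return DistanceMatrix(labels=list(dm.ids), data=dm.data.copy())


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str | Path) -> TreeNode:
    """Read a Newick tree from a path or a literal Newick string."""
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    return TreeNode.read(io.StringIO(text), format="newick")


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Bootstrap supports by sketch resampling


def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_tips):
            other = all_tips - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def bootstrap_support(
    genomes: list[GenomeRecord],
    reps: int,
    seed: int,
    k: int = 21,
    s: int = 1000,
    method: str = "bionj",
) -> TreeNode:
    """Distance tree with sketch-resampling branch supports.

    Each replicate resamples every genome's sketch hashes with replacement,
    recomputes Mash distances, rebuilds the tree and records bipartition
    frequencies in [0, 1], stored on internal nodes as ``support`` (and as
    the node name for Newick export). These supports quantify MinHash
    sampling noise, not sequence-level conflict.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sketches = [make_sketch(g, k=k, s=s, seed=seed) for g in genomes]
    labels = [g.id for g in genomes]

    def matrix_from(sks: list[Sketch]) -> DistanceMatrix:
        n = len(sks)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = mash_distance(sks[i], sks[j])
        return DistanceMatrix(labels=labels, data=d)

    ref_tree = nj_tree(matrix_from(sketches), method=method)
    all_tips = frozenset(labels)
    ref_parts = {
        node: min(
            frozenset(t.name for t in node.tips()),
            all_tips - frozenset(t.name for t in node.tips()),
            key=lambda x: (len(x), sorted(x)),
        )
        for node in ref_tree.non_tips(include_self=False)
    }
    counts = {part: 0 for part in ref_parts.values()}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        resampled = []
        for sk in sketches:
            take = rng.choice(sk.hashes, size=sk.hashes.size, replace=True)
            hashes = np.unique(take)[: sk.s]
            resampled.append(
                Sketch(genome_id=sk.genome_id, k=sk.k, s=sk.s, seed=sk.seed, hashes=hashes)
            )
        rep_tree = nj_tree(matrix_from(resampled), method=method)
        rep_parts = _bipartitions(rep_tree, all_tips)
        for part in counts:
            if part in rep_parts:
                counts[part] += 1
    for node, part in ref_parts.items():
        node.support = counts[part] / reps
        node.name = f"{node.support:g}"
    return ref_tree
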