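"""Tree-based species delimitation: PTP (ML and Bayesian) and GMYC.

The Poisson tree process (PTP) models branch lengths directly: branches are
partitioned into a between-species (speciation) class and a pooled
within-species (coalescent) class, each with exponential waiting times and
its own rate estimated by maximum likelihood (rate = 1 / mean class branch
length). A species partition is a set of "species root" nodes covering all
tips; edges at or above species roots are speciation edges, edges strictly
below are coalescent edges. The ML search enumerates all partitions exactly
when their number is small and hill-climbs (split/merge moves from both
extremes) otherwise; a likelihood-ratio test against the single-class null
guards against over-splitting. The Bayesian variant (bPTP) samples
partitions by Metropolis-Hastings with split/merge moves under a uniform
prior, reporting per-group posterior support as the fraction of post-burn-in
samples containing that exact tip group.

GMYC (single-threshold) assumes an ultrametric tree in which branching
before a time threshold T follows a Yule process and branching after T
follows independent within-species coalescents; T is chosen by maximum
likelihood over the observed node ages. Non-ultrametric inputs are first
smoothed by mean path length (MPL), which is idempotent on ultrametric
trees. Per-cluster supports are likelihood weights accumulated over all
candidate thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from skbio import TreeNode

__all__ = [
    "SpeciesPartition",
    "MCMCConfig",
    "DegenerateTreeError",
    "ptp_ml",
    "bptp",
    "gmyc",
    "ultrametricize_mpl",
]


class DegenerateTreeError(ValueError):
    """Raised when branch lengths cannot support the two-class model."""


@dataclass
class SpeciesPartition:
    """An assignment of tree tips to species with per-group support."""

    assignment: dict[str, int]
    n_species: int
    support: dict[frozenset, float]
    method: str
    log_likelihood: float
    extras: dict = field(default_factory=dict)

    def groups(self) -> list[frozenset]:
        out: dict[int, set] = {}
        for tip, sp in self.assignment.items():
            out.setdefault(sp, set()).add(tip)
        return [frozenset(v) for _, v in sorted(out.items())]

    def to_tsv(self) -> str:
        lines = ["tip\tspecies"]
        for tip in sorted(self.assignment):
            lines.append(f"{tip}\t{self.assignment[tip]}")
        return "\n".join(lines) + "\n"


@dataclass
class MCMCConfig:
    """Settings for the bPTP sampler."""

    iterations: int = 1_000_000
    burn_in_fraction: float = 0.1
    seeds: tuple[int, ...] = (1, 2, 3, 4)
    thinning: int = 100

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 <= self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if not self.seeds:
            raise ValueError("at least one seed required")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


# ---------------------------------------------------------------------------
# tree indexing


class _TreeIndex:
    """Array view of a rooted tree for fast partition arithmetic."""

    def __init__(self, tree: TreeNode):
        nodes = list(tree.postorder(include_self=True))
        self.n = len(nodes)
        self.id_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = [None] * self.n
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        self.length = np.zeros(self.n)
        self.is_tip = np.zeros(self.n, dtype=bool)
        self.tip_name = [None] * self.n
        self.tips_below: list[frozenset] = [frozenset()] * self.n
        for i, nd in enumerate(nodes):
            self.length[i] = nd.length or 0.0
            if nd.is_tip():
                self.is_tip[i] = True
                self.tip_name[i] = nd.name
                self.tips_below[i] = frozenset([nd.name])
            else:
                kids = [self.id_of[id(c)] for c in nd.children]
                self.children[i] = kids
                for c in kids:
                    self.parent[c] = i
                self.tips_below[i] = frozenset().union(
                    *(self.tips_below[c] for c in kids)
                )
        self.root = self.n - 1
        # edges = every node except the root
        self.edge_ids = [i for i in range(self.n) if i != self.root]
        self.total_length = float(self.length[self.edge_ids].sum())
        self.n_edges = len(self.edge_ids)


def _prepare_rooted(tree: TreeNode) -> TreeNode:
    t = tree.copy()
    if len(t.children) > 2:  # unrooted input: midpoint rooting
        t = t.root_at_midpoint()
    for nd in t.traverse(include_self=True):
        if nd.length is None:
            nd.length = 0.0
    return t


def _class_ll(n: int, total: float) -> float:
    """Profile log-likelihood of n exponential waits summing to ``total``."""
    if n == 0:
        return 0.0
    if total <= 0:
        return -math.inf
    return n * (math.log(n / total) - 1.0)


def _partition_ll(ti: _TreeIndex, species_roots: frozenset[int]) -> float:
    coal_n = 0
    coal_sum = 0.0
    for r in species_roots:
        stack = list(ti.children[r])
        while stack:
            v = stack.pop()
            coal_n += 1
            coal_sum += ti.length[v]
            stack.extend(ti.children[v])
    spec_n = ti.n_edges - coal_n
    spec_sum = ti.total_length - coal_sum
    return _class_ll(spec_n, spec_sum) + _class_ll(coal_n, coal_sum)


def _enumerate_covers(ti: _TreeIndex, v: int) -> list[frozenset[int]]:
    """All valid species-root sets for the subtree at v."""
    if ti.is_tip[v]:
        return [frozenset([v])]
    out = [frozenset([v])]
    child_covers = [_enumerate_covers(ti, c) for c in ti.children[v]]
    combos = [frozenset()]
    for covers in child_covers:
        combos = [acc | cov for acc in combos for cov in covers]
    out.extend(combos)
    return out


def _count_covers(ti: _TreeIndex, v: int) -> int:
    if ti.is_tip[v]:
        return 1
    prod = 1
    for c in ti.children[v]:
        prod *= _count_covers(ti, c)
    return 1 + prod


def _moves(ti: _TreeIndex, C: frozenset[int]) -> list[tuple[str, int]]:
    splits = sorted(c for c in C if not ti.is_tip[c])
    parents = {ti.parent[c] for c in C if ti.parent[c] is not None}
    merges = sorted(
        p for p in parents if all(ch in C for ch in ti.children[p])
    )
    return [("split", c) for c in splits] + [("merge", p) for p in merges]


def _apply(ti: _TreeIndex, C: frozenset[int], move: tuple[str, int]) -> frozenset[int]:
    kind, node = move
    if kind == "split":
        return (C - {node}) | set(ti.children[node])
    return (C - set(ti.children[node])) | {node}


def _partition_from_roots(ti: _TreeIndex, C: frozenset[int]) -> dict[str, int]:
    groups = sorted((sorted(ti.tips_below[c]) for c in C), key=lambda g: g[0])
    assignment = {}
    for sp, tips in enumerate(groups, start=1):
        for tip in tips:
            assignment[tip] = sp
    return assignment


def _greedy_search(ti: _TreeIndex, start: frozenset[int]) -> tuple[frozenset[int], float]:
    C = start
    ll = _partition_ll(ti, C)
    improved = True
    while improved:
        improved = False
        best = (ll, C)
        for move in _moves(ti, C):
            C2 = _apply(ti, C, move)
            ll2 = _partition_ll(ti, C2)
            if ll2 > best[0] + 1e-12:
                best = (ll2, C2)
        if best[0] > ll:
            ll, C = best
            improved = True
    return C, ll


def ptp_ml(
    tree: TreeNode, alpha: float = 0.05, max_enumeration: int = 20000
) -> SpeciesPartition:
    """Maximum-likelihood PTP delimitation with a single-class LRT guard.

    Exhaustive over all valid partitions when their count is at most
    ``max_enumeration`` (exact); otherwise greedy split/merge hill-climbing
    from both the one-species and all-singletons extremes. If the two-class
    model does not beat the one-class null at level ``alpha`` (chi-square,
    1 df), the one-species partition is returned, flagged.
    """
    t = _prepare_rooted(tree)
    ti = _TreeIndex(t)
    if ti.total_length <= 0:
        raise DegenerateTreeError("tree has zero total branch length")

    null_ll = _class_ll(ti.n_edges, ti.total_length)
    if _count_covers(ti, ti.root) <= max_enumeration:
        best_C, best_ll, exact = None, -math.inf, True
        for C in _enumerate_covers(ti, ti.root):
            ll = _partition_ll(ti, C)
            if ll > best_ll + 1e-12 or (
                abs(ll - best_ll) <= 1e-12 and best_C is not None and len(C) < len(best_C)
            ):
                best_C, best_ll = C, ll
    else:
        exact = False
        c1, ll1 = _greedy_search(ti, frozenset([ti.root]))
        c2, ll2 = _greedy_search(
            ti, frozenset(i for i in range(ti.n) if ti.is_tip[i])
        )
        best_C, best_ll = (c1, ll1) if ll1 >= ll2 else (c2, ll2)

    stat = 2.0 * (best_ll - null_ll)
    p = float(chi2.sf(max(stat, 0.0), df=1))
    extras = {
        "lrt_p": p,
        "null_log_likelihood": null_ll,
        "search": "exhaustive" if exact else "greedy",
    }
    if p > alpha:
        C = frozenset([ti.root])
        assignment = _partition_from_roots(ti, C)
        extras["null_not_rejected"] = True
        return SpeciesPartition(
            assignment=assignment,
            n_species=1,
            support={frozenset(assignment): 1.0},
            method="ptp_ml",
            log_likelihood=_partition_ll(ti, C),
            extras=extras,
        )
    assignment = _partition_from_roots(ti, best_C)
    support = {ti.tips_below[c]: 1.0 for c in best_C}
    return SpeciesPartition(
        assignment=assignment,
        n_species=len(best_C),
        support=support,
        method="ptp_ml",
        log_likelihood=best_ll,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# bPTP


def _run_chain(ti: _TreeIndex, cfg: MCMCConfig, seed: int):
    rng = np.random.default_rng(seed)
    C = frozenset([ti.root])
    ll = _partition_ll(ti, C)
    burn = int(cfg.iterations * cfg.burn_in_fraction)
    group_counts: dict[frozenset, int] = {}
    count_counts: dict[int, int] = {}
    trace: list[tuple[int, float, int]] = []  # (iteration, logL, n_species)
    n_samples = 0
    best = (ll, C)
    moves = _moves(ti, C)
    for it in range(cfg.iterations):
        if not moves:
            break
        pick = moves[int(rng.integers(len(moves)))]
        C2 = _apply(ti, C, pick)
        ll2 = _partition_ll(ti, C2)
        moves2 = _moves(ti, C2)
        log_acc = (ll2 - ll) + math.log(len(moves)) - math.log(len(moves2))
        if math.log(rng.random() + 1e-300) < log_acc:
            C, ll, moves = C2, ll2, moves2
            if ll > best[0]:
                best = (ll, C)
        if it >= burn and (it - burn) % cfg.thinning == 0:
            n_samples += 1
            count_counts[len(C)] = count_counts.get(len(C), 0) + 1
            trace.append((it, ll, len(C)))
            for r in C:
                g = ti.tips_below[r]
                group_counts[g] = group_counts.get(g, 0) + 1
    supports = {g: c / n_samples for g, c in group_counts.items()} if n_samples else {}
    posterior_counts = (
        {k: v / n_samples for k, v in count_counts.items()} if n_samples else {}
    )
    return supports, posterior_counts, best, trace


def bptp(tree: TreeNode, cfg: MCMCConfig | None = None) -> SpeciesPartition:
    """Bayesian PTP: Metropolis-Hastings over species partitions.

    Moves flip a node between speciation and coalescent status (split a
    species into its two daughter clades, or merge sibling species).
    Replicate seeds run independently; the convergence report is the
    maximum absolute per-group support difference across seeds. The
    returned assignment is the maximum a posteriori partition; supports are
    per-group posterior frequencies averaged over seeds. Thinned per-seed
    traces (iteration, log-likelihood, species count) are returned in
    ``extras['traces']``.
    """
    cfg = cfg or MCMCConfig()
    t = _prepare_rooted(tree)
    ti = _TreeIndex(t)
    if ti.total_length <= 0:
        raise DegenerateTreeError("tree has zero total branch length")

    per_seed = [_run_chain(ti, cfg, s) for s in cfg.seeds]
    all_groups = set().union(*(s[0].keys() for s in per_seed))
    avg_support = {
        g: float(np.mean([s[0].get(g, 0.0) for s in per_seed])) for g in all_groups
    }
    conv = 0.0
    for g in all_groups:
        vals = [s[0].get(g, 0.0) for s in per_seed]
        conv = max(conv, max(vals) - min(vals))
    best_ll, best_C = max((s[2] for s in per_seed), key=lambda bc: bc[0])
    traces = {seed: s[3] for seed, s in zip(cfg.seeds, per_seed)}
    assignment = _partition_from_roots(ti, best_C)
    # posterior over species counts, averaged across seeds
    counts = set().union(*(s[1].keys() for s in per_seed))
    count_posterior = {
        k: float(np.mean([s[1].get(k, 0.0) for s in per_seed])) for k in counts
    }
    return SpeciesPartition(
        assignment=assignment,
        n_species=len(best_C),
        support={g: avg_support[g] for g in (ti.tips_below[c] for c in best_C)},
        method="bptp",
        log_likelihood=best_ll,
        extras={
            "group_support": avg_support,
            "species_count_posterior": count_posterior,
            "convergence_max_support_diff": conv,
            "per_seed_modal_count": [
                max(s[1], key=s[1].get) if s[1] else None for s in per_seed
            ],
            "traces": traces,
        },
    )


# ---------------------------------------------------------------------------
# GMYC


def ultrametricize_mpl(tree: TreeNode) -> TreeNode:
    """Mean-path-length smoothing to an ultrametric tree.

    Each internal node's age is the mean path length to its descendant
    tips, clamped so children are never older than parents; branch lengths
    are rewritten as age differences. Idempotent on ultrametric trees.
    """
    t = tree.copy()
    for nd in t.traverse(include_self=True):
        if nd.length is None:
            nd.length = 0.0
    ages: dict[int, float] = {}
    for nd in t.postorder(include_self=True):
        if nd.is_tip():
            ages[id(nd)] = 0.0
        else:
            paths = []
            for child in nd.children:
                base = ages[id(child)] + child.length
                paths.extend([base] * max(child.count(tips=True), 1))
            ages[id(nd)] = float(np.mean(paths))
    for nd in t.preorder(include_self=False):
        pa = ages[id(nd.parent)]
        if not nd.is_tip() and ages[id(nd)] > pa:
            ages[id(nd)] = pa
        nd.length = max(pa - ages[id(nd)], 0.0)
    return t


def _is_ultrametric(tree: TreeNode, rel_tol: float = 1e-6) -> bool:
    depths = [tree.distance(t) for t in tree.tips()]
    span = max(depths) - min(depths)
    scale = max(max(depths), 1e-12)
    return span / scale < rel_tol


def _gmyc_ll(ti: _TreeIndex, ages: np.ndarray, threshold: float):
    """Mixed Yule/coalescent log-likelihood at a fixed threshold."""
    internal = [i for i in range(ti.n) if not ti.is_tip[i]]
    yule_nodes = [i for i in internal if ages[i] > threshold]
    yule_nodes.sort(key=lambda i: -ages[i])

    # Yule part: forward in time from the root
    n_yule = len(yule_nodes)
    a_yule = 0.0
    log_lineage_terms = 0.0
    lineages = 1
    for idx, v in enumerate(yule_nodes):
        log_lineage_terms += math.log(lineages)
        lineages += len(ti.children[v]) - 1
        t_next = ages[yule_nodes[idx + 1]] if idx + 1 < n_yule else threshold
        a_yule += lineages * (ages[v] - t_next)

    # cluster roots: nodes at or below the threshold whose parent is above
    cluster_roots = []
    for i in range(ti.n):
        if ages[i] <= threshold or ti.is_tip[i]:
            p = ti.parent[i]
            if p is None or ages[p] > threshold:
                cluster_roots.append(i)

    n_coal = 0
    a_coal = 0.0
    log_pair_terms = 0.0
    for r in cluster_roots:
        if ti.is_tip[r]:
            continue
        events = []
        stack = [r]
        while stack:
            v = stack.pop()
            if not ti.is_tip[v]:
                events.append(v)
                stack.extend(ti.children[v])
        events.sort(key=lambda i: ages[i])
        m = len(ti.tips_below[r])  # lineages at present
        prev_age = 0.0
        for v in events:
            a_coal += m * (m - 1) / 2.0 * (ages[v] - prev_age)
            log_pair_terms += math.log(m * (m - 1) / 2.0)
            m -= len(ti.children[v]) - 1
            prev_age = ages[v]
        n_coal += len(events)

    ll = 0.0
    if n_yule:
        if a_yule <= 0:
            return -math.inf, cluster_roots
        lam = n_yule / a_yule
        ll += n_yule * math.log(lam) + log_lineage_terms - lam * a_yule
    if n_coal:
        if a_coal <= 0:
            return -math.inf, cluster_roots
        mu = n_coal / a_coal
        ll += n_coal * math.log(mu) + log_pair_terms - mu * a_coal
    return ll, cluster_roots


def gmyc(
    tree: TreeNode, ultrametricize: bool = True, alpha: float = 0.05
) -> SpeciesPartition:
    """Single-threshold GMYC delimitation.

    Branching before the threshold T is Yule, after T independent
    coalescents; T is optimized over midpoints between observed node ages.
    The null (single-process) model is the better of the all-Yule and
    all-coalescent extremes; a non-significant likelihood-ratio test (2 df)
    returns one entity per tip, flagged "no significant clustering" (the
    GMYC null convention). Cluster supports are likelihood weights summed
    over candidate thresholds containing the cluster.
    """
    t = _prepare_rooted(tree)
    n_tips = t.count(tips=True)
    if n_tips < 3:
        raise ValueError("GMYC requires at least 3 tips")
    if not _is_ultrametric(t):
        if not ultrametricize:
            raise ValueError("tree is not ultrametric (set ultrametricize=True)")
        t = ultrametricize_mpl(t)
    ti = _TreeIndex(t)
    # node ids are postorder, so children precede parents
    ages = np.zeros(ti.n)
    for i in range(ti.n):
        if not ti.is_tip[i]:
            c0 = ti.children[i][0]
            ages[i] = ages[c0] + ti.length[c0]

    internal_ages = sorted({float(ages[i]) for i in range(ti.n) if not ti.is_tip[i]}, reverse=True)
    root_age = internal_ages[0]
    thresholds = [root_age]  # all-coalescent extreme (single cluster)
    for hi, lo in zip(internal_ages, internal_ages[1:]):
        thresholds.append(0.5 * (hi + lo))
    thresholds.append(0.5 * internal_ages[-1])  # all-Yule extreme

    lls, parts = [], []
    for T in thresholds:
        ll, roots = _gmyc_ll(ti, ages, T)
        lls.append(ll)
        parts.append(frozenset(roots))
    lls = np.array(lls)
    null_ll = max(lls[0], lls[-1])
    best_idx = int(np.argmax(lls))
    best_ll = float(lls[best_idx])
    stat = 2.0 * (best_ll - null_ll)
    p = float(chi2.sf(max(stat, 0.0), df=2))

    # likelihood weights over thresholds -> per-cluster support
    w = np.exp(lls - best_ll)
    w = w / w.sum()
    cluster_support: dict[frozenset, float] = {}
    for weight, roots in zip(w, parts):
        for r in roots:
            g = ti.tips_below[r]
            cluster_support[g] = cluster_support.get(g, 0.0) + float(weight)

    extras = {
        "lrt_p": p,
        "null_log_likelihood": float(null_ll),
        "threshold": float(thresholds[best_idx]),
        "root_age": float(root_age),
    }
    if p > alpha:
        extras["no_significant_clustering"] = True
        tips = sorted(ti.tip_name[i] for i in range(ti.n) if ti.is_tip[i])
        assignment = {tip: i + 1 for i, tip in enumerate(tips)}
        return SpeciesPartition(
            assignment=assignment,
            n_species=n_tips,
            support={frozenset([t_]): cluster_support.get(frozenset([t_]), 0.0) for t_ in tips},
            method="gmyc",
            log_likelihood=best_ll,
            extras=extras,
        )
    best_roots = parts[best_idx]
    assignment = _partition_from_roots(ti, best_roots)
    support = {ti.tips_below[r]: cluster_support.get(ti.tips_below[r], 0.0) for r in best_roots}
    return SpeciesPartition(
        assignment=assignment,
        n_species=len(best_roots),
        support=support,
        method="gmyc",
        log_likelihood=best_ll,
        extras=extras,
    )
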