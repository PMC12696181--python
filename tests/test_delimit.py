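"""PTP / bPTP / GMYC species delimitation."""

import itertools
import math

import numpy as np
import pytest
from skbio import TreeNode

from phylophen.delimit import (
    DegenerateTreeError,
    MCMCConfig,
    bptp,
    gmyc,
    ptp_ml,
    ultrametricize_mpl,
)

from conftest import clade_tree


# --- independent brute-force oracle -----------------------------------------

def _all_partitions(tree: TreeNode):
    """Enumerate every valid species-root cover of a rooted tree."""

    def covers(node):
        if node.is_tip():
            return [[node]]
        out = [[node]]
        child_cov = [covers(c) for c in node.children]
        for combo in itertools.product(*child_cov):
            out.append([n for part in combo for n in part])
        return out

    return covers(tree)


def _brute_ll(tree: TreeNode, roots) -> float:
    root_set = set(id(r) for r in roots)
    spec, coal = [], []
    for node in tree.traverse(include_self=False):
        anc_ids = {id(a) for a in node.ancestors()} - {id(tree)}
        below = bool(anc_ids & root_set)
        (coal if below else spec).append(node.length or 0.0)

    def ll(xs):
        n, s = len(xs), sum(xs)
        if n == 0:
            return 0.0
        if s <= 0:
            return -math.inf
        return n * (math.log(n / s) - 1.0)

    return ll(spec) + ll(coal)


class TestPtpML:
    def test_likelihood_matches_enumeration_oracle(self, rng):
        for trial in range(10):
            n = int(rng.integers(4, 8))
            tree = clade_tree(rng, n_clades=2, tips=max(2, n // 2),
                              within=0.01, between=0.5)
            best_oracle = max(
                _brute_ll(tree, roots) for roots in _all_partitions(tree)
            )
            est = ptp_ml(tree, alpha=1.1)  # alpha > 1: never fall back to null
            assert est.log_likelihood == pytest.approx(best_oracle, abs=1e-9)
            assert est.extras["search"] == "exhaustive"

    def test_three_clade_recovery(self, rng):
        hits = 0
        for s in range(20):
            local = np.random.default_rng(500 + s)
            tree = clade_tree(local, n_clades=3, tips=4, within=0.001, between=0.5)
            hits += ptp_ml(tree).n_species == 3
        assert hits >= 18

    def test_star_tree_null_not_rejected(self):
        star = TreeNode(
            children=[TreeNode(name=f"t{i}", length=0.1) for i in range(6)]
        )
        part = ptp_ml(star)
        assert part.n_species == 1
        assert part.extras["lrt_p"] > 0.05
        assert part.extras.get("null_not_rejected")

    def test_two_tips_closed_form(self):
        t = TreeNode(
            children=[TreeNode(name="A", length=0.3), TreeNode(name="B", length=0.7)]
        )
        part = ptp_ml(t, alpha=1.1)
        # both partitions place both edges in one class: equal likelihoods,
        # n(log(n/S) - 1) with n=2, S=1.0
        expected = 2 * (math.log(2 / 1.0) - 1)
        assert part.log_likelihood == pytest.approx(expected)
        assert part.n_species in (1, 2)

    def test_zero_length_tree_degenerate(self):
        t = TreeNode(
            children=[TreeNode(name="A", length=0.0), TreeNode(name="B", length=0.0)]
        )
        with pytest.raises(DegenerateTreeError):
            ptp_ml(t)

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        tree = clade_tree(rng, n_clades=3, tips=4)
        part = ptp_ml(tree)
        tips = {t.name for t in tree.tips()}
        assert set(part.assignment) == tips
        groups = part.groups()
        assert sum(len(g) for g in groups) == len(tips)
        assert all(0 <= s <= 1 for s in part.support.values())


class TestBptp:
    def test_seeded_determinism(self, rng):
        tree = clade_tree(rng, n_clades=3, tips=4)
        cfg = MCMCConfig(iterations=5000, seeds=(7,), thinning=10)
        a = bptp(tree, cfg)
        b = bptp(tree, cfg)
        assert a.assignment == b.assignment
        assert a.support == b.support
        assert a.extras["species_count_posterior"] == b.extras["species_count_posterior"]

    def test_well_separated_recovery_with_high_support(self, rng):
        tree = clade_tree(rng, n_clades=3, tips=4, within=0.001, between=0.5)
        part = bptp(tree, MCMCConfig(iterations=50_000, seeds=(1, 2, 3, 4)))
        posterior = part.extras["species_count_posterior"]
        assert max(posterior, key=posterior.get) == 3
        assert part.n_species == 3
        clade_groups = [g for g in part.support if len(g) == 4]
        assert len(clade_groups) == 3
        assert all(part.support[g] > 0.9 for g in clade_groups)

    def test_single_rate_tree_yields_no_confident_clusters(self, rng):
        # all branches from one exponential: no rate split to find, so the
        # posterior must stay diffuse — no multi-tip species group should
        # reach high support (contrast with the separated-tree test above)
        def grow(n):
            nodes = [TreeNode(name=f"t{i}") for i in range(n)]
            while len(nodes) > 1:
                a, b = nodes.pop(), nodes.pop()
                a.length = float(rng.exponential(0.1))
                b.length = float(rng.exponential(0.1))
                nodes.insert(0, TreeNode(children=[a, b]))
            return nodes[0]

        tree = grow(8)
        part = bptp(tree, MCMCConfig(iterations=50_000, seeds=(1, 2)))
        multi_tip = {
            g: s
            for g, s in part.extras["group_support"].items()
            if 1 < len(g) < 8
        }
        assert max(multi_tip.values(), default=0.0) < 0.8
        # and no single species count hoards the posterior
        posterior = part.extras["species_count_posterior"]
        assert max(posterior.values()) < 0.6

    def test_agreement_with_ml_on_separated_trees(self):
        agree = 0
        for s in range(10):
            local = np.random.default_rng(900 + s)
            tree = clade_tree(local, n_clades=3, tips=3, within=0.001, between=0.5)
            ml = ptp_ml(tree)
            bay = bptp(tree, MCMCConfig(iterations=20_000, seeds=(s,)))
            posterior = bay.extras["species_count_posterior"]
            agree += max(posterior, key=posterior.get) == ml.n_species
        assert agree >= 9


class TestGmyc:
    def test_ultrametricize_idempotent(self, rng):
        tree = clade_tree(rng, n_clades=2, tips=3)
        u1 = ultrametricize_mpl(tree)
        u2 = ultrametricize_mpl(u1)
        d1 = {t.name: u1.distance(t) for t in u1.tips()}
        d2 = {t.name: u2.distance(t) for t in u2.tips()}
        for name in d1:
            assert d1[name] == pytest.approx(d2[name], abs=1e-12)
        # and the result is ultrametric
        depths = list(d1.values())
        assert max(depths) - min(depths) < 1e-9

    def test_four_species_threshold_recovery(self, rng):
        hits = 0
        for s in range(20):
            local = np.random.default_rng(600 + s)
            tree = clade_tree(local, n_clades=4, tips=3, within=0.002, between=1.0)
            hits += gmyc(tree).n_species == 4
        assert hits >= 18

    def test_pure_yule_tree_null_preferred(self, rng):
        # single-rate branching: LRT non-significant, one entity per tip
        def yule(n):
            lineages = [TreeNode(name=f"t{i}") for i in range(n)]
            age = {id(nd): 0.0 for nd in lineages}
            t = 0.0
            while len(lineages) > 1:
                t += float(rng.exponential(1.0 / len(lineages)))
                i, j = sorted(rng.choice(len(lineages), 2, replace=False))
                b, a = lineages.pop(j), lineages.pop(i)
                a.length = t - age[id(a)]
                b.length = t - age[id(b)]
                p = TreeNode(children=[a, b])
                age[id(p)] = t
                lineages.append(p)
            return lineages[0]

        misses = 0
        for _ in range(5):
            tree = yule(10)
            part = gmyc(tree)
            if not part.extras.get("no_significant_clustering"):
                misses += 1
            else:
                assert part.n_species == tree.count(tips=True)
        assert misses <= 1  # LRT has its nominal false-positive rate

    def test_tip_order_permutation_invariance(self, rng):
        tree = clade_tree(rng, n_clades=3, tips=4)
        part1 = gmyc(tree)
        shuffled = tree.copy()
        for node in shuffled.non_tips(include_self=True):
            node.children = list(reversed(node.children))
        part2 = gmyc(shuffled)
        assert part1.n_species == part2.n_species
        assert part1.extras["threshold"] == pytest.approx(part2.extras["threshold"])
        assert set(map(frozenset, part1.groups())) == set(
            map(frozenset, part2.groups())
        )

    def test_fewer_than_three_tips_rejected(self):
        t = TreeNode(
            children=[TreeNode(name="A", length=1.0), TreeNode(name="B", length=1.0)]
        )
        with pytest.raises(ValueError):
            gmyc(t)

    def test_supports_in_unit_interval(self, rng):
        tree = clade_tree(rng, n_clades=3, tips=4)
        part = gmyc(tree)
        assert all(0 <= s <= 1 + 1e-9 for s in part.support.values())


def test_bptp_emits_per_seed_traces(rng):
    tree = clade_tree(rng, n_clades=2, tips=3)
    cfg = MCMCConfig(iterations=2000, seeds=(5, 6), thinning=50)
    part = bptp(tree, cfg)
    traces = part.extras["traces"]
    assert set(traces) == {5, 6}
    for trace in traces.values():
        assert len(trace) > 10
        iters, lls, counts = zip(*trace)
        assert all(1 <= k <= 6 for k in counts)
        assert all(np.isfinite(lls))
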