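"""Synthetic inputs with known truth for every pipeline stage.

Three generators mirror the statistical structure the analysis assumes:

* :func:`evolve_pair` — a random ancestor diverged into two descendants at a
  controlled substitution rate (Poisson, rate d/2 per lineage) and indel
  rate (geometric lengths), with the realized per-base identity recorded.
  This is the ground truth for Mash-distance and ANI parameter recovery.
* :func:`simulate_species_markers` — multi-species marker alignments: a
  sequential species history with exponential inter-species split
  increments, within-species genealogies from the standard neutral
  coalescent (msprime), and Jukes–Cantor mutations. Returns the alignments,
  the true (mutation-scaled) genealogy and the true species partition, the
  inputs for the delimitation and popgen suites.
* :func:`simulate_variant_table` — variant records with a known class and
  indel-length spectrum plus a truth sidecar, for the k-mer insertion screen.

All generators are bitwise reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
from skbio import TreeNode

from .delimit import SpeciesPartition
from .genome import GenomeRecord
from .popgen import MarkerAlignment
from .variants_phenotype import VariantRecord

__all__ = [
    "DivergenceSpec",
    "SpeciesSimSpec",
    "evolve_pair",
    "simulate_species_markers",
    "simulate_variant_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class DivergenceSpec:
    """Parameters for a diverged genome pair."""

    ancestor_length: int = 200_000
    gc: float = 0.485
    substitution_rate: float = 0.05  # expected per-base divergence d between the pair
    indel_rate: float = 0.0  # indel events per base (pair total)
    mean_indel_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate < 0.75):
            raise ValueError("substitution rate must be in [0, 0.75)")
        if self.indel_rate < 0 or self.mean_indel_len <= 0:
            raise ValueError("rates must be non-negative, mean indel length positive")


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    # A=0 C=1 G=2 T=3
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _substitute(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    n_sub = rng.poisson(rate * codes.size)
    n_sub = min(n_sub, codes.size)
    pos = rng.choice(codes.size, size=n_sub, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_sub).astype(np.uint8)) % 4
    return out


def _apply_indels(
    rng: np.random.Generator, codes: np.ndarray, rate: float, mean_len: float, gc: float
) -> np.ndarray:
    if rate <= 0:
        return codes
    n_events = rng.poisson(rate * codes.size)
    if n_events == 0:
        return codes
    positions = np.sort(rng.choice(codes.size, size=n_events, replace=False))
    p_geo = 1.0 / mean_len
    pieces = []
    prev = 0
    for pos in positions:
        pieces.append(codes[prev:pos])
        length = int(rng.geometric(p_geo))
        if rng.random() < 0.5:  # insertion
            pieces.append(_random_codes(rng, length, gc))
            prev = pos
        else:  # deletion
            prev = min(pos + length, codes.size)
    pieces.append(codes[prev:])
    return np.concatenate(pieces)


def evolve_pair(
    spec: DivergenceSpec,
) -> tuple[GenomeRecord, GenomeRecord, dict]:
    """Evolve two descendants from a common random ancestor.

    Each descendant receives Poisson substitutions at rate d/2 and indel
    events at indel_rate/2. The truth record carries the realized per-base
    identity and divergence measured on the substitution stage (before
    indels, where coordinates still correspond).
    """
    rng = np.random.default_rng(spec.seed)
    anc = _random_codes(rng, spec.ancestor_length, spec.gc)
    d1 = _substitute(rng, anc, spec.substitution_rate / 2.0)
    d2 = _substitute(rng, anc, spec.substitution_rate / 2.0)
    realized_div = float(np.mean(d1 != d2))
    g1 = _apply_indels(rng, d1, spec.indel_rate / 2.0, spec.mean_indel_len, spec.gc)
    g2 = _apply_indels(rng, d2, spec.indel_rate / 2.0, spec.mean_indel_len, spec.gc)
    truth = {
        "true_identity": 100.0 * (1.0 - realized_div),
        "true_d": realized_div,
        "requested_d": spec.substitution_rate,
    }
    a = GenomeRecord(id=f"sim_a_seed{spec.seed}", scaffolds=[("chr1", _codes_to_str(g1))])
    b = GenomeRecord(id=f"sim_b_seed{spec.seed}", scaffolds=[("chr1", _codes_to_str(g2))])
    return a, b, truth


# ---------------------------------------------------------------------------
# multi-species coalescent markers


@dataclass
class SpeciesSimSpec:
    """Parameters for multi-species marker simulation.

    ``between_depth`` is the expected inter-species split increment in
    substitutions/site; ``within_theta`` the per-locus coalescent θ (over
    the concatenated marker length).
    """

    n_species: int = 3
    tips_per_species: int = 4
    between_depth: float = 0.05
    within_theta: float = 5.0
    marker_lengths: tuple[int, ...] = (600, 700, 900)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.between_depth <= 0:
            raise ValueError("between_depth must be positive")


_POP_SIZE = 10_000.0  # haploid reference size; mu is scaled to match theta


def _tskit_to_treenode(ts_tree, labels: dict[int, str], scale: float) -> TreeNode:
    def build(u: int) -> TreeNode:
        kids = ts_tree.children(u)
        if not kids:
            return TreeNode(name=labels[u], length=None)
        node = TreeNode(children=[build(c) for c in kids])
        for child_tree, c in zip(node.children, kids):
            child_tree.length = (ts_tree.time(u) - ts_tree.time(c)) * scale
        return node

    return build(ts_tree.root)


def simulate_species_markers(
    spec: SpeciesSimSpec,
) -> tuple[list[MarkerAlignment], TreeNode, SpeciesPartition]:
    """Neutral-coalescent marker alignments for multiple species.

    The species history is a sequential (caterpillar) set of population
    splits with exponential increments of mean ``between_depth``
    (substitution units); within-species genealogies follow the standard
    neutral coalescent; sequences evolve under Jukes–Cantor at finite sites.
    Returns the alignments, the true genealogy of the first marker (branch
    lengths in substitutions/site) and the true species partition.
    """
    rng = np.random.default_rng(spec.seed)
    L_total = int(sum(spec.marker_lengths))
    theta_site = spec.within_theta / L_total
    mu = theta_site / (2.0 * _POP_SIZE)  # per-site per-generation; theta = 2*N*mu

    demography = msprime.Demography()
    for i in range(spec.n_species):
        demography.add_population(name=f"sp{i + 1}", initial_size=_POP_SIZE)
    t = 0.0
    anc_names = []
    if spec.n_species > 1:
        increments = rng.exponential(spec.between_depth / mu, size=spec.n_species - 1)
        prev = "sp1"
        for i in range(1, spec.n_species):
            t += float(increments[i - 1])
            anc = f"anc{i}"
            demography.add_population(name=anc, initial_size=_POP_SIZE)
            demography.add_population_split(
                time=t, derived=[prev, f"sp{i + 1}"], ancestral=anc
            )
            prev = anc
            anc_names.append(anc)

    samples = [
        msprime.SampleSet(spec.tips_per_species, population=f"sp{i + 1}", ploidy=1)
        for i in range(spec.n_species)
    ]

    alignments: list[MarkerAlignment] = []
    true_tree: TreeNode | None = None
    labels: dict[int, str] = {}
    assignment: dict[str, int] = {}
    for m_idx, L in enumerate(spec.marker_lengths):
        seed_anc = int(rng.integers(1, 2**31 - 1))
        seed_mut = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            sequence_length=L,
            ploidy=1,
            random_seed=seed_anc,
        )
        ts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.JC69(), random_seed=seed_mut
        )
        if m_idx == 0:
            counters: dict[int, int] = {}
            for node_id in ts.samples():
                pop = ts.node(node_id).population
                counters[pop] = counters.get(pop, 0) + 1
                label = f"sp{pop + 1}_t{counters[pop]}"
                labels[int(node_id)] = label
                assignment[label] = pop + 1
            true_tree = _tskit_to_treenode(ts.first(), labels, scale=mu)

        sample_ids = list(ts.samples())
        ref = _BASES[rng.integers(0, 4, size=L)].copy()
        seqs = {labels[int(s)]: ref.copy() for s in sample_ids}
        for var in ts.variants():
            pos = int(var.site.position)
            alleles = var.alleles
            for s, g in zip(sample_ids, var.genotypes):
                seqs[labels[int(s)]][pos] = ord(alleles[g])
        alignments.append(
            MarkerAlignment(
                marker_name=f"marker{m_idx + 1}",
                rows={k: v.tobytes().decode("ascii") for k, v in seqs.items()},
            )
        )

    partition = SpeciesPartition(
        assignment=assignment,
        n_species=spec.n_species,
        support={},
        method="truth",
        log_likelihood=float("nan"),
    )
    return alignments, true_tree, partition


# ---------------------------------------------------------------------------
# variant tables


def simulate_variant_table(
    n: int,
    indel_len_distribution=None,
    seed: int = 0,
    p_snv: float = 0.0,
    p_deletion: float = 0.0,
) -> tuple[list[VariantRecord], list[dict]]:
    """Variant records with a known class and indel-size spectrum.

    ``indel_len_distribution`` gives net inserted/deleted lengths: a list
    (cycled in order, so the composition is exact) or a callable
    ``f(rng) -> int``. Remaining probability mass after ``p_snv`` and
    ``p_deletion`` is insertions. Returns the records and a truth sidecar
    (class, net length, ALT length per record).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if indel_len_distribution is None:
        indel_len_distribution = lambda r: int(r.geometric(1 / 10.0))  # noqa: E731
    lengths = None
    if not callable(indel_len_distribution):
        lengths = list(indel_len_distribution)

    records, truth = [], []
    indel_i = 0
    for i in range(n):
        u = rng.random()
        pos = int(rng.integers(1, 10_000_000))
        chrom = f"chr{int(rng.integers(1, 8))}"
        ref_base = "ACGT"[int(rng.integers(0, 4))]
        if u < p_snv:
            alt = "ACGT"[("ACGT".index(ref_base) + int(rng.integers(1, 4))) % 4]
            rec = VariantRecord(chrom=chrom, pos=pos, ref=ref_base, alt=alt)
            truth.append({"class": "snv", "net_length": 0, "alt_length": 1})
        else:
            if lengths is not None:
                net = int(lengths[indel_i % len(lengths)])
                indel_i += 1
            else:
                net = int(indel_len_distribution(rng))
            net = max(net, 1)
            segment = "".join(
                "ACGT"[b] for b in rng.integers(0, 4, size=net)
            )
            if u < p_snv + p_deletion:
                rec = VariantRecord(
                    chrom=chrom, pos=pos, ref=ref_base + segment, alt=ref_base
                )
                truth.append(
                    {"class": "deletion", "net_length": net, "alt_length": 1}
                )
            else:
                alt = ref_base + segment
                rec = VariantRecord(chrom=chrom, pos=pos, ref=ref_base, alt=alt)
                truth.append(
                    {"class": "insertion", "net_length": net, "alt_length": len(alt)}
                )
        records.append(rec)
    return records, truth
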