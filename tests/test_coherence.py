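"""ANI, AAI, POCP and the coherence verdict."""

import numpy as np
import pytest

from phylophen.coherence import (
    CoherencePanel,
    ProteomeRecord,
    UndefinedIndexError,
    aai,
    ani,
    coherence_verdict,
    panel_to_tsv,
    pocp,
    six_frame_orfs,
)
from phylophen.synthetic import DivergenceSpec, evolve_pair

from conftest import random_genome

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length=150):
    return "M" + "".join(rng.choice(list(AA), size=length - 1))


def _mutate_every_10th(rng, seq):
    out = list(seq)
    for j in range(0, len(out), 10):
        choices = [c for c in AA if c != out[j]]
        out[j] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


class TestANI:
    def test_self_identity(self, rng):
        g = random_genome(rng, 20_000)
        assert ani(g, g) == pytest.approx(100.0)

    def test_symmetry(self):
        a, b, _ = evolve_pair(
            DivergenceSpec(ancestor_length=50_000, substitution_rate=0.05, seed=11)
        )
        assert ani(a, b) == pytest.approx(ani(b, a), abs=1e-9)

    def test_parameter_recovery_at_5_percent(self):
        a, b, truth = evolve_pair(
            DivergenceSpec(ancestor_length=200_000, substitution_rate=0.05, seed=12)
        )
        assert ani(a, b) == pytest.approx(95.0, abs=0.5)
        assert ani(a, b) == pytest.approx(truth["true_identity"], abs=0.2)

    def test_unrelated_genomes_undefined(self, rng):
        # no shared seeds above the identity floor -> explicit signal
        a = random_genome(rng, 5_000, gid="a")
        b = random_genome(rng, 5_000, gid="b", gc=0.2)
        with pytest.raises((UndefinedIndexError, ValueError)):
            ani(a, b)

    def test_too_short_genome_rejected(self, rng):
        a = random_genome(rng, 500)
        with pytest.raises(ValueError):
            ani(a, a)


class TestAAI:
    def test_identical_proteomes(self, rng):
        prots = [(f"p{i}", _random_protein(rng)) for i in range(4)]
        A = ProteomeRecord(id="A", proteins=prots)
        assert aai(A, A) == pytest.approx(100.0)

    def test_every_10th_residue_substituted(self, rng):
        prots = [(f"p{i}", _random_protein(rng, 200)) for i in range(4)]
        A = ProteomeRecord(id="A", proteins=prots)
        B = ProteomeRecord(
            id="B", proteins=[(n, _mutate_every_10th(rng, s)) for n, s in prots]
        )
        assert aai(A, B) == pytest.approx(90.0, abs=1.0)

    def test_unrelated_pair_excluded_from_mean(self, rng):
        shared = [(f"p{i}", _random_protein(rng, 180)) for i in range(2)]
        a_only = ("pa", _random_protein(rng, 60))
        b_only = ("pb", "M" + "W" * 59)  # unalignable junk vs random
        A = ProteomeRecord(id="A", proteins=shared + [a_only])
        B = ProteomeRecord(id="B", proteins=shared + [b_only])
        # the unrelated pair fails the 30%/70% filters; mean over the 2 shared
        assert aai(A, B) == pytest.approx(100.0)

    def test_empty_proteome_rejected(self, rng):
        A = ProteomeRecord(id="A", proteins=[("p", _random_protein(rng))])
        with pytest.raises(ValueError):
            aai(A, ProteomeRecord(id="B", proteins=[]))


class TestPOCP:
    def test_identical_proteomes_of_size_10(self, rng):
        prots = [(f"p{i}", _random_protein(rng, 120)) for i in range(10)]
        A = ProteomeRecord(id="A", proteins=prots)
        assert pocp(A, A) == pytest.approx(100.0)

    def test_toy_formula_4_of_7(self, rng):
        # A: 2 shared + 1 private; B: 2 shared + 2 private
        shared = [(f"s{i}", _random_protein(rng, 150)) for i in range(2)]
        A = ProteomeRecord(id="A", proteins=shared + [("a1", "M" + "W" * 80)])
        B = ProteomeRecord(
            id="B",
            proteins=shared + [("b1", "M" + "H" * 80), ("b2", "M" + "Y" * 80)],
        )
        # C1 = 2 of 3, C2 = 2 of 4 -> 100 * 4 / 7
        assert pocp(A, B) == pytest.approx(100.0 * 4 / 7, abs=1e-9)

    def test_brute_force_oracle_small_proteomes(self, rng):
        # the conserved set must match a direct all-vs-all check with the
        # same alignment backend but independently-written filter logic
        from phylophen.coherence import _aligner, _evalue, _local_alignment_stats

        protsA = [(f"pa{i}", _random_protein(rng, 100)) for i in range(5)]
        protsB = [
            (f"pb{i}", _mutate_every_10th(rng, s))
            for i, (_, s) in enumerate(protsA[:3])
        ]
        protsB += [(f"pb{i + 3}", _random_protein(rng, 100)) for i in range(2)]
        A, B = ProteomeRecord(id="A", proteins=protsA), ProteomeRecord(id="B", proteins=protsB)
        al = _aligner()

        def conserved(ps, qs):
            total = sum(len(s) for _, s in qs)
            n = 0
            for _, pa in ps:
                for _, pb in qs:
                    score, ident, _, span, _ = _local_alignment_stats(al, pa, pb)
                    if (
                        _evalue(score, len(pa), total) < 1e-5
                        and ident > 0.40
                        and span / len(pa) > 0.50
                    ):
                        n += 1
                        break
            return n

        expected = 100.0 * (conserved(protsA, protsB) + conserved(protsB, protsA)) / 10
        assert pocp(A, B) == pytest.approx(expected)


class TestVerdict:
    @pytest.mark.parametrize(
        "ani_value,expected",
        [(94.43, "distinct"), (100.0, "conspecific"), (96.0, "borderline"),
         (95.0, "borderline"), (98.0, "conspecific")],
    )
    def test_three_way_rule(self, ani_value, expected):
        panel = CoherencePanel(query_id="q", ref_id="r", d=0.038, ani=ani_value)
        assert coherence_verdict(panel) == expected

    def test_coherence_flag_is_context_not_classification(self):
        panel = CoherencePanel(query_id="q", ref_id="r", d=0.038, ani=94.43)
        coherence_verdict(panel)
        assert panel.metadata["high_genomic_coherence"] is True
        assert panel.verdict == "distinct"  # despite D <= 0.05

    def test_missing_ani_rejected(self):
        with pytest.raises(ValueError):
            coherence_verdict(CoherencePanel(query_id="q", ref_id="r", d=0.01))


def test_indices_bounded_and_self_perfect(rng):
    for i in range(5):
        g = random_genome(rng, 15_000, gid=f"g{i}")
        assert ani(g, g) == 100.0
        prots = [(f"p{j}", _random_protein(rng, 80)) for j in range(3)]
        P = ProteomeRecord(id=f"P{i}", proteins=prots)
        assert aai(P, P) == 100.0
        assert pocp(P, P) == 100.0


def test_panel_tsv_columns():
    row = CoherencePanel(query_id="q", ref_id="GCA_1", d=0.038, ani=94.43,
                         aai=94.62, pocp=95.10, hexamer_similarity=81.97,
                         country="Italy")
    coherence_verdict(row)
    text = panel_to_tsv([row])
    header = text.splitlines()[0].split("\t")
    assert header[:8] == ["Strain", "Assembly accession", "D", "ANI", "AAI",
                          "POCP", "Hexamer frequency", "Country of origin"]
    assert "94.43" in text and "distinct" in text


def test_six_frame_orf_extractor(rng):
    # a genome that embeds one long ORF should yield at least that protein
    core = "ATG" + "GCT" * 150 + "TAA"
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 500)) + core
    from phylophen.genome import GenomeRecord

    g = GenomeRecord(id="g", scaffolds=[("s", seq)])
    prot = six_frame_orfs(g, min_aa=100)
    assert any("A" * 140 in p for _, p in prot.proteins)
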