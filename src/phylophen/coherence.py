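"""Overall genome relatedness indices: ANI, AAI, POCP and the species verdict.

ANI follows the OrthoANI-style scheme: both genomes are cut into
non-overlapping 1,020 bp fragments, each fragment is mapped to the other
genome's fragments by k-mer seeding and aligned (edit distance); only
reciprocal best-hit fragment pairs above an identity floor contribute, and
ANI is their mean percent identity. AAI is the mean identity over reciprocal
best-hit protein pairs (BLOSUM62 local alignment, >30% identity, >70%
alignable fraction of the shorter protein). POCP counts, in each direction,
proteins with a hit at E < 1e-5, identity > 40% and alignable region > 50%
of the query length: POCP = 100 * (C1 + C2) / (T1 + T2).

The verdict applies the conventional ~95% ANI species boundary, with a
conspecific call only at >= 98% since distinct fungal species have been
reported up to ~98% ANI; a Mash D <= 0.05 "high genomic coherence" flag is
reported as context, never as a classification on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from ._kmers import canonical_kmer_codes
from .genome import GenomeRecord

__all__ = [
    "ProteomeRecord",
    "CoherencePanel",
    "UndefinedIndexError",
    "ani",
    "aai",
    "pocp",
    "coherence_verdict",
    "six_frame_orfs",
    "read_proteome",
    "panel_to_tsv",
]

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*BZJUO")


class UndefinedIndexError(ValueError):
    """Raised when an index has no supporting fragment/protein pairs."""


@dataclass
class ProteomeRecord:
    """A named set of protein sequences (20-letter alphabet plus X)."""

    id: str
    proteins: list[tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.proteins]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate protein names in proteome {self.id!r}")
        for name, seq in self.proteins:
            bad = set(seq.upper()) - AMINO_ALPHABET
            if bad:
                raise ValueError(f"non-amino characters {bad} in protein {name!r}")


@dataclass
class CoherencePanel:
    """One query-vs-reference row of the genome relatedness panel."""

    query_id: str
    ref_id: str
    d: float
    ani: Optional[float] = None
    aai: Optional[float] = None
    pocp: Optional[float] = None
    hexamer_similarity: Optional[float] = None
    country: str = ""
    verdict: str = ""
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ANI


def _fragments(g: GenomeRecord, frag_len: int) -> list[str]:
    frags = []
    for _, seq in g.scaffolds:
        up = seq.upper()
        for i in range(0, len(up) - frag_len + 1, frag_len):
            frags.append(up[i : i + frag_len])
    return frags


_SEED_K = 15


def _seed_index(frags: list[str], step: int) -> dict[int, list[int]]:
    index: dict[int, list[int]] = {}
    for fid, frag in enumerate(frags):
        codes = canonical_kmer_codes(frag, _SEED_K)[::step]
        for c in np.unique(codes):
            index.setdefault(int(c), []).append(fid)
    return index


def _best_hits(
    qfrags: list[str],
    tfrags: list[str],
    tindex: dict[int, list[int]],
    step: int,
    n_candidates: int = 2,
) -> dict[int, tuple[int, float]]:
    """Best target fragment (by alignment identity) per query fragment."""
    hits: dict[int, tuple[int, float]] = {}
    for qid, frag in enumerate(qfrags):
        codes = np.unique(canonical_kmer_codes(frag, _SEED_K)[::step])
        votes: dict[int, int] = {}
        for c in codes:
            for fid in tindex.get(int(c), ()):
                votes[fid] = votes.get(fid, 0) + 1
        if not votes:
            continue
        cands = sorted(votes, key=lambda f: (-votes[f], f))[:n_candidates]
        best: tuple[int, float] | None = None
        rc = str(Seq(frag).reverse_complement())
        for fid in cands:
            target = tfrags[fid]
            ident = 0.0
            for query in (frag, rc):
                res = edlib.align(query, target, mode="NW", task="distance")
                span = max(len(query), len(target))
                ident = max(ident, 1.0 - res["editDistance"] / span)
            if best is None or ident > best[1] or (ident == best[1] and fid < best[0]):
                best = (fid, ident)
        if best is not None:
            hits[qid] = best
    return hits


def ani(
    a: GenomeRecord,
    b: GenomeRecord,
    frag_len: int = 1020,
    min_frag_identity: float = 0.3,
    seed_step: int = 4,
) -> float:
    """Average nucleotide identity (%) over reciprocal best-hit fragments.

    Symmetric by construction (the reciprocal best-hit set is); self-ANI is
    exactly 100. Raises :class:`UndefinedIndexError` when no fragment pair
    passes the identity floor.
    """
    fa, fb = _fragments(a, frag_len), _fragments(b, frag_len)
    if not fa or not fb:
        raise ValueError(f"both genomes must be >= {frag_len} bp")
    ia, ib = _seed_index(fa, seed_step), _seed_index(fb, seed_step)
    a2b = _best_hits(fa, fb, ib, seed_step)
    b2a = _best_hits(fb, fa, ia, seed_step)
    idents = []
    for qid, (tid, ident) in a2b.items():
        back = b2a.get(tid)
        if back is not None and back[0] == qid and ident >= min_frag_identity:
            idents.append(ident)
    if not idents:
        raise UndefinedIndexError(
            f"no reciprocal fragment pairs above identity {min_frag_identity} "
            f"between {a.id!r} and {b.id!r}"
        )
    return 100.0 * float(np.mean(idents))


# ---------------------------------------------------------------------------
# AAI / POCP

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# Karlin-Altschul parameters for gapped BLOSUM62 (open 11, extend 1)
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = _BLOSUM62
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    return al


def _local_alignment_stats(al: PairwiseAligner, qa: str, qb: str):
    """(score, identity fraction, aligned columns, span on each sequence)."""
    alignments = al.align(qa.upper().replace("*", "X"), qb.upper().replace("*", "X"))
    if len(alignments) == 0:
        return 0.0, 0.0, 0, 0, 0
    best = alignments[0]
    blocks_a, blocks_b = best.aligned
    matches = aligned = 0
    sa, sb = str(best.sequences[0]), str(best.sequences[1])
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        aligned += a1 - a0
        matches += sum(1 for x, y in zip(sa[a0:a1], sb[b0:b1]) if x == y)
    span_a = int(blocks_a[-1][1] - blocks_a[0][0]) if len(blocks_a) else 0
    span_b = int(blocks_b[-1][1] - blocks_b[0][0]) if len(blocks_b) else 0
    ident = matches / aligned if aligned else 0.0
    return float(best.score), ident, aligned, span_a, span_b


def _evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def aai(
    a: ProteomeRecord,
    b: ProteomeRecord,
    min_identity: float = 0.30,
    min_aligned_fraction: float = 0.70,
) -> float:
    """Average amino-acid identity (%) over reciprocal best-hit proteins.

    Hits must exceed ``min_identity`` and align over more than
    ``min_aligned_fraction`` of the shorter protein.
    """
    if not a.proteins or not b.proteins:
        raise ValueError("both proteomes must be non-empty")
    al = _aligner()

    def best_hits(ps, qs):
        hits = {}
        for i, (_, pa) in enumerate(ps):
            best = None
            for j, (_, pb) in enumerate(qs):
                score, ident, aligned, _, _ = _local_alignment_stats(al, pa, pb)
                if best is None or score > best[1]:
                    best = (j, score, ident, aligned, len(pb))
            if best is not None:
                hits[i] = best
        return hits

    a2b = best_hits(a.proteins, b.proteins)
    b2a = best_hits(b.proteins, a.proteins)
    idents = []
    for i, (j, _, ident, aligned, _) in a2b.items():
        if b2a.get(j, (None,))[0] != i:
            continue
        shorter = min(len(a.proteins[i][1]), len(b.proteins[j][1]))
        if ident > min_identity and aligned / shorter > min_aligned_fraction:
            idents.append(ident)
    if not idents:
        raise UndefinedIndexError(
            f"no reciprocal best-hit protein pairs between {a.id!r} and {b.id!r}"
        )
    return 100.0 * float(np.mean(idents))


def pocp(
    a: ProteomeRecord,
    b: ProteomeRecord,
    max_evalue: float = 1e-5,
    min_identity: float = 0.40,
    min_query_coverage: float = 0.50,
) -> float:
    """Percentage of conserved proteins: 100 * (C1 + C2) / (T1 + T2).

    A protein is conserved in the other proteome when some hit has
    E-value < ``max_evalue`` (Karlin-Altschul, BLOSUM62), identity >
    ``min_identity`` and an alignable region covering more than
    ``min_query_coverage`` of the query length.
    """
    if not a.proteins or not b.proteins:
        raise ValueError("both proteomes must be non-empty")
    al = _aligner()

    def conserved_count(ps, qs):
        db_len = sum(len(s) for _, s in qs)
        count = 0
        for _, pa in ps:
            for _, pb in qs:
                score, ident, _, span_a, _ = _local_alignment_stats(al, pa, pb)
                if (
                    _evalue(score, len(pa), db_len) < max_evalue
                    and ident > min_identity
                    and span_a / len(pa) > min_query_coverage
                ):
                    count += 1
                    break
        return count

    c1 = conserved_count(a.proteins, b.proteins)
    c2 = conserved_count(b.proteins, a.proteins)
    return 100.0 * (c1 + c2) / (len(a.proteins) + len(b.proteins))


def coherence_verdict(
    panel: CoherencePanel, ani_threshold: float = 95.0, d_threshold: float = 0.05
) -> str:
    """Three-way species verdict from the ANI value of a panel row.

    distinct below ``ani_threshold``; conspecific at >= 98%; borderline in
    between. The D <= ``d_threshold`` coherence flag is stored as context in
    ``panel.metadata`` only.
    """
    if panel.ani is None:
        raise ValueError("panel must have ANI populated")
    panel.metadata["high_genomic_coherence"] = panel.d <= d_threshold
    if panel.ani < ani_threshold:
        verdict = "distinct"
    elif panel.ani >= 98.0:
        verdict = "conspecific"
    else:
        verdict = "borderline"
    panel.verdict = verdict
    return verdict


# ---------------------------------------------------------------------------
# convenience I/O

PANEL_COLUMNS = (
    "Strain",
    "Assembly accession",
    "D",
    "ANI",
    "AAI",
    "POCP",
    "Hexamer frequency",
    "Country of origin",
)


def panel_to_tsv(rows: list[CoherencePanel], path: str | Path | None = None) -> str:
    def fmt(x, nd):
        return "-" if x is None else f"{x:.{nd}f}"

    lines = ["\t".join(PANEL_COLUMNS + ("Verdict",))]
    for r in rows:
        lines.append(
            "\t".join(
                [
                    r.metadata.get("strain", r.ref_id),
                    r.ref_id,
                    f"{r.d:.3f}",
                    fmt(r.ani, 2),
                    fmt(r.aai, 2),
                    fmt(r.pocp, 2),
                    fmt(r.hexamer_similarity, 2),
                    r.country or "-",
                    r.verdict or "-",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_proteome(path: str | Path, record_id: str | None = None) -> ProteomeRecord:
    path = Path(path)
    entries = list(SeqIO.parse(str(path), "fasta"))
    if not entries:
        raise ValueError(f"no FASTA records in {path}")
    return ProteomeRecord(
        id=record_id or path.stem,
        proteins=[(e.id, str(e.seq)) for e in entries],
    )


def six_frame_orfs(g: GenomeRecord, min_aa: int = 100) -> ProteomeRecord:
    """Trivial proteome surrogate: longest ORF per scaffold per frame.

    A convenience when no gene predictions are available; it is not a gene
    predictor and under-samples real proteomes.
    """
    proteins = []
    for name, seq in g.scaffolds:
        s = Seq(seq.upper().replace("N", "A"))
        for strand, ss in (("+", s), ("-", s.reverse_complement())):
            for frame in range(3):
                sub = ss[frame : frame + 3 * ((len(ss) - frame) // 3)]
                if len(sub) < 3:
                    continue
                aa = str(sub.translate())
                for k, chunk in enumerate(aa.split("*")):
                    start = chunk.find("M")
                    if start >= 0 and len(chunk) - start >= min_aa:
                        proteins.append(
                            (f"{name}|{strand}{frame}|orf{k}", chunk[start:])
                        )
    return ProteomeRecord(id=f"{g.id}_orfs", proteins=proteins)
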