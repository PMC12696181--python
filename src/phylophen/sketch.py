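"""Bottom-s MinHash genome sketches and the Mash distance.

The Mash distance approximates per-base mutational divergence from the
Jaccard similarity of canonical k-mer sets, estimated on fixed-size bottom
sketches: ``D = -(1/k) * ln(2J / (1+J))``. A distance D <= 0.05 is the
conventional flag for high genomic coherence; the 20 nearest reference
genomes by D form the comparison panel for the downstream coherence metrics.

Jaccard is estimated with the merged-union bottom-s estimator: with
``X`` the s smallest distinct hashes of the union of two sketches,
``J = |X ∩ A ∩ B| / |X|``, which is unbiased for fixed sketch size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kmers import canonical_kmer_codes, hash64
from .genome import GenomeRecord

__all__ = [
    "Sketch",
    "EmptySketchError",
    "make_sketch",
    "mash_distance",
    "select_neighbors",
    "write_sketches",
    "read_sketches",
]

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_SEED = 42


class EmptySketchError(ValueError):
    """Raised when a genome yields no valid k-mer."""


@dataclass
class Sketch:
    """A bottom-s MinHash signature of a genome's canonical k-mer set."""

    genome_id: str
    k: int
    s: int
    seed: int
    hashes: np.ndarray = field(repr=False)  # sorted, strictly increasing uint64

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > 1 and not np.all(np.diff(self.hashes.astype(object)) > 0):
            raise ValueError("sketch hashes must be strictly increasing")
        if self.hashes.size > self.s:
            raise ValueError("sketch holds more than s hashes")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def make_sketch(
    g: GenomeRecord,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    seed: int = DEFAULT_SEED,
) -> Sketch:
    """Sketch a genome: s smallest distinct 64-bit hashes of canonical k-mers.

    Every scaffold of length >= k contributes; windows containing non-ACGT
    characters are skipped. Deterministic for a fixed seed.
    """
    parts = []
    for _, seq in g.scaffolds:
        codes = canonical_kmer_codes(seq, k)
        if codes.size:
            parts.append(hash64(codes, seed))
    if not parts:
        raise EmptySketchError(f"no valid {k}-mer in genome {g.id!r}")
    hashes = np.unique(np.concatenate(parts))  # sorted distinct
    return Sketch(genome_id=g.id, k=k, s=s, seed=seed, hashes=hashes[:s])


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.k != b.k or a.seed != b.seed:
        raise ValueError(
            f"incompatible sketches: k={a.k}/{b.k}, seed={a.seed}/{b.seed}"
        )


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Merged-union bottom-s Jaccard estimate."""
    _check_compatible(a, b)
    s = min(a.s, b.s)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if union.size == 0:
        return 0.0
    shared = np.intersect1d(
        np.intersect1d(union, a.hashes, assume_unique=True),
        b.hashes,
        assume_unique=True,
    )
    return shared.size / union.size


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance D = -(1/k) ln(2J/(1+J)); capped at 1.0 when J = 0.

    Symmetric; D(a, a) = 0.
    """
    j = jaccard_estimate(a, b)
    if j <= 0.0:
        return 1.0  # closed form diverges; documented cap
    if j >= 1.0:
        return 0.0
    return -math.log(2.0 * j / (1.0 + j)) / a.k


def select_neighbors(
    query: Sketch, refs: list[Sketch], n: int = 20
) -> list[tuple[str, float]]:
    """The n nearest reference genomes by Mash distance.

    Ascending by D, ties broken by genome id; returns min(n, len(refs)) rows.
    """
    rows = [(r.genome_id, mash_distance(query, r)) for r in refs]
    rows.sort(key=lambda t: (t[1], t[0]))
    return rows[:n]


def write_sketches(sketches: list[Sketch], path: str | Path) -> None:
    """Serialize sketches as JSON lines (hashes hex-encoded)."""
    with open(path, "w") as fh:
        for sk in sketches:
            fh.write(
                json.dumps(
                    {
                        "genome_id": sk.genome_id,
                        "k": sk.k,
                        "s": sk.s,
                        "seed": sk.seed,
                        "hashes": [format(int(h), "016x") for h in sk.hashes],
                    }
                )
                + "\n"
            )


def read_sketches(path: str | Path) -> list[Sketch]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                Sketch(
                    genome_id=obj["genome_id"],
                    k=obj["k"],
                    s=obj["s"],
                    seed=obj["seed"],
                    hashes=np.array(
                        [int(h, 16) for h in obj["hashes"]], dtype=np.uint64
                    ),
                )
            )
    return out
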