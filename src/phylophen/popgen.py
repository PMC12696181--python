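"""Genetic-diversity summaries of a (concatenated) marker alignment.

Computes the standard neutrality-test panel on an aligned set of sequences:
nucleotide diversity π (mean pairwise difference per analyzed site), the
number of segregating sites S, parsimony-informative sites, Tajima's D,
haplotype count and haplotype diversity Hd. Tajima's D follows the 1989
constants:

    a1 = Σ 1/i,  a2 = Σ 1/i²   (i = 1..n-1)
    b1 = (n+1)/(3(n-1)),       b2 = 2(n²+n+3)/(9n(n-1))
    c1 = b1 - 1/a1,            c2 = b2 - (n+2)/(a1 n) + a2/a1²
    e1 = c1/a1,                e2 = c2/(a2 + a1²)
    D  = (π̂ - S/a1) / sqrt(e1 S + e2 S (S-1))

with π̂ the mean pairwise difference count (not per site). Under the default
``complete_columns`` policy, any column containing a gap or IUPAC ambiguity
is excluded from the analyzed length L (listwise deletion, the convention of
the common haplotype-network tools); ``pairwise`` deletion is available for
π only. Hd uses the small-sample correction n/(n-1) · (1 - Σ p_i²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO

__all__ = [
    "MarkerAlignment",
    "PopgenSummary",
    "concatenate",
    "popgen_summary",
    "read_alignment",
    "tajima_constants",
]

_VALID = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class MarkerAlignment:
    """A named alignment: strain label -> aligned sequence (gap '-')."""

    marker_name: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"rows of marker {self.marker_name!r} have unequal lengths {lengths}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n(self) -> int:
        return len(self.rows)


@dataclass
class PopgenSummary:
    """Diversity statistics of one alignment."""

    n: int
    L: int
    S: int
    pi_per_site: float
    parsimony_informative: int
    tajimas_d: Optional[float]
    n_haplotypes: int
    hd: float
    pi_hat: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_tsv(self) -> str:
        rows = [
            ("n", self.n),
            ("analyzed_sites", self.L),
            ("segregating_sites", self.S),
            ("pi_per_site", f"{self.pi_per_site:.6g}"),
            ("parsimony_informative", self.parsimony_informative),
            ("tajimas_d", "NA" if self.tajimas_d is None else f"{self.tajimas_d:.4f}"),
            ("n_haplotypes", self.n_haplotypes),
            ("haplotype_diversity", f"{self.hd:.4f}"),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def read_alignment(path: str | Path, marker_name: str | None = None) -> MarkerAlignment:
    """Read an aligned multi-FASTA into a :class:`MarkerAlignment`."""
    path = Path(path)
    rows = {}
    for e in SeqIO.parse(str(path), "fasta"):
        if e.id in rows:
            raise ValueError(f"duplicate label {e.id!r} in {path}")
        rows[e.id] = str(e.seq)
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return MarkerAlignment(marker_name=marker_name or path.stem, rows=rows)


def concatenate(
    markers: list[MarkerAlignment], missing_policy: str = "strict"
) -> MarkerAlignment:
    """Row-wise concatenation of marker alignments in the given order.

    With ``missing_policy='strict'`` every strain must be present in every
    marker; with ``'gap-fill'`` absent strains are padded with gaps.
    """
    if not markers:
        raise ValueError("no markers given")
    if missing_policy not in ("strict", "gap-fill"):
        raise ValueError("missing_policy must be 'strict' or 'gap-fill'")
    all_labels: list[str] = []
    for m in markers:
        for label in m.rows:
            if label not in all_labels:
                all_labels.append(label)
    rows = {}
    for label in all_labels:
        parts = []
        for m in markers:
            if label in m.rows:
                parts.append(m.rows[label])
            elif missing_policy == "strict":
                raise ValueError(
                    f"strain {label!r} missing from marker {m.marker_name!r}"
                )
            else:
                parts.append("-" * m.length)
        rows[label] = "".join(parts)
    name = "+".join(m.marker_name for m in markers)
    return MarkerAlignment(marker_name=name, rows=rows)


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's D for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a2 + a1**2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _tajima_d_p_beta(d: float, n: int) -> float:
    """Two-sided p-value for Tajima's D from the beta approximation.

    Uses the bounded-D beta density (the approximation proposed alongside
    the statistic itself); approximate by construction and flagged as such
    where reported — not a substitute for coalescent simulation.
    """
    from scipy.stats import beta as beta_dist

    k = tajima_constants(n)
    sqrt_e2 = np.sqrt(k["e2"])
    d_min = (2.0 / n - 1.0 / k["a1"]) / sqrt_e2
    d_max = ((n + 1) / (2.0 * n) - 1.0 / k["a1"]) / sqrt_e2
    span = d_max - d_min
    alpha = -(1.0 + d_min * d_max) * d_max / span
    bshape = (1.0 + d_min * d_max) * d_min / span
    if alpha <= 0 or bshape <= 0 or not (d_min < d < d_max):
        return float("nan")
    x = (d - d_min) / span  # density in x is Beta(bshape, alpha)
    cdf = float(beta_dist.cdf(x, bshape, alpha))
    return float(2.0 * min(cdf, 1.0 - cdf))


def popgen_summary(
    a: MarkerAlignment,
    site_policy: str = "complete_columns",
    exclude: tuple[str, ...] = (),
) -> PopgenSummary:
    """Compute π, S, parsimony-informative sites, Tajima's D, haplotypes, Hd.

    Sites with any gap or ambiguity are excluded under ``complete_columns``
    (they are also excluded from haplotype strings); ``pairwise`` deletion
    computes π over pairwise-complete sites but keeps the listwise S/D.
    Tajima's D is undefined (None) when S = 0 or n < 4; when defined, an
    approximate two-sided p-value (beta approximation) is reported in
    ``extras`` flagged as approximate. ``exclude`` drops rows (e.g. an
    outgroup) before any computation.
    """
    if site_policy not in ("complete_columns", "pairwise"):
        raise ValueError("site_policy must be 'complete_columns' or 'pairwise'")
    labels = sorted(set(a.rows) - set(exclude))
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    mat = np.frombuffer(
        "".join(a.rows[l].upper() for l in labels).encode("ascii"), dtype=np.uint8
    ).reshape(n, a.length)
    valid = np.isin(mat, _VALID)
    complete = valid.all(axis=0)
    cols = mat[:, complete]
    L = int(cols.shape[1])

    # per-column allele counts -> segregating / informative / pairwise diffs
    S = 0
    pi_hat_num = 0.0
    informative = 0
    npairs = n * (n - 1) / 2.0
    for c in range(L):
        _, counts = np.unique(cols[:, c], return_counts=True)
        if counts.size > 1:
            S += 1
            pi_hat_num += (n * n - np.sum(counts**2)) / 2.0
            if np.sum(counts >= 2) >= 2:
                informative += 1
    pi_hat = pi_hat_num / npairs

    if site_policy == "pairwise":
        diffs = []
        for i in range(n):
            for j in range(i + 1, n):
                ok = valid[i] & valid[j]
                if ok.any():
                    diffs.append(np.mean(mat[i, ok] != mat[j, ok]))
        pi_per_site = float(np.mean(diffs)) if diffs else 0.0
    else:
        pi_per_site = pi_hat / L if L else 0.0

    tajd = None
    tajd_p = None
    if n >= 4 and S > 0:
        k = tajima_constants(n)
        var = k["e1"] * S + k["e2"] * S * (S - 1)
        tajd = float((pi_hat - S / k["a1"]) / np.sqrt(var))
        tajd_p = _tajima_d_p_beta(tajd, n)

    haplotypes = ["".join(chr(b) for b in cols[i]) for i in range(n)]
    uniq, counts = np.unique(haplotypes, return_counts=True)
    p = counts / n
    hd = float(np.clip(n / (n - 1) * (1.0 - np.sum(p**2)), 0.0, 1.0))

    return PopgenSummary(
        n=n,
        L=L,
        S=S,
        pi_per_site=pi_per_site,
        parsimony_informative=informative,
        tajimas_d=tajd,
        n_haplotypes=int(uniq.size),
        hd=hd,
        pi_hat=float(pi_hat),
        extras={
            "site_policy": site_policy,
            "excluded": list(exclude),
            "tajimas_d_p_beta_approx": tajd_p,  # approximate, see docstring
        },
    )
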