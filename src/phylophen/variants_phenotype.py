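"""Variant classification, the k-mer insertion screen, and phenotype statistics.

Variant records follow the VCF convention (1-based POS, REF/ALT strings).
The insertion screen keeps insertion-class records whose ALT reaches the
assembly/variant-calling k-mer size (k = 31 by default): such insertions
introduce k-mers absent from the reference and are the structurally
informative events. Two length readings are supported because "insertion
larger than k" is ambiguous between the full ALT string (REF base included,
the reading that matches published screens) and the net inserted length
(ALT minus REF).

Phenotype statistics: colony growth rate as the OLS slope of diameter vs
time; PIRG (percentage inhibition of radial growth) in dual-culture
antagonism assays, PIRG = (R1 - R2)/R1 × 100 with R1 the pathogen radius
alone and R2 with the antagonist; and a one-way ANOVA + Tukey HSD
comparison of PIRG across antagonists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, linregress
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "VariantRecord",
    "DualCultureMeasure",
    "classify_variant",
    "filter_insertions",
    "read_variant_table",
    "bundled_insertion_table",
    "growth_rate",
    "pirg",
    "compare_pirg_groups",
]

_IUPAC = set("ACGTURYSWKMBDHVN")


@dataclass
class VariantRecord:
    """A minimal variant record (CHROM, POS, REF, ALT, INFO)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        for name, seq in (("ref", self.ref), ("alt", self.alt)):
            bad = set(seq.upper()) - _IUPAC
            if bad:
                raise ValueError(f"non-nucleotide characters {bad} in {name}")


def classify_variant(v: VariantRecord) -> str:
    """snv / insertion / deletion / complex.

    snv: single differing base. insertion: ALT longer with REF as its
    prefix (case-insensitive). deletion: symmetric. complex: anything else.
    """
    ref, alt = v.ref.upper(), v.alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        return "snv" if ref != alt else "complex"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "insertion"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "deletion"
    return "complex"


def filter_insertions(
    vs: list[VariantRecord], k: int = 31, criterion: str = "alt_length"
) -> list[VariantRecord]:
    """Keep insertion records reaching the k-mer length threshold.

    ``alt_length``: |ALT| >= k (the full printed ALT string, REF base
    included). ``net_length``: |ALT| - |REF| >= k. Lengths are counted
    case-insensitively; input order is preserved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if criterion not in ("alt_length", "net_length"):
        raise ValueError("criterion must be 'alt_length' or 'net_length'")
    out = []
    for v in vs:
        if classify_variant(v) != "insertion":
            continue
        size = len(v.alt) if criterion == "alt_length" else len(v.alt) - len(v.ref)
        if size >= k:
            out.append(v)
    return out


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Read a VCF-subset table: CHROM, POS, REF, ALT[, INFO, ...].

    Accepts plain VCF v4.x body lines (## headers skipped) and TSV tables
    whose header row names the columns (e.g. '#CHROM ... ALT-INSERTION').
    Columns beyond the first five are retained in ``info``.
    """
    records: list[VariantRecord] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("##"):
            continue
        parts = line.rstrip("\n").split("\t")
        if line.startswith("#"):
            header = [p.lstrip("#").strip() for p in parts]
            continue
        if header:
            row = dict(zip(header, parts))
            alt_key = next(
                (k for k in row if k.upper().startswith("ALT")), None
            )
            info = {
                k: v
                for k, v in row.items()
                if k not in ("CHROM", "POS", "REF") and k != alt_key
            }
            records.append(
                VariantRecord(
                    chrom=row["CHROM"],
                    pos=int(row["POS"]),
                    ref=row["REF"],
                    alt=row[alt_key],
                    info=info,
                )
            )
        else:
            chrom, pos, *rest = parts
            if len(rest) >= 3 and not rest[0].isdigit():
                # VCF body: CHROM POS ID REF ALT ...
                vid, ref, alt = rest[0], rest[1], rest[2]
                info = {"ID": vid}
                if len(rest) >= 6:
                    info["INFO"] = rest[5]
            else:
                ref, alt = rest[0], rest[1]
                info = {}
            records.append(
                VariantRecord(chrom=chrom, pos=int(pos), ref=ref, alt=alt, info=info)
            )
    return records


def bundled_insertion_table() -> list[VariantRecord]:
    """The published BMH-0061 vs T. harzianum insertion rows shipped with
    the package (the inputs of the k = 31 insertion screen)."""
    with resources.as_file(
        resources.files("phylophen").joinpath("data/bmh0061_insertions.tsv")
    ) as p:
        return read_variant_table(p)


# ---------------------------------------------------------------------------
# phenotype statistics


@dataclass
class DualCultureMeasure:
    """One dual-culture antagonism measurement."""

    pathogen: str
    r1: float  # pathogen alone radius, cm
    r2: float  # pathogen radius with antagonist, cm
    pirg: float = field(init=False)
    flagged: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.pirg = pirg(self.r1, self.r2)
        # r2 > r1 means the pathogen grew MORE with the antagonist present
        self.flagged = self.r2 > self.r1


def growth_rate(times: list[float], diameters: list[float]) -> float:
    """Colony growth rate (cm/h): OLS slope of diameter against time."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(diameters, dtype=float)
    if t.size < 2 or t.size != d.size:
        raise ValueError("need >= 2 (time, diameter) points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(linregress(t, d).slope)


def pirg(r1: float, r2: float) -> float:
    """PIRG = (R1 - R2)/R1 × 100. Negative values (pathogen grew more with
    the antagonist) are allowed and left to the caller to flag."""
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    if r2 < 0:
        raise ValueError("r2 must be non-negative")
    return (r1 - r2) / r1 * 100.0


def compare_pirg_groups(groups: dict[str, list[float]], alpha: float = 0.05) -> dict:
    """One-way ANOVA across antagonists plus Tukey HSD pairwise report.

    Returns ``{"anova_f", "anova_p", "tukey": DataFrame}`` where the Tukey
    table carries adjusted p-values and a reject flag at ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    names = sorted(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if all(np.allclose(s, samples[0], atol=1e-12) for s in samples) and all(
        np.ptp(s) == 0 for s in samples
    ):
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = f_oneway(*samples)
    values = np.concatenate(samples)
    labels = np.concatenate([[n] * len(groups[n]) for n in names])
    if np.ptp(values) == 0:
        tukey_df = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p-adj", "lower", "upper", "reject"]
        )
    else:
        res = pairwise_tukeyhsd(values, labels, alpha=alpha)
        tukey_df = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return {"anova_f": float(f_stat), "anova_p": float(p_val), "tukey": tukey_df}
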