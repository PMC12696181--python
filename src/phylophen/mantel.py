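"""Mantel test of genomic distance against categorical geographic origin.

Tests isolation by distance on a panel of genomes: one matrix of pairwise
genomic (mutational) distances and one categorical geographic matrix
(0 = same country of origin, 1 = different). The statistic is the rank
correlation (Spearman or Kendall tau-b) of the upper-triangle entries; the
null distribution comes from simultaneous row/column permutations of the
second matrix. A coherence-subset helper restricts the panel to genomes
within a mutational distance ceiling of a focal genome before testing.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import kendalltau, spearmanr

from .trees import DistanceMatrix

logger = logging.getLogger("phylophen")

__all__ = ["GeoMatrix", "MantelResult", "subset_by_distance", "mantel"]


@dataclass
class GeoMatrix:
    """Binary categorical geographic distance (same origin = 0, else 1)."""

    labels: list[str]
    origin: dict[str, str]
    d_geo: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        missing = [l for l in self.labels if l not in self.origin]
        if missing:
            raise ValueError(f"labels without origin: {missing}")
        if self.d_geo is None:
            n = len(self.labels)
            d = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = float(
                        self.origin[self.labels[i]] != self.origin[self.labels[j]]
                    )
            self.d_geo = d


@dataclass
class MantelResult:
    r: float
    p: float
    method: str
    n_permutations: int
    seed: int
    tail: str = "one_sided_greater"
    extras: dict = field(default_factory=dict)


def subset_by_distance(
    m: DistanceMatrix, focal: str, max_d: float = 0.1
) -> DistanceMatrix:
    """Keep the focal genome plus all genomes with d(focal, ·) <= max_d."""
    if focal not in m.labels:
        raise ValueError(f"focal label {focal!r} not in matrix")
    fi = m.labels.index(focal)
    keep = [
        l for i, l in enumerate(m.labels) if i == fi or m.data[fi, i] <= max_d
    ]
    return m.submatrix(keep)


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    if method == "kendall":
        return float(kendalltau(x, y).statistic)
    raise ValueError("method must be 'spearman' or 'kendall'")


def mantel(
    d1: DistanceMatrix,
    d2: GeoMatrix | DistanceMatrix,
    method: str = "spearman",
    n_permutations: int = 9999,
    seed: int = 0,
    tail: str = "one_sided_greater",
    exact: bool = False,
) -> MantelResult:
    """Permutation Mantel test between two labelled distance matrices.

    p = (count + 1) / (n_permutations + 1) with count the number of
    permuted statistics >= the observed (one-sided greater) or with
    |r_perm| >= |r_obs| (two-sided). With ``exact=True`` (or whenever n! - 1
    <= n_permutations) all label permutations are enumerated and p is the
    exact enumeration fraction.
    """
    if tail not in ("one_sided_greater", "two_sided"):
        raise ValueError("tail must be 'one_sided_greater' or 'two_sided'")
    labels = d1.labels
    if isinstance(d2, GeoMatrix):
        if sorted(d2.labels) != sorted(labels):
            raise ValueError("label sets of the two matrices differ")
        order = [d2.labels.index(l) for l in labels]
        m2 = d2.d_geo[np.ix_(order, order)]
    else:
        if sorted(d2.labels) != sorted(labels):
            raise ValueError("label sets of the two matrices differ")
        order = [d2.labels.index(l) for l in labels]
        m2 = d2.data[np.ix_(order, order)]
    n = len(labels)
    if n < 4:
        raise ValueError("need at least 4 labels")
    x = _upper(d1.data)
    if np.all(x == x[0]) or np.all(_upper(m2) == _upper(m2)[0]):
        raise ValueError("constant distance matrix: correlation undefined")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_obs = _corr(x, _upper(m2), method)
        # sanity cross-check, logged only: the two rank statistics should
        # agree in sign whenever the signal is non-trivial
        other = "kendall" if method == "spearman" else "spearman"
        r_other = _corr(x, _upper(m2), other)
    if abs(r_obs) > 0.2 and np.sign(r_obs) != np.sign(r_other):
        logger.warning(
            "mantel: %s r=%.3f and %s r=%.3f disagree in sign",
            method, r_obs, other, r_other,
        )

    def exceeds(r_perm: float) -> bool:
        if tail == "one_sided_greater":
            return r_perm >= r_obs - 1e-12
        return abs(r_perm) >= abs(r_obs) - 1e-12

    n_fact = math.factorial(n)
    if exact or n_fact - 1 <= n_permutations:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            pm = m2[np.ix_(perm, perm)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if exceeds(_corr(x, _upper(pm), method)):
                    count += 1
            total += 1
        p = count / total
        used = total - 1
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            pm = m2[np.ix_(perm, perm)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if exceeds(_corr(x, _upper(pm), method)):
                    count += 1
        p = (count + 1) / (n_permutations + 1)
        used = n_permutations
    return MantelResult(
        r=r_obs,
        p=float(p),
        method=method,
        n_permutations=used,
        seed=seed,
        tail=tail,
        extras={"n": n, "exact": exact or n_fact - 1 <= n_permutations},
    )
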