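"""Pedigree kinship and selection of an unrelated sample subset.

The kinship coefficient phi(i, j) is the probability that one allele drawn at
random from i and one from j are identical by descent.  For a non-inbred
individual phi(i, i) = 1/2; 2*Phi is the expected additive genetic
relationship matrix used as the random-effect covariance in the polygenic
mixed model.

Two estimators are provided: the exact recursion on a topologically ordered
pedigree (the workhorse) and a Monte-Carlo gene-dropping estimator used as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import FOUNDER, Pedigree, PedigreeError

__all__ = [
    "KinshipMatrix",
    "pedigree_kinship",
    "monte_carlo_kinship",
    "unrelated_subset",
    "degree_threshold",
]


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients for a set of samples."""

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.phi.shape != (n, n):
            raise ValueError("phi shape does not match ids")
        if not np.allclose(self.phi, self.phi.T, atol=1e-12):
            raise ValueError("kinship matrix is not symmetric")

    def relationship(self) -> np.ndarray:
        """The additive relationship matrix 2*Phi."""
        return 2.0 * self.phi

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.asarray([pos[s] for s in ids], dtype=int)
        return KinshipMatrix(list(ids), self.phi[np.ix_(idx, idx)].copy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.phi, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(dtype=float))


def pedigree_kinship(pedigree: Pedigree) -> KinshipMatrix:
    """Exact kinship coefficients by the standard tabular recursion.

    Founders are taken as mutually unrelated and non-inbred.  For individual
    i with parents (f, m), processed after both parents:

        phi(i, i) = 1/2 * (1 + phi(f, m))
        phi(i, j) = 1/2 * (phi(f, j) + phi(m, j))   for j already processed.
    """
    order = pedigree.topological_order()
    parents = pedigree.parents()
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, ind in enumerate(order):
        f, m = parents[ind]
        if f == FOUNDER:
            phi[k, k] = 0.5
        else:
            fi, mi = pos[f], pos[m]
            phi[k, k] = 0.5 * (1.0 + phi[fi, mi])
            for j in range(k):
                phi[k, j] = phi[j, k] = 0.5 * (phi[fi, j] + phi[mi, j])
    # return in the pedigree's own individual order
    want = pedigree.individuals
    idx = np.asarray([pos[i] for i in want], dtype=int)
    return KinshipMatrix(want, phi[np.ix_(idx, idx)])


def monte_carlo_kinship(
    pedigree: Pedigree, n_drops: int = 100_000, rng: np.random.Generator | None = None
) -> KinshipMatrix:
    """Gene-dropping Monte-Carlo estimate of kinship.

    Each founder receives two unique allele labels; alleles are transmitted
    Mendelianly down the pedigree ``n_drops`` times.  phi(i, j) is estimated
    as the fraction of drops in which one random allele of i matches one
    random allele of j; the average over the four allele pairings is used,
    which equals the expectation of that probability.
    """
    if rng is None:
        rng = np.random.default_rng()
    order = pedigree.topological_order()
    parents = pedigree.parents()
    pos = {ind: k for k, ind in enumerate(order)}
    n = len(order)

    hap = np.zeros((n, 2, n_drops), dtype=np.int32)
    label = 0
    for k, ind in enumerate(order):
        f, m = parents[ind]
        if f == FOUNDER:
            hap[k, 0, :] = label
            hap[k, 1, :] = label + 1
            label += 2
        else:
            pick_f = rng.integers(0, 2, size=n_drops)
            pick_m = rng.integers(0, 2, size=n_drops)
            fi, mi = pos[f], pos[m]
            hap[k, 0, :] = hap[fi, pick_f, np.arange(n_drops)]
            hap[k, 1, :] = hap[mi, pick_m, np.arange(n_drops)]

    phi = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            match = 0.0
            for x in range(2):
                for y in range(2):
                    match += np.mean(hap[a, x, :] == hap[b, y, :])
            phi[a, b] = phi[b, a] = match / 4.0
    want = pedigree.individuals
    idx = np.asarray([pos[i] for i in want], dtype=int)
    return KinshipMatrix(want, phi[np.ix_(idx, idx)])


def degree_threshold(degree: int) -> float:
    """Kinship threshold for a relationship degree: phi >= 2**-(degree+1).

    First-degree relatives (parent-offspring, full sibs) have expected
    phi = 1/4, second-degree 1/8, third-degree 1/16; a pair at or above the
    cutoff's expected kinship counts as related.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    return 2.0 ** -(degree + 1)


def unrelated_subset(kinship: KinshipMatrix, degree_cutoff: int = 3) -> list[str]:
    """Greedy maximal subset with no pair related at ``degree_cutoff`` or closer.

    Repeatedly removes the individual involved in the most violating pairs
    (phi >= threshold); ties are broken by removing the individual whose id
    sorts first, making the result deterministic.  Returned ids keep the
    input order.
    """
    n = len(kinship.ids)
    if n == 0:
        return []
    thr = degree_threshold(degree_cutoff)
    related = kinship.phi >= thr
    np.fill_diagonal(related, False)
    alive = np.ones(n, dtype=bool)
    counts = related.sum(axis=1).astype(int)
    order_key = sorted(range(n), key=lambda i: kinship.ids[i])
    while True:
        max_count = counts[alive].max(initial=0)
        if max_count == 0:
            break
        victim = next(
            i for i in order_key if alive[i] and counts[i] == max_count
        )
        alive[victim] = False
        hit = related[victim] & alive
        counts[hit] -= 1
        counts[victim] = 0
    return [kinship.ids[i] for i in range(n) if alive[i]]
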