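"""Shannon entropy and mutual information of diploid genotypes.

A single biallelic SNP takes one of three genotype states, so its
information content is H(X) = -sum_x p(x) log2 p(x) over the three-state
genotype distribution, at most log2(3) = 1.585 bits (equiprobable
genotypes) and exactly 1.5 bits for a MAF-0.5 SNP at Hardy-Weinberg
equilibrium.  Redundancy between two SNPs (linkage disequilibrium at the
genotype level) is measured by the mutual information
I(X;Y) = sum p(x,y) log2[p(x,y) / (p(x) p(y))].

All probabilities are plug-in (maximum-likelihood) estimates from
genotype counts, without pseudocounts or bias correction.  Everything is
in bits.

For a panel of N SNPs the joint entropy H(X_1..X_N) is the quantity of
interest but is impractical to estimate for large N (3^N cells); it is
bracketed by pairwise-MI bounds:

* lower bound  H_L = sum_k H(X_k) - sum_{j<k} I(X_j; X_k)
* upper bound  H_U = sum_k H(X_k) - sum_{k>=2} max_{j<k} I(X_j; X_k)

H_L subtracts every pairwise redundancy (conservative under pairwise LD,
not a guaranteed bound under higher-order dependence such as XOR-type
triples) and is clamped below at the largest marginal entropy, since a
joint entropy can never be smaller than any marginal.  An exact
empirical joint entropy is provided as an oracle for small N.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .io import MISSING, GenotypeMatrix

#: Negative MI smaller than this (float residue) is clipped to zero.
MI_NEG_TOL = 1e-12

LOG2_3 = float(np.log2(3.0))


class UndefinedEntropyError(ValueError):
    """Entropy requested for an empty genotype count vector."""


def genotype_counts(calls: np.ndarray) -> np.ndarray:
    """3-vector (n_hom_wt, n_het, n_hom_mut) from calls, missing excluded."""
    g = np.asarray(calls)
    g = g[g != MISSING]
    return np.bincount(g, minlength=3)[:3]


def snp_entropy(counts: Sequence[int] | np.ndarray) -> float:
    """Plug-in Shannon entropy (bits) of a genotype count 3-vector.

    0*log(0) is treated as 0; the result lies in [0, log2(3)].
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or (c < 0).any():
        raise ValueError("counts must be a non-negative 1-D vector")
    n = c.sum()
    if n == 0:
        raise UndefinedEntropyError("entropy undefined for zero total count")
    return float(_scipy_entropy(c, base=2))


def mutual_information(table: np.ndarray) -> float:
    """Mutual information (bits) from a joint genotype count table.

    ``table[x, y]`` counts samples with genotype x at the first SNP and y
    at the second (complete cases only).  Tiny negative float residue is
    clipped to 0.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    if n == 0:
        raise UndefinedEntropyError("mutual information undefined for empty table")
    p = t / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())
    if mi < 0:
        if mi < -MI_NEG_TOL:
            raise FloatingPointError(f"mutual information {mi} below -{MI_NEG_TOL}")
        mi = 0.0
    return mi


def pair_joint_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over samples non-missing at both SNPs."""
    mask = (a != MISSING) & (b != MISSING)
    aa, bb = a[mask].astype(np.int64), b[mask].astype(np.int64)
    return np.bincount(3 * aa + bb, minlength=9).reshape(3, 3)


@dataclass
class MiMatrix:
    """Symmetric pairwise mutual-information matrix over a SNP set.

    The diagonal holds each SNP's own entropy (on its non-missing
    samples); off-diagonal entries are pairwise MI on pairwise-complete
    samples.  All values in bits.
    """

    snp_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.snp_ids)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match snp_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("MI matrix must be symmetric")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def entropy(self, snp_id: str) -> float:
        return float(self.values[self._index[snp_id], self._index[snp_id]])

    def mi(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def indices(self, snp_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.asarray([self._index[s] for s in snp_ids])
        except KeyError as exc:
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from None

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("snp_id\t" + "\t".join(self.snp_ids) + "\n")
            for i, snp in enumerate(self.snp_ids):
                fh.write(snp + "\t" + "\t".join(f"{v:.12g}" for v in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MiMatrix":
        with Path(path).open() as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
        snp_ids = lines[0].split("\t")[1:]
        values = np.asarray(
            [[float(c) for c in ln.split("\t")[1:]] for ln in lines[1:]], dtype=float
        )
        return cls(snp_ids, values)


def mi_matrix(M: GenotypeMatrix, snp_subset: Sequence[str] | None = None) -> MiMatrix:
    """Pairwise MI matrix (diagonal = entropies) for a genotype matrix.

    Missing genotypes are excluded per SNP for the diagonal and pairwise
    for the off-diagonal.  A pair with zero co-observed samples is an
    error naming the pair.
    """
    snp_ids = list(snp_subset) if snp_subset is not None else list(M.snp_ids)
    if len(snp_ids) < 2:
        raise ValueError("mi_matrix needs at least 2 SNPs")
    cols = [M.snp_column(s) for s in snp_ids]
    n = len(snp_ids)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = snp_entropy(genotype_counts(cols[i]))
    for i in range(n):
        for j in range(i + 1, n):
            joint = pair_joint_counts(cols[i], cols[j])
            if joint.sum() == 0:
                raise ValueError(
                    f"SNP pair ({snp_ids[i]!r}, {snp_ids[j]!r}) has no co-observed samples"
                )
            values[i, j] = values[j, i] = mutual_information(joint)
    return MiMatrix(snp_ids, values)


#: Default cap on exact joint-entropy subset size (3^8 = 6561 cells).
EXACT_JOINT_CAP = 8


def exact_joint_entropy(
    M: GenotypeMatrix, snp_subset: Sequence[str], cap: int = EXACT_JOINT_CAP
) -> float:
    """Plug-in joint entropy (bits) of the empirical distribution over
    genotype vectors at the given SNPs.

    Samples with any missing call in the subset are excluded.  Exact but
    combinatorial (3^N states), so refused above ``cap`` SNPs; use the
    pairwise bounds instead for larger panels.
    """
    snp_ids = list(snp_subset)
    N = len(snp_ids)
    if N == 0:
        raise ValueError("empty SNP subset")
    if N > cap:
        raise ValueError(f"exact joint entropy refused for N={N} > cap={cap}")
    sub = M.subset_snps(snp_ids).calls
    complete = (sub != MISSING).all(axis=1)
    sub = sub[complete].astype(np.int64)
    if sub.shape[0] == 0:
        raise UndefinedEntropyError("no complete-case samples for subset")
    codes = sub @ (3 ** np.arange(N, dtype=np.int64))
    _, counts = np.unique(codes, return_counts=True)
    return snp_entropy(counts)


@dataclass(frozen=True)
class JointEntropyBounds:
    """Entropy sum and pairwise-MI joint-entropy bounds for an ordered panel."""

    h_sum: float
    h_lower: float
    h_upper: float

    def __post_init__(self) -> None:
        if not self.h_lower <= self.h_upper + 1e-9:
            raise ValueError(f"h_lower {self.h_lower} > h_upper {self.h_upper}")


def joint_entropy_bounds(
    mi: MiMatrix, snp_subset: Sequence[str], upper_rule: str = "max"
) -> JointEntropyBounds:
    """H_L / H_U joint-entropy bounds for an ordered SNP subset.

    ``upper_rule="max"`` (default) subtracts, for each SNP after the
    first, its largest MI against any earlier SNP — the tighter,
    order-robust variant.  ``upper_rule="first"`` subtracts I(X_1; X_k)
    instead, following the literal one-anchor recursion.

    H_L is clamped below at the largest marginal entropy, and H_U at
    H_L, so the invariant max_k H_k <= H_L <= H_U <= sum_k H_k holds.
    """
    idx = mi.indices(list(snp_subset))
    if idx.size == 0:
        raise ValueError("empty SNP subset")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError("duplicate SNP ids in subset")
    sub = mi.values[np.ix_(idx, idx)]
    h = np.diag(sub)
    h_sum = float(h.sum())
    iu = np.triu_indices(idx.size, k=1)
    h_lower = h_sum - float(sub[iu].sum())
    if upper_rule == "max":
        penalties = [float(sub[:k, k].max()) for k in range(1, idx.size)]
    elif upper_rule == "first":
        penalties = [float(sub[0, k]) for k in range(1, idx.size)]
    else:
        raise ValueError(f"unknown upper_rule {upper_rule!r}")
    h_upper = h_sum - float(np.sum(penalties))
    h_lower = max(h_lower, float(h.max()))
    h_upper = min(max(h_upper, h_lower), h_sum)
    return JointEntropyBounds(h_sum=h_sum, h_lower=h_lower, h_upper=h_upper)
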