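"""Closed-form combinatorics of sample-tagging panels.

Model: a population of L individuals is genotyped at N statistically
independent markers, each with S equiprobable genotype states (S = 3 for
diploid biallelic SNPs at maximal entropy).  Two independent individuals
then mismatch at each marker independently with probability (S-1)/S, so
their Hamming distance is Binomial(N, (S-1)/S):

    P(d = k) = C(N, k) (S-1)^k / S^N,      E[d] = N (S-1)/S

(2N/3 for S = 3).  A pair within tolerance t ("duality" at t = 0 —
complete genotype identity, the failure mode of a tagging panel) occurs
with probability P(d <= t); across the C(L, 2) pairs of the population
the chance that at least one pair collides is approximated as

    P_dual ~= 1 - (1 - P(d <= t))^C(L,2)  ~=  C(L,2) P(d <= t)

treating pairs as independent, valid when C(L,2) * P(d <= t) is small
and L <= S^N.  Per-marker probabilities are computed with exact integer
combinatorics (fractions; no float S^N), and the population-level form
in log space via log1p/expm1, so the results are stable at parameter
points like N = 60, S = 3, L = 7e9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np


@dataclass(frozen=True)
class DualitySpec:
    """Parameter bundle (L, N, S, t) for the closed-form tagging math.

    L: population size; N: number of markers; S: genotype states per
    marker (3 for diploid SNPs); t: mismatch tolerance (0 = exact-match
    duality).
    """

    L: int
    N: int
    S: int = 3
    t: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("population size L must be >= 2")
        _check_ns(self.N, self.S)
        if not 0 <= self.t <= self.N:
            raise ValueError(f"tolerance t must be in [0, N={self.N}], got {self.t}")


def _check_ns(N: int, S: int) -> None:
    if N < 1 or int(N) != N:
        raise ValueError(f"N must be a positive integer, got {N}")
    if S < 2 or int(S) != S:
        raise ValueError(f"S must be an integer >= 2, got {S}")


def _pmf_fraction(k: int, N: int, S: int) -> Fraction:
    return Fraction(math.comb(N, k) * (S - 1) ** k, S**N)


def hamming_pmf(N: int, S: int) -> np.ndarray:
    """Distribution of the Hamming distance between two independent
    uniformly-genotyped individuals; entry k = P(d = k), k = 0..N."""
    _check_ns(N, S)
    return np.asarray([float(_pmf_fraction(k, N, S)) for k in range(N + 1)])


def expected_hamming(N: int, S: int) -> float:
    """Expected Hamming distance N(S-1)/S (2N/3 for three-genotype SNPs)."""
    _check_ns(N, S)
    return N * (S - 1) / S


def _p_within(spec: DualitySpec) -> float:
    """P(d <= t) for one pair, exact rational arithmetic then one float cast."""
    return float(sum(_pmf_fraction(k, spec.N, spec.S) for k in range(spec.t + 1)))


def pairwise_all_distinct_probability(spec: DualitySpec) -> float:
    """Probability that every pair of the L individuals is at Hamming
    distance > t: (1 - P(d <= t))^C(L,2), pairs treated as independent."""
    n_pairs = math.comb(spec.L, 2)
    p = _p_within(spec)
    if p >= 1.0:
        return 0.0
    return math.exp(n_pairs * math.log1p(-p))


def duality_probability(spec: DualitySpec, linearized: bool = False) -> float:
    """Probability that at least two of L individuals fall within Hamming
    distance t of each other.

    Default is the exponential form 1 - (1 - P(<=t))^C(L,2), evaluated as
    -expm1(C(L,2) * log1p(-P)); ``linearized=True`` returns the first-order
    form C(L,2) * P(<=t) (capped at 1).  Both are approximations that
    agree to the leading order when C(L,2)*P is small; a warning applies
    when L exceeds S^N (more individuals than distinguishable labels).
    """
    if spec.L > spec.S**spec.N:
        import warnings

        warnings.warn(
            f"L={spec.L} exceeds S^N={spec.S}**{spec.N}; a duality is certain "
            "and the independence approximation is uninformative",
            stacklevel=2,
        )
    n_pairs = math.comb(spec.L, 2)
    p = _p_within(spec)
    if linearized:
        return min(1.0, n_pairs * p)
    if p >= 1.0:
        return 1.0
    return -math.expm1(n_pairs * math.log1p(-p))


def min_markers(population: int, S: int) -> int:
    """Smallest n with S^n >= population, in exact integer arithmetic.

    This is the information-theoretic floor on panel size for a
    population of the given size under ideal (uniform, independent)
    markers; e.g. 33 two-state or 21 three-genotype markers for 7e9
    individuals.
    """
    population = int(population)
    if population < 1:
        raise ValueError("population must be >= 1")
    _check_ns(1, S)
    n = 0
    capacity = 1
    while capacity < population:
        capacity *= S
        n += 1
    return n
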