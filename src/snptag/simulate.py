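"""Synthetic genotype populations under Hardy-Weinberg equilibrium.

Given an alt-allele frequency q, a diploid genotype is two independent
allele draws, so genotype probabilities are (1-q)^2, 2q(1-q), q^2 (no
inbreeding coefficient); SNPs are mutually independent unless linkage
is injected explicitly.  These generators stand in for the simulated
ethnic-group populations used to evaluate panels, and produce all test
fixtures: there is no real genotype data anywhere in the package.

Reproducibility: every generator takes a master seed and derives
per-SNP / per-group streams through ``numpy.random.SeedSequence(
[master_seed, index])``, so any column or group can be regenerated
independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from importlib import resources

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass(frozen=True)
class SimSpec:
    """One simulated HWE population: allele frequencies, size, seed, label."""

    allele_freqs: tuple[float, ...]
    n_individuals: int
    seed: int = 0
    group_label: str = "pop"
    snp_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        freqs = tuple(float(q) for q in self.allele_freqs)
        object.__setattr__(self, "allele_freqs", freqs)
        if not all(0.0 <= q <= 1.0 for q in freqs):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.snp_ids is not None and len(self.snp_ids) != len(freqs):
            raise ValueError("snp_ids length does not match allele_freqs")


def _snp_ids(spec: SimSpec) -> list[str]:
    if spec.snp_ids is not None:
        return list(spec.snp_ids)
    return [f"snp{i:05d}" for i in range(len(spec.allele_freqs))]


def simulate_hwe(spec: SimSpec) -> GenotypeMatrix:
    """Draw an HWE population: independent SNPs, genotypes 0/1/2 as two
    allele draws at the alt frequency; deterministic given the seed."""
    n, m = spec.n_individuals, len(spec.allele_freqs)
    calls = np.empty((n, m), dtype=np.int8)
    for j, q in enumerate(spec.allele_freqs):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, j]))
        calls[:, j] = rng.binomial(1, q, size=n) + rng.binomial(1, q, size=n)
    sample_ids = [f"{spec.group_label}_{i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, _snp_ids(spec), calls)


def simulate_groups(
    freq_table: pd.DataFrame, n_per_group: int, seed: int = 0
) -> dict[str, GenotypeMatrix]:
    """One HWE population per frequency column (rows = SNPs, index = snp ids).

    Group seeds are derived from the master seed by column position, so
    two groups with identical frequencies still get distinct genotypes.
    """
    if freq_table.isna().any().any():
        bad = freq_table.columns[freq_table.isna().any()].tolist()
        raise ValueError(f"missing allele frequencies in group(s) {bad}")
    out: dict[str, GenotypeMatrix] = {}
    for g, group in enumerate(freq_table.columns):
        spec = SimSpec(
            allele_freqs=tuple(freq_table[group].astype(float)),
            n_individuals=n_per_group,
            seed=int(np.random.SeedSequence([seed, 10_000 + g]).generate_state(1)[0] % 2**31),
            group_label=str(group),
            snp_ids=tuple(str(s) for s in freq_table.index),
        )
        out[str(group)] = simulate_hwe(spec)
    return out


@dataclass(frozen=True)
class LdSpec:
    """Pairwise linkage injection: SNP j copies SNP i's genotype with
    probability ``copy_prob`` per individual, else keeps its own
    (independently drawn) genotype."""

    pairs: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for i, j, p in self.pairs:
            if i == j:
                raise ValueError(f"self-copy pair ({i!r}, {j!r})")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"copy_prob {p} outside [0, 1] for pair ({i}, {j})")


def _topo_order(pairs) -> list[tuple[str, str, float]]:
    """Order copy edges so sources are finalized before targets; reject cycles."""
    deps = {j: i for i, j, _ in pairs}
    if len(deps) != len(pairs):
        raise ValueError("a SNP is the target of more than one copy pair")
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 1:
            raise ValueError(f"cyclic copy chain involving {node!r}")
        if state.get(node) == 2:
            return
        state[node] = 1
        if node in deps:
            visit(deps[node])
        state[node] = 2
        order.append(node)

    for _, j, _ in pairs:
        visit(j)
    rank = {s: r for r, s in enumerate(order)}
    return sorted(pairs, key=lambda e: rank[e[1]])


def inject_ld(M: GenotypeMatrix, ld: LdSpec, seed: int = 0) -> GenotypeMatrix:
    """Return a copy of ``M`` with pairwise linkage injected.

    copy_prob = 1 makes the target column identical to the source;
    copy_prob = 0 leaves it untouched; intermediate values interpolate,
    and the empirical MI between the pair rises monotonically with
    copy_prob.  Copy chains are applied source-first; cycles are
    rejected.
    """
    calls = M.calls.copy()
    col = {s: k for k, s in enumerate(M.snp_ids)}
    for e, (src, dst, p) in enumerate(_topo_order(ld.pairs)):
        for s in (src, dst):
            if s not in col:
                raise KeyError(f"LD pair references unknown SNP {s!r}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 20_000 + e]))
        mask = rng.random(M.n_samples) < p
        calls[mask, col[dst]] = calls[mask, col[src]]
    return GenotypeMatrix(list(M.sample_ids), list(M.snp_ids), calls)


def load_default_frequencies() -> pd.DataFrame:
    """Bundled synthetic per-group allele-frequency fixture.

    Emulates the qualified-SNP regime — 30 high-information SNPs with
    alt frequency 0.4-0.5 in every group plus 10 low-MAF distractors —
    with mild between-group differences.  Entirely synthetic; no real
    database frequencies are bundled.
    """
    with resources.files("snptag.data").joinpath("group_freqs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="snp_id")
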