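"""Qualified-SNP production: entropy consistency, locus filters, overlap checks.

A SNP is "qualified" for panel selection when (i) its entropy does not
fluctuate between independent sample sources — tested by a per-SNP
bootstrap on the entropy difference ΔH — and (ii) the locus is
technically reliable: mappability 1, GC content within 0.35-0.55, and
autosomal.  A cross-dataset identity scan flags duplicated individuals
(sample overlap), which would otherwise bias the consistency test.

Bootstrap ΔH test: from two sources with non-missing counts n and m,
draw a size-n resample (with replacement) of the first source's
genotypes and a size-m resample of the second, compute the entropy
difference, repeat n_bootstrap times, and take the [α/2, 1-α/2]
percentile interval.  The SNP qualifies when 0 lies inside that
interval (no detectable entropy shift).  The per-SNP RNG stream is
derived from the master seed and the SNP/dataset labels, so results are
independent of iteration order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import genotype_counts, snp_entropy
from .io import MISSING, GenotypeMatrix, SnpRecord


@dataclass(frozen=True)
class QualificationConfig:
    """Thresholds for entropy-consistency and locus filters."""

    n_bootstrap: int = 1000
    ci_level: float = 0.95
    gc_min: float = 0.35
    gc_max: float = 0.55
    mappability_required: float = 1.0
    overlap_identity_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass(frozen=True)
class ConsistencyResult:
    snp_id: str
    delta_h_observed: float
    ci_low: float
    ci_high: float
    qualified: bool

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low > ci_high")


class SnpNotSharedError(KeyError):
    """SNP absent from one of the datasets under comparison."""


def _derive_seed(master: int, *tokens: str) -> int:
    digest = hashlib.sha256(("|".join(map(str, (master, *tokens)))).encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def bootstrap_consistency(
    genotypes_a: GenotypeMatrix,
    genotypes_b: GenotypeMatrix,
    snp_id: str,
    config: QualificationConfig = QualificationConfig(),
    rule: str = "zero-in-ci",
    labels: tuple[str, str] = ("a", "b"),
) -> ConsistencyResult:
    """Bootstrap test of entropy consistency for one SNP across two datasets.

    ``rule="zero-in-ci"`` (default) qualifies the SNP when 0 lies in the
    percentile CI of the bootstrap ΔH distribution; ``rule="observed-in-ci"``
    applies the literal observed-ΔH-inside-its-own-CI reading (almost
    always true by construction; kept for comparison only).
    """
    for M, lab in ((genotypes_a, labels[0]), (genotypes_b, labels[1])):
        if snp_id not in M.snp_ids:
            raise SnpNotSharedError(f"SNP {snp_id!r} absent from dataset {lab!r}")
    ca = genotype_counts(genotypes_a.snp_column(snp_id))
    cb = genotype_counts(genotypes_b.snp_column(snp_id))
    n, m = int(ca.sum()), int(cb.sum())
    if n < 2 or m < 2:
        raise ValueError(f"SNP {snp_id!r}: need >= 2 non-missing calls per dataset")
    delta_obs = snp_entropy(ca) - snp_entropy(cb)
    rng = np.random.default_rng(
        _derive_seed(config.seed, snp_id, labels[0], labels[1])
    )
    B = config.n_bootstrap
    res_a = rng.multinomial(n, ca / n, size=B)
    res_b = rng.multinomial(m, cb / m, size=B)
    h_a = _entropy_rows(res_a)
    h_b = _entropy_rows(res_b)
    delta = h_a - h_b
    alpha = 1.0 - config.ci_level
    ci_low, ci_high = np.percentile(delta, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if rule == "zero-in-ci":
        qualified = bool(ci_low <= 0.0 <= ci_high)
    elif rule == "observed-in-ci":
        qualified = bool(ci_low <= delta_obs <= ci_high)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ConsistencyResult(snp_id, float(delta_obs), float(ci_low), float(ci_high), qualified)


def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Row-wise plug-in entropies (bits) of an array of count vectors."""
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def filter_snps(
    records: list[SnpRecord], config: QualificationConfig = QualificationConfig()
) -> list[SnpRecord]:
    """Locus filters: mappability, GC window (boundaries inclusive), autosomes."""
    bad = [r.snp_id for r in records if np.isnan(r.gc_content) or np.isnan(r.mappability)]
    if bad:
        raise ValueError(f"records missing gc_content/mappability: {bad}")
    return [
        r
        for r in records
        if r.mappability >= config.mappability_required
        and config.gc_min <= r.gc_content <= config.gc_max
        and r.is_autosomal
    ]


def detect_sample_overlap(
    M_a: GenotypeMatrix, M_b: GenotypeMatrix, threshold: float = 0.95
) -> list[tuple[str, str, float]]:
    """Cross-dataset pairs whose genotype identity exceeds ``threshold``.

    Identity = matching genotypes / SNPs co-observed in both samples,
    over the SNPs shared by the two matrices; the comparison is strict
    (identity exactly at the threshold is not reported).
    """
    shared = [s for s in M_a.snp_ids if s in set(M_b.snp_ids)]
    if not shared:
        raise ValueError("datasets share no SNPs")
    A = M_a.subset_snps(shared).calls
    B = M_b.subset_snps(shared).calls
    hits: list[tuple[str, str, float]] = []
    for i, sid_a in enumerate(M_a.sample_ids):
        both = (A[i] != MISSING) & (B != MISSING)
        n_obs = both.sum(axis=1)
        n_match = ((A[i] == B) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            ident = np.where(n_obs > 0, n_match / np.maximum(n_obs, 1), 0.0)
        for j in np.nonzero(ident > threshold)[0]:
            hits.append((sid_a, M_b.sample_ids[j], float(ident[j])))
    return hits


def qualify_snps(
    datasets: dict[str, GenotypeMatrix],
    records: list[SnpRecord],
    config: QualificationConfig = QualificationConfig(),
    rule: str = "zero-in-ci",
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Full qualification pipeline over two or more datasets.

    A SNP qualifies when it is shared by all datasets, passes the locus
    filters, and passes the pairwise bootstrap consistency test for
    every dataset pair.  Returns the per-SNP report and the combined
    genotype matrix (samples concatenated across datasets, qualified
    SNPs only) on which panel entropies should be re-estimated.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    labels = sorted(datasets)
    shared = set(datasets[labels[0]].snp_ids)
    for lab in labels[1:]:
        shared &= set(datasets[lab].snp_ids)
    kept_records = [r for r in filter_snps(records, config) if r.snp_id in shared]
    rows = []
    qualified_ids = []
    for rec in kept_records:
        ok = True
        for x in range(len(labels)):
            for y in range(x + 1, len(labels)):
                res = bootstrap_consistency(
                    datasets[labels[x]], datasets[labels[y]], rec.snp_id,
                    config, rule=rule, labels=(labels[x], labels[y]),
                )
                rows.append(
                    {
                        "snp_id": rec.snp_id,
                        "pair": f"{labels[x]}|{labels[y]}",
                        "delta_h": res.delta_h_observed,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "qualified_pair": res.qualified,
                    }
                )
                ok &= res.qualified
        if ok:
            qualified_ids.append(rec.snp_id)
    report = pd.DataFrame(
        rows, columns=["snp_id", "pair", "delta_h", "ci_low", "ci_high", "qualified_pair"]
    )
    report["qualified"] = report["snp_id"].isin(qualified_ids)
    combined = _combine(datasets, labels, qualified_ids)
    return report, combined


def _combine(
    datasets: dict[str, GenotypeMatrix], labels: list[str], snp_ids: list[str]
) -> GenotypeMatrix:
    mats = [datasets[lab].subset_snps(snp_ids) for lab in labels]
    calls = np.vstack([m.calls for m in mats]) if snp_ids else np.empty(
        (sum(m.n_samples for m in mats), 0), dtype=np.int8
    )
    sample_ids = [f"{lab}:{sid}" for lab, m in zip(labels, mats) for sid in m.sample_ids]
    return GenotypeMatrix(sample_ids, list(snp_ids), calls)
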