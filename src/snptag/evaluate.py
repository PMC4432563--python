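"""Empirical panel evaluation: Hamming distances and duality detection.

A tagging panel is judged by how far apart it places individuals: the
pairwise Hamming distance (number of panel SNPs at which two samples'
genotypes differ) should be large on average, and exact matches
("dualities" — pairs the panel cannot distinguish) should be vanishingly
rare.  The mean pairwise distance is computed exactly in O(L*N) from
per-SNP genotype frequencies,

    mean d = sum_snp [ 1 - sum_g n_g (n_g - 1) / (L_s (L_s - 1)) ],

(L_s = non-missing count at that SNP), never by enumerating pairs; the
full distance histogram is exact for up to 10^7 pairs and otherwise
estimated from a seeded random pair sample.  Duality detection hashes
the panel genotype strings, so it is O(L*N) as well and practical at
the 100,000-individual populations the method targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .select import Panel

#: Above this many pairs the histogram is estimated from a pair sample.
EXACT_HISTOGRAM_MAX_PAIRS = 10**7


def hamming_distance(g_a: np.ndarray, g_b: np.ndarray) -> tuple[int, int]:
    """Genotype-level Hamming distance between two call vectors.

    Sites missing in either sample are excluded; returns (distance,
    number of sites used).  Symmetric, zero on identical vectors, and
    insensitive to the magnitude of the genotype difference.
    """
    a = np.asarray(g_a)
    b = np.asarray(g_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    used = (a != MISSING) & (b != MISSING)
    return int((a[used] != b[used]).sum()), int(used.sum())


@dataclass(frozen=True)
class DistanceSummary:
    """Pairwise-distance summary for one panel on one population."""

    panel_id: str
    n_individuals: int
    mean_distance: float
    distance_histogram: np.ndarray
    computed_over: str

    def __post_init__(self) -> None:
        n_sites = len(self.distance_histogram) - 1
        if not 0 <= self.mean_distance <= max(n_sites, 0) + 1e-9:
            raise ValueError("mean distance outside [0, N]")


@dataclass(frozen=True)
class DualityReport:
    """Exact-match pairs and duality frequencies for one panel.

    The per-pair frequency (dual pairs / C(L,2)) and the per-individual
    frequency (individuals in >= 1 dual pair / L) are both reported —
    the failure rate of a panel can be quoted either way.
    """

    duality_pairs: tuple[tuple[str, str], ...]
    pair_duality_frequency: float
    individual_duality_frequency: float
    n_individuals: int
    flagged_missing: tuple[str, ...] = ()


def _panel_calls(M: GenotypeMatrix, panel: Panel | list[str]) -> tuple[np.ndarray, list[str]]:
    snp_ids = list(panel.snp_ids) if isinstance(panel, Panel) else list(panel)
    return M.subset_snps(snp_ids).calls, snp_ids


def mean_pairwise_distance(
    M: GenotypeMatrix,
    panel: Panel | list[str],
    panel_id: str = "panel",
    n_sampled_pairs: int = 100_000,
    seed: int = 0,
) -> DistanceSummary:
    """Exact mean pairwise Hamming distance plus a distance histogram.

    The mean uses the per-SNP genotype-frequency identity (complete
    cases per SNP), so it is exact at any population size.  The
    histogram is exact (all pairs) when C(L,2) <= 10^7, else computed
    from ``n_sampled_pairs`` random pairs and marked as sampled.
    """
    calls, snp_ids = _panel_calls(M, panel)
    L, N = calls.shape
    if L < 2:
        raise ValueError("need at least 2 individuals")
    mean = 0.0
    for j in range(N):
        g = calls[:, j]
        g = g[g != MISSING]
        Ls = g.size
        if Ls < 2:
            continue
        n_g = np.bincount(g, minlength=3)[:3].astype(float)
        mean += 1.0 - float((n_g * (n_g - 1)).sum()) / (Ls * (Ls - 1))
    n_pairs = L * (L - 1) // 2
    if n_pairs <= EXACT_HISTOGRAM_MAX_PAIRS:
        hist = np.zeros(N + 1, dtype=np.int64)
        for i in range(L - 1):
            d = _row_distances(calls[i], calls[i + 1 :])
            hist += np.bincount(d, minlength=N + 1)
        computed_over = "all-pairs-exact"
    else:
        rng = np.random.default_rng(seed)
        ii = rng.integers(0, L, size=2 * n_sampled_pairs)
        jj = rng.integers(0, L, size=2 * n_sampled_pairs)
        keep = ii != jj
        ii, jj = ii[keep][:n_sampled_pairs], jj[keep][:n_sampled_pairs]
        d = np.empty(ii.size, dtype=np.int64)
        chunk = 4096
        for s in range(0, ii.size, chunk):
            d[s : s + chunk] = _row_pair_distances(calls[ii[s : s + chunk]],
                                                   calls[jj[s : s + chunk]])
        hist = np.bincount(d, minlength=N + 1)
        computed_over = f"sampled-pairs({ii.size}, seed={seed})"
    return DistanceSummary(
        panel_id=panel_id, n_individuals=L, mean_distance=float(mean),
        distance_histogram=hist, computed_over=computed_over,
    )


def _row_distances(row: np.ndarray, block: np.ndarray) -> np.ndarray:
    used = (row != MISSING) & (block != MISSING)
    return ((row != block) & used).sum(axis=1)


def _row_pair_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    used = (a != MISSING) & (b != MISSING)
    return ((a != b) & used).sum(axis=1)


def find_dualities(M: GenotypeMatrix, panel: Panel | list[str]) -> DualityReport:
    """All pairs of individuals identical on the panel, via hashing.

    Complete-case samples are bucketed by their panel genotype string
    (O(L*N)); any bucket with >= 2 members yields dual pairs.  A sample
    with missing panel calls is never silently matched: it is flagged
    and compared by complete-case distance against all other samples, a
    zero distance counting as a dual pair.
    """
    calls, _ = _panel_calls(M, panel)
    L = calls.shape[0]
    complete = (calls != MISSING).all(axis=1)
    buckets: dict[bytes, list[int]] = {}
    for i in np.nonzero(complete)[0]:
        buckets.setdefault(calls[i].tobytes(), []).append(int(i))
    pairs: list[tuple[int, int]] = []
    for members in buckets.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                pairs.append((members[a], members[b]))
    flagged = np.nonzero(~complete)[0]
    for i in flagged:
        d = _row_distances(calls[int(i)], calls)
        for j in np.nonzero(d == 0)[0]:
            if int(j) != int(i) and (int(i), int(j)) not in pairs and (int(j), int(i)) not in pairs:
                pairs.append((min(int(i), int(j)), max(int(i), int(j))))
    pairs = sorted(set(pairs))
    n_pairs_total = L * (L - 1) // 2
    dual_ids = sorted({i for p in pairs for i in p})
    return DualityReport(
        duality_pairs=tuple(
            (M.sample_ids[a], M.sample_ids[b]) for a, b in pairs
        ),
        pair_duality_frequency=len(pairs) / n_pairs_total if n_pairs_total else 0.0,
        individual_duality_frequency=len(dual_ids) / L if L else 0.0,
        n_individuals=L,
        flagged_missing=tuple(M.sample_ids[int(i)] for i in flagged),
    )


def compare_panels(
    M: GenotypeMatrix,
    optimized: Panel,
    random_panels: list[Panel],
    seed: int = 0,
) -> pd.DataFrame:
    """Optimized-vs-random comparison table on one population.

    One row per panel (mean distance, duality frequencies) plus a
    summary row with the random panels' mean +/- sd of mean distance.
    All panels must have the same size.
    """
    sizes = {optimized.size} | {p.size for p in random_panels}
    if len(sizes) != 1:
        raise ValueError(f"panels differ in size: {sorted(sizes)}")
    rows = []
    for label, panel in [("optimized", optimized)] + [
        (f"random_{k}", p) for k, p in enumerate(random_panels)
    ]:
        ds = mean_pairwise_distance(M, panel, panel_id=label, seed=seed)
        dr = find_dualities(M, panel)
        rows.append(
            {
                "panel": label,
                "mean_distance": ds.mean_distance,
                "pair_duality_frequency": dr.pair_duality_frequency,
                "individual_duality_frequency": dr.individual_duality_frequency,
                "n_dual_pairs": len(dr.duality_pairs),
            }
        )
    df = pd.DataFrame(rows)
    rand = df[df["panel"] != "optimized"]
    if len(rand):
        df.attrs["random_mean_distance"] = float(rand["mean_distance"].mean())
        df.attrs["random_sd_distance"] = float(rand["mean_distance"].std(ddof=1)) if len(rand) > 1 else 0.0
    return df
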