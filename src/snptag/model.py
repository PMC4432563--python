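"""Model/Results front end for panel design.

:class:`SnpPanelModel` wraps a genotype matrix (plus optional per-SNP
annotation), estimates the per-SNP entropies and the pairwise
mutual-information matrix once, and :meth:`~SnpPanelModel.fit` runs the
beam search to produce a :class:`SnpPanelResults` carrying the selected
panel, its joint-entropy bounds, per-SNP estimates, and a ``summary()``
table; evaluation on (simulated or held-out) populations hangs off the
results object.

Example
-------
>>> from snptag import SnpPanelModel, simulate
>>> pop = simulate.simulate_hwe(simulate.SimSpec((0.45,) * 40, 2000, seed=7))
>>> res = SnpPanelModel(pop).fit(panel_size=5)
>>> res.panel.size
5
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from functools import cached_property
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .entropy import MiMatrix, mi_matrix
from .evaluate import DistanceSummary, DualityReport, find_dualities, mean_pairwise_distance
from .io import GenotypeMatrix, SnpRecord
from .select import BeamConfig, Panel, random_panel, select_panel


class SnpPanelModel:
    """Panel-design model over a genotype matrix.

    Parameters
    ----------
    genotypes : GenotypeMatrix
        The (qualified) genotype data the information estimates come from.
    records : list of SnpRecord, optional
        Per-SNP annotation; required for gene-whitelist restriction, BED
        output and MAF-windowed random baselines.
    snp_subset : sequence of str, optional
        Restrict the candidate pool to these SNPs.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        records: list[SnpRecord] | None = None,
        snp_subset: Sequence[str] | None = None,
    ) -> None:
        self.genotypes = genotypes
        self.records = records
        self.snp_subset = list(snp_subset) if snp_subset is not None else None

    @classmethod
    def from_tsv(
        cls, genotype_path: str | Path, annotation_path: str | Path | None = None
    ) -> "SnpPanelModel":
        records = io.read_annotation_tsv(annotation_path) if annotation_path else None
        return cls(io.read_genotype_tsv(genotype_path), records)

    @classmethod
    def from_vcf(
        cls, vcf_path: str | Path, autosomes_only: bool = True
    ) -> "SnpPanelModel":
        region = set(io.AUTOSOMES) if autosomes_only else None
        genotypes, records = io.read_vcf(vcf_path, region_filter=region)
        return cls(genotypes, records)

    @cached_property
    def mi(self) -> MiMatrix:
        """Pairwise MI matrix (diagonal = per-SNP entropies), computed once."""
        return mi_matrix(self.genotypes, self.snp_subset)

    @property
    def entropies(self) -> pd.Series:
        return pd.Series(np.diag(self.mi.values), index=self.mi.snp_ids, name="entropy_bits")

    def fit(
        self,
        panel_size: int,
        beam_width: int = 1000,
        gene_whitelist: Sequence[str] | None = None,
    ) -> "SnpPanelResults":
        """Run the beam search and return the fitted panel results."""
        config = BeamConfig(
            panel_size=panel_size,
            beam_width=beam_width,
            gene_whitelist=frozenset(gene_whitelist) if gene_whitelist else None,
        )
        panel, beam = select_panel(self.mi, self.records, config)
        return SnpPanelResults(self, panel, beam, config)

    def random_baseline(
        self, size: int, n_panels: int = 1000, seed: int = 0,
        maf_min: float = 0.4, maf_max: float = 0.5,
    ) -> list[Panel]:
        """Random MAF-windowed panels as the intuitive comparison design."""
        if self.records is None:
            raise ValueError("random_baseline needs SnpRecords with MAF annotation")
        return [
            random_panel(self.records, size, maf_min, maf_max, seed=seed + k, mi=self.mi)
            for k in range(n_panels)
        ]


class SnpPanelResults:
    """Fitted panel: members, information estimates, diagnostics."""

    def __init__(
        self, model: SnpPanelModel, panel: Panel, beam: list[Panel], config: BeamConfig
    ) -> None:
        self.model = model
        self.panel = panel
        self.beam = beam
        self.config = config

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return self.panel.snp_ids

    @property
    def h_sum(self) -> float:
        return self.panel.h_sum

    @property
    def h_lower(self) -> float:
        return self.panel.h_lower

    @property
    def h_upper(self) -> float:
        return self.panel.h_upper

    def to_frame(self) -> pd.DataFrame:
        """Per-rank table: SNP, gene, entropy, cumulative H_L/H_U."""
        from .entropy import joint_entropy_bounds

        gene_of = {r.snp_id: r.gene for r in (self.model.records or [])}
        rows = []
        for k in range(1, self.panel.size + 1):
            prefix = self.panel.snp_ids[:k]
            b = joint_entropy_bounds(self.model.mi, prefix)
            snp = prefix[-1]
            rows.append(
                {
                    "rank": k,
                    "snp_id": snp,
                    "gene": gene_of.get(snp),
                    "entropy_bits": self.model.mi.entropy(snp),
                    "cum_h_lower": b.h_lower,
                    "cum_h_upper": b.h_upper,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary (panel, bounds, per-rank table)."""
        head = [
            "SNP panel selection (beam search on joint-entropy lower bound)",
            f"  candidates: {len(self.model.mi.snp_ids)}   panel size: {self.panel.size}"
            f"   beam width: {self.config.beam_width}",
            f"  H_sum = {self.h_sum:.4f} bits   H_L = {self.h_lower:.4f} bits"
            f"   H_U = {self.h_upper:.4f} bits",
            "",
        ]
        table = self.to_frame().to_string(
            index=False, float_format=lambda v: f"{v:.4f}"
        )
        return "\n".join(head) + table

    def evaluate(
        self, matrix: GenotypeMatrix | None = None, seed: int = 0
    ) -> tuple[DistanceSummary, DualityReport]:
        """Mean pairwise Hamming distance and duality report for the panel,
        on ``matrix`` (default: the model's own genotypes)."""
        M = matrix if matrix is not None else self.model.genotypes
        return (
            mean_pairwise_distance(M, self.panel, panel_id="fitted", seed=seed),
            find_dualities(M, self.panel),
        )

    def to_bed(self, path: str | Path) -> None:
        if self.model.records is None:
            raise ValueError("BED output needs SnpRecords")
        io.write_panel_bed(self.panel.snp_ids, self.model.records, path)
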