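"""Genotype matrices, per-SNP annotation records, and file formats.

Diploid genotypes at biallelic SNVs are coded on a three-state scale:

* ``0`` — homozygous wild-type (reference)
* ``1`` — heterozygous
* ``2`` — homozygous mutant (alternate)
* :data:`MISSING` (``-1``) — no call

Every downstream computation (entropy, mutual information, Hamming
distance) only needs this three-way partition, so ref/alt orientation
never changes a result.  Missing calls are carried explicitly and are
never imputed; consumers exclude them pairwise or per SNP.

Formats handled here: VCF 4.x (GT field only, via cyvcf2), a plain TSV
genotype dialect (rows = SNPs, columns = samples, cells 0/1/2/NA), BED4
panel output, and an annotation TSV with the per-SNP scores the
qualification filters need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

#: Autosomal chromosome names (optionally "chr"-prefixed forms accepted on input).
AUTOSOMES = frozenset(str(c) for c in range(1, 23))


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed."""


class EmptyInputError(ValueError):
    """No usable records were found in an input file."""


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls on the 0/1/2/missing coding.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row.
    snp_ids : list of str
        Unique SNP identifiers, one per column.
    calls : ndarray of int8, shape (n_samples, n_snps)
        Genotype codes; every entry is 0, 1, 2 or :data:`MISSING`.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate snp_ids")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.calls[~valid][0]
            raise ValueError(f"invalid genotype code {bad}; expected 0/1/2/{MISSING}")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_column(self, snp_id: str) -> np.ndarray:
        """Calls for one SNP across all samples (missing included)."""
        try:
            return self.calls[:, self._snp_index[snp_id]]
        except KeyError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._snp_index[s] for s in snp_ids]
        return GenotypeMatrix(list(self.sample_ids), list(snp_ids), self.calls[:, idx])

    def maf(self, snp_id: str) -> float:
        """Minor-allele frequency recomputed from non-missing calls."""
        g = self.snp_column(snp_id)
        g = g[g != MISSING]
        if g.size == 0:
            return float("nan")
        alt = (g.sum()) / (2 * g.size)
        return float(min(alt, 1.0 - alt))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class SnpRecord:
    """Per-SNP annotation used by qualification filters and panel selection.

    ``maf`` is the minor-allele frequency (<= 0.5); ``gc_content`` the local
    GC fraction around the locus; ``mappability`` the short-read alignment
    uniqueness score (1 means unambiguous).
    """

    snp_id: str
    chrom: str
    pos: int
    ref: str = "N"
    alt: str = "N"
    gene: str | None = None
    maf: float = float("nan")
    gc_content: float = float("nan")
    mappability: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1 (got {self.pos})")
        if not np.isnan(self.maf) and not 0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        for name in ("gc_content", "mappability"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0 <= v <= 1:
                raise ValueError(f"{self.snp_id}: {name} {v} outside [0, 1]")

    @property
    def is_autosomal(self) -> bool:
        return _norm_chrom(self.chrom) in AUTOSOMES


def read_vcf(
    path: str | Path, region_filter: set[str] | None = None
) -> tuple[GenotypeMatrix, list[SnpRecord]]:
    """Read biallelic SNVs with GT fields from a VCF into a genotype matrix.

    Multi-allelic records and indels are skipped (with a logged count);
    phased and unphased separators are treated identically; any partial or
    absent call becomes :data:`MISSING`.  ``region_filter``, when given,
    keeps only records on the named chromosomes (compared without a "chr"
    prefix).  MAF is recomputed from the non-missing calls.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise GenotypeParseError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    norm_filter = {_norm_chrom(c) for c in region_filter} if region_filter else None
    rows: list[np.ndarray] = []
    snp_ids: list[str] = []
    records: list[SnpRecord] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom = _norm_chrom(var.CHROM)
        if norm_filter is not None and chrom not in norm_filter:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        calls = np.full(gt.shape, MISSING, dtype=np.int8)
        calls[gt == 0] = 0
        calls[gt == 1] = 1
        calls[gt == 3] = 2
        snp_id = var.ID or f"{chrom}:{var.POS}:{var.REF}:{var.ALT[0]}"
        obs = calls[calls != MISSING]
        if obs.size:
            alt_freq = obs.sum() / (2 * obs.size)
            maf = min(alt_freq, 1 - alt_freq)
        else:
            maf = float("nan")
        rows.append(calls)
        snp_ids.append(snp_id)
        records.append(
            SnpRecord(snp_id=snp_id, chrom=chrom, pos=var.POS, ref=var.REF,
                      alt=var.ALT[0], maf=float(maf))
        )
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/indel records", n_skipped)
    if not snp_ids:
        raise EmptyInputError(f"no usable biallelic SNV records in {path}")
    calls = np.stack(rows, axis=1)
    return GenotypeMatrix(sample_ids, snp_ids, calls), records


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the TSV genotype dialect: header = sample ids, rows = SNPs."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln and not ln.startswith("#")]
    if not lines:
        raise EmptyInputError(f"{path}: empty genotype TSV")
    header = lines[0].split("\t")
    sample_ids = header[1:]
    snp_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        snp_ids.append(cells[0])
        row = []
        for col, cell in enumerate(cells[1:], start=2):
            if cell == "NA":
                row.append(MISSING)
            elif cell in ("0", "1", "2"):
                row.append(int(cell))
            else:
                raise GenotypeParseError(
                    f"{path}:{lineno}: column {col}: invalid cell {cell!r}"
                )
        rows.append(row)
    calls = np.asarray(rows, dtype=np.int8).T
    return GenotypeMatrix(sample_ids, snp_ids, calls)


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV genotype dialect; round-trips with :func:`read_genotype_tsv`."""
    with Path(path).open("w") as fh:
        fh.write("snp_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for j, snp in enumerate(matrix.snp_ids):
            cells = ["NA" if g == MISSING else str(int(g)) for g in matrix.calls[:, j]]
            fh.write(snp + "\t" + "\t".join(cells) + "\n")


def write_panel_bed(
    panel_snp_ids: Iterable[str],
    records: Iterable[SnpRecord] | dict[str, SnpRecord],
    path: str | Path,
) -> None:
    """Write panel SNPs as BED4 (0-based half-open), one line per SNP in panel order."""
    if not isinstance(records, dict):
        records = {r.snp_id: r for r in records}
    with Path(path).open("w") as fh:
        for snp_id in panel_snp_ids:
            try:
                rec = records[snp_id]
            except KeyError:
                raise KeyError(f"no SnpRecord for panel SNP {snp_id!r}") from None
            fh.write(f"{rec.chrom}\t{rec.pos - 1}\t{rec.pos}\t{rec.snp_id}\n")


_ANNOT_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "gene",
                  "maf", "gc_content", "mappability"]


def read_annotation_tsv(path: str | Path) -> list[SnpRecord]:
    """Read the per-SNP annotation table (snp_id/chrom/pos/ref/alt/gene/maf/gc_content/mappability)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    missing_cols = {"snp_id", "chrom", "pos"} - set(df.columns)
    if missing_cols:
        raise GenotypeParseError(f"{path}: missing columns {sorted(missing_cols)}")
    records = []
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene", None)
        if isinstance(gene, float) and np.isnan(gene):
            gene = None
        records.append(
            SnpRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(getattr(row, "ref", "N")),
                alt=str(getattr(row, "alt", "N")),
                gene=gene,
                maf=float(getattr(row, "maf", float("nan"))),
                gc_content=float(getattr(row, "gc_content", float("nan"))),
                mappability=float(getattr(row, "mappability", float("nan"))),
            )
        )
    return records


def write_annotation_tsv(records: Iterable[SnpRecord], path: str | Path) -> None:
    rows = [
        {
            "snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos, "ref": r.ref,
            "alt": r.alt, "gene": "" if r.gene is None else r.gene,
            "maf": r.maf, "gc_content": r.gc_content, "mappability": r.mappability,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ANNOT_COLUMNS).to_csv(path, sep="\t", index=False)
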