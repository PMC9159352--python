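"""Readers/writers for the standard formats the pipeline touches.

Internal conventions
--------------------
* Coordinates are 0-based half-open everywhere inside the package; VCF and
  GFF3 boundaries are converted at the edges (BED already matches).
* Only biallelic SNP records are kept; multiallelic or indel records are
  dropped (not split) and counted.
* Ploidy is fixed at 2: a :class:`HaplotypePanel` has two haplotype rows per
  diploid sample, ordered ``sampleA_hap1, sampleA_hap2, sampleB_hap1, ...``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing allele/dosage in integer matrices


class PhasingError(ValueError):
    """Raised when phased haplotypes were required but the VCF is unphased."""


class FormatError(ValueError):
    """Raised on malformed input records."""


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype matrix with site and sample metadata.

    Attributes
    ----------
    chrom : str
        Chromosome name (single-chromosome panels; multi-chromosome input is
        handled by one panel per chromosome).
    positions : ndarray of int
        1-based bp positions, strictly increasing.
    ref_allele, alt_allele : ndarray of str
        Single-base alleles per site.
    haplotypes : ndarray of int8, shape (2 * n_samples, n_sites)
        0 = reference allele, 1 = alternate.  When ``phased`` is False,
        entries may be :data:`MISSING`.
    sample_ids : list of str
    breed : list of str
        Per-sample population label ("" when unknown).
    """

    chrom: str
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    haplotypes: np.ndarray
    sample_ids: list[str]
    breed: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.haplotypes.ndim != 2:
            raise FormatError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise FormatError(
                f"haplotype rows ({self.haplotypes.shape[0]}) != "
                f"2 x samples ({len(self.sample_ids)})"
            )
        if len(self.breed) != len(self.sample_ids):
            raise FormatError("breed labels must match sample count")
        if self.haplotypes.shape[1] != len(self.positions):
            raise FormatError("haplotype columns != number of positions")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise FormatError("positions must be strictly increasing")
        allowed = {0, 1} if self.phased else {0, 1, MISSING}
        present = set(np.unique(self.haplotypes).tolist()) if self.haplotypes.size else set()
        if not present <= allowed:
            raise FormatError(f"illegal haplotype entries: {present - allowed}")

    # -- derived views --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_rows(self, sample_indices: np.ndarray | list[int]) -> np.ndarray:
        """Haplotype row indices for the given sample indices."""
        idx = np.asarray(sample_indices, dtype=np.int64)
        return np.stack([2 * idx, 2 * idx + 1], axis=1).reshape(-1)

    def subset_samples(self, sample_indices) -> "HaplotypePanel":
        idx = np.asarray(sample_indices, dtype=np.int64)
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            haplotypes=self.haplotypes[self.sample_rows(idx)].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            breed=[self.breed[i] for i in idx],
            phased=self.phased,
        )

    def subset_sites(self, site_indices) -> "HaplotypePanel":
        idx = np.asarray(site_indices, dtype=np.int64)
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            haplotypes=self.haplotypes[:, idx].copy(),
            sample_ids=list(self.sample_ids),
            breed=list(self.breed),
            phased=self.phased,
        )

    def to_genotype_matrix(self) -> "GenotypeMatrix":
        h = self.haplotypes
        a, b = h[0::2], h[1::2]
        dosage = (a + b).astype(np.int8)
        dosage[(a == MISSING) | (b == MISSING)] = MISSING
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            dosage=dosage,
            sample_ids=list(self.sample_ids),
            breed=list(self.breed),
        )


@dataclass
class GenotypeMatrix:
    """Per-sample alt-allele dosage in {0, 1, 2, MISSING} (samples x sites)."""

    chrom: str
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    dosage: np.ndarray
    sample_ids: list[str]
    breed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), len(self.positions)):
            raise FormatError("dosage shape must be (n_samples, n_sites)")
        if not self.breed:
            self.breed = [""] * len(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def subset_sites(self, site_indices) -> "GenotypeMatrix":
        idx = np.asarray(site_indices, dtype=np.int64)
        return GenotypeMatrix(
            chrom=self.chrom,
            positions=self.positions[idx],
            ref_allele=np.asarray(self.ref_allele, dtype=object)[idx],
            alt_allele=np.asarray(self.alt_allele, dtype=object)[idx],
            dosage=self.dosage[:, idx].copy(),
            sample_ids=list(self.sample_ids),
            breed=list(self.breed),
        )


@dataclass
class PhenotypeTable:
    """Per-sow gestation-length records (days) with per-sample means.

    ``records[i]`` lists the recorded gestation lengths (one per parity) of
    ``sample_ids[i]``; ``mean_gl[i]`` is their arithmetic mean.  Reference
    breeds reported only as a breed average carry a single pseudo-record.
    """

    sample_ids: list[str]
    breeds: list[str]
    records: list[list[float]]
    mean_gl: np.ndarray

    def __post_init__(self) -> None:
        self.mean_gl = np.asarray(self.mean_gl, dtype=float)
        for i, recs in enumerate(self.records):
            if recs and not np.isclose(self.mean_gl[i], float(np.mean(recs))):
                raise FormatError(f"mean_gl inconsistent for {self.sample_ids[i]}")

    @property
    def n_records(self) -> int:
        return sum(len(r) for r in self.records)

    def samples_of_breed(self, breed: str) -> list[str]:
        return [s for s, b in zip(self.sample_ids, self.breeds) if b == breed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "breed": self.breeds, "mean_gl": self.mean_gl}
        )


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval, 0-based half-open."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"gene {self.gene_id}: start must be < end")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str, require_phased: bool = True,
             breeds: dict[str, str] | None = None) -> HaplotypePanel:
    """Load a (phased) multi-sample VCF into a :class:`HaplotypePanel`.

    Non-biallelic and non-SNP records are dropped with a logged count.  With
    ``require_phased``, any unphased or missing genotype raises
    :class:`PhasingError` naming the first offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    chrom = None
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1 \
                or var.REF not in "ACGT" or var.ALT[0] not in "ACGT":
            n_dropped += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise FormatError(
                f"multiple chromosomes in one VCF ({chrom}, {var.CHROM}); "
                "load per-chromosome panels"
            )
        gts = var.genotypes  # [[a0, a1, phased], ...]
        if len(gts) != len(sample_ids):
            raise FormatError(
                f"record {var.CHROM}:{var.POS}: {len(gts)} genotypes for "
                f"{len(sample_ids)} header samples"
            )
        col = np.empty(2 * len(sample_ids), dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1, is_phased = g[0], g[1], bool(g[-1])
            missing = a0 < 0 or a1 < 0
            if require_phased and (missing or not is_phased):
                raise PhasingError(
                    f"unphased or missing genotype for sample "
                    f"{sample_ids[i]} at {var.CHROM}:{var.POS}"
                )
            col[2 * i] = MISSING if a0 < 0 else a0
            col[2 * i + 1] = MISSING if a1 < 0 else a1
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        columns.append(col)
    vcf.close()
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    hap = (np.stack(columns, axis=1) if columns
           else np.empty((2 * len(sample_ids), 0), dtype=np.int8))
    breeds = breeds or {}
    return HaplotypePanel(
        chrom=chrom if chrom is not None else "unknown",
        positions=np.asarray(positions, dtype=np.int64),
        ref_allele=np.asarray(refs, dtype=object),
        alt_allele=np.asarray(alts, dtype=object),
        haplotypes=hap,
        sample_ids=sample_ids,
        breed=[breeds.get(s, "") for s in sample_ids],
        phased=require_phased,
    )


def write_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write a phased panel as uncompressed VCF 4.2.

    Round-trip contract: ``read_vcf(write_vcf(panel))`` reproduces positions,
    alleles and haplotypes exactly.
    """
    max_pos = int(panel.positions[-1]) + 1 if panel.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={max_pos}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        h = panel.haplotypes
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t.\t{panel.ref_allele[j]}\t"
                f"{panel.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path: str) -> PhenotypeTable:
    """Load a TSV of gestation-length records.

    Two layouts are accepted: ``sample_id  breed  gestation_length`` with one
    row per parity record, or ``sample_id  breed  mean_gl`` for breeds known
    only by their reported average.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "breed": str})
    if "gestation_length" in df.columns:
        value_col = "gestation_length"
    elif "mean_gl" in df.columns:
        value_col = "mean_gl"
    else:
        raise FormatError(
            "phenotype TSV needs a 'gestation_length' or 'mean_gl' column"
        )
    vals = pd.to_numeric(df[value_col], errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2  # 1-based + header
        raise FormatError(f"non-numeric {value_col} at line {row} of {path}")
    df = df.assign(_val=vals)
    dup = df.duplicated(subset=["sample_id", "_val"], keep=False)
    if value_col == "gestation_length" and dup.any():
        warnings.warn("duplicate (sample, gestation_length) rows kept as distinct parities")
    sample_ids: list[str] = []
    breeds: list[str] = []
    records: list[list[float]] = []
    means: list[float] = []
    for sid, grp in df.groupby("sample_id", sort=False):
        sample_ids.append(str(sid))
        breeds.append(str(grp["breed"].iloc[0]))
        recs = [float(v) for v in grp["_val"]]
        records.append(recs)
        means.append(float(np.mean(recs)))
    return PhenotypeTable(sample_ids, breeds, records, np.asarray(means))


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_genes(path: str, dialect: str = "BED") -> list[GeneFeature]:
    """Load gene intervals from BED4+ or GFF3 into 0-based half-open features.

    BED is already 0-based half-open; GFF3 is 1-based inclusive, so GFF3
    starts are decremented by one.  Records whose interval is empty after
    normalisation are rejected with a warning.
    """
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "BED":
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: BED4+ requires 4 columns")
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "unknown"
                gene_id = symbol = name
            else:
                if len(fields) < 9:
                    continue
                if fields[2] != "gene":
                    continue
                chrom = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])
                strand = fields[6] if fields[6] in "+-" else "unknown"
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID", f"gene{lineno}")
                symbol = attrs.get("Name", attrs.get("gene_name", gene_id))
            if end <= start:
                warnings.warn(f"{path}:{lineno}: empty interval rejected")
                continue
            genes.append(GeneFeature(gene_id, symbol, chrom, start, end, strand))
    return genes


def read_gene_list(path: str) -> set[str]:
    """Newline-delimited gene symbols (dbPTB-style known-gene list)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
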