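"""Site and sample quality filters for the SNP panel.

Filters follow the conventional resequencing defaults: minor allele
frequency > 0.05, SNP call rate > 0.90, exact Hardy-Weinberg p > 1e-6, and a
per-individual missingness flag at >= 0.10.  All thresholds are strict
inequalities; boundary values fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class SiteQCReport:
    """Per-site QC metrics over all input sites (kept and removed)."""

    maf: np.ndarray        # minor allele frequency in [0, 0.5]
    call_rate: np.ndarray  # fraction of non-missing genotypes
    hwe_p: np.ndarray      # exact HWE p-value in (0, 1]
    passed: np.ndarray     # boolean

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"maf": self.maf, "call_rate": self.call_rate,
             "hwe_p": self.hwe_p, "pass": self.passed}
        )


def site_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency of one site from {0,1,2,MISSING} dosages."""
    d = np.asarray(dosages)
    ok = d != MISSING
    if not ok.any():
        raise ValueError("site has no called genotypes; MAF undefined")
    alt = float(d[ok].sum()) / (2.0 * ok.sum())
    return min(alt, 1.0 - alt)


def hwe_exact_p(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact two-sided Hardy-Weinberg p-value from genotype counts.

    Sums, over all heterozygote counts attainable for the observed allele
    counts, the conditional probabilities that do not exceed the observed
    configuration's probability (no mid-p correction).  Probabilities are
    built by the standard ratio recurrence from the modal heterozygote count,
    which stays accurate where direct factorials overflow.
    """
    if min(n_aa_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n_rare = 2 * min(n_aa_hom1, n_hom2) + n_het  # rare-allele copies
    if n_rare == 0:
        return 1.0

    # attainable het counts share parity with n_rare
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)
    hets = np.arange(het_min, het_max + 1, 2)

    # unnormalised probabilities via P(h+2)/P(h) = 4*hom1(h)*hom2(h) / ((h+2)(h+1))
    probs = np.empty(len(hets), dtype=float)
    mid_idx = len(hets) // 2
    probs[mid_idx] = 1.0
    for k in range(mid_idx, len(hets) - 1):
        h = hets[k]
        hom1 = (n_rare - h) // 2
        hom2 = n - h - hom1
        probs[k + 1] = probs[k] * 4.0 * hom1 * hom2 / ((h + 2.0) * (h + 1.0))
    for k in range(mid_idx, 0, -1):
        h = hets[k]
        hom1 = (n_rare - h) // 2
        hom2 = n - h - hom1
        probs[k - 1] = probs[k] * h * (h - 1.0) / (4.0 * (hom1 + 1.0) * (hom2 + 1.0))
    probs /= probs.sum()

    obs = np.flatnonzero(hets == n_het)
    if len(obs) == 0:  # impossible configuration for these allele counts
        raise ValueError("heterozygote count incompatible with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _site_metrics(matrix: GenotypeMatrix) -> SiteQCReport:
    d = matrix.dosage
    called = d != MISSING
    n_called = called.sum(axis=0)
    call_rate = n_called / matrix.n_samples if matrix.n_samples else n_called * 0.0
    maf = np.zeros(matrix.n_sites)
    hwe_p = np.ones(matrix.n_sites)
    for j in range(matrix.n_sites):
        col = d[called[:, j], j]
        if len(col) == 0:
            maf[j] = np.nan
            hwe_p[j] = np.nan
            continue
        alt = col.sum() / (2.0 * len(col))
        maf[j] = min(alt, 1.0 - alt)
        n_het = int((col == 1).sum())
        hwe_p[j] = hwe_exact_p(int((col == 0).sum()), n_het, int((col == 2).sum()))
    return SiteQCReport(maf=maf, call_rate=np.asarray(call_rate, dtype=float),
                        hwe_p=hwe_p, passed=np.zeros(matrix.n_sites, dtype=bool))


def apply_site_filters(
    matrix: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, SiteQCReport]:
    """Retain sites with MAF > maf_min, call rate > call_rate_min and exact
    HWE p > hwe_alpha (all strict).  The report covers every input site."""
    report = _site_metrics(matrix)
    with np.errstate(invalid="ignore"):
        report.passed = (
            (report.maf > maf_min)
            & (report.call_rate > call_rate_min)
            & (report.hwe_p > hwe_alpha)
        )
    report.passed &= ~np.isnan(report.maf)
    kept = np.flatnonzero(report.passed)
    return matrix.subset_sites(kept), report


def sample_missing_rates(
    matrix: GenotypeMatrix, flag_at: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample missing-genotype fraction and a >= flag_at advisory flag.

    Flags are advisory: downstream haplotype statistics run on phased,
    complete panels, so sample removal is left to the caller/CLI.
    """
    if matrix.n_sites == 0:
        rates = np.zeros(matrix.n_samples)
    else:
        rates = (matrix.dosage == MISSING).mean(axis=1)
    return rates, rates >= flag_at
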