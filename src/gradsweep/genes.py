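"""Gene-level integration: interval annotation, a simple DE test, the
gestational-stage exclusion set logic, and the known-gene overlap.

The differential-expression engine here is an explicitly simple stand-in
for a negative-binomial model: median-of-ratios size factors, a two-sided
pooled-variance t-test on log2(normalised count + 1), and
Benjamini-Hochberg adjustment.  (A Welch test is unusable at the n = 3
design this emulates: the Satterthwaite degrees of freedom collapse toward
2, putting a floor on attainable p-values above the stringent adjusted
threshold however large the effect; pooling the two group variances keeps
the full 2(n-1) degrees of freedom, as small-n expression tests
conventionally do.)  The pipeline equally accepts externally produced per-gene
(log2fc, padj) tables, so a full DESeq2-style analysis can be slotted in;
the contribution here is the set logic that separates breed-specific from
gestational-stage genes and the overlap with a curated birth-timing gene
catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GeneFeature
from .popgen import Window


# ---------------------------------------------------------------------------
# Interval annotation
# ---------------------------------------------------------------------------

def annotate_windows(windows, genes: list[GeneFeature]) -> set[str]:
    """Symbols of genes intersecting any candidate window (half-open, >=1 bp)."""
    out: set[str] = set()
    for g in genes:
        for w in windows:
            chrom = w.chrom if isinstance(w, Window) else w[0]
            start = w.start if isinstance(w, Window) else w[1]
            end = w.end if isinstance(w, Window) else w[2]
            if g.chrom == chrom and g.start < end and start < g.end:
                out.add(g.symbol)
                break
    return out


def annotate_snps(
    snps: list[tuple[str, int]], genes: list[GeneFeature], flank_bp: int = 10_000
) -> set[str]:
    """Genes containing a SNP or with a boundary within ``flank_bp`` of one.

    ``snps`` are (chrom, 1-based position); all genes within reach are
    reported (no nearest-only rule).
    """
    out: set[str] = set()
    for g in genes:
        for chrom, pos in snps:
            if chrom != g.chrom:
                continue
            coord = pos - 1  # 0-based
            if g.start <= coord < g.end:
                out.add(g.symbol)
                break
            dist = g.start - coord if coord < g.start else coord - (g.end - 1)
            if dist <= flank_bp:
                out.add(g.symbol)
                break
    return out


# ---------------------------------------------------------------------------
# Differential expression stand-in
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference.

    Genes with any zero count are excluded from the median, as in the
    standard median-of-ratios normalisation.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)  # per-gene log geometric mean
    usable = counts.gt(0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has all-positive counts; size factors undefined")
    log_ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(log_ratios.median(axis=0))


def simple_de(
    counts: pd.DataFrame,
    groups: dict[str, str] | pd.Series,
    contrast: tuple[str, str],
    label: str | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change and BH-adjusted t-test p-values.

    ``counts`` is genes x samples with non-negative integers; ``groups``
    maps sample -> group label; ``contrast`` = (reference, treatment): the
    log2fc is treatment over reference on normalised means (+0.5 offset).
    All-zero genes get log2fc 0 and p = 1.
    """
    from statsmodels.stats.multitest import multipletests

    groups = pd.Series(groups)
    ref_samples = groups.index[groups == contrast[0]].tolist()
    trt_samples = groups.index[groups == contrast[1]].tolist()
    if len(ref_samples) < 2 or len(trt_samples) < 2:
        raise ValueError("each group in the contrast needs >= 2 samples")
    sub = counts[ref_samples + trt_samples]
    sf = size_factors(sub)
    norm = sub / sf
    mean_ref = norm[ref_samples].mean(axis=1)
    mean_trt = norm[trt_samples].mean(axis=1)
    log2fc = np.log2((mean_trt + 0.5) / (mean_ref + 0.5))
    logn = np.log2(norm + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(
            logn[trt_samples], logn[ref_samples], axis=1, equal_var=True
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    all_zero = sub.sum(axis=1) == 0
    log2fc[all_zero] = 0.0
    pvals[all_zero.to_numpy()] = 1.0
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": counts.index,
            "contrast": label or f"{contrast[1]}_vs_{contrast[0]}",
            "log2fc": log2fc.to_numpy(),
            "pvalue": pvals,
            "padj": padj,
        }
    ).set_index("gene")


def de_call(table: pd.DataFrame, fc_min: float = 2.0, alpha: float = 0.001) -> set[str]:
    """Genes with \\|log2fc\\| > log2(fc_min) and padj < alpha (both strict)."""
    lfc_min = np.log2(fc_min)
    hit = (table["log2fc"].abs() > lfc_min) & (table["padj"] < alpha)
    return set(table.index[hit])


# ---------------------------------------------------------------------------
# Set logic
# ---------------------------------------------------------------------------

def stage_exclusion(
    breed_contrast_sets: dict[str, set[str]],
    stage_contrast_sets: list[set[str]],
) -> tuple[dict[str, set[str]], set[str]]:
    """Remove gestational-stage genes from breed-contrast DE sets.

    ``stage_contrast_sets`` are the within-breed late-pregnancy-vs-
    parturition DE sets; their union is attributed to gestational age and
    subtracted from each breed-contrast set.  Returns the per-stage
    trait-specific sets and their union.
    """
    stage_genes: set[str] = set().union(*stage_contrast_sets) if stage_contrast_sets else set()
    per_stage = {k: s - stage_genes for k, s in breed_contrast_sets.items()}
    final: set[str] = set().union(*per_stage.values()) if per_stage else set()
    assert not final & stage_genes
    return per_stage, final


@dataclass
class CandidateSets:
    """Three-way candidate comparison with disjoint Venn region counts."""

    sweep_genes: set[str]
    de_genes: set[str]
    known_genes: set[str]
    venn: dict[str, int]
    known_overlap: set[str]  # (sweep | de) & known


def _normalise(symbols, name: str) -> set[str]:
    symbols = list(symbols)
    upper = [s.upper() for s in symbols]
    if len(set(upper)) < len(upper):
        warnings.warn(f"duplicate symbols in {name} collapsed (case-insensitive)")
    return set(upper)


def known_gene_venn(sweep_genes, de_genes, known_genes) -> CandidateSets:
    """7-region Venn of sweep, DE and known-gene sets (case-insensitive).

    The headline overlap is (sweep union DE) intersect known: candidate
    genes already reported in the birth-timing catalog.
    """
    s = _normalise(sweep_genes, "sweep_genes")
    d = _normalise(de_genes, "de_genes")
    k = _normalise(known_genes, "known_genes")
    venn = {
        "sweep_only": len(s - d - k),
        "de_only": len(d - s - k),
        "known_only": len(k - s - d),
        "sweep&de": len((s & d) - k),
        "sweep&known": len((s & k) - d),
        "de&known": len((d & k) - s),
        "all_three": len(s & d & k),
    }
    return CandidateSets(
        sweep_genes=s,
        de_genes=d,
        known_genes=k,
        venn=venn,
        known_overlap=(s | d) & k,
    )
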