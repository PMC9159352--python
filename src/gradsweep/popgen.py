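"""Windowed nucleotide diversity, pi ratios and Weir-Cockerham F_ST.

All windowed statistics use non-overlapping 10-kb tiles (window = step) over
0-based half-open coordinates.  Window diversity is the sum of per-site
heterozygosities divided by the window span in bp (not the SNP count), so
empty windows have pi = 0.  The windowed F_ST is the weighted ratio-of-sums
estimator sum(a) / sum(a + b + c); negative per-site components are kept in
the sums rather than truncated at zero, which would bias windowed values
upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import HaplotypePanel


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int    # exclusive

    @property
    def span(self) -> int:
        return self.end - self.start


def make_windows(chrom: str, length: int, span: int = 10_000) -> list[Window]:
    """Tile [0, length) with non-overlapping windows of ``span`` bp.

    The final window is clipped at ``length``, keeping full coverage.
    """
    if span <= 0:
        raise ValueError("window span must be positive")
    return [Window(chrom, s, min(s + span, length)) for s in range(0, length, span)]


def _window_index(positions: np.ndarray, windows: list[Window]) -> np.ndarray:
    """Window index per site (-1 when outside all windows).

    Positions are 1-based bp; a site at 1-based position p occupies the
    0-based coordinate p - 1, so it belongs to windows with start <= p-1 < end.
    """
    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    coord = positions - 1
    idx = np.searchsorted(starts, coord, side="right") - 1
    idx[idx < 0] = -1
    inside = (idx >= 0) & (coord < ends[np.clip(idx, 0, None)])
    idx[~inside] = -1
    return idx


def site_pi(alt_count: int | np.ndarray, hap_count: int) -> float | np.ndarray:
    """Per-site diversity: mean pairwise difference 2c(n-c) / (n(n-1))."""
    n = hap_count
    if n < 2:
        raise ValueError("need at least 2 haplotypes for pairwise diversity")
    c = np.asarray(alt_count, dtype=float)
    out = 2.0 * c * (n - c) / (n * (n - 1.0))
    return float(out) if out.ndim == 0 else out


def window_pi(
    panel: HaplotypePanel,
    sample_indices,
    windows: list[Window],
) -> tuple[np.ndarray, np.ndarray]:
    """Diversity per bp and SNP count for each window over a sample subset."""
    rows = panel.sample_rows(sample_indices)
    if len(rows) < 2:
        raise ValueError("subset must contain at least one diploid sample")
    h = panel.haplotypes[rows]
    n = h.shape[0]
    per_site = site_pi(h.sum(axis=0), n)
    widx = _window_index(panel.positions, windows)
    pi = np.zeros(len(windows))
    n_snps = np.zeros(len(windows), dtype=int)
    ok = widx >= 0
    np.add.at(pi, widx[ok], per_site[ok])
    np.add.at(n_snps, widx[ok], 1)
    spans = np.array([w.span for w in windows], dtype=float)
    return pi / spans, n_snps


def pi_ratio_signal(
    pi_focal: np.ndarray,
    pi_ref: np.ndarray,
    mode: str = "two_tailed_abs_log",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn a pair of windowed diversities into a ranking signal.

    Returns ``(signal, sign, valid)``.  Windows with pi_ref = 0 are invalid
    (undefined ratio) and excluded from ranking.  pi_focal = 0 with positive
    pi_ref yields +inf signal (complete loss of diversity in the focal
    group), ranked above all finite values.

    mode 'two_tailed_abs_log': signal = \\|log10(pi_focal / pi_ref)\\| with the
    log-ratio sign kept as metadata (negative = diversity reduced in focal).
    mode 'low_tail': signal = -log10(pi_focal / pi_ref), i.e. large when the
    focal group has lost diversity.
    """
    pi_focal = np.asarray(pi_focal, dtype=float)
    pi_ref = np.asarray(pi_ref, dtype=float)
    valid = pi_ref > 0
    signal = np.full(pi_focal.shape, np.nan)
    sign = np.zeros(pi_focal.shape)
    with np.errstate(divide="ignore"):
        log_ratio = np.where(valid, np.log10(
            np.where(valid, pi_focal, 1.0) / np.where(valid, pi_ref, 1.0)), np.nan)
    if mode == "two_tailed_abs_log":
        signal[valid] = np.abs(log_ratio[valid])
        sign[valid] = np.sign(log_ratio[valid])
        sign[valid & (pi_focal == 0)] = -1.0
    elif mode == "low_tail":
        signal[valid] = -log_ratio[valid]
        sign[valid] = -np.sign(log_ratio[valid])
    else:
        raise ValueError(f"unknown pi-ratio mode {mode!r}")
    return signal, sign, valid


def wc_fst_site(
    counts1: tuple[int, int, int], counts2: tuple[int, int, int]
) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components for one biallelic site.

    ``counts*`` are (hom-ref, het, hom-alt) genotype counts in each
    population.  Returns (a, b, c): among-population, among-individual and
    within-individual components, using observed heterozygosity.  The site
    estimate is a / (a + b + c) when the denominator is positive.
    """
    n1 = sum(counts1)
    n2 = sum(counts2)
    if n1 < 1 or n2 < 1:
        raise ValueError("each population needs at least one genotyped individual")
    nbar = (n1 + n2) / 2.0
    if nbar <= 1.0:
        raise ValueError("Weir-Cockerham components undefined for nbar <= 1")
    ntot = n1 + n2
    nc = ntot - (n1 * n1 + n2 * n2) / ntot  # r=2: (r*nbar - sum n^2/(r*nbar))/(r-1)
    p1 = (counts1[1] + 2 * counts1[2]) / (2.0 * n1)
    p2 = (counts2[1] + 2 * counts2[2]) / (2.0 * n2)
    h1 = counts1[1] / n1
    h2 = counts2[1] / n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # (r-1)=1
    hbar = (n1 * h1 + n2 * h2) / ntot
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - s2 / 2.0 - hbar * (2 * nbar - 1) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def _genotype_counts(panel: HaplotypePanel, sample_indices) -> np.ndarray:
    """(3, n_sites) genotype counts (hom-ref, het, hom-alt) for a subset."""
    rows = panel.sample_rows(sample_indices)
    h = panel.haplotypes[rows]
    dos = h[0::2] + h[1::2]
    return np.stack([(dos == k).sum(axis=0) for k in (0, 1, 2)])


def window_fst(
    panel: HaplotypePanel,
    pop1_indices,
    pop2_indices,
    windows: list[Window],
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed weighted F_ST: sum(a) / sum(a+b+c) over in-window sites.

    Returns (fst, n_used) where n_used counts sites contributing a nonzero
    denominator; windows with no usable site get NaN (excluded from ranking).
    """
    g1 = _genotype_counts(panel, pop1_indices)
    g2 = _genotype_counts(panel, pop2_indices)
    n1 = g1.sum(axis=0).astype(float)
    n2 = g2.sum(axis=0).astype(float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("both populations must be fully genotyped at every site")
    nbar = (n1 + n2) / 2.0
    ntot = n1 + n2
    nc = ntot - (n1 * n1 + n2 * n2) / ntot
    p1 = (g1[1] + 2 * g1[2]) / (2 * n1)
    p2 = (g2[1] + 2 * g2[2]) / (2 * n2)
    h1 = g1[1] / n1
    h2 = g2[1] / n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
    hbar = (n1 * h1 + n2 * h2) / ntot
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2 - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2.0
    denom_site = a + b + c
    widx = _window_index(panel.positions, windows)
    num = np.zeros(len(windows))
    den = np.zeros(len(windows))
    used = np.zeros(len(windows), dtype=int)
    ok = widx >= 0
    np.add.at(num, widx[ok], a[ok])
    np.add.at(den, widx[ok], denom_site[ok])
    np.add.at(used, widx[ok], (denom_site[ok] != 0).astype(int))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den != 0, num / den, np.nan)
    fst[used == 0] = np.nan
    return fst, used


def window_table(
    panel: HaplotypePanel,
    focal_indices,
    ref_indices,
    windows: list[Window],
    pi_mode: str = "two_tailed_abs_log",
) -> pd.DataFrame:
    """One row per window: pi in both groups, ratio signal, and F_ST."""
    pi_f, n_snps = window_pi(panel, focal_indices, windows)
    pi_r, _ = window_pi(panel, ref_indices, windows)
    signal, sign, valid = pi_ratio_signal(pi_f, pi_r, mode=pi_mode)
    fst, used = window_fst(panel, focal_indices, ref_indices, windows)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi_r > 0, pi_f / pi_r, np.nan)
        log10_ratio = np.where((pi_r > 0) & (pi_f > 0), np.log10(ratio), np.nan)
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_snps": n_snps,
            "pi_focal": pi_f,
            "pi_ref": pi_r,
            "pi_ratio": ratio,
            "log10_ratio": log10_ratio,
            "pi_signal": signal,
            "pi_sign": sign,
            "pi_valid": valid,
            "fst": fst,
            "fst_n_used": used,
        }
    )
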