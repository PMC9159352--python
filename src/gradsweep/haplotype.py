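"""Site-EHH (EHHS), its physical-distance integral (iES) and XP-EHH.

EHHS follows the allele-pooled, normalised site-homozygosity form: at marker
t the haplotypes are partitioned into identity classes over the inclusive
span core..t, the class-size homozygosity h(t) = sum_k n_k (n_k - 1) / (n (n-1))
is computed, and EHHS(t) = h(t) / h(core) with h(core) taken from the two
core-allele classes.  EHHS is therefore 1 at the core and non-increasing
away from it (classes only refine).  iES is the trapezoid integral of EHHS
against bp position, each side truncated at the first marker where EHHS
drops below the decay cutoff (that marker is kept as the final trapezoid
endpoint).  XP-EHH at a core SNP is ln(iES_focal / iES_ref): positive values
mean longer shared haplotypes (a more recent/ongoing sweep) in the focal
population.

No genetic-map integration and no inter-marker gap penalty are applied;
cores whose EHHS never decays below the cutoff before the panel edge are
kept but flagged truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import HaplotypePanel

DEFAULT_CUTOFF = 0.05


@dataclass
class EhhProfile:
    """EHHS decay profile around one core site (both directions)."""

    core_index: int
    core_position: int
    left_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    left_ehhs: np.ndarray = field(default_factory=lambda: np.array([]))
    right_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    right_ehhs: np.ndarray = field(default_factory=lambda: np.array([]))
    truncated_left: bool = False
    truncated_right: bool = False


def _homozygosity(labels: np.ndarray) -> float:
    """Probability two distinct haplotypes share an identity class."""
    n = len(labels)
    counts = np.bincount(labels)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehhs_at(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    cutoff: float = DEFAULT_CUTOFF,
    allow_monomorphic: bool = False,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """EHHS values moving away from ``core`` in one direction.

    Returns (marker positions, EHHS values, truncated) starting at the core
    itself (EHHS = 1).  The scan stops at the first marker whose EHHS falls
    below ``cutoff`` (included in the output) or at the panel edge, in which
    case ``truncated`` is True.

    A core monomorphic within this panel is an error by default; with
    ``allow_monomorphic`` the single core-allele class gives h(core) = 1,
    the convention needed in cross-population scans where a swept
    population may be fixed at cores that still segregate overall.
    """
    n, n_sites = haplotypes.shape
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    core_alleles = haplotypes[:, core].astype(np.int64)
    c = int(core_alleles.sum())
    if (c == 0 or c == n) and not allow_monomorphic:
        raise ValueError("monomorphic core site; EHHS undefined")
    h_core = _homozygosity(core_alleles)
    step = 1 if direction == "right" else -1
    pos_out = [int(positions[core])]
    ehhs_out = [1.0]
    labels = core_alleles.copy()
    t = core + step
    truncated = True
    while 0 <= t < n_sites:
        labels = labels * 2 + haplotypes[:, t]
        _, labels = np.unique(labels, return_inverse=True)
        val = _homozygosity(labels) / h_core
        pos_out.append(int(positions[t]))
        ehhs_out.append(val)
        if val < cutoff:
            truncated = False
            break
        t += step
    return np.asarray(pos_out, dtype=np.int64), np.asarray(ehhs_out), truncated


def ehh_profile(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    cutoff: float = DEFAULT_CUTOFF,
    allow_monomorphic: bool = False,
) -> EhhProfile:
    lpos, lehh, ltrunc = ehhs_at(haplotypes, positions, core, "left", cutoff,
                                 allow_monomorphic)
    rpos, rehh, rtrunc = ehhs_at(haplotypes, positions, core, "right", cutoff,
                                 allow_monomorphic)
    return EhhProfile(
        core_index=core,
        core_position=int(positions[core]),
        left_positions=lpos,
        left_ehhs=lehh,
        right_positions=rpos,
        right_ehhs=rehh,
        truncated_left=ltrunc,
        truncated_right=rtrunc,
    )


def _side_integral(positions: np.ndarray, ehhs: np.ndarray) -> float:
    if len(positions) < 2:
        return 0.0
    widths = np.abs(np.diff(positions.astype(float)))
    return float(np.sum(widths * (ehhs[:-1] + ehhs[1:]) / 2.0))


def ies(profile: EhhProfile) -> float:
    """bp-weighted integral of EHHS, left side + right side."""
    return _side_integral(profile.left_positions, profile.left_ehhs) + \
        _side_integral(profile.right_positions, profile.right_ehhs)


def ies_at_core(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    cutoff: float = DEFAULT_CUTOFF,
    allow_monomorphic: bool = False,
) -> tuple[float, bool]:
    """iES and truncation flag for one population at one core site."""
    prof = ehh_profile(haplotypes, positions, core, cutoff, allow_monomorphic)
    return ies(prof), prof.truncated_left or prof.truncated_right


def xpehh_scan(
    panel: HaplotypePanel,
    focal_indices,
    ref_indices,
    cutoff: float = DEFAULT_CUTOFF,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Unstandardised XP-EHH at every eligible core SNP.

    Cores must have combined MAF > ``maf_min``; a group fixed at a core
    contributes a single core-allele class (h(core) = 1).  A core is valid
    when both integrals are positive; truncation at the panel edge is
    flagged but does not invalidate by default.
    """
    rows_f = panel.sample_rows(focal_indices)
    rows_r = panel.sample_rows(ref_indices)
    if len(rows_f) < 2 or len(rows_r) < 2:
        raise ValueError("both groups need at least 2 haplotypes")
    hf = panel.haplotypes[rows_f]
    hr = panel.haplotypes[rows_r]
    h_all = np.concatenate([hf, hr], axis=0)
    freq = h_all.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    records = []
    for core in range(panel.n_sites):
        if maf[core] <= maf_min:
            continue
        ies_f, trunc_f = ies_at_core(hf, panel.positions, core, cutoff,
                                     allow_monomorphic=True)
        ies_r, trunc_r = ies_at_core(hr, panel.positions, core, cutoff,
                                     allow_monomorphic=True)
        valid = ies_f > 0 and ies_r > 0
        records.append(
            {
                "chrom": panel.chrom,
                "pos": int(panel.positions[core]),
                "site_index": core,
                "ies_focal": ies_f,
                "ies_ref": ies_r,
                "xpehh": np.log(ies_f / ies_r) if valid else np.nan,
                "truncated_focal": trunc_f,
                "truncated_ref": trunc_r,
                "valid": valid,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "chrom", "pos", "site_index", "ies_focal", "ies_ref",
            "xpehh", "truncated_focal", "truncated_ref", "valid",
        ],
    )
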