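"""Phenotype-gradient population pairs, tail selection and gradient filter.

The scan contrasts three nested focal groups against one fixed reference
group: the whole focal breed, then the focal animals below each of two
gestation-length cutoffs (days).  A trait-linked sweep should strengthen as
the focal group is restricted to ever-shorter gestation lengths, so a
candidate unit (window or SNP) is kept only when (i) it sits in the top
tail of the first pair and (ii) its signal increases monotonically across
the three pairs with a consistent sign ("gradient change").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import PhenotypeTable


class ConfigurationError(ValueError):
    pass


@dataclass
class PopulationPair:
    focal_ids: list[str]
    ref_ids: list[str]
    label: str


@dataclass
class PopulationPairSet:
    """Ordered nested pairs: focal sets shrink, reference stays fixed."""

    pairs: list[PopulationPair]
    thresholds: list[float]

    def __post_init__(self) -> None:
        ref0 = set(self.pairs[0].ref_ids)
        prev = set(self.pairs[0].focal_ids)
        for p in self.pairs[1:]:
            if set(p.ref_ids) != ref0:
                raise ConfigurationError("reference set must be identical across pairs")
            cur = set(p.focal_ids)
            if not cur <= prev:
                raise ConfigurationError("focal groups must be nested")
            prev = cur

    def __len__(self) -> int:
        return len(self.pairs)


def build_pairs(
    phenotypes: PhenotypeTable,
    focal_breed: str,
    thresholds: list[float] = (114.0, 113.0),
) -> PopulationPairSet:
    """Nested focal groups by strict mean-gestation-length cutoffs.

    Pair 1 is the whole focal breed; pair k+1 keeps focal samples with
    mean_gl strictly below ``thresholds[k-1]``.  The reference group (all
    non-focal samples) is identical across pairs.
    """
    focal = [
        (s, g) for s, b, g in
        zip(phenotypes.sample_ids, phenotypes.breeds, phenotypes.mean_gl)
        if b == focal_breed
    ]
    ref_ids = [s for s, b in zip(phenotypes.sample_ids, phenotypes.breeds)
               if b != focal_breed]
    if not focal:
        raise ConfigurationError(f"no samples of focal breed {focal_breed!r}")
    if not ref_ids:
        raise ConfigurationError("no reference (non-focal) samples")
    pairs = [PopulationPair([s for s, _ in focal], ref_ids, f"{focal_breed}_all")]
    for thr in thresholds:
        ids = [s for s, g in focal if g < thr]
        if not ids:
            raise ConfigurationError(
                f"threshold {thr} d leaves an empty focal group"
            )
        pairs.append(PopulationPair(ids, ref_ids, f"{focal_breed}<{thr:g}"))
    return PopulationPairSet(pairs=pairs, thresholds=list(thresholds))


def select_top(
    values: np.ndarray, q: float = 0.01, tail: str = "upper"
) -> np.ndarray:
    """Empirical top-tail selection with ties at the cutoff included.

    ``upper`` keeps units at or above the (1-q) quantile (the k-th largest
    valid value with k = ceil(q * n_valid)); ``two_way`` is the union of the
    upper tail and the analogous lower tail.  NaN values are invalid and
    never selected.
    """
    values = np.asarray(values, dtype=float)
    valid = ~np.isnan(values)
    n_valid = int(valid.sum())
    selected = np.zeros(values.shape, dtype=bool)
    if n_valid == 0:
        warnings.warn("no valid values; empty selection")
        return selected
    if n_valid < 1.0 / q:
        warnings.warn(
            f"only {n_valid} valid units for quantile {q}; "
            "the top tail is a single unit"
        )
    k = max(1, int(np.ceil(q * n_valid)))
    v = values[valid]
    upper_thr = np.sort(v)[-k]
    if tail == "upper":
        selected[valid] = v >= upper_thr
    elif tail == "two_way":
        lower_thr = np.sort(v)[k - 1]
        selected[valid] = (v >= upper_thr) | (v <= lower_thr)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return selected


def gradient_filter(
    signals: np.ndarray,
    selected_pair1: np.ndarray,
    signs: np.ndarray | None = None,
    strict: bool = True,
) -> np.ndarray:
    """Units whose signal strengthens across the nested pairs.

    ``signals`` is (n_units, 3): the statistic's magnitude in pairs 1..3.
    A unit passes iff it was selected in pair 1, its three values are all
    present, they increase monotonically (strictly by default), and — for
    signed statistics, when ``signs`` is given — the sign is identical
    across the pairs.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 2 or signals.shape[1] != 3:
        raise ConfigurationError("gradient filter needs signals for exactly 3 pairs")
    selected_pair1 = np.asarray(selected_pair1, dtype=bool)
    complete = ~np.isnan(signals).any(axis=1)
    if strict:
        mono = (signals[:, 0] < signals[:, 1]) & (signals[:, 1] < signals[:, 2])
    else:
        mono = (signals[:, 0] <= signals[:, 1]) & (signals[:, 1] <= signals[:, 2])
    ok = selected_pair1 & complete & mono
    if signs is not None:
        signs = np.asarray(signs, dtype=float)
        same = (signs[:, 0] == signs[:, 1]) & (signs[:, 1] == signs[:, 2])
        ok &= same
    return ok


def combine_candidates(gene_sets: dict[str, set[str]]) -> dict:
    """Union of per-statistic gradient gene sets plus Venn region counts.

    ``gene_sets`` maps statistic name (pi_ratio, fst, xpehh) to its gene
    set.  Returns the union, per-statistic counts, and the pairwise/triple
    intersection counts needed for a 3-set Venn diagram.
    """
    names = list(gene_sets)
    sets = [set(gene_sets[n]) for n in names]
    union: set[str] = set().union(*sets) if sets else set()
    out = {
        "statistics": names,
        "union": union,
        "n_union": len(union),
        "per_statistic": {n: len(s) for n, s in zip(names, sets)},
    }
    if len(sets) == 3:
        a, b, c = sets
        out["venn"] = {
            "only_" + names[0]: len(a - b - c),
            "only_" + names[1]: len(b - a - c),
            "only_" + names[2]: len(c - a - b),
            names[0] + "&" + names[1]: len((a & b) - c),
            names[0] + "&" + names[2]: len((a & c) - b),
            names[1] + "&" + names[2]: len((b & c) - a),
            "all_three": len(a & b & c),
        }
    return out
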