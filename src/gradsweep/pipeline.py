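"""End-to-end orchestration of the phenotype-gradient sweep scan.

``run_scan`` runs the three-pair scan (pi ratios, F_ST, XP-EHH) on one
panel; ``run_de_setlogic`` applies the breed-vs-stage set logic to a count
matrix; ``run_end_to_end`` wires a synthetic study together for recovery
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genes as genes_mod
from . import haplotype, popgen
from .gradient import (PopulationPairSet, build_pairs, combine_candidates,
                       gradient_filter, select_top)
from .io_formats import GeneFeature, HaplotypePanel, PhenotypeTable


@dataclass
class ScanOutput:
    pairs: PopulationPairSet
    windows: list[popgen.Window]
    window_tables: list[pd.DataFrame]        # one per pair
    xpehh_tables: list[pd.DataFrame] | None  # one per pair
    pi_selected_pair1: np.ndarray
    pi_gradient: np.ndarray
    fst_selected_pair1: np.ndarray
    fst_gradient: np.ndarray
    xpehh_frame: pd.DataFrame | None         # aligned across pairs
    xpehh_gradient_positions: list[int] = field(default_factory=list)
    gene_sets: dict[str, set[str]] = field(default_factory=dict)
    combined: dict | None = None


def _indices_of(panel: HaplotypePanel, sample_ids: list[str]) -> np.ndarray:
    lookup = {s: i for i, s in enumerate(panel.sample_ids)}
    missing = [s for s in sample_ids if s not in lookup]
    if missing:
        raise KeyError(f"samples absent from panel: {missing[:5]}")
    return np.asarray([lookup[s] for s in sample_ids], dtype=np.int64)


def _xpehh_for_pairs(
    panel: HaplotypePanel,
    pairs: PopulationPairSet,
    cutoff: float,
    maf_min: float,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """XP-EHH per pair with the reference-side integrals computed once."""
    rows_r = panel.sample_rows(_indices_of(panel, pairs.pairs[0].ref_ids))
    hr = panel.haplotypes[rows_r]
    ref_cache: dict[int, tuple[float, bool]] = {}
    tables = []
    for pair in pairs.pairs:
        rows_f = panel.sample_rows(_indices_of(panel, pair.focal_ids))
        hf = panel.haplotypes[rows_f]
        h_all = np.concatenate([hf, hr])
        freq = h_all.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        recs = []
        for core in range(panel.n_sites):
            if maf[core] <= maf_min:
                continue
            if core not in ref_cache:
                ref_cache[core] = haplotype.ies_at_core(
                    hr, panel.positions, core, cutoff, allow_monomorphic=True)
            ies_r, trunc_r = ref_cache[core]
            ies_f, trunc_f = haplotype.ies_at_core(
                hf, panel.positions, core, cutoff, allow_monomorphic=True)
            valid = ies_f > 0 and ies_r > 0
            recs.append({
                "pos": int(panel.positions[core]), "site_index": core,
                "ies_focal": ies_f, "ies_ref": ies_r,
                "xpehh": np.log(ies_f / ies_r) if valid else np.nan,
                "truncated_focal": trunc_f, "truncated_ref": trunc_r,
                "valid": valid,
            })
        tables.append(pd.DataFrame(
            recs, columns=["pos", "site_index", "ies_focal", "ies_ref",
                           "xpehh", "truncated_focal", "truncated_ref", "valid"]))
    # align across pairs by site index
    frame = None
    for k, t in enumerate(tables):
        cols = t.set_index("site_index")[["pos", "xpehh"]].rename(
            columns={"xpehh": f"xpehh_p{k + 1}"})
        frame = cols if frame is None else frame.join(
            cols[[f"xpehh_p{k + 1}"]], how="outer")
        if k > 0 and "pos" in frame.columns:
            frame["pos"] = frame["pos"].fillna(
                t.set_index("site_index")["pos"])
    if frame is None:
        frame = pd.DataFrame(columns=["pos"])
    return tables, frame


def run_scan(
    panel: HaplotypePanel,
    phenotypes: PhenotypeTable,
    focal_breed: str,
    thresholds: list[float] = (114.0, 113.0),
    window_span: int = 10_000,
    q: float = 0.01,
    pi_mode: str = "two_tailed_abs_log",
    gene_features: list[GeneFeature] | None = None,
    include_xpehh: bool = True,
    xpehh_cutoff: float = 0.05,
    xpehh_maf: float = 0.05,
    flank_bp: int = 10_000,
    strict: bool = True,
    require_tail_all_pairs: bool = False,
) -> ScanOutput:
    """Three-pair gradient scan over one chromosome panel.

    Top-1% tails are selected in the first pair only; the gradient filter
    then requires the raw signal to strengthen monotonically in the nested
    pairs (with a consistent sign for signed statistics).  With
    ``require_tail_all_pairs`` a unit must additionally sit in the top
    tail of pairs 2 and 3 — the stricter reading of "gradient change".
    """
    pairs = build_pairs(phenotypes, focal_breed, thresholds)
    region_len = int(panel.positions[-1]) if panel.n_sites else window_span
    windows = popgen.make_windows(panel.chrom, region_len, window_span)
    ref_idx = _indices_of(panel, pairs.pairs[0].ref_ids)

    tables = []
    for pair in pairs.pairs:
        focal_idx = _indices_of(panel, pair.focal_ids)
        tables.append(popgen.window_table(
            panel, focal_idx, ref_idx, windows, pi_mode=pi_mode))

    def _entry_mask(signals: np.ndarray, tail: str) -> np.ndarray:
        sel = select_top(signals[:, 0], q=q, tail=tail)
        if require_tail_all_pairs:
            for k in (1, 2):
                sel = sel & select_top(signals[:, k], q=q, tail=tail)
        return sel

    pi_signals = np.column_stack([t["pi_signal"].to_numpy() for t in tables])
    pi_signs = np.column_stack([t["pi_sign"].to_numpy() for t in tables])
    pi_sel = _entry_mask(pi_signals, "upper")
    signed = pi_mode == "two_tailed_abs_log"
    pi_grad = gradient_filter(pi_signals, pi_sel,
                              signs=pi_signs if signed else None, strict=strict)

    fst_signals = np.column_stack([t["fst"].to_numpy() for t in tables])
    fst_sel = _entry_mask(fst_signals, "upper")
    fst_grad = gradient_filter(fst_signals, fst_sel, signs=None, strict=strict)

    xpehh_tables = None
    xpehh_frame = None
    xpehh_positions: list[int] = []
    if include_xpehh:
        xpehh_tables, xpehh_frame = _xpehh_for_pairs(
            panel, pairs, xpehh_cutoff, xpehh_maf)
        if len(xpehh_frame):
            vals = xpehh_frame[["xpehh_p1", "xpehh_p2", "xpehh_p3"]].to_numpy()
            sel = _entry_mask(vals, "two_way")
            grad = gradient_filter(np.abs(vals), sel,
                                   signs=np.sign(vals), strict=strict)
            xpehh_positions = [int(p) for p in xpehh_frame["pos"].to_numpy()[grad]]
            xpehh_frame = xpehh_frame.assign(selected_pair1=sel, gradient_pass=grad)

    out = ScanOutput(
        pairs=pairs, windows=windows, window_tables=tables,
        xpehh_tables=xpehh_tables,
        pi_selected_pair1=pi_sel, pi_gradient=pi_grad,
        fst_selected_pair1=fst_sel, fst_gradient=fst_grad,
        xpehh_frame=xpehh_frame,
        xpehh_gradient_positions=xpehh_positions,
    )
    if gene_features is not None:
        pi_windows = [w for w, m in zip(windows, pi_grad) if m]
        fst_windows = [w for w, m in zip(windows, fst_grad) if m]
        snps = [(panel.chrom, p) for p in xpehh_positions]
        out.gene_sets = {
            "pi_ratio": genes_mod.annotate_windows(pi_windows, gene_features),
            "fst": genes_mod.annotate_windows(fst_windows, gene_features),
            "xpehh": genes_mod.annotate_snps(snps, gene_features, flank_bp),
        }
        out.combined = combine_candidates(out.gene_sets)
    return out


def run_de_setlogic(
    counts: pd.DataFrame,
    groups: pd.Series,
    focal_breed: str,
    ref_breed: str,
    fc_min: float = 2.0,
    alpha: float = 0.001,
) -> dict:
    """Breed-contrast DE sets minus gestational-stage DE sets.

    Group labels are "PRE_<breed>" / "PAR_<breed>".  Breed contrasts are
    run per stage (reference breed vs focal breed); stage contrasts are run
    within each breed (late pregnancy vs parturition) and their union is
    subtracted.
    """
    def _call(ref_grp: str, trt_grp: str) -> set[str]:
        table = genes_mod.simple_de(counts, groups, (ref_grp, trt_grp))
        return genes_mod.de_call(table, fc_min=fc_min, alpha=alpha)

    breed_sets = {
        "PRE": _call(f"PRE_{ref_breed}", f"PRE_{focal_breed}"),
        "PAR": _call(f"PAR_{ref_breed}", f"PAR_{focal_breed}"),
    }
    stage_sets = [
        _call(f"PRE_{focal_breed}", f"PAR_{focal_breed}"),
        _call(f"PRE_{ref_breed}", f"PAR_{ref_breed}"),
    ]
    per_stage, final = genes_mod.stage_exclusion(breed_sets, stage_sets)
    return {
        "breed_sets": breed_sets,
        "stage_genes": set().union(*stage_sets),
        "per_stage": per_stage,
        "de_genes": final,
    }


def run_end_to_end(config, known_genes: set[str] | None = None) -> dict:
    """Simulate a full synthetic study and run the whole analysis.

    Returns a summary dict including the truth needed for recovery scoring.
    """
    from . import simulate as sim

    panel_f, panel_r, truth = sim.simulate_panel(config)
    panel = sim.merge_panels(panel_f, panel_r)
    pheno = sim.simulate_phenotypes(panel_f, panel_r, config, truth)
    bed = sim.toy_gene_bed(config)
    features = [GeneFeature(n, n, c, s, e) for c, s, e, n in bed]
    sweep_coord = truth.selected_site_pos - 1
    truth.sweep_gene = next(
        n for c, s, e, n in bed if s <= sweep_coord < e)

    scan = run_scan(panel, pheno, config.focal_breed,
                    thresholds=[114.0, 113.0], gene_features=features)

    counts, groups, de_truth = sim.simulate_counts(config)
    de = run_de_setlogic(counts, groups, config.focal_breed, config.ref_breed)

    known = known_genes
    if known is None:
        known = {truth.sweep_gene} | set(de_truth.breed_genes[:5]) | {
            f"DECOY{i + 1:02d}" for i in range(10)}
    venn = genes_mod.known_gene_venn(
        scan.combined["union"], de["de_genes"], known)
    return {
        "truth": truth,
        "de_truth": de_truth,
        "scan": scan,
        "de": de,
        "venn": venn,
        "phenotypes": pheno,
        "sweep_gene_recovered": truth.sweep_gene in scan.combined["union"],
    }
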