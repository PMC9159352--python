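"""Forward Wright-Fisher synthetic data with a planted, trait-linked sweep.

The generator produces every input the scan consumes, with the structure
the analysis assumes: two demes that split from a common ancestral
population, a focal locus under additive positive selection in the focal
deme only, per-sow repeated gestation-length records whose mean is reduced
by the swept allele, a toy gene annotation tiling the region, and
negative-binomial RNA-seq count matrices with planted breed- and
stage-effect gene blocks.

The simulation is discrete-generation and forward in time: each offspring
draws two parents (weighted by 1 + s * dosage / 2 at the selected site once
selection starts in the focal deme), receives one recombinant gamete from
each (per-adjacent-site crossover probability ``rho``), and per-site
mutations flip alleles with probability ``mu``.  Population sizes, region
length and generation counts are desk-scale (hundreds of diploids, ~10^3
sites, ~10^2 generations) so that a full scan runs in seconds; drift and
hitchhiking behave as theory predicts at these sizes, which the calibration
tests check directly.

All randomness flows from ``SimConfig.seed``; the same seed reproduces
byte-identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import HaplotypePanel, PhenotypeTable


@dataclass
class SimConfig:
    """Study conditions for the synthetic data.

    Defaults emulate the analysed design: a focal breed of 100 sows whose
    mean gestation lengths span roughly 110-117 days with most below the
    114-day porcine norm, against a fixed reference group, with a selected
    locus (s = 0.1) that shortens gestation by ``beta`` days per derived
    allele.
    """

    n_diploid: int = 400            # per deme
    n_generations: int = 150        # total, including burn-in
    split_generation: int = 80      # ancestral generations before the split
    n_sites: int = 1000
    region_length: int = 1_000_000  # bp
    mu: float = 1e-6                # per-site per-generation flip probability
    rho: float = 1e-3               # per-adjacent-pair per-meiosis crossover
    selected_site: int | None = None  # site index; default = middle site
    init_freq_selected: float = 0.2
    founder_mode: str = "hard"      # "hard": carriers share one founder haplotype
    s: float = 0.1                  # additive selection coefficient, focal deme
    sel_start: int | None = None    # defaults to split_generation
    sample_focal: int = 100
    sample_ref: int = 100
    beta: float = 1.5               # days shorter per derived allele
    sigma_env: float = 1.0          # residual SD, days
    records_per_sow: tuple[int, int] = (2, 6)
    mu_gl_focal: float = 115.5      # baseline mean gestation length, days
    mu_gl_ref: float = 114.0
    focal_breed: str = "QP"
    ref_breed: str = "REF"
    # RNA-seq design: 2 breeds x 2 stages x n_reps
    n_genes: int = 1000
    n_breed_genes: int = 50
    n_stage_genes: int = 50
    de_log2_effect: float = 3.0
    dispersion: float = 0.005
    n_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0 or not (0 <= self.mu <= 1) or not (0 <= self.rho <= 1):
            raise ValueError("invalid rate parameters")
        if self.selected_site is None:
            self.selected_site = self.n_sites // 2
        if not 0 <= self.selected_site < self.n_sites:
            raise ValueError("selected_site out of range")
        if self.sel_start is None:
            self.sel_start = self.split_generation
        if self.sample_focal > self.n_diploid or self.sample_ref > self.n_diploid:
            raise ValueError("sample size exceeds deme size")


@dataclass
class SimTruth:
    """Ground truth for recovery scoring; refers only to simulated entities."""

    selected_site_index: int
    selected_site_pos: int
    final_freq_focal: float
    final_freq_ref: float
    genetic_value: dict[str, float] = field(default_factory=dict)  # sow -> -beta*dosage
    breed_genes: list[str] = field(default_factory=list)
    stage_genes: list[str] = field(default_factory=list)
    de_log2_effects: dict[str, float] = field(default_factory=dict)
    sweep_gene: str | None = None


# ---------------------------------------------------------------------------
# Wright-Fisher core
# ---------------------------------------------------------------------------

def _gametes(pop: np.ndarray, parents: np.ndarray, rho: float,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent index (rows of the next generation)."""
    n, length = len(parents), pop.shape[1]
    hap1 = pop[2 * parents]
    hap2 = pop[2 * parents + 1]
    start = rng.integers(0, 2, size=n)
    if length > 1 and rho > 0:
        switches = rng.random((n, length - 1)) < rho
        selector = (start[:, None] + np.cumsum(switches, axis=1)) % 2
        selector = np.concatenate([start[:, None], selector], axis=1)
    else:
        selector = np.repeat(start[:, None], length, axis=1)
    return np.where(selector == 0, hap1, hap2).astype(np.int8)


def _mutate(pop: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    if mu <= 0:
        return
    n_mut = rng.poisson(pop.size * mu)
    if n_mut:
        rows = rng.integers(0, pop.shape[0], size=n_mut)
        cols = rng.integers(0, pop.shape[1], size=n_mut)
        pop[rows, cols] ^= 1


def _next_generation(
    pop: np.ndarray,
    rho: float,
    mu: float,
    rng: np.random.Generator,
    sel_site: int | None = None,
    s: float = 0.0,
) -> np.ndarray:
    """One Wright-Fisher generation; parents weighted 1 + s*dosage/2."""
    n = pop.shape[0] // 2
    if sel_site is not None and s > 0:
        dosage = pop[0::2, sel_site] + pop[1::2, sel_site]
        w = 1.0 + s * dosage / 2.0
        p = w / w.sum()
    else:
        p = None
    mothers = rng.choice(n, size=n, p=p)
    fathers = rng.choice(n, size=n, p=p)
    g_m = _gametes(pop, mothers, rho, rng)
    g_f = _gametes(pop, fathers, rho, rng)
    child = np.empty_like(pop)
    child[0::2] = g_m
    child[1::2] = g_f
    _mutate(child, mu, rng)
    return child


def _positions(config: SimConfig) -> np.ndarray:
    """Evenly spaced 1-based bp positions across the region."""
    step = config.region_length / config.n_sites
    pos = np.round((np.arange(config.n_sites) + 0.5) * step).astype(np.int64)
    return np.maximum.accumulate(pos) + np.arange(config.n_sites) * 0  # already increasing


def simulate_panel(
    config: SimConfig,
) -> tuple[HaplotypePanel, HaplotypePanel, SimTruth]:
    """Run the two-deme simulation; returns (focal panel, ref panel, truth).

    The ancestral population evolves neutrally for ``split_generation``
    generations from standing variation (per-site initial frequencies
    uniform on [0.05, 0.95]; the selected site starts at
    ``init_freq_selected``), then two copies diverge independently, with
    selection applied in the focal deme from ``sel_start`` on.
    """
    rng = np.random.default_rng(config.seed)
    n2 = 2 * config.n_diploid
    freqs = rng.uniform(0.05, 0.95, size=config.n_sites)
    freqs[config.selected_site] = config.init_freq_selected
    pop = (rng.random((n2, config.n_sites)) < freqs).astype(np.int8)

    for _ in range(config.split_generation):
        pop = _next_generation(pop, config.rho, config.mu, rng)

    # Re-seed the selected site at the split with an exact allele count so
    # the to-be-swept variant segregates at init_freq_selected in both demes
    # when they diverge.  "hard" places all copies on one founder haplotype
    # (a recent hard sweep caught at threshold frequency); "soft" scatters
    # them over random standing backgrounds.
    n_derived = int(round(n2 * config.init_freq_selected))
    carriers = rng.choice(n2, size=n_derived, replace=False)
    pop[:, config.selected_site] = 0
    if config.founder_mode == "hard":
        # Recent hard sweep: the variant arose once and rose rapidly to its
        # threshold frequency, so every carrier haplotype is a copy of one
        # founder; recombination and drift reshape it from here on.
        donor = pop[rng.integers(n2)].copy()
        pop[carriers] = donor
    elif config.founder_mode != "soft":
        raise ValueError("founder_mode must be 'hard' or 'soft'")
    pop[carriers, config.selected_site] = 1

    focal = pop.copy()
    ref = pop.copy()
    for t in range(config.split_generation, config.n_generations):
        sel = config.selected_site if t >= config.sel_start else None
        focal = _next_generation(focal, config.rho, config.mu, rng,
                                 sel_site=sel, s=config.s)
        ref = _next_generation(ref, config.rho, config.mu, rng)

    pos = _positions(config)
    ref_allele = np.asarray(["A"] * config.n_sites, dtype=object)
    alt_allele = np.asarray(["G"] * config.n_sites, dtype=object)

    def _sample(pop_arr: np.ndarray, n_sample: int, prefix: str, breed: str
                ) -> HaplotypePanel:
        chosen = rng.choice(config.n_diploid, size=n_sample, replace=False)
        rows = np.stack([2 * chosen, 2 * chosen + 1], axis=1).reshape(-1)
        ids = [f"{prefix}{i + 1:03d}" for i in range(n_sample)]
        return HaplotypePanel(
            chrom="chr1",
            positions=pos,
            ref_allele=ref_allele.copy(),
            alt_allele=alt_allele.copy(),
            haplotypes=pop_arr[rows].copy(),
            sample_ids=ids,
            breed=[breed] * n_sample,
        )

    panel_f = _sample(focal, config.sample_focal, config.focal_breed, config.focal_breed)
    panel_r = _sample(ref, config.sample_ref, config.ref_breed, config.ref_breed)
    truth = SimTruth(
        selected_site_index=config.selected_site,
        selected_site_pos=int(pos[config.selected_site]),
        final_freq_focal=float(panel_f.haplotypes[:, config.selected_site].mean()),
        final_freq_ref=float(panel_r.haplotypes[:, config.selected_site].mean()),
    )
    return panel_f, panel_r, truth


def merge_panels(panel_a: HaplotypePanel, panel_b: HaplotypePanel) -> HaplotypePanel:
    """Concatenate two same-site panels sample-wise."""
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise ValueError("panels must share identical sites")
    return HaplotypePanel(
        chrom=panel_a.chrom,
        positions=panel_a.positions.copy(),
        ref_allele=panel_a.ref_allele.copy(),
        alt_allele=panel_a.alt_allele.copy(),
        haplotypes=np.concatenate([panel_a.haplotypes, panel_b.haplotypes]),
        sample_ids=panel_a.sample_ids + panel_b.sample_ids,
        breed=panel_a.breed + panel_b.breed,
        phased=panel_a.phased and panel_b.phased,
    )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    panel_focal: HaplotypePanel,
    panel_ref: HaplotypePanel,
    config: SimConfig,
    truth: SimTruth | None = None,
) -> PhenotypeTable:
    """Per-sow gestation-length records (days, rounded to whole days).

    Each focal sow gets k records (k uniform in ``records_per_sow``), each
    ``mu_gl_focal - beta * dosage(selected site) + Normal(0, sigma_env)``.
    Reference samples carry their breed-average as a single pseudo-record.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sample_ids: list[str] = []
    breeds: list[str] = []
    records: list[list[float]] = []
    means: list[float] = []
    h = panel_focal.haplotypes
    dosage = h[0::2, config.selected_site] + h[1::2, config.selected_site]
    lo, hi = config.records_per_sow
    for i, sid in enumerate(panel_focal.sample_ids):
        k = int(rng.integers(lo, hi + 1))
        vals = (
            config.mu_gl_focal
            - config.beta * dosage[i]
            + rng.normal(0.0, config.sigma_env, size=k)
        )
        recs = [float(v) for v in np.round(vals)]
        sample_ids.append(sid)
        breeds.append(config.focal_breed)
        records.append(recs)
        means.append(float(np.mean(recs)))
        if truth is not None:
            truth.genetic_value[sid] = float(-config.beta * dosage[i])
    for sid in panel_ref.sample_ids:
        sample_ids.append(sid)
        breeds.append(config.ref_breed)
        records.append([config.mu_gl_ref])
        means.append(config.mu_gl_ref)
    return PhenotypeTable(sample_ids, breeds, records, np.asarray(means))


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, SimTruth]:
    """Negative-binomial count matrix for a 2-breed x 2-stage design.

    Three planted blocks: breed-effect genes (log2 effect in the focal
    breed at both stages), stage-effect genes (log2 effect at parturition
    in both breeds) and null genes.  Returns (counts genes x samples,
    sample -> group labels, truth with the planted lists).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    base = rng.lognormal(mean=np.log(500.0), sigma=0.7, size=config.n_genes)
    breed_idx = np.arange(config.n_breed_genes)
    stage_idx = np.arange(config.n_breed_genes,
                          config.n_breed_genes + config.n_stage_genes)
    signs_breed = rng.choice([-1.0, 1.0], size=len(breed_idx))
    signs_stage = rng.choice([-1.0, 1.0], size=len(stage_idx))

    samples: list[str] = []
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for breed in (config.focal_breed, config.ref_breed):
        for stage in ("PRE", "PAR"):
            for rep in range(config.n_reps):
                mean = base.copy()
                log2fc = np.zeros(config.n_genes)
                if breed == config.focal_breed:
                    log2fc[breed_idx] += signs_breed * config.de_log2_effect
                if stage == "PAR":
                    log2fc[stage_idx] += signs_stage * config.de_log2_effect
                mean = mean * 2.0 ** log2fc
                if config.dispersion > 0:
                    shape = 1.0 / config.dispersion
                    lam = rng.gamma(shape, mean / shape)
                else:
                    lam = mean
                cols.append(rng.poisson(lam))
                samples.append(f"{stage}_{breed}_{rep + 1}")
                labels.append(f"{stage}_{breed}")
    counts = pd.DataFrame(np.column_stack(cols), index=genes, columns=samples)
    groups = pd.Series(labels, index=samples)
    truth = SimTruth(
        selected_site_index=-1,
        selected_site_pos=-1,
        final_freq_focal=np.nan,
        final_freq_ref=np.nan,
        breed_genes=[genes[i] for i in breed_idx],
        stage_genes=[genes[i] for i in stage_idx],
        de_log2_effects={
            **{genes[i]: float(s * config.de_log2_effect)
               for i, s in zip(breed_idx, signs_breed)},
            **{genes[i]: float(s * config.de_log2_effect)
               for i, s in zip(stage_idx, signs_stage)},
        },
    )
    return counts, groups, truth


# ---------------------------------------------------------------------------
# Gene annotation and full fixture
# ---------------------------------------------------------------------------

def toy_gene_bed(config: SimConfig, gene_span: int = 25_000) -> list[tuple]:
    """Contiguous toy genes tiling the region; returns (chrom, start, end, name)."""
    rows = []
    k = 0
    for start in range(0, config.region_length, gene_span):
        k += 1
        rows.append(("chr1", start, min(start + gene_span, config.region_length),
                     f"SGENE{k:03d}"))
    return rows


def make_fixture(outdir: str | Path, config: SimConfig) -> SimTruth:
    """Write a complete, self-consistent input set for the full pipeline.

    Files: panel.vcf (both demes), phenotypes.tsv, genes.bed, counts.tsv,
    groups.tsv, known_genes.txt, truth.json.  The known-gene list contains
    the gene overlapping the selected site, a handful of planted DE genes,
    and decoys absent from the data.  Same seed => byte-identical files.
    """
    from .io_formats import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel_f, panel_r, truth = simulate_panel(config)
    pheno = simulate_phenotypes(panel_f, panel_r, config, truth)
    counts, groups, de_truth = simulate_counts(config)
    truth.breed_genes = de_truth.breed_genes
    truth.stage_genes = de_truth.stage_genes
    truth.de_log2_effects = de_truth.de_log2_effects

    write_vcf(merge_panels(panel_f, panel_r), outdir / "panel.vcf")

    rows = []
    for sid, breed, recs in zip(pheno.sample_ids, pheno.breeds, pheno.records):
        for r in recs:
            rows.append({"sample_id": sid, "breed": breed, "gestation_length": r})
    pd.DataFrame(rows).to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)

    bed = toy_gene_bed(config)
    with open(outdir / "genes.bed", "w") as fh:
        for chrom, start, end, name in bed:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    sweep_coord = truth.selected_site_pos - 1  # 0-based
    truth.sweep_gene = next(
        name for chrom, start, end, name in bed if start <= sweep_coord < end
    )

    counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    groups.rename("group").to_csv(outdir / "groups.tsv", sep="\t",
                                  index_label="sample")

    known = [truth.sweep_gene] + truth.breed_genes[:5] + [
        f"DECOY{i + 1:02d}" for i in range(10)
    ]
    with open(outdir / "known_genes.txt", "w") as fh:
        fh.write("\n".join(known) + "\n")

    with open(outdir / "truth.json", "w") as fh:
        payload = asdict(truth)
        payload["config"] = asdict(config)
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
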