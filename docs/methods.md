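# Methods

`gradsweep` detects selective sweeps linked to a quantitative trait —
short gestation length in a pig breed — by contrasting *nested,
phenotype-defined* subsets of the focal breed against one fixed reference
group, and keeping only signals that strengthen as the focal group is
restricted to ever more extreme trait values.  This note records the
models, the numerical choices, and what the synthetic data do and do not
establish.

## Statistics

**Nucleotide diversity (π).**  Per site, the mean pairwise difference among
n haplotypes with c copies of the alternate allele is `2c(n−c)/(n(n−1))`.
Windowed π sums per-site values over non-overlapping 10-kb tiles and
divides by the window span in bp (not the SNP count), so empty windows are
0 and SNP density does not inflate the estimate.  The π-ratio signal per
window is `|log10(π_focal/π_ref)|` with the sign of the log ratio kept as
metadata (the default, "two-tailed" reading), or `−log10(π_focal/π_ref)`
when only diversity loss in the focal group should rank ("low-tail" mode).
Both readings are implemented because the tail convention is genuinely
ambiguous in practice; the mode is a configuration knob (`--pi-tail`).
Windows with π_ref = 0 have an undefined ratio and are excluded from
ranking; π_focal = 0 against a positive reference maps to a +∞ sentinel
that ranks above all finite signals.

**F_ST.**  Per-site Weir–Cockerham (1984) variance components (a, b, c)
are computed from genotype counts with observed heterozygosity; the
windowed value is the weighted ratio-of-sums `Σa / Σ(a+b+c)` over in-window
sites, the standard choice for windowed scans.  Negative per-site
components stay in the sums — truncating them at zero would bias windowed
estimates upward.  Windows with no site contributing a nonzero denominator
are excluded from ranking.  A regression test pins ratio-of-sums against
the (different) mean-of-ratios value on a constructed two-site window.

**EHHS / iES / XP-EHH.**  Site-EHH uses the allele-pooled, normalised
homozygosity form: at marker t, haplotypes are partitioned into identity
classes over the inclusive span core..t, `h(t) = Σ n_k(n_k−1)/(n(n−1))`,
and `EHHS(t) = h(t)/h(core)`.  The scan stops when EHHS falls below the
decay cutoff (default 0.05; that marker is retained as the last trapezoid
endpoint) or at the panel edge, which sets a truncation flag; truncated
cores are kept but flagged.  iES is the trapezoid integral of EHHS against
physical position, left plus right.  XP-EHH per core is
`ln(iES_focal/iES_ref)`, unstandardised; positive values mean longer
shared haplotypes in the focal group.  In cross-population scans a core
may be fixed *within* one group while segregating overall — there the
single core-allele class gives h(core)=1 and the statistic remains
defined; requiring within-group polymorphism would blind the scan exactly
where a sweep has completed.  No genetic map, gap penalty, or
frequency-bin standardisation is applied.  Only this one EHHS variant is
implemented; analyses run elsewhere with a different within-population
normalisation will differ numerically.

**Exact Hardy–Weinberg test.**  The two-sided exact p-value sums, over all
heterozygote counts attainable for the observed allele counts, the
conditional probabilities not exceeding the observed configuration's (no
mid-p).  Probabilities are built by the ratio recurrence from the modal
heterozygote count, which is stable where factorials overflow; tests
verify exact agreement with full rational-arithmetic enumeration for every
genotype table with up to 50 individuals.

**QC thresholds.**  MAF > 0.05, site call rate > 0.90, HWE p > 1e-6,
per-individual missingness flagged at ≥ 0.10 — all strict inequalities;
boundary values fail.  Sample flags are advisory because the haplotype
statistics run on phased, complete panels.

## The gradient design

The three population pairs are: (1) the whole focal breed, (2) focal
animals with mean gestation length < 114 d, (3) < 113 d — each against the
same fixed reference group.  Cutoffs are strict; a sow at exactly 114.0 d
is excluded from pair 2.  Top tails (1% by default, ties at the cutoff
included; two-way for XP-EHH, i.e. 1% of each tail) are selected in the
**first** pair only.  The gradient filter then requires, per unit, strictly
monotone signal increase across the three pairs and, for signed statistics
(XP-EHH, two-tailed log π-ratio), an identical sign throughout; a
non-strict (≤) mode is available.  "Gradient change" has no numerical
definition in common usage, so strict monotonicity was chosen to make the
filter falsifiable and deterministic.  Tail membership is *not*
re-required in pairs 2 and 3 (raw signals are compared); an option
implements the stricter reading.  Candidate windows/SNPs are annotated to
genes by half-open interval overlap (≥1 bp) for windows and by gene body
or ±10-kb flank for SNPs (all genes within reach, no nearest-only rule);
per-statistic gene sets are unioned, with Venn region counts reported.

## RNA-seq stand-in and set logic

The DE engine is deliberately simple and clearly labelled as a stand-in
for a negative-binomial model: median-of-ratios size factors (genes with
any zero excluded from the median), `log2fc` on normalised means with a
+0.5 offset, a two-sided **pooled-variance** t-test on
`log2(normalised+1)`, and Benjamini–Hochberg adjustment.  A Welch test was
considered and rejected: at the n = 3 per group design the
Welch–Satterthwaite degrees of freedom collapse toward 2, which floors
attainable p-values near 1e-4–1e-5 regardless of effect size and makes the
padj < 0.001 call threshold unreachable; pooling keeps the full 2(n−1)
degrees of freedom, the conventional small-n choice.  Externally produced
(gene, log2fc, padj) tables are accepted in its place, so a DESeq2-style
analysis slots in unchanged.  DE calls use |log2fc| > 1 and padj < 0.001,
both strict.

Stage exclusion: genes differentially expressed between late pregnancy and
parturition within either breed are attributed to gestational age; their
union is subtracted from the per-stage breed-contrast sets, whose union is
the trait-specific DE set (provably disjoint from the stage genes).  The
known-gene overlap matches symbols case-insensitively; unresolvable
symbols pass through and are reported rather than guessed at.

## Synthetic data: what it emulates

The generator is a discrete-generation forward Wright–Fisher model: each
offspring draws two parents (weight `1 + s·dosage/2` at the selected site
in the focal deme once selection starts), receives one recombinant gamete
from each (crossover probability `rho` per adjacent site pair), and
per-site mutation flips alleles with probability `mu`.  An ancestral
population evolves 80 generations from standing variation (per-site
initial frequencies uniform on [0.05, 0.95]) to build linkage
disequilibrium, then splits into a focal and a reference deme.

At the split, the selected variant is (re)introduced at exactly its
threshold frequency (0.2) with all carrier copies on a **single founder
haplotype** — the standard device for a recent hard sweep caught at
threshold frequency.  This matters: scattering the copies over random
standing backgrounds makes the sweep maximally soft, and fixing a soft
sweep barely reduces local diversity, leaving nothing for a π-ratio scan
to detect.  A `founder_mode="soft"` switch retains the scattered variant
for neutral calibration work.

Default study conditions (chosen once, as the conditions the analysis
presumes, and frozen):

| parameter | default | why |
|---|---|---|
| demes | 2 × 400 diploids | drift background F_ST ≈ t/2N stays below the planted signal at 100-window scale |
| region | 1 Mb, 1000 SNPs | 100 windows of 10 kb with ~10 SNPs each; scan in seconds |
| rho | 1e-3 per adjacent pair | LD decays over tens of kb, localising the sweep to a few windows |
| selection | s = 0.1 for 70 post-split generations | deterministic expectation of the final focal frequency ≈ 0.88 — strong enough to rank in the pair-1 tail, short of fixation so the phenotype subgroups still enrich carrier frequency (a fixed allele has no within-breed gradient) |
| phenotype | baseline 115.5 d focal / 114 d reference; −1.5 d per derived allele; residual SD 1 d; 2–6 records per sow, rounded to whole days | per-sow means span ≈ 111–117 d, most below 114 d, ≈ 400 records over 100 sows |
| counts | 2 breeds × 2 stages × 3 reps; mean ≈ 500 (log-normal σ = 0.7); NB dispersion 0.005; planted 8-fold blocks of 50 breed- and 50 stage-effect genes | deeply sequenced, near-isogenic tissue: an 8-fold effect is informative at n = 3 under the stand-in test |

Everything is driven by one integer seed; the same seed reproduces
byte-identical fixture files.

**What passing tests do not show.**  The simulated world has one sweep and
pure drift elsewhere; real breed comparisons carry many sweeps, population
structure within the reference, genotyping error, and imputation
artefacts.  The phenotype model is a single additive locus plus noise;
gestation length is polygenic.  Count matrices have no batch effects or
library-composition extremes.  Recovery rates measured here therefore
bound the method's behaviour under its own assumptions, not its field
performance.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; VCF/GFF3 converted at the
  edges.  A SNP at 1-based position p belongs to the window containing
  coordinate p−1; a window's `end` is exclusive.
- Multiallelic and non-SNP VCF records are dropped (not split) with a
  logged count; ploidy is fixed at 2.
- LD pruning is the greedy sliding-window procedure; on an r² violation
  the later site by position is dropped (position tie: the higher
  alt-frequency site is kept), making the retained set deterministic.
- PCA scales dosages by `sqrt(2p̂(1−p̂))` after centring by `2p̂`
  (frequency scaling); monomorphic sites are dropped first; coordinates
  are eigenvectors scaled by the square root of their eigenvalues.
- The NJ tree input distance is allele sharing (1 − IBS, with per-site
  IBS = 1 − |d_i − d_j|/2); neighbour joining itself is delegated to
  scikit-bio.  Tree results are structural (clustering), not calibrated
  branch lengths.
- Tail selection takes the k = ⌈qN⌉ largest valid values and includes all
  ties at the cutoff, so slightly more than qN units can be selected.
- Empirical checks in the test suite use fixed seeds; Monte-Carlo
  assertions state their replicate counts and use 3–4 SE tolerances.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at the
default conditions above (400 diploids per deme, 1000 SNPs over 1 Mb, 150
total generations, ~8–10 s per study on one core) and measure planted-
sweep recovery over 20 seeded replicate studies, with 10 null replicates
for the background rate.  Simulator calibration uses 200 neutral
single-locus replicates at N = 50 for 50 generations.  These sizes were
chosen so a complete run is a coffee-break affair on a laptop while
keeping the Monte-Carlo tolerances meaningful.

## Known limitations

- Only the Sabeti-style EHHS normalisation is implemented; no cM map.
- The DE stand-in has no dispersion shrinkage; its power at n = 3 depends
  on count depth, as quantified by the recovery numbers the acceptance
  script reports.
- The gene-prioritisation step that would rank novel candidates by
  functional similarity to known genes is out of scope by design, as are
  GO/KEGG enrichment, imputation, and upstream read processing.
- Single-chromosome panels; multi-chromosome data are processed one
  panel at a time.
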