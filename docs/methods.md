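# Methods

## Pooled-sequencing model

Each strain (resistant R, susceptible S) is represented by a true per-site
alternate-allele frequency; non-selected sites share one ancestral frequency
drawn uniformly from `base_freq_range` (default (0.1, 0.9), keeping expected
minor counts large enough for the χ² approximation at ~100× depth). Selected
sites are separated by `delta_f`: the ancestral frequency is clipped into
[δ/2, 1−δ/2] and the strains placed symmetrically about it, so the planted
difference is exactly δ and both frequencies stay in [0, 1].

Sequencing is simulated in two stages per library:

1. **pool stage** — the alternate-allele count among the 2N chromosomes of a
   pool of N = 22 diploids is Binomial(2N, f), giving the realized pool
   frequency;
2. **read stage** — the alternate read count is Binomial(d, pool frequency),
   with per-library depth d either fixed or negative-binomial
   (variance = μ + μ²/k) to mimic capture-coverage heterogeneity. The true
   coverage distribution of real capture libraries is not known to this
   package; the negative-binomial is a stand-in, not a calibration.

Replicate pools are independent mosquito samples, so read-level frequencies
across replicates are overdispersed relative to binomial read sampling by a
factor ≈ 1 + d/(2N). A single-stage mode (`two_stage=False`) draws reads
directly from the strain frequency; it is used for null-calibration studies
where the site test should be exactly nominal.

What the generator does **not** emulate: alignment artifacts, base-calling
error, indels, linkage between sites, or allele-specific capture bias.
Passing tests therefore demonstrate correctness of the statistics under the
declared sampling model, not robustness to those real-data complications.

## Association scan

Per site, counts are summed across a strain's replicate libraries and the
2×2 alleles × strains table is tested by Pearson χ² (1 df, no continuity
correction; expected counts are large at the mandated minimum coverage of
22 reads per library). p values are floored at 1e−300 before −log₁₀ so
scores stay finite. A zero column margin (allele absent everywhere) yields
χ² = 0, p = 1 by convention. An optional Fisher-exact fallback
(`fisher_fallback`) covers small expected counts. The χ² is invariant to
ref/alt labelling and to exchanging the strains (asserted by property
tests); ref/alt orientation is fixed by the stated reference base, never by
frequency.

**Replicate filter.** Within each strain, the two replicate libraries are
compared by the same Pearson χ² and the site is dropped when p < 0.10 in
either strain (p exactly at the cutoff is kept). This reproduces the plain
read-count test; under the two-stage model it has null expectation
λ ≈ 1 + d/(2N), so at 200× it removes roughly three-quarters of sites whose
*strain* frequencies are identical — it is a filter against pool-sampling
noise as much as against technical inconsistency, and it removes true
signal sites at the same rate. Users who want the filter to flag only
super-Poisson inconsistency can set `rep_filter_pool_chromosomes = 2N`,
which deflates the replicate χ² by 1 + d̃/2N (harmonic-mean depth); even a
perfectly calibrated filter still drops 1 − 0.9² = 19% of honest sites at
the 0.10 cutoff, which is the price of the published filtering rule. This
dropout is the dominant source of run-to-run variability in planted-signal
recovery: with three planted sites per gene at 200×, the gene retains at
least one passing site in ~80% of seeds, and a single planted hairpin SNP
survives in ~25–45% of seeds.

**Aggregation.** The Benjamini–Hochberg step-up adjustment (via statsmodels)
is applied across passing-site p values — site level, because p values exist
only per site — with significance at adjusted p ≤ 0.001. Passing sites are
assigned to genes by interval overlap (a site inside two overlapping genes
contributes to both; duplication is conservative). The gene score is the
weighted mean of site scores with weights equal to each site's summed
cross-library depth — the natural precision weight; `weight_mode="uniform"`
is available since the weighting rule is a free choice. Genes with no
passing site are omitted and listed in a skipped-genes report. Calls use
weighted score ≥ 15; per-chromosome tallies of called genes always sum to
the genome-wide count.

## Hairpin SNP scan

Pre-miRNA intervals are scanned for passing sites with score strictly
greater than 3.0 (χ² p < 10⁻³) — permissive because hairpins are ~100 nt
and carry at most a few segregating sites. A hairpin is "sufficiently
covered" when ≥80% of its bases reach the minimum per-base depth; the 0.8
fraction is a package choice (configurable), as no principled standard
exists. Per-base depth tables are only generated over the hairpin intervals,
which is all this stage consumes.

## Enrichment

Category over-representation is P(X ≥ k) for X ~ Hypergeometric(N, K, n)
via the scipy survival function (log-space, stable for N ~ 10⁴), against a
Bonferroni family-wise alpha that defaults to 0.007. The alpha is taken as
given rather than derived from the category count, because 0.05/6 and
0.05/7 bracket it and either family size is defensible; it is a parameter.
Genes with dual curation carry one primary label; enrichment uses primary
labels only. Percentage breakdowns are rounded to one decimal and checked
to sum to 100 ± 1.

## Dose–response and assays

Probit LC50: GLM with probit link of (dead, alive) on log₁₀ dose;
LC50 = 10^(−α/β). The 95% CI uses the delta method on log₁₀(LC50) — the
default because it is standard and cheap — with Fieller's theorem behind
`ci_method="fieller"`. Degenerate responses (all dead / all alive, or
non-positive slope) return `converged=False` with a diagnostic instead of
raising. The fit is scale-equivariant: multiplying doses by c multiplies
LC50 by c exactly. Monte-Carlo checks at the bottle design (20 × 3 × 5,
slope 3/decade, doses log-spaced ±0.6 decades around truth) show ~95% CI
coverage and ±20% LC50 recovery in >90% of runs at both the ~2.4 µg and
~25 µg strain scales.

The noise-free generator rounds expected deaths half up for deterministic
integer fixtures; `round_deaths=False` returns exact fractional expectations,
which the probit refit inverts to machine precision (with rounding at
n = 20 the 0%/50%/100% pattern makes the slope unidentifiable).

Knockdown time courses are summarised as per-timepoint proportions and
compared by one-way ANOVA on replicate-level proportions at the 60-minute
endpoint (the end of the standard 1-hour observation window; configurable).
Mortality endpoints differ by assay — 24 h for LC50 assays, 3 days for
discriminating-dose assays — and are data fields, not assumptions. No
control-mortality (Abbott's) correction is applied.

ΔΔCt: technical replicates are averaged per (sample, gene); the two
reference genes are combined by the arithmetic mean of their Cts
(equivalent to a geometric mean of quantities at equal efficiency);
RQ = 2^(−ΔΔCt) versus the calibrator-group mean ΔCt. RQ is invariant to a
constant Ct offset (amplifier shift), and the calibrator group's mean RQ is
identically 1.

## Problem sizes

Simulation studies in the tests and the acceptance script use 10,001 sites ×
500 genes at 100× (null calibration), 184 sites × 61 genes at 200× over 20
seeds (planted recovery), and 200 Monte-Carlo bottle-assay fits per strain
scale — sizes chosen so every property is measured with useful precision on
a single CPU in seconds.

## Known limitations

* No linkage, so gene scores aggregate independent sites; real pool-seq
  sites within a gene are correlated.
* The replicate filter reproduces the published read-count rule, which is
  strongly anti-signal at high depth (see above); the overdispersion-aware
  variant is offered but not the default.
* BH adjustment at the site level is one of two defensible choices (the
  gene level being the other); it is configurable in spirit via the site
  table, which carries all per-site adjusted values.
* Enrichment assumes one primary category per gene and a fully annotated
  background.
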