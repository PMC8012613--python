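"""Synthetic pool-seq and bioassay data with the structure the scan assumes.

The pooled-sequencing generator models the two-stage sampling process of
pooled libraries explicitly: for each library, a pool of ``n_diploids_per_pool``
mosquitoes (2N chromosomes) is drawn binomially from the strain's true allele
frequency, and reads are then drawn binomially from the realized pool
frequency at a negative-binomial (or fixed) depth. Two replicate pools per
strain are independent sets of mosquitoes, so replicate read counts are
overdispersed relative to single-stage binomial read sampling — the property
that drives the replicate-consistency filter's behaviour downstream.

Selected ("planted") sites get strain frequencies separated by ``delta_f``,
clipped so both stay in [0, 1]; non-selected sites share one ancestral
frequency. One planted site always sits inside a pre-miRNA hairpin interval
so the hairpin SNP scan is exercised end to end. A single-stage mode
(``two_stage=False``) bypasses the pool stage for calibration studies.

Dose–response, genotype and qPCR generators mirror the bioassay designs:
20 insects per bottle × 3 replicates × 5 doses for LC50 estimation, class
frequencies for multi-locus KDR genotypes, and Ct tables encoding a chosen
fold-change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import (
    BASES,
    GenomicInterval,
    write_depth_table,
    write_intervals_bed,
    write_readcounts,
)

CHROMS = ("chr1", "chr2", "chr3")

#: The hairpin hosting the planted SNP; the SNP sits at chr1:50888906.
MIR33_INTERVAL = GenomicInterval("chr1", 50888851, 50888950, "mir-33", "pre_miRNA")
MIR33_SNP_POS = 50888906


def default_premirna_intervals() -> list[GenomicInterval]:
    """Seven hairpin intervals; only mir-33 contains a segregating site."""
    others = [
        GenomicInterval("chr1", 60_000_001, 60_000_100, "mir-100a", "pre_miRNA"),
        GenomicInterval("chr1", 61_000_001, 61_000_090, "mir-12", "pre_miRNA"),
        GenomicInterval("chr2", 55_000_001, 55_000_110, "mir-8", "pre_miRNA"),
        GenomicInterval("chr2", 56_000_001, 56_000_095, "mir-281", "pre_miRNA"),
        GenomicInterval("chr3", 70_000_001, 70_000_100, "mir-184", "pre_miRNA"),
        GenomicInterval("chr3", 71_000_001, 71_000_105, "mir-275", "pre_miRNA"),
    ]
    return [MIR33_INTERVAL] + others


@dataclass
class PoolSimParams:
    """Parameters of the two-stage pooled-sequencing simulator.

    Defaults mirror the study design this emulates: dual replicate pools of
    22 diploids per strain. ``depth_dispersion`` is the negative-binomial
    size parameter (variance = mean + mean²/dispersion); ``None`` fixes depth
    at ``depth_mean``. ``base_freq_range`` bounds the shared ancestral allele
    frequency (uniform draw). ``delta_f`` is the absolute strain difference
    planted at selected sites, clipped so frequencies stay in [0, 1].
    """

    n_sites: int
    n_genes: int
    n_diploids_per_pool: int = 22
    n_replicates_per_strain: int = 2
    depth_mean: float = 100.0
    depth_dispersion: Optional[float] = None
    base_freq_range: tuple[float, float] = (0.1, 0.9)
    n_selected_sites: int = 0
    delta_f: float = 0.0
    premirna_intervals: list[GenomicInterval] = field(
        default_factory=default_premirna_intervals
    )
    seed: int = 0
    two_stage: bool = True

    def __post_init__(self):
        if self.n_sites < 1 or self.n_genes < 1:
            raise ValidationError("n_sites and n_genes must be >= 1")
        if self.n_selected_sites > self.n_sites:
            raise ValidationError("n_selected_sites cannot exceed n_sites")
        if self.n_selected_sites < 0:
            raise ValidationError("n_selected_sites must be >= 0")
        if not 0.0 <= self.delta_f <= 1.0:
            raise ValidationError("delta_f must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be positive")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise ValidationError("depth_dispersion must be positive")
        lo, hi = self.base_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("base_freq_range must satisfy 0 < lo <= hi < 1")
        if self.n_diploids_per_pool < 1 or self.n_replicates_per_strain < 2:
            raise ValidationError("need >=1 diploid per pool and >=2 replicates")
        if not self.premirna_intervals:
            raise ValidationError("premirna_intervals must be non-empty")


@dataclass
class Bundle:
    """Everything one simulated study provides to the pipeline."""

    params: PoolSimParams
    counts: pd.DataFrame          # wide per-site matrix (association input)
    truth: pd.DataFrame           # per-site true frequencies and flags
    genes: list                   # GenomicInterval, kind="gene"
    premirnas: list               # GenomicInterval, kind="pre_miRNA"
    depth: pd.DataFrame           # per-base depth over the hairpin intervals
    library_ids: list


def _draw_depth(rng, mean, dispersion, size):
    if dispersion is None:
        return np.full(size, int(round(mean)), dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _site_layout(params: PoolSimParams) -> tuple[pd.DataFrame, list[GenomicInterval]]:
    """Place genes on three chromosomes and spread sites inside them.

    The first site of the table is the planted hairpin SNP (chr1:50888906);
    the remaining ``n_sites - 1`` sites are split as evenly as possible
    across ``n_genes`` consecutive 1 kb gene intervals (extra sites go to the
    first genes).
    """
    n_gene_sites = params.n_sites - 1
    per_gene = np.full(params.n_genes, n_gene_sites // params.n_genes)
    per_gene[: n_gene_sites % params.n_genes] += 1
    chrom_of_gene = [CHROMS[(3 * g) // params.n_genes] for g in range(params.n_genes)]

    genes, rows = [], []
    index_on_chrom: dict[str, int] = {}
    for g in range(params.n_genes):
        chrom = chrom_of_gene[g]
        i = index_on_chrom.get(chrom, 0)
        index_on_chrom[chrom] = i + 1
        start = 10_001 + i * 2_000
        genes.append(GenomicInterval(chrom, start, start + 999, f"gene{g + 1:05d}", "gene"))
        m = per_gene[g]
        if m == 0:
            continue
        offsets = np.unique(np.round(np.linspace(0, 999, m)).astype(int))
        for off in offsets:
            rows.append((chrom, start + int(off), f"gene{g + 1:05d}"))

    hairpin = next(
        iv for iv in params.premirna_intervals if iv.contains("chr1", MIR33_SNP_POS)
    )
    layout = pd.DataFrame(
        [("chr1", MIR33_SNP_POS, "")] + rows, columns=["chrom", "pos", "gene"]
    )
    layout["in_premirna"] = False
    layout.loc[0, "in_premirna"] = True
    return layout, genes


def simulate_bundle(params: PoolSimParams) -> Bundle:
    """Simulate one full study: counts, truth table, intervals and depth."""
    rng = np.random.default_rng(params.seed)
    layout, genes = _site_layout(params)
    n = len(layout)

    lo, hi = params.base_freq_range
    f0 = rng.uniform(lo, hi, n)
    selected = np.zeros(n, dtype=bool)
    if params.n_selected_sites > 0:
        selected[: params.n_selected_sites] = True  # hairpin SNP first, then gene 1, ...
    centre = np.clip(f0, params.delta_f / 2, 1 - params.delta_f / 2)
    f_R = np.where(selected, centre + params.delta_f / 2, f0)
    f_S = np.where(selected, centre - params.delta_f / 2, f0)

    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4

    library_ids = [
        f"{strain}{rep + 1}"
        for strain in ("R", "S")
        for rep in range(params.n_replicates_per_strain)
    ]
    counts = layout[["chrom", "pos"]].copy()
    counts["ref_base"] = np.array(BASES)[ref_idx]
    counts["alt_base"] = np.array(BASES)[alt_idx]
    counts["multiallelic"] = False
    n_chrom = 2 * params.n_diploids_per_pool
    for lib in library_ids:
        f_true = f_R if lib.startswith("R") else f_S
        if params.two_stage:
            pool_f = rng.binomial(n_chrom, f_true, n) / n_chrom
        else:
            pool_f = f_true
        depth = _draw_depth(rng, params.depth_mean, params.depth_dispersion, n)
        alt = rng.binomial(depth, pool_f)
        counts[f"ref_{lib}"] = depth - alt
        counts[f"alt_{lib}"] = alt
    counts["depth_total"] = sum(
        counts[f"ref_{lib}"] + counts[f"alt_{lib}"] for lib in library_ids
    )

    truth = layout.copy()
    truth["f_R"] = f_R
    truth["f_S"] = f_S
    truth["selected"] = selected
    gene_has_selected = (
        truth.loc[truth["gene"] != ""].groupby("gene")["selected"].any()
    )
    truth["gene_contains_selected"] = np.asarray(
        truth["gene"].map(gene_has_selected).to_numpy(na_value=False), dtype=bool
    )

    depth_rows = []
    for iv in params.premirna_intervals:
        positions = np.arange(iv.start, iv.end + 1)
        per_lib = {
            f"depth_{lib}": _draw_depth(
                rng, params.depth_mean, params.depth_dispersion, positions.size
            )
            for lib in library_ids
        }
        block = pd.DataFrame({"chrom": iv.chrom, "pos": positions, **per_lib})
        depth_rows.append(block)
    depth = pd.concat(depth_rows, ignore_index=True)

    return Bundle(
        params=params,
        counts=counts,
        truth=truth,
        genes=genes,
        premirnas=list(params.premirna_intervals),
        depth=depth,
        library_ids=library_ids,
    )


def simulate_pool_readcounts(
    params: PoolSimParams,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-library readcount tables (TSV dialect layout) plus the truth table."""
    bundle = simulate_bundle(params)
    tables = {}
    for lib in bundle.library_ids:
        table = bundle.counts[["chrom", "pos", "ref_base"]].rename(
            columns={"ref_base": "ref"}
        )
        for base in BASES:
            table[base] = 0
        rows = np.arange(len(table))
        base_pos = {b: i for i, b in enumerate(BASES)}
        mat = np.zeros((len(table), 4), dtype=np.int64)
        ref_cols = bundle.counts["ref_base"].map(base_pos).to_numpy()
        alt_cols = bundle.counts["alt_base"].map(base_pos).to_numpy()
        mat[rows, ref_cols] = bundle.counts[f"ref_{lib}"].to_numpy()
        mat[rows, alt_cols] = bundle.counts[f"alt_{lib}"].to_numpy()
        table[list(BASES)] = mat
        tables[lib] = table
    return tables, bundle.truth


def write_bundle(bundle: Bundle, outdir) -> dict[str, Path]:
    """Write the fixture-bundle directory layout consumed by the pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_pool_readcounts(bundle.params)
    paths = {}
    for lib, table in tables.items():
        path = outdir / f"readcounts_{lib}.tsv"
        write_readcounts(table, path)
        paths[f"readcounts_{lib}"] = path
    write_intervals_bed(bundle.genes, outdir / "genes.bed")
    write_intervals_bed(bundle.premirnas, outdir / "premirna.bed")
    write_depth_table(bundle.depth, outdir / "depth.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    paths.update(
        genes=outdir / "genes.bed",
        premirna=outdir / "premirna.bed",
        depth=outdir / "depth.tsv",
        truth=outdir / "truth.tsv",
    )
    return paths


# ---------------------------------------------------------------------------
# dose–response
# ---------------------------------------------------------------------------

@dataclass
class BioassaySimParams:
    """Bottle-bioassay design: 20 insects/bottle × 3 replicates × 5 doses."""

    true_lc50: float
    probit_slope: float = 3.0
    doses: Optional[Sequence[float]] = None
    n_per_bottle: int = 20
    n_replicates: int = 3
    population: str = "pop"
    seed: int = 0

    def __post_init__(self):
        if self.true_lc50 <= 0 or self.probit_slope <= 0:
            raise ValidationError("true_lc50 and probit_slope must be positive")
        if self.doses is None:
            # five doses log-spaced ±0.6 decades around the true LC50
            self.doses = list(self.true_lc50 * 10.0 ** np.linspace(-0.6, 0.6, 5))
        if any(d <= 0 for d in self.doses):
            raise ValidationError("doses must be strictly positive")
        if self.n_per_bottle < 1 or self.n_replicates < 1:
            raise ValidationError("n_per_bottle and n_replicates must be >= 1")


def simulate_dose_response(
    params: BioassaySimParams,
    noise_free: bool = False,
    round_deaths: bool = True,
) -> pd.DataFrame:
    """Deaths per bottle under the log-dose probit model.

    Deaths are binomial with P(death) = Φ(slope·(log10 dose − log10 LC50)).
    ``noise_free`` replaces the draw by the expected deaths, rounded half up
    (or exact fractional counts with ``round_deaths=False``, which a probit
    refit inverts exactly).
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for dose in params.doses:
        p = stats.norm.cdf(
            params.probit_slope * (np.log10(dose) - np.log10(params.true_lc50))
        )
        for rep in range(1, params.n_replicates + 1):
            if noise_free:
                expected = params.n_per_bottle * p
                dead = float(np.floor(expected + 0.5)) if round_deaths else expected
            else:
                dead = int(rng.binomial(params.n_per_bottle, p))
            rows.append((params.population, dose, rep, params.n_per_bottle, dead))
    return pd.DataFrame(
        rows, columns=["population", "dose", "replicate", "n_exposed", "n_dead"]
    )


# ---------------------------------------------------------------------------
# genotype and qPCR tables
# ---------------------------------------------------------------------------

KDR_LOCI = ("V410L", "V1016I", "F1534C")


def simulate_genotype_table(
    class_frequencies: Mapping[str, float],
    n_individuals: int,
    seed: int = 0,
    loci: Sequence[str] = KDR_LOCI,
) -> pd.DataFrame:
    """Multi-locus genotype records with multinomially drawn composite classes.

    Each individual receives one composite class (the same genotype at every
    locus), drawn from ``class_frequencies`` — e.g. 67% homozygous-resistant
    at all three KDR loci.
    """
    if n_individuals < 1:
        raise ValidationError("n_individuals must be >= 1")
    classes = list(class_frequencies)
    freqs = np.array([class_frequencies[c] for c in classes], dtype=float)
    if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValidationError("class frequencies must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    assigned = rng.choice(len(classes), size=n_individuals, p=freqs)
    rows = [
        (f"ind{i + 1:04d}", locus, classes[assigned[i]])
        for i in range(n_individuals)
        for locus in loci
    ]
    return pd.DataFrame(rows, columns=["individual", "locus", "genotype"])


def simulate_ct_table(
    fold_changes: Mapping[str, float],
    calibrator_group: str = "control",
    n_samples_per_group: int = 3,
    n_technical: int = 3,
    noise_sd: float = 0.0,
    target: str = "VGSC",
    reference_genes: Sequence[str] = ("ACTIN", "RPS7"),
    seed: int = 0,
    reference_ct: float = 18.0,
    calibrator_delta_ct: float = 2.0,
) -> pd.DataFrame:
    """Ct records encoding a chosen expression fold-change per group.

    The calibrator group's target sits ``calibrator_delta_ct`` cycles above
    the reference mean; a group with fold-change F is shifted by −log2(F)
    cycles. Gaussian noise of ``noise_sd`` cycles is added per record.
    """
    if calibrator_group not in fold_changes:
        raise ValidationError("fold_changes must include the calibrator group")
    if any(f <= 0 for f in fold_changes.values()):
        raise ValidationError("fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fc in fold_changes.items():
        rel = fc / fold_changes[calibrator_group]
        for s in range(1, n_samples_per_group + 1):
            sample = f"{group}_s{s}"
            target_ct = reference_ct + calibrator_delta_ct - np.log2(rel)
            for gene, ct in [(target, target_ct)] + [
                (ref, reference_ct) for ref in reference_genes
            ]:
                for tech in range(1, n_technical + 1):
                    rows.append(
                        (sample, group, gene, ct + rng.normal(0.0, noise_sd), tech)
                    )
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct", "technical"])


def simulate_assay_tables(
    class_frequencies: Mapping[str, float],
    fold_changes: Mapping[str, float],
    n_individuals: int,
    seed: int = 0,
    **ct_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype table plus Ct table from one seed (fixtures for the assays)."""
    genotypes = simulate_genotype_table(class_frequencies, n_individuals, seed=seed)
    cts = simulate_ct_table(fold_changes, seed=seed + 1, **ct_kwargs)
    return genotypes, cts
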