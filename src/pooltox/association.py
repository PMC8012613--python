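"""Per-site strain-differentiation scan and gene-wise score aggregation.

The core statistic is a Pearson χ² (1 df, no continuity correction) on the
2×2 table of pooled ref/alt read counts in the resistant (R) versus
susceptible (S) strain, with counts summed across each strain's replicate
libraries. Sites pass three filters, in order:

1. coverage — total depth >= ``min_coverage`` in every library (applied at
   parse time by :mod:`pooltox.io`, re-checked here);
2. replicate consistency — a within-strain χ² between the two replicate
   libraries must NOT reject homogeneity at ``rep_p_cutoff`` (a site is kept
   only if it is consistent in both strains);
3. the association χ² itself, summarised as −log10(p), with a
   Benjamini–Hochberg adjustment across all passing sites.

Passing sites are aggregated to genes by interval overlap as a depth-weighted
mean of site scores; a gene is called at ``weighted_score >= gene_threshold``.

A practical caveat documented here because it shapes every downstream result:
with pools of 2N chromosomes sequenced to per-library depth d, the
between-replicate χ² on read counts has null expectation ≈ 1 + d/(2N) —
replicate pools are different mosquitoes, so deep sequencing resolves real
pool-composition differences and the replicate filter removes a substantial
fraction of sites whose *strain* frequencies are identical. An optional
pool-size-aware correction (``rep_filter_pool_chromosomes``) rescales the
replicate χ² by that factor for users who want the filter to flag only
super-Poisson inconsistency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import GenomicInterval, intervals_to_frame

#: p values are floored here before taking −log10, keeping scores finite.
P_FLOOR = 1e-300


@dataclass
class FilterParams:
    """Thresholds controlling the association scan.

    min_coverage
        Minimum reads per library at a site (default 22 — one read per pooled
        diploid genome).
    rep_p_cutoff
        Between-replicate χ² p below this drops the site (default 0.10).
    bh_cutoff
        Benjamini–Hochberg adjusted-p significance level over site p values
        (default 0.001).
    gene_threshold
        Gene-wise weighted −log10(p) call threshold (default 15).
    mirna_threshold
        Per-SNP score threshold for the pre-miRNA scan (default 3.0, strict >).
    weight_mode
        "depth" (default) weights each site by its summed cross-library depth;
        "uniform" gives every passing site equal weight.
    fisher_fallback
        If True, sites where any expected cell count is < 5 use Fisher's exact
        p instead of the χ² tail.
    rep_filter_pool_chromosomes
        If set (e.g. 44 for pools of 22 diploids), the replicate χ² is divided
        by 1 + depth/(pool chromosomes) to correct for pool-sampling
        overdispersion. Default None reproduces the plain read-count test.
    """

    min_coverage: int = 22
    rep_p_cutoff: float = 0.10
    bh_cutoff: float = 0.001
    gene_threshold: float = 15.0
    mirna_threshold: float = 3.0
    weight_mode: str = "depth"
    fisher_fallback: bool = False
    rep_filter_pool_chromosomes: Optional[int] = None

    def __post_init__(self):
        for name in ("rep_p_cutoff", "bh_cutoff"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {value}")
        if self.min_coverage < 0 or self.gene_threshold < 0 or self.mirna_threshold < 0:
            raise ValidationError("coverage/thresholds must be >= 0")
        if self.weight_mode not in ("depth", "uniform"):
            raise ValidationError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class SiteAssociation:
    chi2: float
    p: float
    neg_log10_p: float


@dataclass
class GeneAssociation:
    gene_id: str
    chrom: str
    weighted_score: float
    n_sites_pass: int
    total_depth_weight: float
    passes_threshold: bool
    bh_significant: bool = False


@dataclass
class AssociationResult:
    """Site table, ranked gene table, skipped genes and per-chromosome tallies."""

    site_table: pd.DataFrame
    gene_table: pd.DataFrame
    skipped_genes: list
    tallies: dict


# ---------------------------------------------------------------------------
# χ² primitives (vectorised; scalars are 0-d arrays)
# ---------------------------------------------------------------------------

def _pearson_chi2_2x2(a, b, c, d):
    """Pearson χ² for tables [[a, b], [c, d]], no continuity correction.

    A zero column margin (an allele absent everywhere) gives χ²=0 by
    convention; zero row margins are the caller's responsibility.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValidationError("counts must be non-negative")
    n = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    num = n * (a * d - b * c) ** 2
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def site_chi2(
    counts_R: Sequence[float], counts_S: Sequence[float], p_floor: float = P_FLOOR
) -> SiteAssociation:
    """Strain-differentiation χ² at one site from pooled (ref, alt) counts.

    ``counts_R``/``counts_S`` are the per-strain (ref, alt) read counts summed
    over that strain's replicate libraries. Returns the 1-df χ², its upper
    tail p (floored at ``p_floor``) and −log10(p).
    """
    ref_r, alt_r = counts_R
    ref_s, alt_s = counts_S
    if ref_r + alt_r <= 0 or ref_s + alt_s <= 0:
        raise ValidationError("both strain totals must be positive")
    chi2 = float(_pearson_chi2_2x2(ref_r, alt_r, ref_s, alt_s))
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    p = max(p, p_floor)
    return SiteAssociation(chi2=chi2, p=p, neg_log10_p=-np.log10(p))


def replicate_consistency_filter(
    rep1: Sequence[float],
    rep2: Sequence[float],
    rep_p_cutoff: float = 0.10,
    pool_chromosomes: Optional[int] = None,
) -> tuple[float, bool]:
    """Between-replicate homogeneity χ² for one strain at one site.

    Returns ``(p, keep)`` with ``keep = (p >= rep_p_cutoff)`` — a p exactly at
    the cutoff is kept (strict-less-than drops). With ``pool_chromosomes``
    set, the χ² is deflated by 1 + depth/pool_chromosomes (harmonic-mean
    depth) to account for pool-sampling overdispersion.
    """
    chi2 = float(_pearson_chi2_2x2(rep1[0], rep1[1], rep2[0], rep2[1]))
    if pool_chromosomes:
        d1, d2 = rep1[0] + rep1[1], rep2[0] + rep2[1]
        d_harm = 2.0 / (1.0 / d1 + 1.0 / d2)
        chi2 /= 1.0 + d_harm / pool_chromosomes
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return p, p >= rep_p_cutoff


def bh_adjust(
    p_values: Sequence[float], bh_cutoff: float = 0.001
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p values and significance flags.

    Returns ``(adjusted, significant)``; adjusted values are monotone, capped
    at 1 and stable under input reordering. Empty input yields empty arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p values must be in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return adjusted, adjusted <= bh_cutoff


def gene_score(
    gene_id: str,
    site_scores: Sequence[float],
    site_depths: Sequence[float],
    params: FilterParams = None,
    chrom: str = "",
) -> GeneAssociation:
    """Depth-weighted mean of passing-site scores for one gene.

    Weights are each site's total cross-library depth (or uniform under
    ``weight_mode='uniform'``). Requires at least one passing site.
    """
    params = params or FilterParams()
    scores = np.asarray(site_scores, dtype=float)
    depths = np.asarray(site_depths, dtype=float)
    if scores.size == 0:
        raise ValidationError(f"gene {gene_id} has no passing sites")
    weights = depths if params.weight_mode == "depth" else np.ones_like(scores)
    weighted = float(np.average(scores, weights=weights))
    return GeneAssociation(
        gene_id=gene_id,
        chrom=chrom,
        weighted_score=weighted,
        n_sites_pass=int(scores.size),
        total_depth_weight=float(depths.sum()),
        passes_threshold=weighted >= params.gene_threshold,
    )


# ---------------------------------------------------------------------------
# full scan
# ---------------------------------------------------------------------------

def _library_columns(counts: pd.DataFrame) -> dict[str, list[str]]:
    """Map strain letter -> library ids found in the wide count matrix."""
    libs: dict[str, list[str]] = {}
    for col in counts.columns:
        if col.startswith("ref_") and col != "ref_base":
            lib = col[4:]
            libs.setdefault(lib[0], []).append(lib)
    return libs


def _rep_chi2_array(counts, libs, params):
    """Vectorised 2×k replicate-homogeneity χ² (k replicate libraries)."""
    refs = np.column_stack([counts[f"ref_{lib}"].to_numpy(float) for lib in libs])
    alts = np.column_stack([counts[f"alt_{lib}"].to_numpy(float) for lib in libs])
    depths = refs + alts
    n = depths.sum(axis=1, keepdims=True)
    ref_tot = refs.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        e_ref = depths * ref_tot / n
        e_alt = depths * (n - ref_tot) / n
        chi2 = np.nansum(
            np.where(e_ref > 0, (refs - e_ref) ** 2 / e_ref, 0.0)
            + np.where(e_alt > 0, (alts - e_alt) ** 2 / e_alt, 0.0),
            axis=1,
        )
    if params.rep_filter_pool_chromosomes:
        d_harm = depths.shape[1] / (1.0 / np.maximum(depths, 1)).sum(axis=1)
        chi2 = chi2 / (1.0 + d_harm / params.rep_filter_pool_chromosomes)
    df = depths.shape[1] - 1
    p = stats.chi2.sf(chi2, df=df)
    return np.where(chi2 > 0, p, 1.0)


def _assign_sites_to_genes(site_table: pd.DataFrame, genes: pd.DataFrame):
    """Yield (gene row, integer index array of overlapping sites).

    Sites are matched by 1-based position overlap; overlapping genes each
    receive the shared sites (duplication is deliberate and logged upstream).
    """
    by_chrom = {}
    for chrom, sub in site_table.groupby("chrom", sort=False):
        order = np.argsort(sub["pos"].to_numpy())
        by_chrom[chrom] = (sub["pos"].to_numpy()[order], sub.index.to_numpy()[order])
    for gene in genes.itertuples(index=False):
        if gene.chrom not in by_chrom:
            yield gene, np.array([], dtype=int)
            continue
        pos, idx = by_chrom[gene.chrom]
        lo = np.searchsorted(pos, gene.start, side="left")
        hi = np.searchsorted(pos, gene.end, side="right")
        yield gene, idx[lo:hi]


def run_association(
    counts: pd.DataFrame,
    genes,
    params: FilterParams = None,
) -> AssociationResult:
    """Run the per-site scan and gene aggregation over a wide count matrix.

    ``counts`` is the matrix produced by :func:`pooltox.io.load_pool_counts`
    or the simulator: one row per biallelic site with ``ref_<lib>``/
    ``alt_<lib>`` columns for libraries named ``R1, R2, ..., S1, S2, ...``.
    ``genes`` is a list of :class:`GenomicInterval` or an equivalent frame.
    """
    params = params or FilterParams()
    if isinstance(genes, (list, tuple)):
        genes = intervals_to_frame(genes)
    if genes.empty:
        raise ValidationError("gene intervals must be non-empty")
    libs = _library_columns(counts)
    if set(libs) != {"R", "S"} or any(len(v) < 2 for v in libs.values()):
        raise ValidationError(
            "need >=2 libraries per strain named R*/S*, got " f"{libs}"
        )

    site = counts[["chrom", "pos", "ref_base", "alt_base"]].copy()
    lib_ids = libs["R"] + libs["S"]
    depth_total = sum(
        counts[f"ref_{lib}"].to_numpy(float) + counts[f"alt_{lib}"].to_numpy(float)
        for lib in lib_ids
    )
    site["depth_total"] = depth_total
    per_lib_depth = np.column_stack(
        [
            counts[f"ref_{lib}"].to_numpy(float) + counts[f"alt_{lib}"].to_numpy(float)
            for lib in lib_ids
        ]
    )
    low_coverage = (per_lib_depth < params.min_coverage).any(axis=1)

    site["rep_p_R"] = _rep_chi2_array(counts, libs["R"], params)
    site["rep_p_S"] = _rep_chi2_array(counts, libs["S"], params)
    discordant = (site["rep_p_R"] < params.rep_p_cutoff) | (
        site["rep_p_S"] < params.rep_p_cutoff
    )

    ref_R = sum(counts[f"ref_{lib}"].to_numpy(float) for lib in libs["R"])
    alt_R = sum(counts[f"alt_{lib}"].to_numpy(float) for lib in libs["R"])
    ref_S = sum(counts[f"ref_{lib}"].to_numpy(float) for lib in libs["S"])
    alt_S = sum(counts[f"alt_{lib}"].to_numpy(float) for lib in libs["S"])
    chi2 = _pearson_chi2_2x2(ref_R, alt_R, ref_S, alt_S)
    p = np.where(chi2 > 0, stats.chi2.sf(chi2, df=1), 1.0)
    if params.fisher_fallback:
        n = ref_R + alt_R + ref_S + alt_S
        with np.errstate(invalid="ignore", divide="ignore"):
            e_min = np.min(
                np.stack(
                    [
                        (ref_R + alt_R) * (ref_R + ref_S) / n,
                        (ref_R + alt_R) * (alt_R + alt_S) / n,
                        (ref_S + alt_S) * (ref_R + ref_S) / n,
                        (ref_S + alt_S) * (alt_R + alt_S) / n,
                    ]
                ),
                axis=0,
            )
        for i in np.flatnonzero(e_min < 5):
            table = [[ref_R[i], alt_R[i]], [ref_S[i], alt_S[i]]]
            p[i] = stats.fisher_exact(np.asarray(table, dtype=int))[1]
    p = np.maximum(p, P_FLOOR)
    site["chi2"] = chi2
    site["p"] = p
    site["neg_log10_p"] = -np.log10(p)

    status = np.full(len(site), "pass", dtype=object)
    status[discordant.to_numpy()] = "replicate_discordant"
    status[low_coverage] = "low_coverage"
    site["status"] = status
    passing = site["status"] == "pass"

    site["bh_adjusted_p"] = np.nan
    site["bh_significant"] = False
    if passing.any():
        adjusted, significant = bh_adjust(
            site.loc[passing, "p"].to_numpy(), params.bh_cutoff
        )
        site.loc[passing, "bh_adjusted_p"] = adjusted
        site.loc[passing, "bh_significant"] = significant

    pass_sites = site.loc[passing]
    gene_rows, skipped = [], []
    gene_bh_flags = []
    for gene, idx in _assign_sites_to_genes(pass_sites, genes):
        if idx.size == 0:
            skipped.append(gene.name)
            continue
        sub = pass_sites.loc[idx]
        ga = gene_score(
            gene.name,
            sub["neg_log10_p"].to_numpy(),
            sub["depth_total"].to_numpy(),
            params,
            chrom=gene.chrom,
        )
        ga.bh_significant = bool(sub["bh_significant"].any())
        gene_rows.append(ga)
        gene_bh_flags.append(ga.bh_significant)

    gene_table = pd.DataFrame(
        [
            (
                g.gene_id,
                g.chrom,
                g.weighted_score,
                g.n_sites_pass,
                g.total_depth_weight,
                g.passes_threshold,
                g.bh_significant,
            )
            for g in gene_rows
        ],
        columns=[
            "gene_id",
            "chrom",
            "weighted_score",
            "n_sites_pass",
            "total_depth_weight",
            "passes_threshold",
            "bh_significant",
        ],
    )
    gene_table = gene_table.sort_values(
        ["weighted_score", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    gene_table["rank"] = np.arange(1, len(gene_table) + 1)

    called = gene_table.loc[gene_table["passes_threshold"]]
    per_chrom = called.groupby("chrom").size().to_dict()
    tallies = {
        "genes_total": int(len(gene_table)),
        "genes_passing_threshold": int(len(called)),
        "genes_passing_by_chrom": {k: int(v) for k, v in sorted(per_chrom.items())},
        "sites_total": int(len(site)),
        "sites_pass": int(passing.sum()),
        "sites_low_coverage": int((site["status"] == "low_coverage").sum()),
        "sites_replicate_discordant": int(
            (site["status"] == "replicate_discordant").sum()
        ),
    }
    return AssociationResult(
        site_table=site,
        gene_table=gene_table,
        skipped_genes=skipped,
        tallies=tallies,
    )
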