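"""Pre-miRNA hairpin coverage report and SNP scan.

SNP discovery inside microRNA hairpins uses a deliberately permissive score
threshold (default 3.0, i.e. χ² p < 10⁻³, strict greater-than): hairpins are
short (~100 nt), so at most a handful of segregating sites exist per hairpin
and genome-wide multiplicity does not apply. A hairpin is reported as having
sufficient coverage for association analysis when at least
``coverage_fraction`` of its bases reach the scan's minimum per-base depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .association import FilterParams
from .errors import ConfigError
from .io import GenomicInterval, interval_mean_depth


@dataclass
class MirnaHit:
    mirna: str
    chrom: str
    pos: int
    neg_log10_p: float
    interval_mean_depth: float
    covered_fraction: float


def scan_premirna_snps(
    site_table: pd.DataFrame,
    premirna_intervals: Sequence[GenomicInterval],
    depth_table: Optional[pd.DataFrame] = None,
    params: FilterParams = None,
    coverage_fraction: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag passing SNPs inside pre-miRNA hairpins above the score threshold.

    ``site_table`` is the per-site output of
    :func:`pooltox.association.run_association`. Returns ``(hits, coverage)``:
    ``hits`` has one row per (hairpin, SNP) with score > ``mirna_threshold``,
    sorted by score descending; ``coverage`` reports every hairpin's mean
    depth, covered fraction and sufficiency call. Hairpins overlapping the
    same SNP each report it.
    """
    params = params or FilterParams()
    intervals = list(premirna_intervals)
    if not intervals:
        raise ConfigError("no pre-miRNA intervals supplied")

    coverage_rows = []
    for iv in intervals:
        if depth_table is not None:
            mean, covered = interval_mean_depth(depth_table, iv, params.min_coverage)
        else:
            mean, covered = float("nan"), float("nan")
        coverage_rows.append(
            (
                iv.name,
                iv.chrom,
                iv.start,
                iv.end,
                mean,
                covered,
                bool(covered >= coverage_fraction) if depth_table is not None else None,
            )
        )
    coverage = pd.DataFrame(
        coverage_rows,
        columns=[
            "mirna",
            "chrom",
            "start",
            "end",
            "mean_depth",
            "covered_fraction",
            "sufficient_coverage",
        ],
    )

    passing = site_table.loc[
        (site_table["status"] == "pass")
        & (site_table["neg_log10_p"] > params.mirna_threshold)
    ]
    hit_rows = []
    for iv, cov in zip(intervals, coverage_rows):
        inside = passing.loc[
            (passing["chrom"] == iv.chrom)
            & (passing["pos"] >= iv.start)
            & (passing["pos"] <= iv.end)
        ]
        for snp in inside.itertuples(index=False):
            hit_rows.append(
                MirnaHit(
                    mirna=iv.name,
                    chrom=iv.chrom,
                    pos=int(snp.pos),
                    neg_log10_p=float(snp.neg_log10_p),
                    interval_mean_depth=cov[4],
                    covered_fraction=cov[5],
                )
            )
    hits = pd.DataFrame(
        [
            (h.mirna, h.chrom, h.pos, h.neg_log10_p, h.interval_mean_depth, h.covered_fraction)
            for h in hit_rows
        ],
        columns=[
            "mirna",
            "chrom",
            "pos",
            "neg_log10_p",
            "interval_mean_depth",
            "covered_fraction",
        ],
    )
    hits = hits.sort_values(
        ["neg_log10_p", "mirna", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return hits, coverage
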