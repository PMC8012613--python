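"""End-to-end orchestration: simulate → associate → scan hairpins → enrich → assays.

A :class:`PipelineConfig` either points at an on-disk fixture bundle
(readcounts TSVs, BED intervals, depth table) or asks for one to be simulated
in place. Every stage writes its table under the output directory with a
provenance header (tool version, seed, config hash), and ``summary.json``
collects the headline numbers. The same config and seed produce byte-identical
summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .association import FilterParams, run_association
from .enrichment import BONFERRONI_ALPHA, category_percentages, enrich_categories
from .errors import ConfigError
from .io import load_pool_counts, read_depth_table, read_intervals
from .mirna import scan_premirna_snps
from .simulate import Bundle, PoolSimParams, simulate_bundle, write_bundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Exactly one of ``simulate``/``readcounts`` modes is used: with
    ``simulate`` settings present a fixture bundle is generated under
    ``outdir/fixture``; otherwise ``readcounts`` (mapping library id → path),
    ``genes_bed``, ``premirna_bed`` and ``depth_table`` must point at files.
    """

    outdir: str = "pipeline_out"
    seed: int = 0
    # simulate mode
    simulate: Optional[dict] = None
    # file mode
    readcounts: Optional[dict] = None
    genes_bed: Optional[str] = None
    premirna_bed: Optional[str] = None
    depth_table: Optional[str] = None
    # analysis settings
    filter_params: dict = field(default_factory=dict)
    category_map: Optional[str] = None      # CSV gene_id,category
    bonferroni_alpha: float = BONFERRONI_ALPHA
    enrichment_set: str = "threshold"       # "threshold" | "bh"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        valid = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - valid)
        if unknown:
            raise ConfigError(
                f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
            )
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        settings = asdict(self)
        settings.pop("outdir", None)
        blob = json.dumps(settings, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance_lines(config: PipelineConfig) -> str:
    return (
        f"# pooltox {__version__}\n"
        f"# seed: {config.seed}\n"
        f"# config: {config.config_hash()}\n"
    )


def _write_csv(frame: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "wt") as fh:
        fh.write(_provenance_lines(config))
        frame.to_csv(fh, index=False)


def _load_inputs(config: PipelineConfig, outdir: Path):
    params = FilterParams(**config.filter_params)
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        sim_params = PoolSimParams(**sim)
        bundle = simulate_bundle(sim_params)
        write_bundle(bundle, outdir / "fixture")
        return bundle.counts, bundle.genes, bundle.premirnas, bundle.depth, params
    for key in ("readcounts", "genes_bed", "premirna_bed"):
        if getattr(config, key) is None:
            raise ConfigError(f"file mode requires config key {key!r}")
    counts = load_pool_counts(config.readcounts, min_coverage=params.min_coverage)
    genes = read_intervals(config.genes_bed, kind="gene")
    premirnas = read_intervals(config.premirna_bed, kind="pre_miRNA")
    depth = read_depth_table(config.depth_table) if config.depth_table else None
    return counts, genes, premirnas, depth, params


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all genomic stages and write the report bundle; returns the summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, genes, premirnas, depth, params = _load_inputs(config, outdir)

    result = run_association(counts, genes, params)
    _write_csv(result.site_table, outdir / "site_table.csv", config)
    _write_csv(result.gene_table, outdir / "gene_table.csv", config)
    _write_csv(
        pd.DataFrame({"gene_id": result.skipped_genes}),
        outdir / "skipped_genes.csv",
        config,
    )

    hits, coverage = scan_premirna_snps(
        result.site_table, premirnas, depth, params
    )
    _write_csv(hits, outdir / "mirna_hits.csv", config)
    _write_csv(coverage, outdir / "mirna_coverage.csv", config)

    enrichment_summary = None
    if config.category_map:
        cat = pd.read_csv(config.category_map, comment="#")
        assignment = dict(zip(cat["gene_id"], cat["category"]))
        background = list(result.gene_table["gene_id"])
        flag = (
            "passes_threshold" if config.enrichment_set == "threshold" else "bh_significant"
        )
        selected = list(
            result.gene_table.loc[result.gene_table[flag], "gene_id"]
        )
        if selected:
            enr = enrich_categories(
                selected, background, assignment, config.bonferroni_alpha
            )
            pct = category_percentages(selected, assignment)
            _write_csv(enr, outdir / "enrichment.csv", config)
            _write_csv(pct, outdir / "category_percentages.csv", config)
            enrichment_summary = {
                "n_selected": len(selected),
                "n_background": len(background),
                "significant_categories": sorted(
                    enr.loc[enr["significant"], "category"]
                ),
            }
        else:
            logger.info("no genes selected for enrichment; stage skipped")

    summary = {
        "provenance": {
            "tool": "pooltox",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
        "tallies": result.tallies,
        "n_skipped_genes": len(result.skipped_genes),
        "mirna": {
            "n_hits": int(len(hits)),
            "hits": [
                {"mirna": r.mirna, "chrom": r.chrom, "pos": int(r.pos),
                 "score": round(float(r.neg_log10_p), 6)}
                for r in hits.itertuples(index=False)
            ],
            "n_sufficient_coverage": int(
                coverage["sufficient_coverage"].fillna(False).sum()
            ),
        },
        "enrichment": enrichment_summary,
    }
    if result.site_table.empty or result.gene_table.empty:
        logger.warning("no site or gene passed all filters")
        summary["empty_result"] = True
    with open(outdir / "summary.json", "wt") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
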