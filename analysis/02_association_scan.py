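#!/usr/bin/env python
"""Per-SNP χ² association scan and gene-wise weighted scores.

Reads the fixture bundle written by 01_simulate_pools.py (regenerating it if
absent), applies coverage and replicate-consistency filters, computes each
site's strain-differentiation χ² and aggregates passing sites to
depth-weighted gene scores. Writes site/gene tables under results/ and
reports the filter attrition — note how many truly-consistent sites the
replicate filter removes at 200× depth: two pools of 22 mosquitoes genuinely
differ, and the filter flags that real pool-sampling noise.
"""

from pathlib import Path

import importlib.util

spec = importlib.util.spec_from_file_location(
    "sim01", Path(__file__).resolve().parent / "01_simulate_pools.py"
)
sim01 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim01)

from pooltox import run_association, simulate_bundle

RESULTS = sim01.RESULTS


def main():
    bundle = simulate_bundle(sim01.PARAMS)
    result = run_association(bundle.counts, bundle.genes)
    RESULTS.mkdir(exist_ok=True)
    result.site_table.to_csv(RESULTS / "site_table.csv", index=False)
    result.gene_table.to_csv(RESULTS / "gene_table.csv", index=False)

    t = result.tallies
    print(f"sites: {t['sites_total']}  pass: {t['sites_pass']}  "
          f"low-coverage: {t['sites_low_coverage']}  "
          f"replicate-discordant: {t['sites_replicate_discordant']}")
    print(f"genes emitted: {t['genes_total']}  at threshold >=15: "
          f"{t['genes_passing_threshold']}  per chromosome: {t['genes_passing_by_chrom']}")
    print(f"genes with no passing site (skipped): {len(result.skipped_genes)}")
    print("top genes by weighted score:")
    cols = ["gene_id", "chrom", "weighted_score", "n_sites_pass", "bh_significant"]
    print(result.gene_table[cols].head(5).to_string(index=False))
    top = result.gene_table.iloc[0]
    if top["gene_id"] == "gene00001" and top["weighted_score"] >= 15:
        print("-> the planted gene ranks first and clears the call threshold")
    else:
        print("-> the planted gene lost all its sites to the replicate filter "
              "this seed (expected in a minority of runs; see docs/methods.md)")


if __name__ == "__main__":
    main()
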