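#!/usr/bin/env python
"""Simulate the pooled-exome study and write the fixture bundle.

Two strains (R = permethrin-selected, S = unselected) × two replicate pools
of 22 diploids each, sequenced to ~200× per library. One gene (gene00001)
carries three planted sites with |f_R − f_S| = 0.8 and one planted SNP sits
in the mir-33 hairpin at chr1:50888906. Outputs go to results/fixture/.
"""

from pathlib import Path

from pooltox import PoolSimParams, simulate_bundle, write_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"

PARAMS = PoolSimParams(
    n_sites=184,
    n_genes=61,
    depth_mean=200.0,
    n_selected_sites=4,
    delta_f=0.8,
    seed=1,
)


def main():
    bundle = simulate_bundle(PARAMS)
    paths = write_bundle(bundle, RESULTS / "fixture")
    truth = bundle.truth
    print(f"wrote fixture bundle to {RESULTS / 'fixture'}")
    print(f"  sites: {len(truth)}  (selected: {int(truth['selected'].sum())})")
    print(f"  genes: {len(bundle.genes)}  hairpins: {len(bundle.premirnas)}")
    planted = truth.loc[truth["selected"], ["chrom", "pos", "gene", "f_R", "f_S"]]
    print("planted sites:")
    print(planted.to_string(index=False))
    print(f"files: {', '.join(sorted(p.name for p in paths.values()))}")


if __name__ == "__main__":
    main()
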