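#!/usr/bin/env python
"""Functional-category over-representation at the study's design sizes.

Builds a synthetic background of 10,447 annotated genes with a transport
category planted at 3× excess in a 2,112-gene selected set, tests each
category by the one-tailed cumulative hypergeometric with Bonferroni alpha
0.007, and prints the percentage composition of the selected set. Writes
results/enrichment.csv and results/category_percentages.csv.
"""

from pathlib import Path

import numpy as np

from pooltox import category_percentages, enrich_categories

RESULTS = Path(__file__).resolve().parent.parent / "results"

N_BACKGROUND = 10_447
N_SET = 2_112
BASE_RATES = {  # background composition; TRP enriched 3× in the selected set
    "TRP": 0.05, "MET/LIPID": 0.08, "SIGT": 0.03, "ReDox": 0.07,
    "RRTT": 0.09, "CYT/STR": 0.04, "PROT": 0.08, "UNK": 0.20, "DIV": 0.36,
}


def main():
    rng = np.random.default_rng(7)
    labels = list(BASE_RATES)
    bg_labels = rng.choice(labels, N_BACKGROUND, p=list(BASE_RATES.values()))
    background = [f"g{i}" for i in range(N_BACKGROUND)]
    assignment = dict(zip(background, bg_labels))

    # selected set: transport genes drawn at 3× their background rate
    trp = [g for g in background if assignment[g] == "TRP"]
    non_trp = [g for g in background if assignment[g] != "TRP"]
    n_trp_set = min(len(trp), round(3 * BASE_RATES["TRP"] * N_SET))
    gene_set = (
        list(rng.choice(trp, n_trp_set, replace=False))
        + list(rng.choice(non_trp, N_SET - n_trp_set, replace=False))
    )

    result = enrich_categories(gene_set, background, assignment, bonferroni_alpha=0.007)
    pct = category_percentages(gene_set, assignment)
    RESULTS.mkdir(exist_ok=True)
    result.to_csv(RESULTS / "enrichment.csv", index=False)
    pct.to_csv(RESULTS / "category_percentages.csv", index=False)

    print(f"background {N_BACKGROUND} genes; selected set {N_SET} genes")
    print(result.to_string(index=False))
    sig = result.loc[result["significant"], "category"].tolist()
    print(f"significant at Bonferroni 0.007: {sig}")
    print("selected-set composition (%):")
    print(pct.to_string(index=False))


if __name__ == "__main__":
    main()
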