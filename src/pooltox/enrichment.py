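"""Functional-category over-representation by the hypergeometric tail.

Genes carry one primary label from a controlled vocabulary of curated
functional categories (transport, metabolism/lipid, signal transduction,
redox, mitochondrial, repair/replication/transcription/translation, ...).
A category's over-representation in a selected gene set of size n against a
background of size N is P(X >= k) for X ~ Hypergeometric(N, K, n), computed
from the survival function in log space, with a Bonferroni family-wise
control across the tested categories (default alpha 0.007).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Controlled vocabulary of primary category labels.
CATEGORIES = frozenset(
    {
        "CSR",        # chemosensory
        "CYT/STR",    # cytoskeletal / structural
        "DIV",        # diverse
        "UNK",        # uncharacterized
        "Detox",
        "Detox/Redox",
        "ReDox",
        "MIT",        # mitochondrial
        "PROT",       # proteolysis / proteosomal
        "RRTT",       # repair / DNA replication / transcription / translation
        "RNA_PROC",
        "SIGT",       # signal transduction
        "MET/LIPID",
        "TRP",        # transport
        "IMM",        # immunity
    }
)

#: Default Bonferroni family-wise alpha for the enrichment scan.
BONFERRONI_ALPHA = 0.007


def validate_assignment(assignment: Mapping[str, str]) -> None:
    bad = sorted({c for c in assignment.values() if c not in CATEGORIES})
    if bad:
        raise ValidationError(f"labels outside the vocabulary: {bad}")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if min(k, K, n, N) < 0:
        raise ValidationError("arguments must be non-negative")
    if K > N or n > N:
        raise ValidationError("K and n cannot exceed N")
    if k > min(K, n):
        raise ValidationError(f"k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_categories(
    gene_set: Iterable[str],
    background: Iterable[str],
    assignment: Mapping[str, str],
    bonferroni_alpha: float = BONFERRONI_ALPHA,
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One-tailed hypergeometric over-representation per tested category.

    ``gene_set`` must be contained in ``background``; every background gene
    needs a primary label in ``assignment``. ``categories`` restricts the
    tested labels (default: every label present in the background). Results
    are sorted by p ascending; ``significant`` applies the Bonferroni alpha
    directly to the raw p (the alpha already encodes the family size).
    """
    validate_assignment(assignment)
    gene_set = list(dict.fromkeys(gene_set))
    background = list(dict.fromkeys(background))
    bg = set(background)
    missing = sorted(set(gene_set) - bg)
    if missing:
        raise ValidationError(f"gene set members absent from background: {missing[:10]}")
    labels = {g: assignment.get(g, "UNK") for g in background}
    if categories is None:
        categories = sorted(set(labels.values()))
    else:
        bad = sorted(set(categories) - CATEGORIES)
        if bad:
            raise ValidationError(f"unknown tested categories: {bad}")

    N, n = len(background), len(gene_set)
    set_members = set(gene_set)
    rows = []
    for cat in categories:
        K = sum(1 for g in background if labels[g] == cat)
        k = sum(1 for g in gene_set if labels[g] == cat)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((cat, k, K, n, N, p, bonferroni_alpha, p <= bonferroni_alpha))
    result = pd.DataFrame(
        rows,
        columns=["category", "k", "K", "n", "N", "p_upper", "bonferroni_alpha", "significant"],
    )
    return result.sort_values(["p_upper", "category"]).reset_index(drop=True)


def category_percentages(
    gene_set: Iterable[str], assignment: Mapping[str, str]
) -> pd.DataFrame:
    """Percentage composition (one decimal) of a gene set by category.

    Unassigned genes are counted as UNK with a warning. Post-rounding the
    percentages sum to 100 within ±1.
    """
    validate_assignment(assignment)
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValidationError("empty gene set")
    unassigned = [g for g in genes if g not in assignment]
    if unassigned:
        logger.warning("%d unassigned genes counted as UNK", len(unassigned))
    labels = pd.Series([assignment.get(g, "UNK") for g in genes])
    counts = labels.value_counts().sort_index()
    percent = np.round(100.0 * counts / len(genes), 1)
    out = pd.DataFrame(
        {"category": counts.index, "count": counts.to_numpy(), "percent": percent.to_numpy()}
    ).reset_index(drop=True)
    total = out["percent"].sum()
    assert 99.0 <= total <= 101.0, f"rounded percentages sum to {total}"
    return out
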