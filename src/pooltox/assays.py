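"""Bioassay and molecular-assay statistics.

Dose–response mortality is modelled by log-dose probit regression:
P(death | dose) = Φ(α + β·log10 dose). The LC50 (dose killing half the
exposed insects) is 10^(−α/β); its 95% confidence interval comes from the
delta method on log10(LC50) using the fit's covariance (Fieller's theorem is
available as an alternative). Mortality for LC50 assays is scored at 24 h
post-treatment; discriminating-dose mortality at 3 days post-treatment —
both are data fields, not assumptions of the fit.

Also here: the resistance ratio (LC50_R / LC50_S), Fisher's exact test for
mortality contrasts, one-way ANOVA for knockdown time-course comparisons,
multi-locus KDR genotype frequency summaries, and ΔΔCt relative
quantitation (RQ = 2^(−ΔΔCt)) against reference genes and a calibrator
group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError

KDR_LOCI = ("V410L", "V1016I", "F1534C")
GENOTYPE_CLASSES = ("hom_susceptible", "heterozygous", "hom_resistant")

#: resistant-allele dose carried by each genotype class
_RESISTANT_DOSE = {"hom_susceptible": 0, "heterozygous": 1, "hom_resistant": 2}


@dataclass
class ProbitFit:
    """Log-dose probit parameters and the derived LC50 with 95% CI (µg)."""

    intercept: float
    slope: float
    lc50: float
    ci_lower: float
    ci_upper: float
    converged: bool
    message: str = ""


def fit_probit_lc50(
    records: pd.DataFrame, ci_method: str = "delta", level: float = 0.95
) -> ProbitFit:
    """Maximum-likelihood probit regression of mortality on log10(dose).

    ``records`` needs columns ``dose``, ``n_exposed``, ``n_dead`` (one row
    per bottle/replicate; fractional expected deaths are accepted for
    noise-free calibration data). Requires >=3 distinct doses. Returns a
    non-converged fit (with diagnostic message) rather than raising when the
    response is degenerate (all dead / all alive) or the slope is not
    positive.
    """
    required = {"dose", "n_exposed", "n_dead"}
    if not required.issubset(records.columns):
        raise ValidationError(f"records need columns {sorted(required)}")
    dose = records["dose"].to_numpy(float)
    n = records["n_exposed"].to_numpy(float)
    dead = records["n_dead"].to_numpy(float)
    if (dose <= 0).any():
        raise ValidationError("doses must be strictly positive")
    if (dead < 0).any() or (dead > n).any() or (n <= 0).any():
        raise ValidationError("need 0 <= n_dead <= n_exposed and n_exposed > 0")
    if np.unique(dose).size < 3:
        raise ValidationError("need >=3 distinct doses")

    total_dead, total = dead.sum(), n.sum()
    if total_dead == 0 or total_dead == total:
        return ProbitFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                         "all-alive or all-dead response: LC50 not identifiable")

    x = sm.add_constant(np.log10(dose))
    model = sm.GLM(np.column_stack([dead, n - dead]), x,
                   family=sm.families.Binomial(link=sm.families.links.Probit()))
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # near-saturated doses are expected
            fit = model.fit(maxiter=200)
    except Exception as exc:  # singular design, separation
        return ProbitFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, str(exc))
    alpha, beta = fit.params
    if not np.isfinite([alpha, beta]).all() or beta <= 0:
        return ProbitFit(float(alpha), float(beta), np.nan, np.nan, np.nan, False,
                         "non-positive or non-finite slope")
    log_lc50 = -alpha / beta
    cov = fit.cov_params()
    z = stats.norm.ppf(0.5 + level / 2)
    if ci_method == "delta":
        grad = np.array([-1.0 / beta, alpha / beta**2])
        var = float(grad @ cov @ grad)
        half = z * np.sqrt(max(var, 0.0))
        lo, hi = log_lc50 - half, log_lc50 + half
    elif ci_method == "fieller":
        vaa, vbb, vab = cov[0, 0], cov[1, 1], cov[0, 1]
        g = z**2 * vbb / beta**2
        if g >= 1:
            return ProbitFit(float(alpha), float(beta), float(10**log_lc50),
                             np.nan, np.nan, False, "Fieller interval unbounded (g >= 1)")
        centre = log_lc50 + g * (log_lc50 + vab / vbb) / (1 - g)
        half = (z / (abs(beta) * (1 - g))) * np.sqrt(
            vaa + 2 * log_lc50 * vab + log_lc50**2 * vbb
            - g * (vaa - vab**2 / vbb)
        )
        lo, hi = centre - half, centre + half
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return ProbitFit(
        intercept=float(alpha),
        slope=float(beta),
        lc50=float(10**log_lc50),
        ci_lower=float(10**lo),
        ci_upper=float(10**hi),
        converged=bool(fit.converged),
    )


def resistance_ratio(fit_R: ProbitFit, fit_S: ProbitFit) -> float:
    """LC50 ratio of resistant over susceptible strain, to two decimals."""
    if not (fit_R.converged and fit_S.converged):
        raise ValidationError("both probit fits must have converged")
    if not (fit_R.lc50 > 0 and fit_S.lc50 > 0):
        raise ValidationError("LC50s must be positive")
    return round(fit_R.lc50 / fit_S.lc50, 2)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 dead/alive × group table.

    Sums hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one.
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (table < 0).any() or not np.issubdtype(table.dtype, np.integer):
        raise ValidationError("cells must be non-negative integers")
    if table.sum(axis=1).min() == 0:
        raise ValidationError("a group has no subjects (zero row margin)")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way F test across >=2 groups of replicate measurements."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need >=2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValidationError("each group needs >=2 observations")
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    grand = np.concatenate(arrays).mean()
    between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if within == 0 and between == 0:
        raise ValidationError("zero variance within and between groups")
    f, p = stats.f_oneway(*arrays)
    if between == 0:  # identical group means: F = 0, p = 1 by convention
        return 0.0, 1.0
    return float(f), float(p)


# ---------------------------------------------------------------------------
# knockdown time courses
# ---------------------------------------------------------------------------

def knockdown_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean knockdown proportion per group × timepoint (10-min grid, 1 h)."""
    required = {"group", "replicate", "timepoint", "n_down", "n_total"}
    if not required.issubset(records.columns):
        raise ValidationError(f"records need columns {sorted(required)}")
    bad_t = set(records["timepoint"]) - {10, 20, 30, 40, 50, 60}
    if bad_t:
        raise ValidationError(f"timepoints off the 10-minute grid: {sorted(bad_t)}")
    if ((records["n_down"] < 0) | (records["n_down"] > records["n_total"])).any():
        raise ValidationError("need 0 <= n_down <= n_total")
    out = records.assign(proportion=records["n_down"] / records["n_total"])
    return (
        out.groupby(["group", "timepoint"], sort=True)["proportion"]
        .mean()
        .reset_index()
    )


def compare_knockdown(records: pd.DataFrame, timepoint: int = 60) -> tuple[float, float]:
    """One-way ANOVA on replicate-level knockdown proportions at one timepoint.

    The 60-minute endpoint is the default comparison point for the 1-hour
    time course.
    """
    at_t = records.loc[records["timepoint"] == timepoint]
    if at_t.empty:
        raise ValidationError(f"no records at timepoint {timepoint}")
    groups = [
        (sub["n_down"] / sub["n_total"]).to_numpy()
        for _, sub in at_t.groupby("group", sort=True)
    ]
    return oneway_anova(groups)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def genotype_frequencies(
    records: pd.DataFrame, loci: Sequence[str] = KDR_LOCI
) -> dict:
    """Composite genotype-class and per-locus allele frequency summary.

    ``records`` has one row per (individual, locus) with a ``genotype`` in
    ``hom_susceptible | heterozygous | hom_resistant``. Individuals missing
    any requested locus are excluded from the composite-class denominator
    (the excluded count is reported). Composite classes label individuals
    with the same class at every requested locus; mixed individuals are
    "mixed".
    """
    required = {"individual", "locus", "genotype"}
    if not required.issubset(records.columns):
        raise ValidationError(f"records need columns {sorted(required)}")
    unknown_loci = set(records["locus"]) - set(loci) - {"miR33"}
    if unknown_loci:
        raise ValidationError(f"unknown loci: {sorted(unknown_loci)}")
    bad = set(records["genotype"]) - set(GENOTYPE_CLASSES)
    if bad:
        raise ValidationError(f"unknown genotype codes: {sorted(bad)}")

    sub = records.loc[records["locus"].isin(loci)]
    wide = sub.pivot_table(
        index="individual", columns="locus", values="genotype", aggfunc="first"
    )
    for locus in loci:
        if locus not in wide.columns:
            wide[locus] = np.nan
    complete = wide.dropna(subset=list(loci))
    n_excluded = len(wide) - len(complete)
    if complete.empty:
        raise ValidationError("no individual fully genotyped at requested loci")

    def composite(row):
        classes = {row[locus] for locus in loci}
        return classes.pop() if len(classes) == 1 else "mixed"

    comp = complete.apply(composite, axis=1)
    class_freq = (comp.value_counts() / len(complete)).to_dict()

    allele_freq = {}
    for locus in loci:
        doses = complete[locus].map(_RESISTANT_DOSE)
        allele_freq[locus] = float(doses.sum()) / (2 * len(complete))

    return {
        "n": int(len(complete)),
        "n_excluded_incomplete": int(n_excluded),
        "class_frequencies": {k: float(v) for k, v in sorted(class_freq.items())},
        "resistant_allele_frequencies": allele_freq,
    }


# ---------------------------------------------------------------------------
# ΔΔCt relative quantitation
# ---------------------------------------------------------------------------

def ddct_relative_quantity(
    cts: pd.DataFrame,
    target: str,
    reference_genes: Sequence[str],
    calibrator_group: str,
) -> pd.DataFrame:
    """Comparative-Ct relative quantities per sample.

    Technical replicates are averaged per (sample, gene) first; then
    ΔCt = Ct_target − mean(Ct_references), ΔΔCt = ΔCt − mean ΔCt of the
    calibrator group, RQ = 2^(−ΔΔCt). Averaging reference Cts arithmetically
    equals a geometric mean of reference quantities at equal efficiency.
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(cts.columns):
        raise ValidationError(f"Ct table needs columns {sorted(required)}")
    if (cts["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    mean_ct = cts.groupby(["sample", "group", "gene"], sort=True)["ct"].mean().reset_index()
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    missing_target = wide.index[wide.get(target, pd.Series(np.nan, index=wide.index)).isna()]
    if target not in wide.columns or len(missing_target):
        names = [s for s, _ in missing_target] if target in wide.columns else "all samples"
        raise ValidationError(f"samples lacking target gene {target!r}: {names}")
    for ref in reference_genes:
        if ref not in wide.columns or wide[ref].isna().any():
            bad = (
                [s for (s, _), isna in wide.get(ref, pd.Series(True, index=wide.index)).isna().items() if isna]
                if ref in wide.columns
                else "all samples"
            )
            raise ValidationError(f"samples lacking reference gene {ref!r}: {bad}")
    ref_mean = wide[list(reference_genes)].mean(axis=1)
    dct = wide[target] - ref_mean
    out = dct.reset_index().rename(columns={0: "delta_ct"})
    out.columns = ["sample", "group", "delta_ct"]
    calib = out.loc[out["group"] == calibrator_group, "delta_ct"]
    if calib.empty:
        raise ValidationError(f"empty calibrator group {calibrator_group!r}")
    out["delta_delta_ct"] = out["delta_ct"] - calib.mean()
    out["rq"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def group_fold_changes(rq_table: pd.DataFrame) -> pd.Series:
    """Geometric-mean RQ per treatment group (means on the ΔΔCt scale)."""
    return 2.0 ** (-(rq_table.groupby("group")["delta_delta_ct"].mean()))
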