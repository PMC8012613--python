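"""Probit LC50, resistance ratio, exact/ANOVA tests, genotypes and ΔΔCt."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import fisher_two_sided_exact, hypergeom_pmf_exact
from pooltox import (
    BioassaySimParams,
    ProbitFit,
    ValidationError,
    compare_knockdown,
    ddct_relative_quantity,
    fisher_exact_2x2,
    fit_probit_lc50,
    genotype_frequencies,
    group_fold_changes,
    knockdown_summary,
    oneway_anova,
    resistance_ratio,
    simulate_dose_response,
)


def noise_free_records(lc50, slope, doses, n=20, reps=3):
    params = BioassaySimParams(
        true_lc50=lc50, probit_slope=slope, doses=doses, n_per_bottle=n,
        n_replicates=reps,
    )
    return simulate_dose_response(params, noise_free=True, round_deaths=False)


class TestProbitFit:
    def test_noise_free_data_is_inverted_exactly(self):
        fit = fit_probit_lc50(noise_free_records(10.0, 2.0, [1.0, 10.0, 100.0]))
        assert fit.converged
        assert fit.lc50 == pytest.approx(10.0, abs=1e-6)
        assert fit.slope == pytest.approx(2.0, abs=1e-6)
        assert fit.ci_lower < fit.lc50 < fit.ci_upper

    def test_lc50_identity_holds(self):
        fit = fit_probit_lc50(noise_free_records(25.0, 3.0, [5, 10, 25, 50, 100]))
        assert fit.lc50 == pytest.approx(10 ** (-fit.intercept / fit.slope))

    def test_scale_equivariance(self):
        doses = [2.0, 8.0, 32.0, 128.0]
        base = fit_probit_lc50(noise_free_records(16.0, 2.5, doses))
        scaled = fit_probit_lc50(noise_free_records(160.0, 2.5, [10 * d for d in doses]))
        assert scaled.lc50 == pytest.approx(10 * base.lc50, rel=1e-6)

    def test_constant_dose_rejected(self):
        records = pd.DataFrame(
            {"dose": [5.0] * 6, "n_exposed": 20, "n_dead": [1, 4, 9, 14, 18, 19]}
        )
        with pytest.raises(ValidationError):
            fit_probit_lc50(records)

    def test_all_dead_everywhere_is_not_identifiable(self):
        records = pd.DataFrame(
            {"dose": [1.0, 10.0, 100.0], "n_exposed": 20, "n_dead": 20}
        )
        fit = fit_probit_lc50(records)
        assert not fit.converged and "not identifiable" in fit.message

    def test_fieller_interval_close_to_delta(self):
        records = simulate_dose_response(
            BioassaySimParams(true_lc50=25.0, probit_slope=3.0, seed=8)
        )
        delta = fit_probit_lc50(records, ci_method="delta")
        fieller = fit_probit_lc50(records, ci_method="fieller")
        assert fieller.ci_lower == pytest.approx(delta.ci_lower, rel=0.15)
        assert fieller.ci_upper == pytest.approx(delta.ci_upper, rel=0.15)


class TestResistanceRatio:
    def make_fit(self, lc50):
        return ProbitFit(0.0, 1.0, lc50, lc50 * 0.9, lc50 * 1.1, True)

    def test_strain_scale_ratio(self):
        assert resistance_ratio(self.make_fit(24.92), self.make_fit(2.41)) == 10.34

    def test_identical_lc50s_give_one(self):
        assert resistance_ratio(self.make_fit(5.0), self.make_fit(5.0)) == 1.00

    def test_degenerate_inputs_rejected(self):
        good = self.make_fit(5.0)
        bad = ProbitFit(0.0, 1.0, np.nan, np.nan, np.nan, False)
        with pytest.raises(ValidationError):
            resistance_ratio(bad, good)
        with pytest.raises(ValidationError):
            resistance_ratio(self.make_fit(0.0), good)


class TestFisherExact:
    def test_worked_example_matches_enumeration(self):
        table = [[3, 7], [9, 1]]
        p = fisher_exact_2x2(table)
        assert p == pytest.approx(fisher_two_sided_exact(table), rel=1e-9)
        assert p == pytest.approx(0.0198, abs=0.0005)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == 1.0

    def test_negative_or_fractional_cells_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 2], [3, 4]])
        with pytest.raises(ValidationError):
            fisher_exact_2x2(np.array([[1.5, 2.0], [3.0, 4.0]]))

    def test_zero_row_margin_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_table_probabilities_sum_to_one(self):
        """Hypergeometric probabilities over all margin-fixed tables sum to 1."""
        r1, c1, n = 10, 12, 20
        lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
        total = sum(hypergeom_pmf_exact(a, c1, r1, n) for a in range(lo, hi + 1))
        assert total == 1


class TestOnewayAnova:
    def test_identical_group_means_give_zero_f(self):
        f, p = oneway_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == 0.0 and p == 1.0

    def test_two_groups_equal_t_squared(self):
        g1, g2 = [1.0, 2.0, 4.0], [3.0, 5.0, 6.0]
        f, p = oneway_anova([g1, g2])
        t, p_t = stats.ttest_ind(g1, g2)
        assert f == pytest.approx(t**2, rel=1e-12)
        assert p == pytest.approx(p_t, rel=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValidationError):
            oneway_anova([[1.0, 2.0], [3.0]])

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            oneway_anova([[1.0, 2.0]])


class TestKnockdown:
    def records(self):
        rows = []
        for group, shift in (("G-pre-miR-33", 0.2), ("control", 0.0)):
            for rep in (1, 2, 3):
                for t in (10, 20, 30, 40, 50, 60):
                    frac = min(1.0, t / 60 * (0.6 + shift) + 0.02 * rep)
                    rows.append((group, rep, t, round(frac * 20), 20))
        return pd.DataFrame(
            rows, columns=["group", "replicate", "timepoint", "n_down", "n_total"]
        )

    def test_summary_proportions_bounded(self):
        summary = knockdown_summary(self.records())
        assert ((summary["proportion"] >= 0) & (summary["proportion"] <= 1)).all()
        assert len(summary) == 12  # 2 groups × 6 timepoints

    def test_group_comparison_uses_final_timepoint(self):
        f, p = compare_knockdown(self.records())
        assert f > 0 and p < 0.05  # shifted group is detectably higher

    def test_off_grid_timepoint_rejected(self):
        bad = self.records()
        bad.loc[0, "timepoint"] = 15
        with pytest.raises(ValidationError):
            knockdown_summary(bad)


class TestGenotypeFrequencies:
    LOCI = ("V410L", "V1016I", "F1534C")

    def records(self, classes):
        rows = []
        for i, cls in enumerate(classes):
            for locus in self.LOCI:
                if cls is not None:
                    rows.append((f"ind{i}", locus, cls))
        # one extra individual genotyped at a single locus only
        rows.append(("partial", "V410L", "heterozygous"))
        return pd.DataFrame(rows, columns=["individual", "locus", "genotype"])

    def test_composite_heterozygote_fraction(self):
        """5 of 20 triple-heterozygous individuals → 25% composite class."""
        classes = ["heterozygous"] * 5 + ["hom_resistant"] * 15
        out = genotype_frequencies(self.records(classes))
        assert out["n"] == 20
        assert out["class_frequencies"]["heterozygous"] == pytest.approx(0.25)
        assert out["n_excluded_incomplete"] == 1

    def test_all_identical_is_single_class(self):
        out = genotype_frequencies(self.records(["hom_resistant"] * 7))
        assert out["class_frequencies"] == {"hom_resistant": 1.0}
        assert out["resistant_allele_frequencies"]["V410L"] == 1.0

    def test_allele_frequencies_count_doses(self):
        classes = ["heterozygous"] * 10 + ["hom_susceptible"] * 10
        out = genotype_frequencies(self.records(classes))
        assert out["resistant_allele_frequencies"]["F1534C"] == pytest.approx(0.25)

    def test_unknown_genotype_code_rejected(self):
        records = pd.DataFrame(
            [("i", "V410L", "resistant-ish")],
            columns=["individual", "locus", "genotype"],
        )
        with pytest.raises(ValidationError):
            genotype_frequencies(records, loci=("V410L",))


class TestDdct:
    def ct_table(self, target_treated=20.0, target_calib=22.0, ref=18.0):
        rows = []
        for group, target_ct in (("treated", target_treated), ("control", target_calib)):
            for gene, ct in (("VGSC", target_ct), ("ACTIN", ref), ("RPS7", ref)):
                for tech in (1, 2):
                    rows.append((f"{group}_s1", group, gene, ct, tech))
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct", "technical"])

    def test_calibrator_rq_is_one(self):
        rq = ddct_relative_quantity(
            self.ct_table(), "VGSC", ["ACTIN", "RPS7"], "control"
        )
        calib = rq.loc[rq["group"] == "control", "rq"]
        assert calib.to_numpy() == pytest.approx(1.0)

    def test_two_cycle_shift_is_fourfold(self):
        rq = ddct_relative_quantity(
            self.ct_table(), "VGSC", ["ACTIN", "RPS7"], "control"
        )
        treated = rq.loc[rq["group"] == "treated", "rq"].iloc[0]
        assert treated == pytest.approx(4.0)  # ΔΔCt = −2 → 2² = 4

    def test_invariant_to_global_ct_offset(self):
        base = ddct_relative_quantity(self.ct_table(), "VGSC", ["ACTIN", "RPS7"], "control")
        shifted_table = self.ct_table()
        shifted_table["ct"] += 3.5  # amplifier offset
        shifted = ddct_relative_quantity(shifted_table, "VGSC", ["ACTIN", "RPS7"], "control")
        assert np.allclose(base["rq"], shifted["rq"])

    def test_missing_reference_gene_names_sample(self):
        table = self.ct_table()
        table = table.loc[~((table["group"] == "treated") & (table["gene"] == "RPS7"))]
        with pytest.raises(ValidationError, match="RPS7"):
            ddct_relative_quantity(table, "VGSC", ["ACTIN", "RPS7"], "control")

    def test_empty_calibrator_rejected(self):
        with pytest.raises(ValidationError, match="calibrator"):
            ddct_relative_quantity(self.ct_table(), "VGSC", ["ACTIN"], "mock")

    def test_group_fold_changes_geometric_mean(self):
        rq = ddct_relative_quantity(self.ct_table(), "VGSC", ["ACTIN", "RPS7"], "control")
        folds = group_fold_changes(rq)
        assert folds["treated"] == pytest.approx(4.0)
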