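"""Synthetic-data generator: determinism, conservation, sampling structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pooltox import (
    BioassaySimParams,
    PoolSimParams,
    ValidationError,
    ddct_relative_quantity,
    fit_probit_lc50,
    group_fold_changes,
    simulate_assay_tables,
    simulate_bundle,
    simulate_dose_response,
    simulate_pool_readcounts,
)


def small_params(**overrides):
    defaults = dict(n_sites=301, n_genes=100, depth_mean=100.0, seed=7)
    defaults.update(overrides)
    return PoolSimParams(**defaults)


class TestPoolSimulator:
    def test_same_seed_is_bit_identical(self):
        t1, truth1 = simulate_pool_readcounts(small_params())
        t2, truth2 = simulate_pool_readcounts(small_params())
        for lib in t1:
            pd.testing.assert_frame_equal(t1[lib], t2[lib])
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_different_seeds_differ(self):
        b1 = simulate_bundle(small_params(seed=1))
        b2 = simulate_bundle(small_params(seed=2))
        assert not b1.counts.equals(b2.counts)

    def test_null_truth_has_equal_strain_frequencies(self):
        bundle = simulate_bundle(small_params(n_selected_sites=0, delta_f=0.0))
        assert np.array_equal(bundle.truth["f_R"], bundle.truth["f_S"])
        assert not bundle.truth["selected"].any()

    def test_selected_sites_carry_delta_and_flag_count(self):
        bundle = simulate_bundle(small_params(n_selected_sites=10, delta_f=0.6))
        truth = bundle.truth
        assert truth["selected"].sum() == 10
        diffs = (truth["f_R"] - truth["f_S"]).to_numpy()
        assert np.allclose(diffs[truth["selected"]], 0.6)
        assert np.allclose(diffs[~truth["selected"].to_numpy()], 0.0)
        assert truth[["f_R", "f_S"]].to_numpy().min() >= 0.0
        assert truth[["f_R", "f_S"]].to_numpy().max() <= 1.0

    def test_counts_conserve_depth(self):
        bundle = simulate_bundle(small_params(depth_dispersion=2.0))
        per_lib = [
            bundle.counts[f"ref_{lib}"] + bundle.counts[f"alt_{lib}"]
            for lib in bundle.library_ids
        ]
        total = sum(per_lib)
        assert (total == bundle.counts["depth_total"]).all()
        assert all((d >= 0).all() for d in per_lib)

    def test_hairpin_site_planted_inside_interval(self):
        bundle = simulate_bundle(small_params(n_selected_sites=1, delta_f=0.5))
        snp = bundle.truth.iloc[0]
        assert snp["in_premirna"] and snp["selected"]
        mir33 = next(iv for iv in bundle.premirnas if iv.name == "mir-33")
        assert mir33.contains(snp["chrom"], snp["pos"])

    def test_empirical_frequencies_converge_at_high_depth(self):
        """Read-level frequencies approach truth within 0.02 at depth 10,000."""
        bundle = simulate_bundle(
            small_params(depth_mean=10_000.0, two_stage=False, seed=3)
        )
        for lib in bundle.library_ids:
            truth_f = bundle.truth["f_R" if lib.startswith("R") else "f_S"]
            emp = bundle.counts[f"alt_{lib}"] / (
                bundle.counts[f"ref_{lib}"] + bundle.counts[f"alt_{lib}"]
            )
            assert np.abs(emp - truth_f).max() < 0.02

    def test_two_stage_exceeds_binomial_read_variance(self):
        """Across-replicate spread shows the pool-stage overdispersion."""
        params = small_params(n_sites=1001, n_genes=200, depth_mean=200.0, seed=9)
        two = simulate_bundle(params)
        f1 = two.counts["alt_R1"] / (two.counts["ref_R1"] + two.counts["alt_R1"])
        f2 = two.counts["alt_R2"] / (two.counts["ref_R2"] + two.counts["alt_R2"])
        truth_f = two.truth["f_R"].to_numpy()
        observed_var = ((f1 - f2) ** 2 / 2).mean()
        binomial_var = (truth_f * (1 - truth_f) / 200.0).mean()
        assert observed_var > 1.5 * binomial_var

    def test_selected_sites_dominate_oracle_chi2(self):
        """Oracle χ² at planted sites dwarfs null sites (>10×) at depth 200."""
        params = small_params(
            n_sites=1001, n_genes=200, depth_mean=200.0,
            n_selected_sites=50, delta_f=0.8, seed=13,
        )
        bundle = simulate_bundle(params)
        c = bundle.counts
        table = np.stack(
            [
                np.stack([c["ref_R1"] + c["ref_R2"], c["alt_R1"] + c["alt_R2"]], axis=1),
                np.stack([c["ref_S1"] + c["ref_S2"], c["alt_S1"] + c["alt_S2"]], axis=1),
            ],
            axis=1,
        )
        chi2 = np.array(
            [stats.chi2_contingency(t, correction=False)[0] for t in table]
        )
        selected = bundle.truth["selected"].to_numpy()
        assert chi2[selected].mean() > 10 * chi2[~selected].mean()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            small_params(n_selected_sites=1000)
        with pytest.raises(ValidationError):
            small_params(delta_f=1.5)
        with pytest.raises(ValidationError):
            small_params(depth_mean=-1)
        with pytest.raises(ValidationError):
            small_params(base_freq_range=(0.0, 0.9))


class TestDoseResponseSimulator:
    def test_noise_free_half_mortality_at_lc50(self):
        params = BioassaySimParams(true_lc50=25.0, doses=[5, 10, 25, 50, 100])
        rec = simulate_dose_response(params, noise_free=True)
        at_lc50 = rec.loc[rec["dose"] == 25.0]
        assert (at_lc50["n_dead"] == 10).all()  # half of 20 per bottle

    def test_seeded_determinism(self):
        params = BioassaySimParams(true_lc50=25.0, seed=4)
        pd.testing.assert_frame_equal(
            simulate_dose_response(params), simulate_dose_response(params)
        )

    def test_rounding_rule_is_half_up(self):
        params = BioassaySimParams(
            true_lc50=10.0, probit_slope=1.0, doses=[10.0], n_per_bottle=21,
            n_replicates=1,
        )
        rec = simulate_dose_response(params, noise_free=True)
        assert rec.loc[0, "n_dead"] == 11  # expected 10.5 rounds up

    def test_invalid_design_rejected(self):
        with pytest.raises(ValidationError):
            BioassaySimParams(true_lc50=-1.0)
        with pytest.raises(ValidationError):
            BioassaySimParams(true_lc50=10.0, probit_slope=0.0)
        with pytest.raises(ValidationError):
            BioassaySimParams(true_lc50=10.0, doses=[0.0, 1.0, 10.0])

    def test_monte_carlo_lc50_recovery(self):
        """Refit LC50 lands within ±20% of truth in >=90 of 100 seeded runs."""
        truth = 25.0
        hits = 0
        for seed in range(100):
            params = BioassaySimParams(true_lc50=truth, probit_slope=3.0, seed=seed)
            fit = fit_probit_lc50(simulate_dose_response(params))
            if fit.converged and abs(fit.lc50 - truth) / truth <= 0.2:
                hits += 1
        assert hits >= 90


class TestAssayTableSimulator:
    CLASS_FREQS = {
        "hom_resistant": 0.67,
        "heterozygous": 0.25,
        "hom_susceptible": 0.08,
    }

    def test_class_fractions_match_multinomial_expectation(self):
        genotypes, _ = simulate_assay_tables(
            self.CLASS_FREQS, {"control": 1.0}, n_individuals=1000, seed=21
        )
        per_ind = genotypes.groupby("individual")["genotype"].first()
        frac = (per_ind == "hom_resistant").mean()
        assert frac == pytest.approx(0.67, abs=0.04)

    def test_encoded_fold_change_recovered_exactly_without_noise(self):
        _, cts = simulate_assay_tables(
            self.CLASS_FREQS, {"control": 1.0, "treated": 4.0},
            n_individuals=10, seed=2,
        )
        rq = ddct_relative_quantity(cts, "VGSC", ["ACTIN", "RPS7"], "control")
        folds = group_fold_changes(rq)
        assert folds["treated"] == pytest.approx(4.0)
        assert folds["control"] == pytest.approx(1.0)

    def test_seeded_determinism(self):
        a = simulate_assay_tables(self.CLASS_FREQS, {"control": 1.0}, 50, seed=5)
        b = simulate_assay_tables(self.CLASS_FREQS, {"control": 1.0}, 50, seed=5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_frequencies_outside_simplex_rejected(self):
        with pytest.raises(ValidationError):
            simulate_assay_tables({"hom_resistant": 0.8}, {"control": 1.0}, 10)
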