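"""Additive and multiplicative score construction, quantile assignment,
and the subsample validation contract."""

import numpy as np
import pandas as pd
import pytest

from cadgrs import (GenotypeWeights, SimConfig, SnpPanel, SnpSpec,
                    additive_grs, multiplicative_grs, quantile_assign,
                    simulate_genotypes, validate_subsample)


def _geno(rows, cols=None):
    arr = np.asarray(rows, dtype=float)
    cols = cols or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, columns=cols)


def _weights(panel):
    return GenotypeWeights.from_panel(panel)


class TestAdditive:
    def test_all_reference_is_zero(self):
        assert additive_grs(_geno([[0, 0, 0]])).scores.iloc[0] == 0.0

    def test_31_homozygous_loci_give_62(self):
        g = _geno([[2] * 31])
        assert additive_grs(g).scores.iloc[0] == 62.0

    def test_simple_sum(self):
        assert additive_grs(_geno([[2, 1, 0]])).scores.iloc[0] == 3.0

    def test_missing_imputed_with_cohort_mean(self):
        g = _geno([[2, 2], [0, 0], [1, np.nan]])
        scores = additive_grs(g).scores
        assert scores.iloc[2] == pytest.approx(1 + 1.0)  # col mean = 1

    def test_all_missing_subject_flagged(self):
        g = _geno([[1, 1], [np.nan, np.nan]])
        vec = additive_grs(g)
        assert len(vec.unscorable) == 1
        assert np.isnan(vec.scores.iloc[1])

    def test_locus_permutation_invariance(self):
        rng = np.random.default_rng(0)
        g = _geno(rng.integers(0, 3, (50, 6)))
        perm = list(np.random.default_rng(1).permutation(g.columns))
        np.testing.assert_allclose(additive_grs(g).scores,
                                   additive_grs(g[perm]).scores)


class TestMultiplicative:
    def test_unit_weights_score_one(self):
        panel = SnpPanel([SnpSpec("s0", maf=0.3, per_allele_or=1.0),
                          SnpSpec("s1", maf=0.4, per_allele_or=1.0)])
        g = _geno([[0, 2], [1, 1]], cols=["s0", "s1"])
        scores = multiplicative_grs(g, _weights(panel), normalize=False).scores
        np.testing.assert_allclose(scores, 1.0)

    def test_heterozygote_product(self):
        panel = SnpPanel([SnpSpec("s0", maf=0.3, per_allele_or=1.2),
                          SnpSpec("s1", maf=0.3, per_allele_or=1.3)])
        g = _geno([[1, 1]], cols=["s0", "s1"])
        raw = multiplicative_grs(g, _weights(panel), normalize=False).scores
        assert raw.iloc[0] == pytest.approx(1.2 * 1.3)

    def test_normalized_population_mean_is_one(self):
        # Monte-Carlo oracle: mean over 1e5 HWE subjects
        panel = SnpPanel([
            SnpSpec("a", maf=0.3, per_allele_or=1.4, inheritance="additive"),
            SnpSpec("b", maf=0.2, per_allele_or=1.5, inheritance="dominant"),
            SnpSpec("c", maf=0.4, per_allele_or=1.6, inheritance="recessive"),
        ])
        g = simulate_genotypes(panel, 100_000, seed=5, apply_missingness=False)
        scores = multiplicative_grs(g, _weights(panel)).scores
        se = scores.std() / np.sqrt(len(scores))
        assert abs(scores.mean() - 1.0) < 3 * se

    def test_log_linear_equivalence_with_additive_inheritance(self):
        panel = SnpPanel([SnpSpec(f"s{j}", maf=0.3, per_allele_or=1.0 + 0.1 * j)
                          for j in range(1, 5)])
        g = simulate_genotypes(panel, 500, seed=6, apply_missingness=False)
        raw = multiplicative_grs(g, _weights(panel), normalize=False).scores
        log_linear = np.exp(sum(
            g[s.snp_id] * np.log(s.per_allele_or) for s in panel))
        np.testing.assert_allclose(raw, log_linear, rtol=1e-12)

    def test_monotone_in_dosage_for_risk_increasing_locus(self):
        panel = SnpPanel([SnpSpec("a", maf=0.3, per_allele_or=1.5),
                          SnpSpec("b", maf=0.3, per_allele_or=1.2)])
        g = _geno([[0, 1]], cols=["a", "b"])
        g_up = _geno([[1, 1]], cols=["a", "b"])
        w = _weights(panel)
        assert (multiplicative_grs(g_up, w).scores.iloc[0]
                > multiplicative_grs(g, w).scores.iloc[0])
        assert (additive_grs(g_up).scores.iloc[0]
                > additive_grs(g).scores.iloc[0])

    def test_missing_locus_contributes_unit_factor_when_normalized(self):
        panel = SnpPanel([SnpSpec("a", maf=0.3, per_allele_or=1.4),
                          SnpSpec("b", maf=0.3, per_allele_or=1.4)])
        w = _weights(panel)
        full = _geno([[1, np.nan]], cols=["a", "b"])
        only_a = multiplicative_grs(_geno([[1, 0]], cols=["a", "b"]), w).scores
        with_missing = multiplicative_grs(full, w).scores
        # missing b == expected-mean factor == 1 after normalisation
        r0_factor = 1.0 / w.expected_mean["b"]
        assert with_missing.iloc[0] == pytest.approx(
            only_a.iloc[0] / r0_factor)

    def test_nonpositive_weight_rejected(self):
        panel = SnpPanel([SnpSpec("a", maf=0.3, per_allele_or=1.4)])
        w = _weights(panel)
        bad = GenotypeWeights({"a": (1.0, -0.5, 1.0)}, w.expected_mean)
        with pytest.raises(ValueError, match="non-positive"):
            multiplicative_grs(_geno([[1]], cols=["a"]), bad)


class TestQuantiles:
    def test_even_bins_on_distinct_scores(self):
        scores = pd.Series(np.arange(1, 101, dtype=float))
        qa = quantile_assign(scores, 4)
        counts = qa.bins.value_counts()
        assert sorted(counts) == [25, 25, 25, 25]

    def test_tie_at_cutpoint_goes_low(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        qa = quantile_assign(scores, 2)
        assert qa.cutpoints[0] == 3.0
        assert qa.bins[scores == 3.0].iloc[0] == 1  # tie -> lower bin

    def test_group_quartile_means_are_ordered(self, panel33, small_cohort, fitted_results):
        res = fitted_results
        scores = res.multiplicative.scores
        bins = res.quartiles.bins
        y = res.model.cohort.phenotype
        for grp in (0, 1):
            means = [scores[(bins == b) & (y == grp)].mean()
                     for b in (1, 2, 3, 4)]
            assert means[0] < means[1] < means[2] < means[3]

    def test_controls_basis_cutpoints(self, fitted_results):
        dec = fitted_results.deciles
        assert dec.basis == "controls"
        assert len(dec.cutpoints) == 9
        assert (np.diff(dec.cutpoints) >= 0).all()

    def test_degenerate_scores_error(self):
        with pytest.raises(ValueError, match="smaller k"):
            quantile_assign(pd.Series(np.ones(50)), 4)


class TestValidation:
    def test_subsample_recomputation_matches(self, rng):
        g = pd.DataFrame(rng.integers(0, 3, (200, 5)).astype(float),
                         columns=[f"s{j}" for j in range(5)])
        report = validate_subsample(g, additive_grs, fraction=0.2, seed=1)
        assert report["ok"] and report["n_mismatch"] == 0
        assert report["n_checked"] == 40

    def test_full_fraction_checks_everyone(self, rng):
        g = pd.DataFrame(rng.integers(0, 3, (50, 3)).astype(float),
                         columns=list("abc"))
        report = validate_subsample(g, additive_grs, fraction=1.0, seed=2)
        assert report["n_checked"] == 50 and report["ok"]

    def test_corrupted_reference_detected(self, rng):
        g = pd.DataFrame(rng.integers(0, 3, (50, 3)).astype(float),
                         columns=list("abc"))
        ref = additive_grs(g).scores.copy()
        victim = ref.index[10]
        ref.loc[victim] += 1.0
        report = validate_subsample(g, additive_grs, fraction=1.0, seed=3,
                                    reference=ref)
        assert report["n_mismatch"] == 1
        assert report["mismatched_subjects"] == [victim]
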