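"""Risk-score construction: orientation, imputation, scoring, HWE QC."""

import numpy as np
import pandas as pd
import pytest

import casecohort as cc
from casecohort.score import GenotypeDataError


def toy_loci(n, weight=1.0):
    return pd.DataFrame(
        {
            "locus_id": [f"L{i}" for i in range(n)],
            "risk_allele": ["A"] * n,
            "other_allele": ["G"] * n,
            "weight": [weight] * n,
            "risk_allele_frequency": [0.4] * n,
        }
    )


class TestOrientDosages:
    def test_risk_counted_identity_and_complement(self):
        loci = toy_loci(2)
        g = pd.DataFrame({"L0": [2.0, 1.0], "L1": [2.0, 0.0]})
        out = cc.orient_dosages(g, loci, {"L0": "A", "L1": "G"})
        assert out["L0"].tolist() == [2.0, 1.0]  # counted on risk allele
        assert out["L1"].tolist() == [0.0, 2.0]  # counted on other: flipped

    def test_flip_preserves_two_minus_mean(self):
        rng = np.random.default_rng(0)
        loci = toy_loci(5)
        g = pd.DataFrame(rng.integers(0, 3, (200, 5)).astype(float), columns=loci["locus_id"])
        flipped = {"L1": "G", "L3": "G"}
        out = cc.orient_dosages(g, loci, flipped)
        for lid in loci["locus_id"]:
            if lid in flipped:
                assert np.isclose(out[lid].mean(), 2 - g[lid].mean())
            else:
                assert np.isclose(out[lid].mean(), g[lid].mean())

    def test_missing_stays_missing(self):
        loci = toy_loci(1)
        g = pd.DataFrame({"L0": [np.nan, 1.0]})
        out = cc.orient_dosages(g, loci, {"L0": "G"})
        assert np.isnan(out["L0"].iloc[0]) and out["L0"].iloc[1] == 1.0

    def test_unknown_allele_names_locus(self):
        with pytest.raises(GenotypeDataError, match="L0"):
            cc.orient_dosages(pd.DataFrame({"L0": [1.0]}), toy_loci(1), {"L0": "T"})


class TestImputation:
    def test_below_min_genotyped_excluded(self):
        # an individual typed at 46 of 49 loci fails a 47-of-49 rule
        g = pd.DataFrame(np.ones((2, 49)), columns=[f"L{i}" for i in range(49)])
        g.iloc[1, :3] = np.nan
        imputed, included = cc.impute_missing_dosages(g, [0, 0], min_genotyped=47)
        assert included.tolist() == [True, False]
        assert imputed.iloc[1].isna().sum() == 3  # left unimputed

    def test_no_missing_is_identity(self):
        g = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        imputed, included = cc.impute_missing_dosages(g, [0, 1, 0])
        pd.testing.assert_frame_equal(imputed, g)
        assert included.all()

    def test_mean_within_case_status_group(self):
        g = pd.DataFrame({"L0": [0.0, 1.0, 2.0, 1.0, np.nan, 2.0], "L1": np.ones(6)})
        case = [0, 0, 0, 0, 0, 1]
        imputed, included = cc.impute_missing_dosages(g, case, min_genotyped=1)
        assert imputed.iloc[4, 0] == 1.0  # mean of {0,1,2,1} among non-cases
        assert included.all()

    def test_observed_group_means_preserved(self):
        rng = np.random.default_rng(1)
        g = pd.DataFrame(rng.integers(0, 3, (300, 6)).astype(float), columns=[f"L{i}" for i in range(6)])
        mask = rng.random(g.shape) < 0.05
        g_miss = g.mask(mask)
        case = rng.integers(0, 2, 300).astype(bool)
        before = {s: np.nanmean(g_miss[case == s], axis=0) for s in (False, True)}
        imputed, _ = cc.impute_missing_dosages(g_miss, case, min_genotyped=0)
        observed = g_miss.notna().to_numpy()
        assert np.array_equal(imputed.to_numpy()[observed], g_miss.to_numpy()[observed])
        for s in (False, True):
            np.testing.assert_allclose(np.nanmean(g_miss[case == s], axis=0), before[s])

    def test_entirely_missing_group_locus_raises(self):
        g = pd.DataFrame({"L0": [np.nan, 1.0], "L1": [1.0, 1.0]})
        with pytest.raises(GenotypeDataError, match="L0"):
            cc.impute_missing_dosages(g, [0, 1], min_genotyped=1)


class TestComputeScore:
    def test_boundary_sums(self):
        loci = toy_loci(49)
        g0 = pd.DataFrame(np.zeros((2, 49)), columns=loci["locus_id"])
        g2 = pd.DataFrame(2 * np.ones((2, 49)), columns=loci["locus_id"])
        assert cc.compute_score(g0, loci)["raw_score"].tolist() == [0.0, 0.0]
        assert cc.compute_score(g2, loci)["raw_score"].tolist() == [98.0, 98.0]

    def test_quartile_assignment_from_reference_cutoffs(self):
        # reference raw scores {46, 49, 52, 55, 58} put the 25/50/75
        # percentiles exactly at 49/52/55; a raw score of 50 falls in Q2,
        # and boundary values go to the upper quartile
        loci = toy_loci(30)
        targets = [46, 49, 52, 55, 58, 50, 49, 55]
        rows = []
        for t in targets:
            full, rest = divmod(t, 2)
            row = [2.0] * full + ([1.0] if rest else []) + [0.0] * (30 - full - rest)
            rows.append(row)
        g = pd.DataFrame(rows, columns=loci["locus_id"], index=[f"P{i}" for i in range(8)])
        res = cc.compute_score(g, loci, reference_rows=[f"P{i}" for i in range(5)])
        assert res.attrs["quartile_cutoffs"] == [49.0, 52.0, 55.0]
        assert res.loc["P5", "quartile"] == 2  # raw 50
        assert res.loc["P6", "quartile"] == 2  # raw 49 on the boundary: upper
        assert res.loc["P7", "quartile"] == 4  # raw 55 on the boundary: upper

    def test_weighted_equals_unweighted_with_unit_weights(self):
        rng = np.random.default_rng(2)
        loci = toy_loci(8, weight=1.0)
        g = pd.DataFrame(rng.integers(0, 3, (50, 8)).astype(float), columns=loci["locus_id"])
        a = cc.compute_score(g, loci, weighted=False)
        b = cc.compute_score(g, loci, weighted=True)
        np.testing.assert_allclose(a["raw_score"], b["raw_score"])

    def test_reference_standardisation_and_partition(self):
        rng = np.random.default_rng(3)
        loci = toy_loci(20)
        g = pd.DataFrame(rng.binomial(2, 0.4, (400, 20)).astype(float), columns=loci["locus_id"], index=[f"P{i}" for i in range(400)])
        ref = [f"P{i}" for i in range(200)]
        res = cc.compute_score(g, loci, reference_rows=ref)
        ref_std = res.loc[ref, "standardized_score"]
        assert abs(ref_std.mean()) < 1e-12
        assert abs(ref_std.std(ddof=1) - 1.0) < 1e-12
        sizes = res.loc[ref, "quartile"].value_counts()
        ties = sum((res.loc[ref, "raw_score"] == c).sum() for c in res.attrs["quartile_cutoffs"])
        assert sizes.max() - sizes.min() <= ties

    def test_remaining_missing_rejected(self):
        loci = toy_loci(2)
        g = pd.DataFrame({"L0": [1.0, np.nan], "L1": [1.0, 1.0]})
        with pytest.raises(GenotypeDataError):
            cc.compute_score(g, loci, included=np.array([True, True]))


class TestHWE:
    def test_exact_proportions_give_zero(self):
        res = cc.hwe_test(25, 50, 25)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_no_heterozygotes_statistic_100(self):
        # freq 0.5 -> expected (25, 50, 25); chi-square = 25+50+25 = 100
        res = cc.hwe_test(50, 0, 50)
        assert np.isclose(res.statistic, 100.0)
        assert res.p_value < 1e-20

    def test_monomorphic_flagged(self):
        res = cc.hwe_test(100, 0, 0)
        assert res.monomorphic and res.statistic == 0.0

    def test_invalid_counts(self):
        with pytest.raises(GenotypeDataError):
            cc.hwe_test(-1, 2, 3)
        with pytest.raises(GenotypeDataError):
            cc.hwe_test(0, 0, 0)
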