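from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from handtracer.attribution_stats import (NullDistribution, RELATIONS,
                                          cmh_enrichment, compare_groups,
                                          observed_relation_counts,
                                          permute_null, signal_above_noise,
                                          summarize_cohort, summarize_palm)
from handtracer.st_core import MixingEstimate
from tests.conftest import make_metadata


def _estimate(sink_id, source_ids, props, depth=1000):
    props = np.asarray(props, dtype=float)
    return MixingEstimate(sink_id, list(source_ids), props / props.sum(),
                          np.full(len(props), 0.01), n_draws=10, depth=depth)


class TestSummarizePalm:
    def test_all_own_forehead(self, family_metadata):
        est = _estimate("kid.palm.left",
                        ["kid.forehead", "kid.stool", "kid.tongue",
                         "mom.stool", "mom.tongue", "stranger.stool",
                         "stranger.forehead"],
                        [1, 0, 0, 0, 0, 0, 0, 0])
        s = summarize_palm(est, family_metadata)
        assert s.by_site["forehead"] == pytest.approx(1.0)
        assert s.by_relation["self"] == pytest.approx(1.0)

    def test_half_mother_stool_half_unknown(self, family_metadata):
        est = _estimate("kid.palm.left",
                        ["kid.forehead", "kid.stool", "kid.tongue",
                         "mom.stool", "mom.tongue", "stranger.stool",
                         "stranger.forehead"],
                        [0, 0, 0, 0.5, 0, 0, 0, 0.5])
        s = summarize_palm(est, family_metadata)
        assert s.by_site["stool"] == pytest.approx(0.5)
        assert s.by_relation["family"] == pytest.approx(0.5)
        assert s.by_site["unknown"] == pytest.approx(0.5)

    def test_family_share_of_fecal_signal(self, family_metadata):
        # family fixture in the style of the published single family: 81.5%
        # of the fecal signal on the child's palm from the mother
        stool_total = 0.4
        est = _estimate("kid.palm.left",
                        ["kid.forehead", "kid.stool", "kid.tongue",
                         "mom.stool", "mom.tongue", "stranger.stool",
                         "stranger.forehead"],
                        [0.3, stool_total * 0.185, 0.0,
                         stool_total * 0.815, 0.0, 0.0, 0.1, 0.2])
        s = summarize_palm(est, family_metadata)
        assert s.by_site_relation[("stool", "family")] / s.by_site["stool"] \
            == pytest.approx(0.815)

    def test_relation_and_unknown_partition_unity(self, cohort3, fitted3):
        for est in fitted3:
            s = summarize_palm(est, cohort3.metadata)
            total = sum(s.by_relation.values()) + s.by_site["unknown"]
            assert total == pytest.approx(1.0, abs=1e-9)
            for site in ("forehead", "stool", "tongue"):
                site_sum = sum(s.by_site_relation[(site, r)]
                               for r in RELATIONS)
                assert site_sum == pytest.approx(s.by_site[site], abs=1e-9)

    def test_missing_source_metadata_named(self, family_metadata):
        est = _estimate("kid.palm.left", ["ghost.sample"], [0.5, 0.5])
        with pytest.raises(KeyError, match="ghost.sample"):
            summarize_palm(est, family_metadata)


class TestSignalAboveNoise:
    def test_zero_mean_never_significant(self):
        assert signal_above_noise(0.0, 0.05, 10) is False
        assert signal_above_noise(0.0, 0.0, 10) is False

    def test_strong_signal(self):
        assert signal_above_noise(0.2, 0.01, 10) is True  # t ~ 63

    def test_zero_sd_positive_mean(self):
        assert signal_above_noise(0.01, 0.0, 10) is True

    @pytest.mark.parametrize("mean,sd,n", [
        (0.02, 0.05, 10), (0.05, 0.04, 10), (0.01, 0.1, 5), (0.3, 0.2, 4),
    ])
    def test_matches_t_cdf_closed_form(self, mean, sd, n):
        # independent closed form via the regularized incomplete beta
        t = mean / (sd / np.sqrt(n))
        df = n - 1
        from scipy.special import betainc
        p = 0.5 * betainc(df / 2, 0.5, df / (df + t * t))
        assert signal_above_noise(mean, sd, n) is bool(p < 0.05)


class TestPermuteNull:
    def _setup(self, n_self=2, n_family=8, n_unrelated=190):
        rows = [("palm", "h0", "f0", "palm")]
        sids = []
        for i in range(n_self):
            sid = f"self{i}"
            rows.append((sid, "h0", "f0", "stool"))
            sids.append(sid)
        for i in range(n_family):
            sid = f"fam{i}"
            rows.append((sid, f"hf{i}", "f0", "stool"))
            sids.append(sid)
        for i in range(n_unrelated):
            sid = f"unrel{i}"
            rows.append((sid, f"hu{i}", f"fu{i}", "stool"))
            sids.append(sid)
        md = make_metadata(rows)
        props = np.full(len(sids) + 1, 1.0)
        est = _estimate("palm", sids, props)
        return est, md

    def test_uniform_expectation(self):
        est, md = self._setup()
        null = permute_null([est], md, n_perm=200, seed=1)
        # each attributed read hits a self source w.p. 2/200
        p = 2 / 200
        n_reads = null.per_palm_null_counts[0].sum(axis=1)[0]
        se = np.sqrt(p * (1 - p) / n_reads / 200)
        assert abs(null.summary_mean[0] - p) < 3 * se

    def test_counts_preserved_every_permutation(self):
        est, md = self._setup(3, 5, 20)
        null = permute_null([est], md, n_perm=25, seed=2)
        n_att = int(round(float(est.assignment_counts[:-1].sum())))
        assert np.all(null.per_palm_null_counts.sum(axis=2) == n_att)

    def test_deterministic(self):
        est, md = self._setup(1, 2, 10)
        a = permute_null([est], md, n_perm=25, seed=9)
        b = permute_null([est], md, n_perm=25, seed=9)
        assert np.array_equal(a.per_palm_null_counts, b.per_palm_null_counts)

    def test_too_few_permutations(self):
        est, md = self._setup(1, 1, 5)
        with pytest.raises(ValueError):
            permute_null([est], md, n_perm=1, seed=0)


def _null_from_expected(palms, expected, n_perm=2):
    counts = np.zeros((len(palms), n_perm, 3), dtype=np.int64)
    for i, e in enumerate(expected):
        counts[i, :, :] = e
    return NullDistribution(list(palms), n_perm, counts, np.zeros(3),
                            np.zeros(3))


class TestCmh:
    def test_null_case(self):
        expected = [np.array([10, 40, 150]), np.array([5, 20, 75])]
        null = _null_from_expected(["p1", "p2"], expected)
        stat, p = cmh_enrichment({"p1": expected[0], "p2": expected[1]}, null)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_single_stratum_is_pearson_chi_square(self):
        obs = np.array([30.0, 12.0, 158.0])
        exp = np.array([20.0, 25.0, 155.0])
        null = _null_from_expected(["p1"], [exp])
        stat, p = cmh_enrichment({"p1": obs}, null)
        chi2, pp, _, _ = stats.chi2_contingency(np.stack([obs, exp]),
                                                correction=False)
        assert stat == pytest.approx(chi2, abs=1e-6)
        assert p == pytest.approx(pp, abs=1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        palms = [f"p{i}" for i in range(6)]
        obs = {p: rng.integers(5, 50, 3).astype(float) for p in palms}
        exp = [rng.integers(5, 50, 3).astype(float) for _ in palms]
        null = _null_from_expected(palms, exp)
        s1 = cmh_enrichment(obs, null)
        rev = {p: obs[p] for p in reversed(palms)}
        s2 = cmh_enrichment(rev, null)
        assert s1[1] == pytest.approx(s2[1], rel=1e-12)

    def test_zero_stratum_dropped(self, caplog):
        obs = {"p1": np.array([30.0, 12.0, 158.0]),
               "pz": np.zeros(3)}
        null = _null_from_expected(["p1", "pz"],
                                   [np.array([20.0, 25.0, 155.0]),
                                    np.zeros(3)])
        with caplog.at_level("WARNING"):
            stat, _ = cmh_enrichment(obs, null)
        assert any("dropped" in r.message for r in caplog.records)
        assert np.isfinite(stat)


class TestCompareGroups:
    def test_identical_distributions(self):
        vals = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labs = ["a"] * 3 + ["b"] * 3
        _, p = compare_groups(vals, labs)
        assert p == pytest.approx(1.0, abs=0.05)

    def test_separated_groups_exact(self):
        U, p = compare_groups([1, 2, 3, 10, 11, 12],
                              ["a"] * 3 + ["b"] * 3)
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2/20 label assignments as extreme

    def test_label_swap_invariance(self):
        vals = [3.0, 1.5, 4.0, 2.0, 5.5, 0.5]
        labs = ["x", "y", "x", "y", "x", "y"]
        swapped = ["y" if l == "x" else "x" for l in labs]
        assert compare_groups(vals, labs)[1] == \
            pytest.approx(compare_groups(vals, swapped)[1])

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"])


class TestSummarizeCohort:
    def _two_palm_summaries(self, stool=(0.01, 0.30),
                            above=(False, True)):
        md = make_metadata([
            ("p1", "h1", "f1", "palm", {"age_years": 30.0, "gender": "female",
                                        "hand_side": "left"}),
            ("p2", "h1", "f1", "palm", {"age_years": 30.0, "gender": "female",
                                        "hand_side": "right"}),
            ("src.stool", "h2", "f2", "stool"),
            ("src.forehead", "h2", "f2", "forehead"),
            ("src.tongue", "h2", "f2", "tongue"),
        ])
        sids = ["src.stool", "src.forehead", "src.tongue"]
        summaries = []
        for pid, st_p, ab in zip(("p1", "p2"), stool, above):
            est = _estimate(pid, sids, [st_p, 1 - st_p - 0.1, 0.05, 0.05])
            s = summarize_palm(est, md)
            s.above_noise["stool"] = ab
            summaries.append(s)
        return summaries, md

    def test_median_and_high_stool_fraction(self):
        summaries, md = self._two_palm_summaries()
        rep = summarize_cohort(summaries, md)
        assert rep.site_summary.loc["stool", "median"] == pytest.approx(0.155)
        assert rep.frac_palms_stool_over_25 == pytest.approx(0.5)

    def test_individual_counted_once(self):
        # same host: one palm above noise, one below -> individual fraction 1
        summaries, md = self._two_palm_summaries()
        rep = summarize_cohort(summaries, md)
        assert rep.above_noise_fractions.loc["stool", "frac_palms"] == 0.5
        assert rep.above_noise_fractions.loc["stool", "frac_individuals"] == 1.0

    def test_injected_age_effect_detected(self, cohort3, fitted3):
        # generator truth: infant/child palms carry more tongue than adults
        summaries = [summarize_palm(e, cohort3.metadata) for e in fitted3]
        rep = summarize_cohort(summaries, cohort3.metadata)
        t = rep.tests
        row = t[(t.grouping == "age_class") & (t.variable == "site_tongue")]
        assert not row.empty
        gm = rep.group_means.loc["age_class"]
        assert gm.loc["child", "site_tongue"] > gm.loc["adult", "site_tongue"]


class TestObservedCounts:
    def test_counts_scale_to_attributed_reads(self, cohort3, fitted3):
        obs = observed_relation_counts(fitted3, cohort3.metadata)
        for est in fitted3:
            attributed = float(est.assignment_counts[:-1].sum())
            assert obs[est.sink_id].sum() == pytest.approx(attributed, abs=2)
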