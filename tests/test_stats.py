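"""Statistical operations against enumeration and closed-form oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from telofuseq.core import FeatureTrack
from telofuseq.errors import InputError
from telofuseq.stats import (binom_two_sided, chi_squared_yates,
                             chromosome_enrichment, class_proportions,
                             compare_coincidence, compare_growth_divergence,
                             feature_coincidence, fisher_exact_2x2,
                             fusion_frequency, growth_divergence,
                             mann_whitney_u, maximal_fusion_frequency,
                             ols_slope, summarize_junctions,
                             wilcoxon_signed_rank)


class TestFusionFrequency:
    def test_hand_arithmetic(self):
        # 66 ng at 6.6 pg/genome = 10,000 diploid genome equivalents
        f = fusion_frequency(5, 66.0, 6.6)
        assert f.frequency_per_diploid_genome == pytest.approx(5e-4)

    def test_zero_count_zero_frequency(self):
        assert fusion_frequency(0, 50.0).frequency_per_diploid_genome == 0.0

    def test_homogeneity_in_input_and_count(self):
        base = fusion_frequency(4, 30.0).frequency_per_diploid_genome
        assert fusion_frequency(4, 60.0).frequency_per_diploid_genome == \
            pytest.approx(base / 2)
        assert fusion_frequency(8, 30.0).frequency_per_diploid_genome == \
            pytest.approx(base * 2)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(InputError):
            fusion_frequency(1, 0.0)

    def test_maximal_over_timecourse(self):
        tc = pd.DataFrame({
            "sample": ["s1"] * 3, "timepoint": [1, 2, 3],
            "amplicon_count": [1, 5, 2], "dna_input_ng": [66.0] * 3})
        out = maximal_fusion_frequency(tc)
        assert out["max_frequency_per_diploid_genome"].iloc[0] == pytest.approx(5e-4)


class TestClassProportions:
    def test_small_example(self):
        calls = pd.DataFrame({"fusion_class":
                              ["intra", "intra", "inter", "genomic"]})
        out = class_proportions(calls).set_index("fusion_class")
        assert out.loc["intra", "proportion"] == 0.5
        assert out.loc["inter", "proportion"] == 0.25
        assert out.loc["genomic", "proportion"] == 0.25
        assert out["proportion"].sum() == pytest.approx(1.0)

    def test_all_unresolved_rejected(self):
        with pytest.raises(InputError):
            class_proportions(pd.DataFrame({"fusion_class": ["unresolved"] * 3}))


class TestSummarizeJunctions:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["fusion_class", "mh_len", "ins_seq",
                                           "ins_templated"])

    def test_all_blunt(self):
        calls = self._calls([("intra", 0, ".", None)] * 4)
        out = summarize_junctions(calls)
        row = out[out.fusion_class == "intra"].iloc[0]
        assert (row.prop_mh, row.prop_ins, row.prop_blunt) == (0.0, 0.0, 1.0)

    def test_chemistry_proportions_partition(self):
        calls = self._calls([("inter", 3, ".", None), ("inter", 0, "AAC", True),
                             ("inter", 0, ".", None), ("inter", 2, ".", None)])
        row = summarize_junctions(calls).set_index("fusion_class").loc["inter"]
        assert row.prop_mh + row.prop_ins + row.prop_blunt == pytest.approx(1.0)
        assert row.templated_fraction == 1.0

    def test_class_independence(self):
        base = self._calls([("intra", 4, ".", None), ("intra", 6, ".", None)])
        extra = pd.concat([base, self._calls([("genomic", 1, ".", None)])])
        a = summarize_junctions(base).set_index("fusion_class").loc["intra"]
        b = summarize_junctions(extra).set_index("fusion_class").loc["intra"]
        assert a.mh_mean_bp == b.mh_mean_bp


def _fisher_oracle(a, b, c, d):
    """Full hypergeometric enumeration."""
    N, K, n1 = a + b + c + d, a + c, a + b
    ks = np.arange(max(0, K + n1 - N), min(K, n1) + 1)
    pmf = sps.hypergeom.pmf(ks, N, K, n1)
    pobs = sps.hypergeom.pmf(a, N, K, n1)
    return float(pmf[pmf <= pobs * (1 + 1e-7)].sum())


class TestFisher:
    def test_symmetric_table(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_two_zero_diagonal(self):
        # 3 tables with these margins: P(k=0) = P(k=2) = 1/6 -> two-sided 1/3
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_degenerate_margin_warns_p1(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2([[0, 0], [3, 4]]) == 1.0

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(_fisher_oracle(a, b, c, d), rel=1e-7)


class TestChiSquaredYates:
    def test_no_association(self):
        stat, p = chi_squared_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_transposition_invariance(self):
        t = [[12, 5], [3, 20]]
        assert chi_squared_yates(t)[0] == pytest.approx(
            chi_squared_yates(np.transpose(t))[0])

    def test_textbook_formula_oracle(self):
        """|ad - bc| continuity-corrected formula agrees to 1e-10 on 100
        random tables."""
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 100:
            a, b, c, d = rng.integers(1, 40, size=4)
            n = a + b + c + d
            stat, _ = chi_squared_yates([[a, b], [c, d]])
            num = n * (abs(a * d - b * c) - n / 2) ** 2
            den = (a + b) * (c + d) * (a + c) * (b + d)
            expected = max(0.0, num / den) if abs(a * d - b * c) > n / 2 else 0.0
            assert stat == pytest.approx(expected, abs=1e-10)
            checked += 1

    def test_zero_expected_rejected(self):
        with pytest.raises(InputError):
            chi_squared_yates([[0, 0], [5, 5]])


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_complete_separation_small_n(self):
        # U = 0; 2 of the 20 assignments are as extreme -> p = 0.1
        assert mann_whitney_u([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_monotone_transform_invariance(self):
        x, y = [1.0, 2.5, 3.1, 7.0], [0.5, 2.0, 4.4]
        f = lambda v: [math.exp(t) for t in v]
        assert mann_whitney_u(x, y) == pytest.approx(mann_whitney_u(f(x), f(y)))

    def test_small_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney_u([1, 2], [3, 4, 5])

    def test_exact_matches_full_enumeration_with_ties(self):
        """Independent enumeration oracle over all group assignments."""
        x, y = [1, 1, 2, 5], [2, 3, 3]
        ranks = sps.rankdata(x + y)
        n1, mu = len(x), len(x) * len(y) / 2
        obs = abs(ranks[:n1].sum() - n1 * (n1 + 1) / 2 - mu)
        hits = total = 0
        for idx in itertools.combinations(range(7), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            total += 1
            hits += abs(u - mu) >= obs - 1e-12
        assert mann_whitney_u(x, y) == pytest.approx(hits / total)


class TestWilcoxon:
    def test_all_positive_small(self):
        # all 5 ranks positive: 2 of 32 sign patterns as extreme
        assert wilcoxon_signed_rank([1, 2, 3, 4, 5]) == pytest.approx(2 / 32)

    def test_all_zero_degenerate(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([0.0] * 6) == 1.0

    def test_pair_order_invariance(self):
        d = [1.5, -0.5, 2.0, 3.0, -1.0, 0.7]
        rng = np.random.default_rng(3)
        shuffled = list(d)
        rng.shuffle(shuffled)
        assert wilcoxon_signed_rank(d) == pytest.approx(
            wilcoxon_signed_rank(shuffled))

    def test_paired_signature(self):
        a, b = [5, 6, 7, 8, 9, 10], [4, 4, 4, 4, 4, 4]
        assert wilcoxon_signed_rank(a, b) == pytest.approx(
            wilcoxon_signed_rank([x - y for x, y in zip(a, b)]))


class TestChromosomeEnrichment:
    def test_balanced_counts(self):
        pos = [("c1", i) for i in range(5)] + [("c2", i) for i in range(5)]
        df = chromosome_enrichment(pos, {"c1": 1000, "c2": 1000})
        assert df["expected"].sum() == pytest.approx(10)
        assert (df["p_value"] > 0.99).all()

    def test_total_depletion_exact_p(self):
        pos = [("c1", i) for i in range(10)]
        df = chromosome_enrichment(pos, {"c1": 1000, "c2": 1000})
        p2 = df.set_index("chrom").loc["c2", "p_value"]
        assert p2 == pytest.approx(2 * 2.0 ** -10)

    def test_expected_conserves_total(self):
        rng = np.random.default_rng(4)
        lengths = {f"c{i}": int(l) for i, l in
                   enumerate(rng.integers(10_000, 90_000, size=4))}
        pos = [(f"c{rng.integers(4)}", 0) for _ in range(57)]
        df = chromosome_enrichment(pos, lengths)
        assert df["expected"].sum() == pytest.approx(57)

    def test_unknown_chromosome_rejected(self):
        from telofuseq.errors import DataError
        with pytest.raises(DataError):
            chromosome_enrichment([("cX", 5)], {"c1": 100})


class TestFeatureCoincidence:
    track = FeatureTrack("t", [("c1", 100, 200, "gene")])

    def test_half_open_convention(self):
        inside = feature_coincidence([("c1", 150)], self.track)
        boundary = feature_coincidence([("c1", 200)], self.track)
        assert inside.loc[inside.label == "any", "coincident"].iloc[0] == 1
        assert boundary.loc[boundary.label == "any", "coincident"].iloc[0] == 0

    def test_null_positions_recover_track_coverage(self):
        """10,000 uniform positions vs a 10%-coverage track land inside at a
        rate inside the exact binomial 99% CI of 0.10."""
        from telofuseq.simulate import simulate_null_junction_positions
        track = FeatureTrack("t", [("c1", i * 10_000, i * 10_000 + 1000, "x")
                                   for i in range(10)])
        pos = simulate_null_junction_positions(10_000, {"c1": 100_000}, seed=5)
        out = feature_coincidence(pos, track)
        k = int(out.loc[out.label == "any", "coincident"].iloc[0])
        lo, hi = sps.binom.ppf([0.005, 0.995], 10_000, 0.10)
        assert lo <= k <= hi

    def test_comparator_switches_to_yates_for_large_sets(self):
        small = compare_coincidence(5, 50, 10, 60)
        large = compare_coincidence(5, 50, 900, 10_000)
        assert small["test_name"] == "fisher_exact"
        assert large["test_name"] == "chi_squared_yates"


class TestGrowth:
    def _record(self, slope, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        days = np.arange(n, dtype=float)
        return pd.DataFrame({"day": days,
                             "pd": slope * days + noise * rng.normal(size=n)})

    def test_identical_clone_and_control(self):
        r = self._record(0.8)
        assert growth_divergence(r, r) == pytest.approx(0.0)

    def test_exact_lines(self):
        assert growth_divergence(self._record(0.6), self._record(1.0)) == \
            pytest.approx(0.4)

    def test_ols_matches_closed_form(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 30, size=12))
        y = 0.7 * t + rng.normal(size=12)
        tc = t - t.mean()
        expected = (tc * (y - y.mean())).sum() / (tc ** 2).sum()
        assert ols_slope(t, y) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_time_vector_rejected(self):
        with pytest.raises(InputError):
            ols_slope([1.0, 1.0, 1.0], [1, 2, 3])

    def test_welch_comparator_detects_shift(self):
        a = [0.1, 0.15, 0.12, 0.09, 0.11]
        b = [0.5, 0.55, 0.52, 0.49, 0.51]
        assert compare_growth_divergence(a, b) < 1e-4


def test_binom_two_sided_matches_fisher_convention():
    # sum of P(k) <= P(obs), by hand at n=2: P(0)=P(2)=1/4 qualify, P(1)=1/2
    # does not -> p = 1/2
    assert binom_two_sided(0, 2, 0.5) == pytest.approx(0.5)
    assert binom_two_sided(0, 10, 0.5) == pytest.approx(2 * 2.0 ** -10)
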