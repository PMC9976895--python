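"""Saturation resampling, bin-wise FDR, gene-set logic and bin profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from jloe import (
    BinProfile,
    GeneSet,
    binwise_fdr,
    common_context_sets,
    expression_by_bin,
    high_confidence_set,
    nonhit_bf_by_bin,
    saturation_sample,
)


def _matrix(hits: np.ndarray) -> pd.DataFrame:
    """Boolean hit pattern -> BF matrix (hit 20, miss -10)."""
    return pd.DataFrame(
        np.where(hits, 20.0, -10.0),
        index=[f"g{i}" for i in range(hits.shape[0])],
        columns=[f"s{j:02d}" for j in range(hits.shape[1])],
    )


class TestSaturationSample:
    def test_universal_hit_lands_in_top_bin_never_fp(self):
        hits = np.zeros((3, 8), dtype=bool)
        hits[0] = True  # one gene hit in every screen
        profile, freq = saturation_sample(_matrix(hits), k=4, iterations=20, seed=0)
        assert profile.tp_mean[-1] == 1.0
        assert profile.fp_mean.sum() == 0.0
        assert freq.mean_frequency["g0"] == 4.0

    def test_too_few_screens_names_tissue(self):
        hits = np.zeros((2, 6), dtype=bool)
        with pytest.raises(ValueError, match="pancreas"):
            saturation_sample(_matrix(hits), k=4, tissue="pancreas")

    def test_histograms_match_exhaustive_partitions(self, rng):
        # 6 genes, 8 screens, k=4: the subsequent set is the complement of
        # the initial set, so the 70 initial choices enumerate all partitions
        hits = rng.random((6, 8)) < 0.4
        k, n_screens = 4, 8
        tp_exp = np.zeros(k)
        fp_exp = np.zeros(k)
        parts = list(itertools.combinations(range(n_screens), k))
        for init in parts:
            subs = [s for s in range(n_screens) if s not in init]
            fi = hits[:, init].sum(axis=1)
            fs = hits[:, subs].sum(axis=1)
            for b in range(1, k + 1):
                tp_exp[b - 1] += (fi == b).sum()
                fp_exp[b - 1] += ((fi == 0) & (fs == b)).sum()
        tp_exp /= len(parts)
        fp_exp /= len(parts)
        profile, _ = saturation_sample(_matrix(hits), k=k, iterations=8000, seed=1)
        tp_se = profile.tp_sd / np.sqrt(8000)
        fp_se = profile.fp_sd / np.sqrt(8000)
        assert np.all(np.abs(profile.tp_mean - tp_exp) <= 3 * tp_se + 1e-9)
        assert np.all(np.abs(profile.fp_mean - fp_exp) <= 3 * fp_se + 1e-9)

    def test_tp_bins_sum_to_cumulative_initial_hits(self, colorectal):
        bf, _, _ = colorectal
        profile, freq = saturation_sample(bf, k=8, iterations=30, seed=2)
        per_iter_hits = (freq.counts > 0).sum(axis=0)  # genes with >= 1 initial hit
        assert profile.tp_mean.sum() == pytest.approx(per_iter_hits.mean())

    def test_fp_mass_concentrates_in_single_screen_bin(self, colorectal):
        # spurious hits do not replicate: most new genes appear once
        bf, _, _ = colorectal
        profile, _ = saturation_sample(bf, k=8, iterations=50, seed=3)
        assert profile.fp_mean[0] > 0.5 * profile.fp_mean.sum()

    def test_flag_once_mode_puts_all_fp_mass_in_bin_one(self, colorectal):
        bf, _, _ = colorectal
        profile, _ = saturation_sample(
            bf, k=8, iterations=20, seed=4, fp_binning="flag_once"
        )
        assert profile.fp_mean[1:].sum() == 0.0
        with pytest.raises(ValueError, match="fp_binning"):
            saturation_sample(bf, k=8, fp_binning="bogus")


class TestBinwiseFdr:
    def _profile(self, tp, fp, k=8):
        tp = np.asarray(tp, dtype=float)
        fp = np.asarray(fp, dtype=float)
        return BinProfile(k=k, tp_mean=tp, tp_sd=np.zeros_like(tp),
                          fp_mean=fp, fp_sd=np.zeros_like(fp))

    def test_worked_first_bin_example(self):
        # 247 subsequent-set new hits vs 648 initial hits in bin 1 -> ~38%
        profile = self._profile([648, 100, 50, 20, 10, 5, 2, 400],
                                [247, 10, 1, 0, 0, 0, 0, 0])
        table = binwise_fdr(profile)
        assert table.fdr[1] == pytest.approx(247 / 648, abs=1e-12)
        assert round(100 * table.fdr[1]) == 38

    def test_zero_fp_bin_capped_prior(self):
        table = binwise_fdr(self._profile([10, 10, 10, 10, 10, 10, 10, 10],
                                          [5, 0, 0, 0, 0, 0, 0, 0]))
        assert table.fdr[2] == 0.0
        assert table.log_prior[2] == 9.0

    def test_matches_direct_ratio_oracle(self, rng):
        tp = rng.integers(1, 500, 8).astype(float)
        fp = rng.integers(0, 200, 8).astype(float)
        table = binwise_fdr(self._profile(tp, fp))
        for b in range(1, 8):
            assert table.fdr[b] == pytest.approx(min(fp[b - 1] / tp[b - 1], 1.0))

    def test_empty_bin_inherits_lower_bin(self):
        table = binwise_fdr(self._profile([100, 50, 0, 0, 10, 10, 10, 10],
                                          [40, 5, 3, 3, 0, 0, 0, 0]))
        assert table.fdr[3] == table.fdr[2]  # nearest populated lower bin
        assert table.fdr[4] == table.fdr[2]

    def test_leading_empty_bins_default_to_zero_fdr(self):
        table = binwise_fdr(self._profile([0, 0, 10, 10, 10, 10, 10, 10],
                                          [5, 5, 1, 0, 0, 0, 0, 0]))
        assert table.fdr[1] == 0.0
        assert table.log_prior[1] == 9.0

    def test_scale_free(self):
        p1 = self._profile([100, 50, 10, 5, 2, 1, 1, 1], [40, 5, 1, 0, 0, 0, 0, 0])
        p2 = self._profile([200, 100, 20, 10, 4, 2, 2, 2], [80, 10, 2, 0, 0, 0, 0, 0])
        assert binwise_fdr(p1).fdr == binwise_fdr(p2).fdr


class TestHighConfidenceSet:
    def _freq(self, means):
        from jloe.saturation import FrequencyProfile

        genes = pd.Index([f"g{i}" for i in range(len(means))])
        counts = np.asarray(means, dtype=float)[:, None]
        return FrequencyProfile(
            k=8, gene_ids=genes, screen_ids=pd.Index([]), counts=counts,
            initial_screens=np.zeros((1, 8), dtype=int),
            subsequent_screens=np.zeros((1, 8), dtype=int),
        )

    def test_boundary_inclusive_at_three(self):
        gs = high_confidence_set(self._freq([3.0, 2.999, 8.0, 0.0]))
        assert gs.members == frozenset({"g0", "g2"})

    def test_all_zero_profile_empty(self):
        assert len(high_confidence_set(self._freq([0.0, 0.0]))) == 0

    def test_monotone_in_threshold(self, rng):
        means = rng.uniform(0, 8, 50)
        lo = high_confidence_set(self._freq(means), min_mean_freq=2.0)
        hi = high_confidence_set(self._freq(means), min_mean_freq=5.0)
        assert hi.members <= lo.members


class TestCommonContextSets:
    def test_identical_sets(self):
        s = GeneSet("a", ["x", "y"])
        common, context, unique = common_context_sets({"t1": s, "t2": s})
        assert common.members == s.members
        assert all(len(c) == 0 for c in context.values())
        assert all(len(u) == 0 for u in unique.values())

    def test_disjoint_sets(self):
        a, b = GeneSet("a", ["x"]), GeneSet("b", ["y"])
        common, context, unique = common_context_sets({"t1": a, "t2": b})
        assert len(common) == 0
        assert unique["t1"].members == a.members
        assert unique["t2"].members == b.members

    def test_matches_membership_matrix_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        sets = {
            t: GeneSet(t, [g for g in genes if rng.random() < 0.5])
            for t in ("t1", "t2", "t3")
        }
        common, context, unique = common_context_sets(sets)
        membership = pd.DataFrame(
            {t: [g in sets[t] for g in genes] for t in sets}, index=genes
        )
        assert common.members == frozenset(membership.index[membership.all(axis=1)])
        for t in sets:
            assert context[t].members == sets[t].members - common.members
            only_t = membership.index[
                membership[t] & (membership.drop(columns=t).sum(axis=1) == 0)
            ]
            assert unique[t].members == frozenset(only_t)

    def test_requires_two_tissues(self):
        with pytest.raises(ValueError):
            common_context_sets({"t1": GeneSet("a", ["x"])})


class TestExpressionByBin:
    def test_uniform_expression(self):
        hits = np.eye(4, 8, dtype=bool) | np.ones((4, 8), dtype=bool)
        bf = _matrix(hits)
        expr = pd.DataFrame(5.0, index=bf.index, columns=bf.columns)
        _, freq = saturation_sample(bf, k=4, iterations=5, seed=0)
        means, excluded = expression_by_bin(freq, bf, expr)
        assert excluded == 0
        populated = means.dropna()
        assert np.allclose(populated, 5.0)

    def test_hand_computed_two_gene_toy(self):
        # k=1 set from 2 screens: expression averaged only over hit screens
        bf = pd.DataFrame({"s1": [20.0, 20.0], "s2": [20.0, -10.0]},
                          index=["a", "b"])
        expr = pd.DataFrame({"s1": [1.0, 7.0], "s2": [3.0, 100.0]},
                            index=["a", "b"])
        _, freq = saturation_sample(bf, k=1, iterations=400, seed=1)
        means, _ = expression_by_bin(freq, bf, expr)
        # hand oracle: iterations drawing s1 record genes a (1.0) and b (7.0);
        # iterations drawing s2 record only a (3.0)
        n_s1 = int((freq.initial_screens[:, 0] == 0).sum())
        n_s2 = freq.iterations - n_s1
        expected = (n_s1 * (1.0 + 7.0) + n_s2 * 3.0) / (2 * n_s1 + n_s2)
        assert means[1] == pytest.approx(expected, abs=1e-9)

    def test_expression_increases_with_frequency(self, colorectal):
        bf, expr, _ = colorectal
        _, freq = saturation_sample(bf, k=8, iterations=30, seed=2)
        means, _ = expression_by_bin(freq, bf, expr)
        assert means.loc[6:8].mean() > means.loc[1:3].mean()

    def test_missing_expression_counted(self, colorectal):
        bf, expr, _ = colorectal
        _, freq = saturation_sample(bf, k=8, iterations=3, seed=2)
        means, excluded = expression_by_bin(freq, bf, expr.iloc[10:], 10.0)
        assert excluded > 0


class TestNonhitBfByBin:
    def test_hand_computed_mean(self):
        from jloe.saturation import FrequencyProfile

        # gene with BFs {12, 4, 2} in a 3-screen set at threshold 10:
        # one hit (bin 1), non-hit mean (4 + 2) / 2 = 3
        bf = pd.DataFrame({"s1": [12.0], "s2": [4.0], "s3": [2.0]}, index=["g"])
        freq = FrequencyProfile(
            k=3, gene_ids=bf.index, screen_ids=bf.columns,
            counts=np.array([[1]]),
            initial_screens=np.array([[0, 1, 2]]),
            subsequent_screens=np.array([[0, 1, 2]]),
        )
        out = nonhit_bf_by_bin(freq, bf)
        assert len(out) == 1
        assert out.iloc[0]["bin"] == 1
        assert out.iloc[0]["mean_nonhit_bf"] == pytest.approx(3.0)

    def test_saturated_genes_excluded(self):
        hits = np.ones((2, 8), dtype=bool)
        hits[1, :4] = False
        bf = _matrix(hits)
        _, freq = saturation_sample(bf, k=4, iterations=10, seed=1)
        out = nonhit_bf_by_bin(freq, bf)
        assert "g0" not in set(out["gene"])  # hit in all screens

    def test_mean_over_nonhit_screens_matches_hand_value(self):
        # one gene, 8 screens: hit in 4 (BF 20), miss in 4 (BFs 4, 2, 0, -2)
        bf = pd.DataFrame(
            [[20.0, 20.0, 20.0, 20.0, 4.0, 2.0, 0.0, -2.0]], index=["g"],
            columns=[f"s{j}" for j in range(8)],
        )
        _, freq = saturation_sample(bf, k=4, iterations=50, seed=2)
        out = nonhit_bf_by_bin(freq, bf)
        # every record's mean is an average of a subset of {4, 2, 0, -2}
        assert out["mean_nonhit_bf"].between(-2.0, 4.0).all()
        assert (out["bin"] >= 1).all()  # zero-hit iterations never reported

    def test_false_negatives_sit_nearer_zero_than_nonessentials(self, colorectal):
        bf, _, truth = colorectal
        _, freq = saturation_sample(bf, k=8, iterations=30, seed=3)
        out = nonhit_bf_by_bin(freq, bf)
        per_gene = out.groupby("gene").agg(
            bin=("bin", "mean"), v=("mean_nonhit_bf", "mean")
        )
        high = per_gene[per_gene["bin"] >= 5]["v"].mean()
        low = per_gene[per_gene["bin"] <= 2]["v"].mean()
        assert high > low  # frequent hits miss near BF 0, not deeply negative
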