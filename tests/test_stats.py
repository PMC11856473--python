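"""Statistics: Lilliefors KS behaviour, Wilcoxon exactness and power,
Spearman cluster bootstrap, and bias/residual summaries."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from trabec_bvtv import (
    PairedMeasurement,
    bias_and_residuals,
    compile_report,
    ks_normality,
    spearman_with_cluster_bootstrap,
    wilcoxon_ranksum,
)


def make_pairs(x, y, specimens=None):
    specimens = specimens or ["s0"] * len(x)
    return [
        PairedMeasurement(s, i, bvtv_mr=float(np.clip(a, 0, 1)), bvtv_uct=float(np.clip(b, 0, 1)))
        for i, (s, a, b) in enumerate(zip(specimens, x, y))
    ]


class TestKSNormality:
    def test_calibrated_size_and_power(self):
        """The Monte-Carlo null is calibrated (size ~ 5% on normal data) and
        the test has power against non-normal alternatives: strong against a
        skewed (exponential) sample, and well above the nominal level against
        a uniform one (whose power at n=60 is modest for any KS-type test,
        about 30-35% - cross-checked against an independent implementation)."""
        rng = np.random.default_rng(0)

        def rejection_rate(draw):
            return sum(
                ks_normality(draw(), n_mc=500, seed=1)[1] < 0.05 for _ in range(200)
            )

        assert 2 <= rejection_rate(lambda: rng.normal(0, 1, 60)) <= 20
        assert rejection_rate(lambda: rng.exponential(1, 60)) >= 160
        assert rejection_rate(lambda: rng.uniform(0, 1, 60)) >= 50

    def test_accepts_exact_normal_quantiles(self):
        q = sps.norm.ppf((np.arange(1, 61) - 0.5) / 60)
        stat, p = ks_normality(q, seed=0)
        assert p > 0.5

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ks_normality([0.3] * 10)

    def test_statistic_matches_statsmodels_lilliefors(self):
        from statsmodels.stats.diagnostic import lilliefors

        rng = np.random.default_rng(5)
        x = rng.normal(0.3, 0.05, 40)
        stat, _ = ks_normality(x, seed=0)
        sm_stat, _ = lilliefors(x, dist="norm")
        assert stat == pytest.approx(sm_stat, abs=1e-10)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([0.1, 0.2, 0.3])


def enumerate_ranksum_p(a, b):
    """Brute-force two-sided rank-sum p over all label assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    sums = [
        ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n_a)
    ]
    sums = np.array(sums)
    p_le = (sums <= w_obs + 1e-9).mean()
    p_ge = (sums >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_extreme_separation_small_groups(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 9), rng.integers(2, 9)
        # discrete values force ties
        a = rng.integers(0, 6, n_a).astype(float)
        b = rng.integers(0, 6, n_b).astype(float)
        _, p = wilcoxon_ranksum(a, b, exact=True)
        assert p == pytest.approx(enumerate_ranksum_p(a, b), abs=1e-12)

    def test_approximate_path_tracks_scipy(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.22, 0.03, 60)
        b = rng.normal(0.31, 0.03, 60)
        _, p = wilcoxon_ranksum(a, b, exact=False)
        p_scipy = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(p_scipy, rel=0.05, abs=1e-12)

    def test_power_at_study_effect_size(self):
        """A 9-point offset with 3-point SD at n=60/60 is detected at
        p < 0.01 in nearly all repeats."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(40):
            a = rng.normal(0.22, 0.03, 60)
            b = rng.normal(0.31, 0.03, 60)
            hits += wilcoxon_ranksum(a, b, exact=False)[1] < 0.01
        assert hits >= 38

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([1.0], [2.0, 3.0])


class TestSpearmanBootstrap:
    def monotone_pairs(self):
        x = np.linspace(0.15, 0.45, 20)
        specimens = [f"s{i // 10}" for i in range(20)]
        return make_pairs(x + 0.09, x, specimens)

    def test_perfectly_monotone(self):
        res = spearman_with_cluster_bootstrap(self.monotone_pairs(), n_boot=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci95 == (pytest.approx(1.0), pytest.approx(1.0))

    def test_anti_monotone(self):
        x = np.linspace(0.15, 0.45, 20)
        specimens = [f"s{i // 10}" for i in range(20)]
        pairs = make_pairs(0.6 - x, x, specimens)
        res = spearman_with_cluster_bootstrap(pairs, n_boot=100, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 0.5, 30)
        y = x + rng.normal(0, 0.05, 30)
        specimens = [f"s{i // 10}" for i in range(30)]
        r1 = spearman_with_cluster_bootstrap(make_pairs(y, x, specimens), 50, seed=0).r
        r2 = spearman_with_cluster_bootstrap(
            make_pairs(np.sqrt(y), x**3, specimens), 50, seed=0
        ).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_point_estimate_matches_scipy(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.25, 0.75, 40)
        y = x + rng.normal(0, 0.1, 40)
        specimens = [f"s{i // 10}" for i in range(40)]
        res = spearman_with_cluster_bootstrap(make_pairs(y, x, specimens), 10, seed=0)
        assert res.r == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_cluster_ci_wider_than_naive_under_dependence(self):
        """With strong within-specimen correlation (ICC ~ 0.5), resampling
        whole specimens yields a wider CI than pretending slices are
        independent."""
        rng = np.random.default_rng(8)
        pairs = []
        for j in range(6):
            u = rng.normal(0, 0.08)
            for i in range(10):
                x = float(np.clip(0.3 + u + rng.normal(0, 0.05), 0.01, 0.99))
                y = float(np.clip(0.25 + u + rng.normal(0, 0.05), 0.01, 0.99))
                pairs.append(PairedMeasurement(f"s{j}", i, bvtv_mr=y, bvtv_uct=x))
        cluster = spearman_with_cluster_bootstrap(pairs, n_boot=800, seed=0)
        # naive bootstrap: every row its own cluster
        naive_pairs = [
            PairedMeasurement(f"r{k}", 0, bvtv_mr=p.bvtv_mr, bvtv_uct=p.bvtv_uct)
            for k, p in enumerate(pairs)
        ]
        naive = spearman_with_cluster_bootstrap(naive_pairs, n_boot=800, seed=0)
        assert (cluster.ci95[1] - cluster.ci95[0]) >= (naive.ci95[1] - naive.ci95[0])

    def test_single_specimen_rejected(self):
        pairs = make_pairs(np.linspace(0, 1, 12), np.linspace(0, 1, 12))
        with pytest.raises(ValueError, match="single specimen"):
            spearman_with_cluster_bootstrap(pairs, 10, seed=0)

    def test_too_few_pairs_rejected(self):
        pairs = make_pairs([0.1, 0.2], [0.2, 0.3], ["a", "b"])
        with pytest.raises(ValueError, match="10 pairs"):
            spearman_with_cluster_bootstrap(pairs, 10, seed=0)


class TestBiasAndResiduals:
    def test_constant_offset(self):
        x = np.linspace(0.2, 0.4, 10)
        pairs = make_pairs(x - 0.09, x)
        out = bias_and_residuals(pairs)
        assert out.difference.mean == pytest.approx(0.09, abs=1e-12)
        assert out.difference.sd == pytest.approx(0.0, abs=1e-9)
        assert out.residuals.sd == pytest.approx(0.0, abs=1e-9)
        assert out.slope == pytest.approx(1.0, abs=1e-9)

    def test_residual_mean_vanishes(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0.15, 0.45, 50)
        y = 0.7 * x + rng.normal(0, 0.02, 50)
        out = bias_and_residuals(make_pairs(y, x))
        assert abs(out.residuals.mean) < 1e-12

    def test_constant_uct_rejected(self):
        pairs = make_pairs([0.1, 0.2, 0.3], [0.3, 0.3, 0.3])
        with pytest.raises(ValueError, match="constant"):
            bias_and_residuals(pairs)


def test_compile_report_surfaces_all_sections():
    rng = np.random.default_rng(12)
    pairs = []
    for j in range(6):
        base = 0.15 + 0.06 * j
        for i in range(10):
            x = float(np.clip(base + rng.normal(0, 0.02), 0.01, 0.99))
            pairs.append(
                PairedMeasurement(f"s{j}", i, bvtv_mr=max(x - 0.09, 0.01), bvtv_uct=x)
            )
    report = compile_report(pairs, n_boot=200, seed=0)
    assert report.n_pairs == 60
    assert report.n_specimens == 6
    assert report.wilcoxon_p < 0.01
    assert report.spearman.r > 0.9
    assert report.uct_pct.mean > report.mr_pct.mean
    d = report.to_dict()
    assert set(d) >= {"ks_mr", "ks_uct", "spearman", "bias", "mr_pct", "uct_pct"}
    text = report.summary()
    assert "Spearman" in text and "Wilcoxon" in text
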