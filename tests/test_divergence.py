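"""Resampling divergence/TE tests, BH adjustment, regulatory categories."""

import numpy as np
import pytest
from scipy import stats

import ribostrain as rs
from ribostrain import divergence as dv
from ribostrain import simulate as sim
from ribostrain.io import OrthologPair


def _pair_counts(cov_b, cov_y, seq_b, seq_y, libs=None, assay="mrna",
                 reps=(1, 2)):
    """Assemble OrthologCounts from per-replicate vectors."""
    from ribostrain.io import nucleotide_freq
    pair = OrthologPair("gB", "gY", len(seq_b), len(seq_y),
                        nucleotide_freq(seq_b), nucleotide_freq(seq_y))
    cov, sizes = {}, {}
    for r in reps:
        cov[("B", assay, r)] = np.asarray(cov_b[r - 1])
        cov[("Y", assay, r)] = np.asarray(cov_y[r - 1])
        sizes[("B", assay, r)] = libs[0] if libs else cov[("B", assay, r)].sum()
        sizes[("Y", assay, r)] = libs[1] if libs else cov[("Y", assay, r)].sum()
    return dv.OrthologCounts(pair, seq_b, seq_y, cov, sizes)


class TestStratifiedResampling:
    def test_constant_coverage_is_exact(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 120))
        total = dv.stratified_resample_total(
            np.full(120, 3.0), seq, 90, (0.1, 0.2, 0.3, 0.4), rng)
        assert total == 90 * 3.0

    def test_single_class_reduces_to_plain_bootstrap(self, rng):
        cov = rng.integers(0, 5, size=50).astype(float)
        seq = "A" * 50
        totals = dv.stratified_resample_total(
            cov, seq, 200, (1.0, 0.0, 0.0, 0.0), np.random.default_rng(0),
            size=2000)
        # plain bootstrap of 200 positions: mean 200 * mean(cov)
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - 200 * cov.mean()) < 3 * se

    def test_bootstrap_expectation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        cov = rng.poisson(2.0, size=300).astype(float)
        pi = (0.25, 0.25, 0.25, 0.25)
        totals = dv.stratified_resample_total(
            cov, seq, 300, pi, np.random.default_rng(1), size=10000)
        # expectation: sum over classes of n_b * mean(class counts)
        from ribostrain.divergence import _largest_remainder, _positions_by_base
        by = _positions_by_base(seq)
        quotas = _largest_remainder(300, np.asarray(pi))
        expect = sum(q * cov[by[b]].mean() for b, q in enumerate(quotas))
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - expect) < 3 * se

    def test_empty_coverage_rejected(self):
        with pytest.raises(ValueError):
            dv.stratified_resample_total(np.array([]), "", 10, (1, 0, 0, 0), 0)

    def test_absent_base_class_quota_reallocated(self, rng):
        seq = "ATATAT"  # no G or C positions
        total = dv.stratified_resample_total(
            np.full(6, 2.0), seq, 9, (0.25, 0.25, 0.25, 0.25), rng)
        assert total == 18.0  # full quota still drawn, from present classes


def test_largest_remainder_partition():
    q = dv._largest_remainder(10, np.array([0.5, 0.3, 0.1, 0.1]))
    assert q.tolist() == [5, 3, 1, 1]
    q = dv._largest_remainder(7, np.array([0.5, 0.5, 0.0, 0.0]))
    assert q.sum() == 7 and q[2] == q[3] == 0


class TestNullDistribution:
    def test_constant_coverage_degenerate_at_zero(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 90))
        counts = _pair_counts([np.full(90, 4)] * 2, [np.full(90, 4)] * 2,
                              seq, seq, libs=(1000, 1000))
        null = dv.null_log2_distribution(counts, "mrna", 1, "B", 200, seed=0)
        assert np.allclose(null, 0.0)

    def test_two_seeds_agree_in_distribution(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        cov = [rng.poisson(2.0, 300), rng.poisson(2.0, 300)]
        counts = _pair_counts(cov, cov, seq, seq)
        n1 = dv.null_log2_distribution(counts, "mrna", 1, "B", 10000, seed=1)
        n2 = dv.null_log2_distribution(counts, "mrna", 1, "B", 10000, seed=2)
        assert stats.ks_2samp(n1, n2).pvalue > 0.01

    def test_strain_swap_negates_null_exactly(self, rng):
        seq_b = "".join(rng.choice(list("ACGT"), 240))
        seq_y = "".join(rng.choice(list("ACGT"), 270))
        cb = [rng.poisson(3.0, 240), rng.poisson(3.0, 240)]
        cy = [rng.poisson(2.0, 270), rng.poisson(2.0, 270)]
        counts = _pair_counts(cb, cy, seq_b, seq_y)
        null = dv.null_log2_distribution(counts, "mrna", 2, "B", 500, seed=3)
        null_sw = dv.null_log2_distribution(counts.swapped(), "mrna", 2, "Y",
                                            500, seed=3)
        assert np.allclose(null_sw, -null)


class TestDivergenceTest:
    def test_identical_strains_never_significant(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        cov = [rng.poisson(2.0, 150), rng.poisson(2.0, 150)]
        counts = _pair_counts(cov, cov, seq, seq, libs=(5000, 5000))
        row = dv.divergence_test(counts, "mrna", n_resamples=500, seed=4)
        assert row.log2_ratio == 0.0
        assert row.p_max > 0.5

    def test_insufficient_reads_skipped_with_reason(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        cov = [np.zeros(150, int), np.ones(150, int) * 0]
        counts = _pair_counts(cov, cov, seq, seq, libs=(100, 100))
        row = dv.divergence_test(counts, "mrna", n_resamples=100, seed=0)
        assert not row.tested and "50" in row.skip_reason

    def test_missing_replicate_is_an_error(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 90))
        counts = _pair_counts([np.ones(90, int)], [np.ones(90, int)],
                              seq, seq, reps=(1,), libs=(500, 500))
        with pytest.raises(ValueError, match="replicate"):
            dv.divergence_test(counts, "mrna", n_resamples=100, seed=0)

    def test_planted_difference_detected(self):
        cfg = sim.SimConfig(n_genes=6, seed=21,
                            fold_change_spec=[(0, "mrna", 2.0)])
        pair = sim.simulate_strain_pair(cfg)
        cov = sim.simulate_coverage(pair, assays=("mrna",))
        counts = rs.counts_from_simulation(pair, cov, assays=("mrna",))
        res = rs.DivergenceModel(counts, assay="mrna").fit(
            n_resamples=1000, seed=5)
        f = res.frame
        assert bool(f.loc[0, "significant"])
        assert f.loc[0, "log2_ratio"] == pytest.approx(2.0, abs=0.5)
        assert f.loc[0, "p_max"] == pytest.approx(2.0 / 1001)


class TestEmpiricalP:
    def test_matches_exhaustive_counting(self, rng):
        for n in (7, 50, 200):
            null = rng.normal(size=n)
            for obs in (-2.0, 0.0, float(null[0]), 3.0):
                lo = sum(1 for x in null if x <= obs) + 1
                hi = sum(1 for x in null if x >= obs) + 1
                expect = min(1.0, 2 * min(lo, hi) / (n + 1))
                assert dv.empirical_p_two_sided(null, obs) == expect

    def test_never_zero_never_above_one(self, rng):
        null = rng.normal(size=100)
        assert 0 < dv.empirical_p_two_sided(null, 99.0) <= 1
        assert dv.empirical_p_two_sided(null, 99.0) == 2 / 101
        assert dv.empirical_p_two_sided(null, float(np.median(null))) <= 1


class TestBH:
    def test_hand_computed_step_up(self):
        assert dv.bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert dv.bh_adjust([0.37]) == pytest.approx([0.37])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dv.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            dv.bh_adjust([0.5, 1.5])

    def test_matches_rank_based_oracle(self, rng):
        def oracle(p):
            n = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(n)
            prev = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * n / rank)
                q[i] = prev
            return q
        for _ in range(200):
            p = rng.uniform(0.001, 1.0, size=int(rng.integers(1, 13)))
            assert dv.bh_adjust(p) == pytest.approx(oracle(p))


class TestTE:
    def test_pure_transcriptional_shift_is_te_null(self, rng):
        """mRNA and RFP shifted identically: TE difference is exactly 0,
        directionality cannot agree, call is non-significant."""
        seq = "".join(rng.choice(list("ACGT"), 150))
        cb = [rng.poisson(2.0, 150), rng.poisson(2.0, 150)]
        cy = [rng.poisson(8.0, 150), rng.poisson(8.0, 150)]
        pair = _pair_counts(cb, cy, seq, seq, libs=(3000, 3000))
        # duplicate mRNA coverage into RFP
        for r in (1, 2):
            pair.coverage[("B", "rfp", r)] = pair.coverage[("B", "mrna", r)]
            pair.coverage[("Y", "rfp", r)] = pair.coverage[("Y", "mrna", r)]
            pair.library_size[("B", "rfp", r)] = 3000
            pair.library_size[("Y", "rfp", r)] = 3000
        row = dv.te_test(pair, n_resamples=300, seed=6)
        assert row.log2_te_ratio == 0.0
        assert not row.direction_agrees and row.p_max == 1.0

    def test_opposite_replicate_directions_never_significant(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 150))
        base = rng.poisson(3.0, 150)
        pair = _pair_counts([base, base], [base, base], seq, seq,
                            libs=(2000, 2000))
        # RFP: strong opposite shifts in the two replicates
        pair.coverage[("B", "rfp", 1)] = base * 4
        pair.coverage[("Y", "rfp", 1)] = base
        pair.coverage[("B", "rfp", 2)] = base
        pair.coverage[("Y", "rfp", 2)] = base * 4
        for r in (1, 2):
            pair.library_size[("B", "rfp", r)] = 2000
            pair.library_size[("Y", "rfp", r)] = 2000
        row = dv.te_test(pair, n_resamples=300, seed=7)
        assert not row.direction_agrees and row.p_max == 1.0

    def test_translation_only_shift_detected_with_sign(self):
        """RFP ratio 4, mRNA ratio 1: TE divergence called with positive
        log2 TE ratio (B/Y) when the shift favours strain B."""
        n = 30
        cfg = sim.SimConfig(n_genes=n, seed=23,
                            fold_change_spec=[(i, "rfp", -2.0)
                                              for i in range(n)])
        pair = sim.simulate_strain_pair(cfg)
        cov = sim.simulate_coverage(pair)
        counts = rs.counts_from_simulation(pair, cov)
        res = rs.TranslationEfficiencyModel(counts, normalize=False).fit(
            n_resamples=500, seed=8)
        f = res.frame
        assert f["significant"].mean() >= 0.9
        assert (f.loc[f["significant"], "log2_te_ratio"] > 0).all()


@pytest.mark.parametrize("mrna,te,expected", [
    (True, False, "mRNA-only"),
    (False, True, "TE-only"),
    (True, True, "both"),
    (False, False, "neither"),
])
def test_classify_regulation(mrna, te, expected):
    assert dv.classify_regulation(mrna, te) == expected


def test_results_summary_and_tsv(tmp_path, toy_pair, toy_coverage):
    counts = rs.counts_from_simulation(toy_pair, toy_coverage)
    res = rs.DivergenceModel(counts, assay="mrna").fit(n_resamples=200, seed=9)
    text = res.summary()
    assert "ortholog pairs" in text and "FDR" in text
    res.to_tsv(tmp_path / "d.tsv")
    import pandas as pd
    back = pd.read_csv(tmp_path / "d.tsv", sep="\t")
    assert len(back) == len(counts) and "q" in back.columns
    te = rs.TranslationEfficiencyModel(counts).fit(n_resamples=200, seed=9)
    cats = te.categories(res)
    assert set(cats) <= set(dv.REGULATORY_CATEGORIES)
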