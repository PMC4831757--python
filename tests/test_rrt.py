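"""Codon windows, relative frequencies, RRT permutation statistics."""

import numpy as np
import pandas as pd
import pytest

from ribostrain import io as rio
from ribostrain import mapping, rrt
from ribostrain import simulate as sim
from ribostrain.codons import SENSE_CODONS, codon_indices


def test_window_geometry_and_uniform_expectation():
    assert rrt.eligible_positions() == 9
    assert rrt.uniform_expected_rf() == pytest.approx(1 / 9)
    # a 15-codon window admits fewer placements: starts c-7..c-1
    assert rrt.eligible_positions(window_codons=15) == 7


class TestInFrameFootprints:
    model = rio.GeneModel("g", "c", "+", ((30, 120),))

    def _aln(self, pos, length=27):
        return mapping.ReadAlignment("r", "c", pos, "+", length, 0)

    def test_length_below_27_dropped(self):
        fps = rrt.in_frame_footprints([self._aln(30, 26)], [self.model])
        assert len(fps) == 0
        fps = rrt.in_frame_footprints([self._aln(30, 27)], [self.model])
        assert len(fps) == 1

    def test_off_frame_five_prime_end_dropped(self):
        assert len(rrt.in_frame_footprints([self._aln(31)], [self.model])) == 0
        assert len(rrt.in_frame_footprints([self._aln(32)], [self.model])) == 0
        fps = rrt.in_frame_footprints([self._aln(33)], [self.model])
        assert len(fps) == 1 and fps.codon_start[0] == 1

    def test_counts_match_brute_force_tally(self, rng):
        alns = [self._aln(int(p), int(l)) for p, l in zip(
            rng.integers(0, 150, size=500), rng.integers(24, 33, size=500))]
        fps = rrt.in_frame_footprints(alns, [self.model])
        brute = sum(1 for a in alns
                    if a.length >= 27 and 30 <= a.pos5 < 120
                    and (a.pos5 - 30) % 3 == 0)
        assert len(fps) == brute


class TestBuildWindows:
    def test_single_window_in_17_codon_cds(self):
        cods = ["GCT"] * 8 + ["CCA"] + ["GCT"] * 8
        seq = codon_indices("".join(cods))
        assert rrt.build_windows(seq, "CCA") == [8]
        assert rrt.build_windows(seq, "GGG") == []

    def test_duplicate_in_window_excluded(self):
        cods = ["GCT"] * 8 + ["CCA"] + ["GCT"] * 5 + ["CCA"] + ["GCT"] * 2
        seq = codon_indices("".join(cods))
        assert rrt.build_windows(seq, "CCA") == []

    def test_matches_quadratic_scan_oracle(self, rng):
        from ribostrain.codons import CODON_INDEX
        sense = np.array([CODON_INDEX[c] for c in SENSE_CODONS])
        for _ in range(50):
            cods = rng.choice(sense, size=int(rng.integers(17, 120)))
            codon = SENSE_CODONS[int(rng.integers(61))]
            got = rrt.build_windows(cods, codon)
            ci = CODON_INDEX[codon]
            expect = [c for c in range(8, len(cods) - 8)
                      if cods[c] == ci
                      and sum(cods[j] == ci for j in range(c - 8, c + 9)) == 1]
            assert got == expect


def _uniform_model(n_genes=6, n_codons=120, seed=0, dwell=None, reads=30000):
    rng = np.random.default_rng(seed)
    sense = list(SENSE_CODONS)
    cds = {}
    for i in range(n_genes):
        body = "".join(rng.choice(sense, size=n_codons - 2))
        cds[f"g{i}"] = "ATG" + body + "TAA"
    fps = sim.simulate_footprints(cds, dwell or {}, reads, seed=seed + 1)
    return rrt.ResidenceTimeModel(cds, fps)


class TestRRTTable:
    def test_equal_counts_give_rrt_one(self):
        cds = {"g": "ATG" + "GCT" * 8 + "CCA" + "GCT" * 8 + "TAA"}
        # window for CCA centered at codon 9 (0-based within the CDS)
        gi = np.zeros(9, dtype=np.int64)
        cs = np.arange(1, 10, dtype=np.int64)  # one footprint per position
        fps = sim.FootprintSet(["g"], gi, cs, 27)
        res = rrt.ResidenceTimeModel(cds, fps).fit(permutations=50, seed=0,
                                                   codons=("CCA",))
        t = res.table
        assert np.allclose(t["rf"], 1 / 9)
        assert np.allclose(t["rrt"], 1.0)
        assert (t["n_windows"] == 1).all()

    def test_rf_normalization_sums_to_one(self):
        model = _uniform_model(seed=3)
        res = model.fit(permutations=20, seed=1)
        sums = res.table.dropna(subset=["rf"]).groupby("codon")["rf"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        rrts = res.table.dropna(subset=["rrt"]).groupby("codon")["rrt"].sum()
        assert np.allclose(rrts, 9.0, atol=1e-6)

    def test_rf_0_2222_maps_to_rrt_2(self):
        assert 0.2222 / (1 / 9) == pytest.approx(2.0, abs=1e-3)

    def test_codon_without_windows_reported_missing(self):
        cds = {"g": "ATG" + "GCT" * 20 + "TAA"}
        fps = sim.FootprintSet(["g"], np.zeros(3, np.int64),
                               np.arange(3, dtype=np.int64), 27)
        res = rrt.ResidenceTimeModel(cds, fps).fit(permutations=20, seed=0,
                                                   codons=("CCA",))
        assert res.table["rrt"].isna().all()
        assert (res.table["n_windows"] == 0).all()

    def test_site_flags(self):
        model = _uniform_model(seed=4, reads=2000)
        res = model.fit(permutations=10, seed=0, codons=("GCT",))
        t = res.table.set_index("position")["site"]
        assert t[6] == "A" and t[5] == "P" and t[4] == "E"
        assert t[1] == "" and t[9] == ""


class TestPermutationP:
    def test_degenerate_single_window_extreme_position(self):
        cds = {"g": "ATG" + "GCT" * 8 + "CCA" + "GCT" * 8 + "TAA"}
        gi = np.zeros(40, dtype=np.int64)
        cs = np.full(40, 5, dtype=np.int64)  # all footprints at one site
        fps = sim.FootprintSet(["g"], gi, cs, 27)
        res = rrt.ResidenceTimeModel(cds, fps).fit(permutations=2000, seed=0,
                                                   codons=("CCA",))
        t = res.table.set_index("position")
        assert t.loc[5, "rf"] == 1.0
        # single-window null: the permuted RF at a position equals 1 with
        # probability exactly 1/9 (ties count on both sides), so the
        # two-sided P sits at ~2/9 — the floor for one window
        assert t.loc[5, "p"] == pytest.approx(2 / 9, abs=0.06)
        assert (t.loc[[1, 2, 3, 4, 6, 7, 8, 9], "rf"] == 0).all()

    def test_fixed_seed_reproducible(self):
        model = _uniform_model(seed=5, reads=5000)
        r1 = model.fit(permutations=200, seed=11, codons=("GCT", "CCA"))
        r2 = model.fit(permutations=200, seed=11, codons=("GCT", "CCA"))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_uniform_null_p_values_not_extreme(self):
        model = _uniform_model(seed=6)
        res = model.fit(permutations=500, seed=12)
        pvals = res.table.dropna(subset=["p"])["p"]
        # under uniform footprints extreme P at the minimal band is rare
        assert (pvals <= 0.004).mean() < 0.02


class TestStallingFilter:
    def _results(self, table):
        return rrt.ResidenceTimeResults(None, table, {}, 0, 0)

    def _row(self, rrt_val, p, n):
        base = 1.0 + (1 / 9 - 1.0)  # unused filler
        return {"codon": "CCA", "position": 5, "rf": rrt_val / 9,
                "rrt": rrt_val, "n_windows": n, "p": p, "site": "P"}

    def test_effect_boundary(self):
        t = pd.DataFrame([self._row(1.19, 1e-6, 500)])
        assert len(self._results(t).significant_stalling()) == 0
        t = pd.DataFrame([self._row(1.20, 1e-6, 500)])
        assert len(self._results(t).significant_stalling()) == 1

    def test_window_count_boundary(self):
        t = pd.DataFrame([self._row(1.5, 1e-5, 299)])
        assert len(self._results(t).significant_stalling()) == 0
        t = pd.DataFrame([self._row(1.5, 1e-5, 300)])
        assert len(self._results(t).significant_stalling()) == 1

    def test_p_boundary_and_under_representation(self):
        t = pd.DataFrame([self._row(1.5, 2e-4, 400)])
        assert len(self._results(t).significant_stalling()) == 0
        # under-represented occupancy is symmetric: 1/1.25 = 0.8
        t = pd.DataFrame([self._row(0.8, 1e-5, 400)])
        out = self._results(t).significant_stalling()
        assert len(out) == 1 and out.loc[0, "direction"] == "under"


class TestDwellRecovery:
    def test_planted_multipliers_recovered_in_rank_order(self):
        dwell = {"CCA": (5, 1.8), "GGT": (5, 1.3)}
        model = _uniform_model(n_genes=20, n_codons=150, seed=7,
                               dwell=dwell, reads=80000)
        res = model.fit(permutations=300, seed=13)
        t = res.table.set_index(["codon", "position"])
        r_cca = t.loc[("CCA", 5), "rrt"]
        r_ggt = t.loc[("GGT", 5), "rrt"]
        others = res.table.query("position == 5 and codon not in ('CCA','GGT')")
        assert r_cca > r_ggt > others["rrt"].median()


class TestStrainRatio:
    def test_identical_strains_ratio_one_nothing_called(self):
        model = _uniform_model(seed=8, reads=20000)
        res = model.fit(permutations=100, seed=14, codons=("GCT", "CCA"))
        out = rrt.strain_rrt_ratio_test(res, res, permutations=100, seed=15)
        assert np.allclose(out["rrt_ratio"], 1.0)
        assert not out["significant"].any()

    def test_label_swap_inverts_ratio_with_same_p(self):
        m1 = _uniform_model(seed=9, reads=15000)
        m2 = _uniform_model(seed=10, reads=15000)
        r1 = m1.fit(permutations=50, seed=16, codons=("GCT", "CCA", "GGT"))
        r2 = m2.fit(permutations=50, seed=16, codons=("GCT", "CCA", "GGT"))
        fwd = rrt.strain_rrt_ratio_test(r1, r2, permutations=300, seed=17)
        rev = rrt.strain_rrt_ratio_test(r2, r1, permutations=300, seed=17)
        merged = fwd.merge(rev, on=["codon", "position"], suffixes=("_f", "_r"))
        assert np.allclose(merged["rrt_ratio_f"] * merged["rrt_ratio_r"], 1.0)
        assert np.allclose(merged["p_f"], merged["p_r"])
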