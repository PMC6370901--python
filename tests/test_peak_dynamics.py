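import numpy as np
import pandas as pd
import pytest

import th2screen as t2
from th2screen.io_formats import PeakSet
from th2screen.peak_dynamics import (
    jaccard_peaks,
    motif_trajectory,
    nearest_tss,
    normalize_signal,
    peak_ratio_rank,
    replicate_consistent_peaks,
    tf_network,
)
from conftest import make_peakset


def _ps(rows, **labels):
    return make_peakset(rows, **labels)


class TestReplicateConsistentPeaks:
    def test_identical_peaks_merge_to_one(self):
        r1 = _ps([("chr1", 100, 200, "a", 1.0)], replicate="r1")
        r2 = _ps([("chr1", 100, 200, "b", 3.0)], replicate="r2")
        merged = replicate_consistent_peaks([r1, r2])
        assert len(merged) == 1
        row = merged.table.iloc[0]
        assert (row["start"], row["end"]) == (100, 200)
        assert row["height"] == pytest.approx(2.0)

    def test_below_threshold_dropped(self):
        r1 = _ps([("chr1", 100, 200, "a", 1.0)], replicate="r1")
        r2 = _ps([("chr1", 190, 300, "b", 1.0)], replicate="r2")  # 10 bp overlap
        merged = replicate_consistent_peaks([r1, r2])
        assert len(merged) == 0

    def test_exactly_half_overlap_kept_and_unioned(self):
        r1 = _ps([("chr1", 100, 200, "a", 1.0)], replicate="r1")
        r2 = _ps([("chr1", 150, 250, "b", 1.0)], replicate="r2")  # 50 bp = 50% of 100
        merged = replicate_consistent_peaks([r1, r2])
        assert len(merged) == 1
        row = merged.table.iloc[0]
        assert (row["start"], row["end"]) == (100, 250)

    def test_symmetric_in_replicate_order(self, rng):
        def random_set(rep):
            starts = np.sort(rng.integers(0, 50_000, 40))
            return _ps(
                [("chr1", s, s + rng.integers(100, 400), f"{rep}_{i}", 1.0) for i, s in enumerate(starts)],
                replicate=rep,
            )

        r1, r2 = random_set("r1"), random_set("r2")
        a = replicate_consistent_peaks([r1, r2]).table[["chrom", "start", "end"]]
        b = replicate_consistent_peaks([r2, r1]).table[["chrom", "start", "end"]]
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_output_pairwise_disjoint(self, rng):
        sets = []
        for rep in ("r1", "r2"):
            starts = np.sort(rng.integers(0, 20_000, 60))
            sets.append(
                _ps(
                    [("chr1", s, s + rng.integers(50, 600), f"{rep}_{i}", 1.0) for i, s in enumerate(starts)],
                    replicate=rep,
                )
            )
        with pytest.warns(UserWarning):
            merged = replicate_consistent_peaks(sets).table.sort_values("start")
        assert (merged["start"].to_numpy()[1:] >= merged["end"].to_numpy()[:-1]).all()

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            replicate_consistent_peaks([_ps([("chr1", 0, 10, "a", 1.0)])])


class TestNormalizeSignal:
    def _heights(self, mat, ids=None):
        ids = ids or [f"p{i}" for i in range(len(mat))]
        return pd.DataFrame(mat, index=ids, columns=[f"t{j}" for j in range(len(mat[0]))])

    def test_constant_heights_all_one(self):
        h = self._heights([[4.0, 4.0, 4.0], [7.0, 7.0, 7.0]])
        bg = pd.Series(2.0, index=h.columns)
        sig = normalize_signal(h, bg)
        assert np.allclose(sig.matrix.to_numpy(), 1.0)
        assert sig.anchor == "t1"

    def test_background_linearity(self):
        h = self._heights([[4.0, 4.0, 4.0]])
        bg1 = pd.Series([1.0, 1.0, 1.0], index=h.columns)
        bg2 = pd.Series([1.0, 1.0, 2.0], index=h.columns)
        s1 = normalize_signal(h, bg1).matrix
        s2 = normalize_signal(h, bg2).matrix
        assert s2.iloc[0, 2] == pytest.approx(s1.iloc[0, 2] / 2.0)

    def test_elementwise_oracle(self, rng):
        mat = rng.uniform(1, 10, (20, 4))
        h = self._heights(mat.tolist())
        bg = pd.Series(rng.uniform(0.5, 2, 4), index=h.columns)
        sig = normalize_signal(h, bg, anchor_index=1)
        rel = mat / bg.to_numpy()[None, :]
        oracle = rel / rel[:, [1]]
        assert np.allclose(sig.matrix.to_numpy(), oracle)

    def test_zero_anchor_peak_excluded(self):
        h = self._heights([[1.0, 0.0, 2.0], [1.0, 1.0, 1.0]])
        bg = pd.Series(1.0, index=h.columns)
        with pytest.warns(UserWarning, match="anchor"):
            sig = normalize_signal(h, bg)
        assert list(sig.matrix.index) == ["p1"]

    def test_nonpositive_background_rejected(self):
        h = self._heights([[1.0, 1.0]])
        with pytest.raises(ValueError, match="background"):
            normalize_signal(h, pd.Series([1.0, 0.0], index=h.columns))


class TestMotifTrajectory:
    def test_flat_peaks_give_unit_trajectory(self):
        mat = pd.DataFrame(
            np.ones((3, 4)), index=["p0", "p1", "p2"], columns=["t0", "t1", "t2", "t3"]
        )
        hits = pd.DataFrame({"motif": ["m"] * 3, "peak_id": ["p0", "p1", "p2"]})
        traj = motif_trajectory(mat, hits)
        assert np.allclose(traj.loc["m"], 1.0)

    def test_identical_peaksets_identical_trajectories(self, rng):
        mat = pd.DataFrame(rng.uniform(0.5, 3, (5, 3)), index=[f"p{i}" for i in range(5)])
        hits = pd.DataFrame(
            {"motif": ["a"] * 5 + ["b"] * 5, "peak_id": list(mat.index) * 2}
        )
        traj = motif_trajectory(mat, hits)
        assert np.allclose(traj.loc["a"], traj.loc["b"])

    def test_union_is_size_weighted_mean(self, rng):
        mat = pd.DataFrame(rng.uniform(0.5, 3, (6, 3)), index=[f"p{i}" for i in range(6)])
        hits = pd.DataFrame(
            {
                "motif": ["a"] * 2 + ["b"] * 4 + ["u"] * 6,
                "peak_id": list(mat.index[:2]) + list(mat.index[2:]) + list(mat.index),
            }
        )
        traj = motif_trajectory(mat, hits)
        expected = (2 * traj.loc["a"] + 4 * traj.loc["b"]) / 6
        assert np.allclose(traj.loc["u"], expected)

    def test_unknown_motif_omitted_with_warning(self):
        mat = pd.DataFrame(np.ones((1, 2)), index=["p0"])
        hits = pd.DataFrame({"motif": ["m", "ghost"], "peak_id": ["p0", "nope"]})
        with pytest.warns(UserWarning, match="ghost"):
            traj = motif_trajectory(mat, hits)
        assert list(traj.index) == ["m"]


class TestPeakRatioRank:
    def _setup(self):
        ids = [f"p{i}" for i in range(5)]
        peaks = _ps([("chr1", 1000 * i, 1000 * i + 100, pid, 1.0) for i, pid in enumerate(ids)])
        tss = pd.DataFrame(
            {"gene": ["gA", "gB"], "chrom": "chr1", "tss_position": [0, 4000], "strand": "+"}
        )
        return ids, peaks, tss

    def test_sorting_top_bottom(self):
        ids, peaks, tss = self._setup()
        # choose heights so that (h72+1)/(h24+1) = 4,3,2,1,0.5
        h24 = pd.Series([1.0, 1.0, 1.0, 1.0, 3.0], index=ids)
        h72 = pd.Series([7.0, 5.0, 3.0, 1.0, 1.0], index=ids)
        top, bottom = peak_ratio_rank(h72, h24, peaks, tss, n=2)
        assert top["id"].tolist() == ["p0", "p1"]
        assert bottom["id"].tolist() == ["p4", "p3"]

    def test_tie_break_on_id(self):
        ids, peaks, tss = self._setup()
        h = pd.Series(2.0, index=ids)
        top, bottom = peak_ratio_rank(h, h, peaks, tss, n=2)
        assert top["id"].tolist() == ["p0", "p1"]
        assert bottom["id"].tolist() == ["p0", "p1"]

    def test_n_larger_than_peaks_warns(self):
        ids, peaks, tss = self._setup()
        h = pd.Series(1.0, index=ids)
        with pytest.warns(UserWarning, match="using all"):
            top, _ = peak_ratio_rank(h, h, peaks, tss, n=50)
        assert len(top) == 5

    def test_nearest_gene_brute_force(self, rng):
        n = 30
        starts = rng.integers(0, 100_000, n)
        peaks = _ps([("chr1", s, s + 200, f"p{i}", 1.0) for i, s in enumerate(starts)])
        tss = pd.DataFrame(
            {
                "gene": [f"g{j}" for j in range(10)],
                "chrom": "chr1",
                "tss_position": rng.integers(0, 100_000, 10),
                "strand": "+",
            }
        )
        res = nearest_tss(peaks, tss).set_index("id")
        for i, s in enumerate(starts):
            mid = s + 100
            dists = (tss["tss_position"] - mid).abs()
            best = tss.assign(d=dists).sort_values(["d", "gene"]).iloc[0]
            assert res.loc[f"p{i}", "gene"] == best["gene"]


class TestJaccard:
    def test_identical_sets_one(self):
        a = _ps([("chr1", 0, 100, "a", 1.0), ("chr2", 50, 80, "b", 1.0)])
        assert jaccard_peaks(a, a) == pytest.approx(1.0)

    def test_half_shifted_third(self):
        a = _ps([("chr1", 0, 100, "a", 1.0)])
        b = _ps([("chr1", 50, 150, "b", 1.0)])
        assert jaccard_peaks(a, b) == pytest.approx(1.0 / 3.0)

    def test_empty_set_zero_with_warning(self):
        a = _ps([("chr1", 0, 100, "a", 1.0)])
        empty = PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "id", "height"]))
        with pytest.warns(UserWarning):
            assert jaccard_peaks(a, empty) == 0.0

    def test_random_sets_match_per_bp_oracle(self, rng):
        for _ in range(20):
            def rand_set(tag):
                rows = []
                for i in range(rng.integers(1, 8)):
                    s = int(rng.integers(0, 500))
                    rows.append(("chr1", s, s + int(rng.integers(1, 80)), f"{tag}{i}", 1.0))
                return _ps(rows)

            a, b = rand_set("a"), rand_set("b")
            bp_a = set()
            for r in a.table.itertuples():
                bp_a.update(range(r.start, r.end))
            bp_b = set()
            for r in b.table.itertuples():
                bp_b.update(range(r.start, r.end))
            oracle = len(bp_a & bp_b) / len(bp_a | bp_b)
            assert jaccard_peaks(a, b) == pytest.approx(oracle)

    def test_symmetry(self, rng):
        a = _ps([("chr1", 0, 100, "a", 1.0), ("chr1", 300, 350, "b", 1.0)])
        b = _ps([("chr1", 80, 320, "c", 1.0)])
        assert jaccard_peaks(a, b) == pytest.approx(jaccard_peaks(b, a))


class TestTfNetwork:
    def _tss(self):
        return pd.DataFrame(
            {
                "gene": ["gA", "gB"],
                "chrom": "chr1",
                "tss_position": [10_000, 100_000],
                "strand": "+",
            }
        )

    def test_peak_at_tss_gives_edge(self):
        chip = {"TF1": _ps([("chr1", 9_950, 10_050, "p", 1.0)])}
        edges, mat = tf_network(chip, self._tss())
        assert edges.values.tolist() == [["TF1", "gA"]]
        assert mat.loc["TF1", "gA"] == 1

    def test_exactly_20kb_excluded(self):
        # midpoint at 30_000 -> distance to gA TSS exactly 20_000
        chip = {"TF1": _ps([("chr1", 29_950, 30_050, "p", 1.0)])}
        edges, _ = tf_network(chip, self._tss(), max_dist=20_000)
        assert edges.empty
        chip2 = {"TF1": _ps([("chr1", 29_949, 30_049, "p", 1.0)])}
        edges2, _ = tf_network(chip2, self._tss(), max_dist=20_000)
        assert len(edges2) == 1

    def test_random_instance_brute_force(self, rng):
        tss = pd.DataFrame(
            {
                "gene": [f"g{j}" for j in range(6)],
                "chrom": "chr1",
                "tss_position": rng.integers(0, 200_000, 6),
                "strand": "+",
            }
        )
        chip = {}
        for tf in ("A", "B"):
            starts = rng.integers(0, 200_000, 15)
            chip[tf] = _ps([("chr1", s, s + 100, f"{tf}{i}", 1.0) for i, s in enumerate(starts)])
        edges, _ = tf_network(chip, tss, max_dist=20_000)
        expected = set()
        for tf, ps in chip.items():
            for r in ps.table.itertuples():
                mid = (r.start + r.end) // 2
                d = (tss["tss_position"] - mid).abs()
                best = tss.assign(d=d).sort_values(["d", "gene"]).iloc[0]
                if best["d"] < 20_000:
                    expected.add((tf, best["gene"]))
        assert set(map(tuple, edges.values)) == expected
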