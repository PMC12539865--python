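import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromascreen import screening
from chromascreen.compartments import Segment, TransitionTrack
from chromascreen.coexpression import ExpressionMatrix
from chromascreen.io_formats import BinTable, Gene


def _expr(counts, groups):
    counts = np.asarray(counts, dtype=float)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    meta = pd.DataFrame(
        {"sample": samples, "group": groups, "stage": "S1"}
    ).set_index("sample", drop=False)
    return ExpressionMatrix(
        [f"g{i}" for i in range(counts.shape[0])], samples, counts, meta
    )


class TestCallDegs:
    def test_identical_groups_all_ns(self, rng):
        base = rng.poisson(100, size=(20, 4)).astype(float)
        counts = np.hstack([base, base])
        expr = _expr(counts, ["a"] * 4 + ["b"] * 4)
        out = screening.call_degs(expr, "a", "b")
        assert (out["direction"] == "ns").all()
        assert np.abs(out["log2fc"]).max() < 0.01

    def test_planted_fourfold_gene_called_up(self, rng):
        n = 10
        counts = np.tile(rng.uniform(80, 120, size=(50, 1)), (1, 2 * n))
        counts += rng.normal(scale=2.0, size=counts.shape)
        counts[0, :n] *= 4  # 4x CPM in group a, low variance, large n
        expr = _expr(np.clip(counts, 1, None), ["a"] * n + ["b"] * n)
        row = screening.call_degs(expr, "a", "b").iloc[0]
        assert row["direction"] == "up"
        assert row["log2fc"] == pytest.approx(2.0, abs=0.3)

    def test_bh_adjusted_p_nondecreasing_in_rank(self, rng):
        counts = rng.poisson(50, size=(40, 8)).astype(float) + 1
        expr = _expr(counts, ["a"] * 4 + ["b"] * 4)
        out = screening.call_degs(expr, "a", "b").sort_values("p")
        assert (np.diff(out["padj"].to_numpy()) >= -1e-12).all()
        assert (out["padj"] >= out["p"] - 1e-12).all()

    def test_single_sample_group_rejected(self, rng):
        expr = _expr(rng.poisson(50, (5, 3)).astype(float) + 1, ["a", "b", "b"])
        with pytest.raises(Exception):
            screening.call_degs(expr, "a", "b")


def _tt(segments, n_bins=100, resolution=100_000, chrom="chr2"):
    bt = BinTable(chrom, resolution, n_bins * resolution)
    segs = [
        Segment(lab, s, e, s * resolution, e * resolution)
        for lab, s, e in segments
    ]
    joint = np.full(n_bins, "A2A", dtype=object)
    for lab, s, e in segments:
        joint[s:e] = lab
    return TransitionTrack(bt, joint, segs)


class TestTransitionWindows:
    def test_no_switching_segments_empty(self):
        tt = _tt([("A2A", 0, 100)])
        genes = [Gene("g1", "chr2", 0, 1000)]
        assert screening.window_genes_around_transitions(tt, genes) == {}

    def test_half_open_window_boundary(self):
        tt = _tt([("B2A", 50, 52)])
        win_end = 52 * 100_000 + 3_000_000
        at_end = Gene("gx", "chr2", win_end, win_end + 500)
        just_in = Gene("gy", "chr2", win_end - 1, win_end + 500)
        out = screening.window_genes_around_transitions(tt, [at_end, just_in])
        assert "gx" not in out and "gy" in out

    def test_matches_brute_force_overlap(self):
        tt = _tt([("A2B", 40, 45)])
        res, w = 100_000, 3_000_000
        genes = [
            Gene("g1", "chr2", 0, 5_000),               # far upstream
            Gene("g2", "chr2", 1_500_000, 1_501_000),   # inside window
            Gene("g3", "chr2", 4_200_000, 4_201_000),   # inside segment
            Gene("g4", "chr2", 7_400_000, 7_401_000),   # inside window
            Gene("g5", "chr2", 9_900_000, 9_901_000),   # beyond window
        ]
        out = screening.window_genes_around_transitions(tt, genes, window_bp=w)
        win = (40 * res - w, 45 * res + w)
        expect = {
            g.gene_id for g in genes if g.start < win[1] and g.end > win[0]
        }
        assert set(out) == expect
        assert out["g3"][1] == 0  # inside the segment itself
        assert out["g2"][1] == 40 * res - 1_501_000 + 1

    def test_monotone_in_window_size(self, rng):
        tt = _tt([("B2A", 30, 33), ("A2B", 70, 72)])
        genes = [
            Gene(f"g{i}", "chr2", int(p), int(p) + 800)
            for i, p in enumerate(rng.integers(0, 9_900_000, size=60))
        ]
        sizes = [
            len(screening.window_genes_around_transitions(tt, genes, window_bp=w))
            for w in (100_000, 1_000_000, 3_000_000)
        ]
        assert sizes == sorted(sizes)


class TestFourWayVenn:
    def test_disjoint_sets_only_singleton_regions(self):
        v = screening.four_way_venn({"a"}, {"b"}, {"c"}, {"d"})
        assert v.region("known") == {"a"}
        assert v.region("up") == {"b"}
        assert v.region("down") == {"c"}
        assert v.region("windowed") == {"d"}
        sizes = v.region_sizes().set_index("region")["size"]
        assert sizes.sum() == 4

    def test_identical_sets_fill_full_intersection(self):
        s = {"a", "b"}
        v = screening.four_way_venn(s, s, s, s)
        assert v.region("known", "up", "down", "windowed") == s
        assert sum(len(m) for m in v.regions.values()) == 2

    @given(st.integers(0, 2**32 - 1))
    def test_matches_bitmask_tally(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(50)]
        sets = [set(np.array(ids)[rng.random(50) < 0.4]) for _ in range(4)]
        v = screening.four_way_venn(*sets)
        tally: dict[tuple, int] = {}
        for gid in set().union(*sets):
            sig = tuple(gid in s for s in sets)
            tally[sig] = tally.get(sig, 0) + 1
        for sig, members in v.regions.items():
            assert len(members) == tally.get(sig, 0)

    @given(st.integers(0, 2**32 - 1))
    def test_regions_partition_the_union(self, seed):
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(40)]
        sets = [set(np.array(ids)[rng.random(40) < 0.5]) for _ in range(4)]
        v = screening.four_way_venn(*sets)
        union = set().union(*sets)
        regions = list(v.regions.values())
        assert set().union(*regions) == union if union else True
        assert sum(len(r) for r in regions) == len(union)


class TestRankCandidates:
    def _venn(self):
        return screening.four_way_venn(
            known={"cand", "known_only"},
            up={"upgene"},
            down={"cand", "downgene"},
            windowed={"cand", "win_ns"},
        )

    def test_all_evidence_gene_is_unique_candidate(self):
        report = screening.rank_candidates(self._venn(), hubs={1: ["cand"]})
        assert report.candidates == ["cand"]
        assert report.table.iloc[0]["gene_id"] == "cand"

    def test_windowed_but_ns_gene_annotated_not_candidate(self):
        report = screening.rank_candidates(self._venn(), hubs={})
        tab = report.table.set_index("gene_id")
        assert "win_ns" in tab.index
        assert not tab.loc["win_ns", "is_candidate"]

    def test_evidence_ties_break_lexicographically(self):
        venn = screening.four_way_venn(set(), {"b", "a"}, set(), {"a", "b"})
        report = screening.rank_candidates(venn, hubs={}, require_known=False)
        assert report.candidates == ["a", "b"]

    def test_empty_candidate_set_warns(self):
        venn = screening.four_way_venn({"x"}, set(), set(), set())
        with pytest.warns(UserWarning):
            report = screening.rank_candidates(venn, hubs={})
        assert report.candidates == []
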