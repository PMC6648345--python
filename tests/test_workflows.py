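"""Horizontal scanning, vertical comparison, baseline score, clustering."""

import numpy as np
import pandas as pd
import pytest

from epialign import (
    GenomicRegion,
    ScoreParams,
    SegmentationTrack,
    SimulationConfig,
    epigenome_cluster,
    group_compare,
    group_compare_regions,
    horizontal_scan,
    naive_horizontal_scan,
    naive_score,
    region_similarity,
    simulate_track,
    tile_genome,
    top_regions,
    vertical_align,
)

from conftest import random_compressed, seq_from_letters


@pytest.fixture(scope="module")
def iid_cfg():
    return dict(
        Q=15,
        stationary=tuple([1 / 15] * 15),
        dwell_mean_bins=tuple([3.0] * 15),
        tile_size=50_000,
    )


class TestHorizontalScan:
    def test_duplicated_chromosome_mutual_best_hits(self, alpha15):
        rng = np.random.default_rng(0)
        states = rng.integers(1, 16, size=200)
        rows = [[i * 200, (i + 1) * 200, int(s)] for i, s in enumerate(states)]
        # two identical 40 kb "chromosomes" -> one tile each, identical content
        track = SegmentationTrack(
            {"chr1": np.array(rows), "chr2": np.array(rows)}, alpha15
        )
        res = horizontal_scan(track, bin_size=40_000, B=10, rng=1)
        tab = res.table.set_index("name")
        assert tab.loc["chr1:0-40000", "best_name"] == "chr2:0-40000"
        assert tab.loc["chr2:0-40000", "best_name"] == "chr1:0-40000"
        # best hit of an identical region is the self-alignment score 2*n
        n = len(np.unique(np.r_[0, np.flatnonzero(np.diff(states)) + 1]))
        assert tab["raw_score"].iloc[0] == pytest.approx(2 * n)

    def test_iid_track_scores_center_near_zero(self, iid_cfg):
        """No recurrent structure -> horizontal scores near 0 on average."""
        cfg = SimulationConfig(chrom_lengths={"chr1": 2_500_000}, seed=11, **iid_cfg)
        track = simulate_track(cfg)
        res = horizontal_scan(track, bin_size=50_000, B=50, rng=5)
        assert len(res.table) >= 50
        assert abs(res.table["horizontal_score"].mean()) < 0.3

    def test_deterministic_given_seed(self, iid_cfg):
        cfg = SimulationConfig(chrom_lengths={"chr1": 500_000}, seed=3, **iid_cfg)
        track = simulate_track(cfg)
        a = horizontal_scan(track, bin_size=50_000, B=10, rng=7).table
        b = horizontal_scan(track, bin_size=50_000, B=10, rng=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_single_region_rejected(self, alpha15):
        track = SegmentationTrack({"chr1": np.array([[0, 500_000, 1]])}, alpha15)
        with pytest.raises(ValueError, match="2 non-empty"):
            horizontal_scan(track, B=5)

    def test_planted_pair_takes_top_two(self):
        """One motif in exactly two tiles: mutual best hits with top scores."""
        from epialign import MotifSpec

        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(
                chrom_lengths={"chr1": 5_000_000},
                seed=seed,
                motifs=(MotifSpec("egegegegeg", tiles=(2, 7), copies=3),),
            )
            track = simulate_track(cfg)
            names = [t.display_name for t in tile_genome(track)]
            res = horizontal_scan(track, ScoreParams(mode="max"), B=50, rng=seed + 500)
            tab = res.table
            mutual = (
                tab.loc[2, "best_name"] == names[7]
                and tab.loc[7, "best_name"] == names[2]
            )
            top2 = set(top_regions(res, 2)["name"]) == {names[2], names[7]}
            wins += mutual and top2
        assert wins >= 9


class TestTopRegions:
    def _result(self, scores):
        rows = [
            {
                "chrom": "chr1",
                "start": i,
                "end": i + 1,
                "name": f"r{i}",
                "best_name": "x",
                "raw_score": 0.0,
                "horizontal_score": s,
                "provenance": "",
            }
            for i, s in enumerate(scores)
        ]
        from epialign.workflows import HorizontalScanResult

        return HorizontalScanResult(pd.DataFrame(rows), [])

    def test_top_one_is_argmax(self):
        res = self._result([1.0, 5.0, 3.0])
        assert top_regions(res, 1)["name"].tolist() == ["r1"]

    def test_full_k_is_sort_by_score(self):
        res = self._result([1.0, 5.0, 3.0])
        assert top_regions(res, 3)["name"].tolist() == ["r1", "r2", "r0"]

    def test_ties_broken_by_genome_order(self):
        res = self._result([2.0, 2.0, 1.0])
        assert top_regions(res, 2)["name"].tolist() == ["r0", "r1"]

    def test_overlong_k_warns_and_returns_all(self):
        res = self._result([1.0, 2.0])
        with pytest.warns(UserWarning, match="returning all"):
            assert len(top_regions(res, 10)) == 2


class TestVerticalAlign:
    def test_same_track_twice_gives_self_scores(self, iid_cfg):
        cfg = SimulationConfig(chrom_lengths={"chr1": 200_000}, seed=5, **iid_cfg)
        track = simulate_track(cfg)
        regions = tile_genome(track, bin_size=50_000)
        out = vertical_align([track, track], regions)
        from epialign import align_score, extract_region

        for _, row in out.iterrows():
            region = next(r for r in regions if r.display_name == row["region"])
            seq = extract_region(track, region)
            assert row["score"] == pytest.approx(align_score(seq, seq))

    def test_region_empty_in_one_track_is_nan(self, alpha15):
        t1 = SegmentationTrack({"chr1": np.array([[0, 100_000, 1]])}, alpha15)
        t2 = SegmentationTrack(
            {"chr1": np.array([[50_000, 100_000, 2]])}, alpha15
        )
        region = GenomicRegion("chr1", 0, 40_000, name="g")
        out = vertical_align([t1, t2], [region])
        assert np.isnan(out["score"].iloc[0])

    def test_disjoint_tracks_rejected(self, alpha15):
        t1 = SegmentationTrack({"chr1": np.array([[0, 1000, 1]])}, alpha15)
        t2 = SegmentationTrack({"chr2": np.array([[0, 1000, 1]])}, alpha15)
        with pytest.raises(ValueError, match="chromosome"):
            vertical_align([t1, t2], [])


class TestGroupCompare:
    def test_exact_p_for_separated_triplets(self):
        res = group_compare([5, 6, 7], [1, 2, 3])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.05)  # 1 / C(6,3)

    def test_identical_lists_no_evidence(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value >= 0.5

    def test_complete_separation_n10(self):
        res = group_compare(list(range(11, 21)), list(range(1, 11)))
        assert res.p_value < 0.001

    def test_exact_branch_matches_enumeration(self):
        """Exact p equals the tail proportion over all rank assignments."""
        from itertools import combinations
        from scipy.stats import rankdata

        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=3)
            res = group_compare(x, y)
            pooled = np.concatenate([x, y])
            ranks = rankdata(pooled)
            u_obs = ranks[:4].sum() - 4 * 5 / 2
            count = total = 0
            for idx in combinations(range(7), 4):
                u = ranks[list(idx)].sum() - 4 * 5 / 2
                count += u >= u_obs
                total += 1
            assert res.p_value == pytest.approx(count / total)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            group_compare([], [1.0])

    def test_region_ranking_prefers_group_specific_motif(self):
        from epialign import simulate_cohort

        cfg = SimulationConfig(chrom_lengths={"chr1": 2_000_000}, seed=0)
        cohort = simulate_cohort(
            3,
            ["brain", "heart"],
            {"brain": "egegegegeg", "heart": "ihihihihih"},
            cfg,
            motif_tiles=(1,),
            copies=2,
        )
        tracks = [t for t, _ in cohort]
        names = [f"{lab}{i}" for i, (_, lab) in enumerate(cohort)]
        groups = dict(zip(names, [lab for _, lab in cohort]))
        regions = tile_genome(tracks[0])
        ranked = group_compare_regions(
            vertical_align(tracks, regions, track_names=names), groups
        )
        assert ranked.iloc[0]["region"] == regions[1].display_name


class TestNaiveScore:
    def test_identical_sequences_score_zero(self, alpha4):
        s = seq_from_letters("abab", alpha4)
        assert naive_score(s, s, alpha4) == 0.0

    def test_disjoint_supports(self, alpha4):
        s1 = seq_from_letters("ab", alpha4)
        s2 = seq_from_letters("cd", alpha4)
        assert naive_score(s1, s2, alpha4) == pytest.approx(-1.0)

    def test_bounded_symmetric(self, alpha15):
        rng = np.random.default_rng(13)
        for _ in range(20):
            s1 = random_compressed(rng, int(rng.integers(1, 30)), 15)
            s2 = random_compressed(rng, int(rng.integers(1, 30)), 15)
            v = naive_score(s1, s2, alpha15)
            assert -2.0 <= v <= 0.0
            assert v == pytest.approx(naive_score(s2, s1, alpha15))

    def test_empty_rejected(self, alpha4):
        from epialign.state_model import CompressedSequence

        empty = CompressedSequence(np.empty(0, dtype=int), np.empty(0, dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            naive_score(seq_from_letters("a", alpha4), empty, alpha4)

    def test_baseline_scan_ranks_by_proportion_similarity(self, iid_cfg):
        cfg = SimulationConfig(chrom_lengths={"chr1": 500_000}, seed=9, **iid_cfg)
        track = simulate_track(cfg)
        res = naive_horizontal_scan(track, bin_size=50_000)
        assert (res.table["raw_score"] <= 0).all()


class TestRegionSimilarity:
    def test_matrix_invariants(self):
        rng = np.random.default_rng(14)
        seqs = [random_compressed(rng, 25, 5) for _ in range(6)]
        a, labels, z = region_similarity(seqs, n_clusters=2)
        assert np.allclose(np.diag(a), 1.0)
        off = a[~np.eye(6, dtype=bool)]
        assert np.all(off > 0) and np.all(off < 1)
        assert np.allclose(a, a.T)
        # the maximizing pair is forced to 1/alpha
        assert off.max() == pytest.approx(1 / 1.1, abs=1e-12)
        assert len(labels) == 6 and set(labels) == {1, 2}

    def test_planted_groups_cluster_together(self, alpha15):
        rng = np.random.default_rng(15)
        motif_a = seq_from_letters("egegegeg", alpha15)
        motif_b = seq_from_letters("ihihihih", alpha15)
        seqs = []
        for motif in (motif_a, motif_b, motif_a, motif_b):
            bg = random_compressed(rng, 30, 15)
            states = np.concatenate([bg.states, motif.states])
            # drop a possible adjacent repeat at the junction
            if states[29] == states[30]:
                states = np.delete(states, 29)
            from epialign.state_model import CompressedSequence

            seqs.append(
                CompressedSequence(states, np.ones(states.size, dtype=int))
            )
        _, labels, _ = region_similarity(seqs, ScoreParams(mode="max"), n_clusters=2)
        assert labels[0] == labels[2] and labels[1] == labels[3]
        assert labels[0] != labels[1]

    def test_degenerate_all_zero_rejected(self, alpha4):
        s1 = seq_from_letters("a", alpha4)
        s2 = seq_from_letters("b", alpha4)
        s3 = seq_from_letters("c", alpha4)
        with pytest.raises(ValueError, match="degenerate"):
            region_similarity([s1, s2, s3])


class TestEpigenomeCluster:
    def test_identical_vectors_merge_first(self):
        rng = np.random.default_rng(16)
        v = rng.normal(size=20)
        df = pd.DataFrame(
            [v, v, rng.normal(size=20)], index=["e1", "e2", "e3"]
        )
        corr, z, order = epigenome_cluster(df)
        assert corr.loc["e1", "e2"] == pytest.approx(1.0)
        # first merge joins the identical pair at height ~0
        assert sorted(z[0, :2].astype(int)) == [0, 1]
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pair_distance_two(self):
        v = np.linspace(-1, 1, 10)
        df = pd.DataFrame([v, -v, v + np.random.default_rng(0).normal(0, 0.1, 10)],
                          index=list("abc"))
        corr, z, _ = epigenome_cluster(df)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)
        assert z[-1, 2] > 1.0  # the anticorrelated merge comes last and high

    def test_zero_variance_vector_named(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"]
        )
        with pytest.raises(ValueError, match="flat"):
            epigenome_cluster(df)

    def test_shared_motif_layout_forms_clade(self):
        """Epigenomes with the same planted layout cluster together."""
        from epialign import MotifSpec

        ok = 0
        for seed in range(5):
            rows = []
            for kind_seed, tiles in [(0, (1, 3)), (1, (1, 3)), (2, (0, 2))]:
                cfg = SimulationConfig(
                    chrom_lengths={"chr1": 2_000_000},
                    seed=seed * 10 + kind_seed,
                    motifs=(MotifSpec("egegegegeg", tiles=tiles, copies=3),),
                )
                track = simulate_track(cfg)
                res = horizontal_scan(
                    track, ScoreParams(mode="max"), B=30, rng=seed * 10 + kind_seed
                )
                rows.append(res.table.set_index("name")["horizontal_score"])
            df = pd.DataFrame(rows, index=["same1", "same2", "other"])
            _, z, order = epigenome_cluster(df)
            first_merge = sorted(z[0, :2].astype(int))
            ok += first_merge == [0, 1]
        assert ok >= 4
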