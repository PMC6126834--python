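"""Total LD scores, random pruning replicates and LD windows."""

import numpy as np
import pandas as pd
import pytest

from stratenrich import ld_ops


def _pairs(rows):
    return pd.DataFrame(rows, columns=["id_a", "pos_a", "id_b", "pos_b", "r2"])


def _variants(ids, positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": positions,
            "maf": 0.2,
            "is_genic": True,
            "tss_distance": 1000.0,
            "total_ld": np.nan,
        }
    )


class TestTotalLd:
    def test_isolated_variant_scores_one(self):
        v = _variants(["a"], [100])
        score = ld_ops.total_ld_score(v, _pairs([]))
        assert score["a"] == 1.0

    def test_hand_sum(self):
        v = _variants(["a", "b", "c"], [100, 200, 300])
        pairs = _pairs([("a", 100, "b", 200, 0.3), ("a", 100, "c", 300, 0.2)])
        score = ld_ops.total_ld_score(v, pairs)
        assert score["a"] == pytest.approx(1.5)
        assert score["b"] == pytest.approx(1.3)

    def test_partner_outside_window_excluded(self):
        v = _variants(["a", "b"], [100, 2_000_000])
        pairs = _pairs([("a", 100, "b", 2_000_000, 0.9)])
        score = ld_ops.total_ld_score(v, pairs, window_bp=1_000_000)
        assert score["a"] == 1.0

    def test_brute_force_oracle(self, tiny_world):
        variants, ld_pairs, _ = tiny_world
        sub = variants.head(200)
        score = ld_ops.total_ld_score(sub, ld_pairs, window_bp=1_000_000)
        pos = sub.set_index("variant_id")[["chrom", "pos"]]
        for vid in sub["variant_id"].sample(20, random_state=0):
            acc = 1.0
            for ia, pa, ib, pb, r2 in ld_pairs[["id_a", "pos_a", "id_b", "pos_b", "r2"]].itertuples(index=False):
                other = ib if ia == vid else ia if ib == vid else None
                if other is None or other not in pos.index:
                    continue
                if pos.loc[other, "chrom"] == pos.loc[vid, "chrom"] and abs(
                    int(pos.loc[other, "pos"]) - int(pos.loc[vid, "pos"])
                ) <= 1_000_000:
                    acc += r2
            assert score[vid] == pytest.approx(acc, rel=1e-10)


class TestRandomPrune:
    def test_single_variant_in_all_sets(self):
        v = _variants(["a"], [100])
        reps = ld_ops.random_prune(v, _pairs([]), n_sets=10, seed=0)
        assert all(s == {"a"} for s in reps.sets)

    def test_conflicting_pair_keeps_exactly_one_each_side_half_the_time(self):
        v = _variants(["a", "b"], [100, 10_100])
        pairs = _pairs([("a", 100, "b", 10_100, 0.5)])
        picks = {"a": 0, "b": 0}
        for seed in range(200):
            reps = ld_ops.random_prune(v, pairs, n_sets=1, seed=seed)
            (only,) = reps.sets
            assert len(only) == 1  # brute force over both orderings: one survives
            picks[next(iter(only))] += 1
        assert 60 <= picks["a"] <= 140  # each ordering roughly half the time

    def test_pair_outside_window_both_retained(self):
        v = _variants(["a", "b"], [100, 2_000_100])
        pairs = _pairs([("a", 100, "b", 2_000_100, 0.9)])
        reps = ld_ops.random_prune(v, pairs, n_sets=3, seed=1)
        assert all(s == {"a", "b"} for s in reps.sets)

    def test_soundness_exhaustive_scan(self, tiny_world):
        """No retained pair violates r2 >= 0.2 within 1 Mb, in any replicate."""
        variants, ld_pairs, _ = tiny_world
        reps = ld_ops.random_prune(variants, ld_pairs, n_sets=10, seed=4)
        pos = variants.set_index("variant_id")[["chrom", "pos"]]
        conflicts = ld_pairs[ld_pairs["r2"] >= 0.2]
        for rep in reps.sets:
            for ia, ib, r2 in conflicts[["id_a", "id_b", "r2"]].itertuples(index=False):
                if ia in rep and ib in rep:
                    same = pos.loc[ia, "chrom"] == pos.loc[ib, "chrom"]
                    dist = abs(int(pos.loc[ia, "pos"]) - int(pos.loc[ib, "pos"]))
                    assert not (same and dist <= 1_000_000), (ia, ib, r2)

    def test_maximality(self, tiny_world):
        """Every excluded variant conflicts with some retained variant."""
        variants, ld_pairs, _ = tiny_world
        reps = ld_ops.random_prune(variants, ld_pairs, n_sets=2, seed=9)
        _, neighbors = ld_ops.build_conflict_graph(variants, ld_pairs)
        ids = variants["variant_id"].to_numpy()
        index = {v: i for i, v in enumerate(ids)}
        for rep in reps.sets:
            kept = np.zeros(len(ids), dtype=bool)
            kept[[index[v] for v in rep]] = True
            for i in range(len(ids)):
                if not kept[i]:
                    assert kept[neighbors[i]].any(), ids[i]

    def test_reproducibility_and_seed_sensitivity(self, tiny_world):
        variants, ld_pairs, _ = tiny_world
        a = ld_ops.random_prune(variants, ld_pairs, n_sets=3, seed=7)
        b = ld_ops.random_prune(variants, ld_pairs, n_sets=3, seed=7)
        c = ld_ops.random_prune(variants, ld_pairs, n_sets=3, seed=8)
        assert a.sets == b.sets and a.seeds == b.seeds
        assert a.sets != c.sets

    def test_zero_ld_universe_returns_everything(self):
        v = _variants([f"v{i}" for i in range(50)], np.arange(50) * 1000 + 1)
        reps = ld_ops.random_prune(v, _pairs([]), n_sets=5, seed=0)
        assert all(s == set(v["variant_id"]) for s in reps.sets)

    def test_n_sets_validation(self):
        with pytest.raises(ValueError):
            ld_ops.random_prune(_variants(["a"], [1]), _pairs([]), n_sets=0)

    def test_disjoint_flag(self, tiny_world):
        variants, ld_pairs, _ = tiny_world
        reps = ld_ops.random_prune(variants, ld_pairs, n_sets=3, seed=2, disjoint=True)
        assert not (reps.sets[0] & reps.sets[1])
        assert not (reps.sets[0] & reps.sets[2]) and not (reps.sets[1] & reps.sets[2])

    def test_save_load_round_trip(self, tiny_world, tmp_path):
        variants, ld_pairs, _ = tiny_world
        reps = ld_ops.random_prune(variants, ld_pairs, n_sets=3, seed=5)
        ld_ops.save_replicates(reps, tmp_path / "reps")
        back = ld_ops.load_replicates(tmp_path / "reps")
        assert back.sets == reps.sets and back.seeds == reps.seeds


class TestLdWindow:
    def test_lead_without_partners(self):
        v = _variants(["a", "b"], [100, 500])
        win = ld_ops.ld_window("a", v, _pairs([]))
        assert win.members == {"a"} and win.start == win.end == 100

    def test_threshold_is_inclusive(self):
        v = _variants(["lead", "x", "y"], [100, 200, 300])
        pairs = _pairs([("lead", 100, "x", 200, 0.85), ("lead", 100, "y", 300, 0.79)])
        win = ld_ops.ld_window("lead", v, pairs, r2_min=0.8)
        assert win.members == {"lead", "x"}

    def test_interval_spans_qualifying_members(self):
        ids = ["lead", "p1", "p2", "p3", "p4", "p5"]
        v = _variants(ids, [5000, 1000, 2000, 7000, 9000, 20_000])
        pairs = _pairs(
            [
                ("lead", 5000, "p1", 1000, 0.9),
                ("lead", 5000, "p2", 2000, 0.95),
                ("lead", 5000, "p3", 7000, 0.81),
                ("lead", 5000, "p4", 9000, 0.5),
                ("lead", 5000, "p5", 20_000, 0.99),
            ]
        )
        win = ld_ops.ld_window("lead", v, pairs, r2_min=0.8)
        assert win.members == {"lead", "p1", "p2", "p3", "p5"}
        assert (win.start, win.end) == (1000, 20_000)

    def test_absent_lead_errors(self):
        with pytest.raises(ValueError, match="not in variant table"):
            ld_ops.ld_window("nope", _variants(["a"], [1]), _pairs([]))
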