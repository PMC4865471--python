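"""Swap proposals, acceptance rule, incremental state, end-to-end contracts."""
import numpy as np
import pytest

from landgen import (
    LandscapeRaster,
    ObjectiveList,
    TargetSpec,
    OptimizerConfig,
    adjacency_tally,
    batch_generate,
    incremental_update,
    label_patches,
    optimize,
    percolation_map,
    propose_swap,
    synth_landscape,
)
from landgen.optimizer import NoLegalPairError, acceptance_rule

from .conftest import random_raster


def _simple_objectives(**kw):
    return ObjectiveList(
        targets=[
            TargetSpec("PLAND", 1, value=kw.get("pland1", 25.0), tolerance=0.5),
            TargetSpec("NP", 1, value=kw.get("np1", 1.0)),
        ],
        grid=kw.get("grid"),
    )


class TestProposeSwap:
    def test_single_legal_pair_always_returned(self):
        codes = np.array([[1, 1], [1, 2]], dtype=np.int32)
        fixed = np.array([[True, False], [True, False]])
        r = LandscapeRaster(codes, fixed=fixed)
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = propose_swap(r, rng)
            assert {a, b} == {(0, 1), (1, 1)}

    def test_uniform_raster_has_no_legal_pair(self):
        with pytest.raises(NoLegalPairError):
            propose_swap(synth_landscape("uniform", 3, 3), np.random.default_rng(0))

    def test_pair_frequencies_uniform(self):
        # 1x3 raster [1, 2, 2]: legal ordered pairs are (0,1),(0,2),(1,0),(2,0)
        r = LandscapeRaster(np.array([[1, 2, 2]], dtype=np.int32))
        rng = np.random.default_rng(42)
        n = 10_000
        counts = {}
        for _ in range(n):
            a, b = propose_swap(r, rng)
            counts[(a[1], b[1])] = counts.get((a[1], b[1]), 0) + 1
        assert set(counts) == {(0, 1), (0, 2), (1, 0), (2, 0)}
        p = 1 / 4
        sigma = (n * p * (1 - p)) ** 0.5
        for k, v in counts.items():
            assert abs(v - n * p) < 3.5 * sigma, (k, v)

    def test_never_returns_fixed_cells(self):
        codes = np.array([[1, 2], [2, 1]], dtype=np.int32)
        fixed = np.array([[True, False], [False, False]])
        r = LandscapeRaster(codes, fixed=fixed)
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = propose_swap(r, rng)
            assert (0, 0) not in (a, b)


class TestAcceptanceRule:
    def _objs(self):
        return ObjectiveList(
            targets=[
                TargetSpec("NP", 1, value=5.0),
                TargetSpec("NP", 2, value=3.0),
                TargetSpec("TE", 1, value=100.0, bound="max"),
            ]
        )

    def test_strict_improvement_accepted(self):
        accept, focus = acceptance_rule(self._objs(), [0.0, 0.0, 5.0], [0.0, 0.0, 3.0], 2)
        assert accept and focus == 2

    def test_breaking_earlier_objective_rejected(self):
        accept, _ = acceptance_rule(self._objs(), [0.0, 0.0, 5.0], [1.0, 0.0, 3.0], 2)
        assert not accept

    def test_equal_deviation_rejected(self):
        accept, _ = acceptance_rule(self._objs(), [0.0, 0.0, 5.0], [0.0, 0.0, 5.0], 2)
        assert not accept

    def test_focus_retreats_to_first_unsatisfied(self):
        accept, focus = acceptance_rule(
            self._objs(), [0.0, 2.0, 5.0], [0.0, 1.0, 5.0], 1
        )
        assert accept and focus == 1
        accept, focus = acceptance_rule(
            self._objs(), [0.0, 1.0, 5.0], [0.0, 0.0, 5.0], 1
        )
        assert accept and focus == 2


class TestIncrementalUpdate:
    def _check(self, raster, a, b):
        lab = label_patches(raster)
        tally = adjacency_tally(raster)
        post, new_lab, new_tally = incremental_update(raster, lab, tally, a, b)
        want_lab = label_patches(post)
        want_tally = adjacency_tally(post)
        assert np.array_equal(new_lab.labels, want_lab.labels)
        assert new_lab.patches == want_lab.patches
        assert new_tally == want_tally
        return post

    def test_patch_split_handled(self):
        # removing the middle of a 3-cell line splits it in two
        codes = np.full((3, 3), 2, dtype=np.int32)
        codes[1, :] = 1
        self._check(LandscapeRaster(codes), (1, 1), (0, 0))

    def test_patch_merge_handled(self):
        # dropping a class-1 cell between two class-1 lines merges them
        codes = np.full((3, 3), 2, dtype=np.int32)
        codes[0, :] = 1
        codes[2, :] = 1
        self._check(LandscapeRaster(codes), (0, 0), (1, 1))

    @pytest.mark.parametrize("seed", range(40))
    def test_random_swap_sequences_match_full_recompute(self, seed):
        gen = np.random.default_rng(seed)
        raster = random_raster(seed + 7000, max_size=8)
        for _ in range(5):
            try:
                a, b = propose_swap(raster, gen)
            except NoLegalPairError:
                return
            raster = self._check(raster, a, b)


class TestOptimize:
    def test_already_satisfied_returns_success_without_swaps(self):
        r = synth_landscape("square_block", 8, 8, block=4)
        obj = _simple_objectives(pland1=25.0, np1=1.0)
        res = optimize(r, obj, OptimizerConfig(seed=0))
        assert res.success and res.acceptances == 0

    def test_conflicting_pland_is_infeasible(self):
        r = percolation_map(10, 10, {1: 0.35, 2: 0.65}, seed=0)
        obj = ObjectiveList(targets=[TargetSpec("PLAND", 1, value=40.0)])
        res = optimize(r, obj, OptimizerConfig(seed=0))
        assert res.status == "infeasible"
        assert "composition" in res.message

    def test_grid_mismatch_rejected(self):
        r = percolation_map(5, 5, {1: 0.4, 2: 0.6}, seed=0)
        obj = _simple_objectives(grid=(10, 10), pland1=40.0)
        with pytest.raises(ValueError, match="grid"):
            optimize(r, obj, OptimizerConfig(seed=0))

    def test_merge_to_single_patch_on_8x8(self):
        obj = ObjectiveList(
            targets=[
                TargetSpec("PLAND", 1, value=25.0),
                TargetSpec("NP", 1, value=1.0),
            ]
        )
        r = percolation_map(8, 8, {1: 0.25, 2: 0.75}, seed=5)
        res = optimize(r, obj, OptimizerConfig(seed=5, max_proposals=50_000))
        assert res.success
        assert label_patches(res.raster).n_patches(1) == 1
        assert res.raster.class_counts() == r.class_counts()

    def test_composition_and_fixed_cells_preserved(self):
        codes = percolation_map(12, 12, {1: 0.3, 2: 0.7}, seed=3).codes.copy()
        fixed = np.zeros((12, 12), dtype=bool)
        fixed[:2, :] = True
        r = LandscapeRaster(codes, fixed=fixed)
        obj = ObjectiveList(
            targets=[TargetSpec("NP", 1, value=2.0)]
        )
        res = optimize(r, obj, OptimizerConfig(seed=3, max_proposals=60_000))
        assert np.array_equal(res.raster.codes[:2, :], codes[:2, :])
        assert res.raster.class_counts() == r.class_counts()

    def test_seed_determinism(self):
        obj = ObjectiveList(
            targets=[
                TargetSpec("PLAND", 1, value=30.0, tolerance=0.5),
                TargetSpec("NP", 1, value=2.0),
                TargetSpec("TE", 1, value=80.0, bound="max"),
            ]
        )
        r = percolation_map(10, 10, {1: 0.3, 2: 0.7}, seed=8)
        one = optimize(r, obj, OptimizerConfig(seed=8, max_proposals=40_000))
        two = optimize(r, obj, OptimizerConfig(seed=8, max_proposals=40_000))
        assert one.raster == two.raster
        assert one.proposals == two.proposals
        assert one.acceptances == two.acceptances

    def test_distinct_seeds_distinct_landscapes(self):
        obj = ObjectiveList(targets=[TargetSpec("NP", 1, value=2.0)])
        r = percolation_map(12, 12, {1: 0.3, 2: 0.7}, seed=9)
        a = optimize(r, obj, OptimizerConfig(seed=1, max_proposals=60_000))
        b = optimize(r, obj, OptimizerConfig(seed=2, max_proposals=60_000))
        assert a.success and b.success
        assert a.raster != b.raster

    def test_input_raster_not_mutated(self):
        r = percolation_map(8, 8, {1: 0.25, 2: 0.75}, seed=4)
        before = r.codes.copy()
        optimize(
            r,
            ObjectiveList(targets=[TargetSpec("NP", 1, value=1.0)]),
            OptimizerConfig(seed=4, max_proposals=30_000),
        )
        assert np.array_equal(r.codes, before)

    def test_verify_incremental_mode(self):
        r = percolation_map(10, 10, {1: 0.3, 2: 0.7}, seed=6)
        obj = ObjectiveList(targets=[TargetSpec("NP", 1, value=2.0)])
        res = optimize(
            r, obj, OptimizerConfig(seed=6, max_proposals=40_000, verify_incremental=True)
        )
        assert res.success

    def test_econ_target_reached_within_band(self):
        # one focal patch whose adjacency to the contrast class is tuned
        obj = ObjectiveList(
            targets=[
                TargetSpec("PLAND", 1, value=25.0, tolerance=0.5),
                TargetSpec("PLAND", 2, value=40.0, tolerance=0.5),
                TargetSpec("PLAND", 3, value=35.0, tolerance=0.5),
                TargetSpec("NP", 2, value=3.0),
                TargetSpec("NP", 1, value=1.0),
                TargetSpec("ECON", 1, value=50.0, tolerance=10.0, patch_rank=0),
            ],
            contrast=(1, 2),
            grid=(16, 16),
        )
        r = percolation_map(16, 16, {1: 0.25, 2: 0.40, 3: 0.35}, seed=0)
        res = optimize(
            r,
            obj,
            OptimizerConfig(seed=0, max_proposals=120_000, stall_limit=6_000, restarts=4),
        )
        assert res.success
        econ = next(s for s in res.objectives if s.target.metric == "ECON")
        assert abs(econ.achieved - 50.0) <= 10.0

    def test_stalled_reported_not_raised(self):
        # a 2x2 raster cannot hold five separate class-1 patches
        r = percolation_map(2, 2, {1: 0.5, 2: 0.5}, seed=0)
        obj = ObjectiveList(targets=[TargetSpec("NP", 1, value=5.0)])
        res = optimize(
            r, obj, OptimizerConfig(seed=0, max_proposals=2_000, stall_limit=500, restarts=1)
        )
        assert res.status == "stalled"
        assert not res.success


class TestBatchGenerate:
    def _jobs(self, n=3):
        jobs = []
        for seed in range(n):
            obj = ObjectiveList(targets=[TargetSpec("NP", 1, value=2.0)])
            r = percolation_map(9, 9, {1: 0.3, 2: 0.7}, seed=seed)
            jobs.append((r, obj, OptimizerConfig(seed=seed, max_proposals=40_000)))
        return jobs

    def test_empty_job_list(self):
        assert batch_generate([]) == []

    def test_worker_count_does_not_change_results(self):
        serial = batch_generate(self._jobs(), workers=1)
        parallel = batch_generate(self._jobs(), workers=4)
        assert len(serial) == len(parallel) == 3
        for s, p in zip(serial, parallel):
            assert s.raster == p.raster
            assert s.status == p.status
            assert s.proposals == p.proposals

    def test_different_seeds_satisfy_same_targets_differently(self):
        results = batch_generate(self._jobs(5), workers=1)
        assert all(r.success for r in results)
        rasters = [tuple(r.raster.codes.ravel()) for r in results]
        assert len(set(rasters)) == 5
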