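"""Cluster-level FWE, conjunctions, contrasts and contribution analysis."""

import numpy as np
import pandas as pd
import pytest

from cbmeta.ale import (
    cluster_fwe,
    conjunction,
    contrast,
    contribution,
    make_ma_map,
)
from cbmeta.io import Experiment, Focus
from cbmeta.kernels import kernel_sigma
from cbmeta.synthetic import FociSimConfig, TruthCenter, gen_foci_dataset


@pytest.fixture(scope="module")
def strong_center_result(sim_grid):
    cfg = FociSimConfig(n_experiments=20,
                        truth_centers=[TruthCenter(0, 0, 0, 1.0, 5.0)],
                        n_noise_foci=8, seed=42)
    es, _ = gen_foci_dataset(cfg, sim_grid)
    with pytest.warns(UserWarning):
        return cluster_fwe(es, n_sim=150, seed=1, min_experiments=25)


class TestClusterFWE:
    def test_single_truth_center_yields_one_cluster_at_the_center(
            self, strong_center_result):
        table = strong_center_result.cluster_table
        sig = table[table["significant"]]
        assert len(sig) == 1
        peak = sig[["peak_x", "peak_y", "peak_z"]].to_numpy()[0]
        fwhm = kernel_sigma(20).fwhm_mm
        assert np.linalg.norm(peak) <= fwhm

    def test_cluster_sizes_meet_extent_where_significant(self, strong_center_result):
        table = strong_center_result.cluster_table
        assert (table.loc[table["significant"], "size"]
                > strong_center_result.crit_size).all()

    def test_alpha_one_reports_every_suprathreshold_cluster(self, sim_grid):
        cfg = FociSimConfig(n_experiments=12, truth_centers=[],
                            n_noise_foci=10, seed=3)
        es, _ = gen_foci_dataset(cfg, sim_grid)
        with pytest.warns(UserWarning):
            res = cluster_fwe(es, alpha=1.0, n_sim=100, seed=2)
        assert res.cluster_table["significant"].all() or res.cluster_table.empty

    def test_no_suprathreshold_voxels_gives_empty_table(self, sim_grid):
        exps = [Experiment(f"s{i}", f"e{i}", 20,
                           [Focus(0, 0, 0) if i == 0 else Focus(40.0, 0, 0)])
                for i in range(2)]
        with pytest.warns(UserWarning):
            res = cluster_fwe(exps, sim_grid, cluster_forming_p=1e-12,
                              n_sim=100, seed=0)
        assert res.cluster_table.empty
        assert not res.thresholded.any()

    def test_too_few_experiments_is_an_error(self, sim_grid):
        with pytest.raises(ValueError):
            cluster_fwe([Experiment("s", "e", 10, [Focus(0, 0, 0)])], sim_grid)

    def test_rerun_with_same_seed_is_identical(self, sim_grid):
        cfg = FociSimConfig(n_experiments=18, truth_centers=[],
                            n_noise_foci=8, seed=9)
        es, _ = gen_foci_dataset(cfg, sim_grid)
        a = cluster_fwe(es, n_sim=80, seed=5, min_experiments=2)
        b = cluster_fwe(es, n_sim=80, seed=5, min_experiments=2)
        pd.testing.assert_frame_equal(a.cluster_table, b.cluster_table)
        np.testing.assert_array_equal(a.null_max_sizes, b.null_max_sizes)


class TestConjunction:
    def _blob(self, grid, center_ijk, radius):
        m = np.zeros(grid.shape)
        idx = np.indices(grid.shape)
        d2 = sum((idx[a] - center_ijk[a]) ** 2 for a in range(3))
        m[d2 <= radius**2] = 0.5
        return m

    def test_identical_maps_conjoin_to_themselves(self, sim_grid):
        m = self._blob(sim_grid, (15, 18, 15), 3)  # ~120 voxels
        out = conjunction([m, m], extent=25)
        np.testing.assert_array_equal(out, m)

    def test_disjoint_maps_conjoin_to_nothing(self, sim_grid):
        a = self._blob(sim_grid, (10, 18, 15), 3)
        b = self._blob(sim_grid, (22, 18, 15), 3)
        assert not conjunction([a, b], extent=25).any()

    def test_small_overlap_is_removed_by_extent_rule(self, sim_grid):
        a = self._blob(sim_grid, (15, 18, 15), 3)
        b = self._blob(sim_grid, (15, 18, 15), 2)  # overlap ~33 voxels
        overlap = int(((a > 0) & (b > 0)).sum())
        out_loose = conjunction([a, b], extent=overlap)
        out_strict = conjunction([a, b], extent=overlap + 1)
        assert (out_loose > 0).sum() == overlap
        assert not out_strict.any()

    def test_minimum_statistic_takes_the_voxelwise_min(self, sim_grid):
        a = self._blob(sim_grid, (15, 18, 15), 3)
        b = a * 0.4
        out = conjunction([a, b], extent=10)
        np.testing.assert_array_equal(out, b)

    def test_needs_two_maps(self, sim_grid):
        with pytest.raises(ValueError):
            conjunction([np.zeros(sim_grid.shape)])


class TestContrast:
    def _sets(self, sim_grid, seed=11):
        cfg = FociSimConfig(
            n_experiments=32, n_noise_foci=5, seed=seed,
            truth_centers=[TruthCenter(-28.0, -16.0, 8.0, 0.95, 5.0),
                           TruthCenter(28.0, 16.0, -8.0, 0.95, 5.0)],
            moderator_name="material",
            moderator_assignment={"color_word": [0], "emotional": [1]},
        )
        es, _ = gen_foci_dataset(cfg, sim_grid)
        a = es.subset(material="color_word")
        b = es.subset(material="emotional")
        ra = cluster_fwe(a, sim_grid, n_sim=120, seed=1, min_experiments=2)
        rb = cluster_fwe(b, sim_grid, n_sim=120, seed=2, min_experiments=2)
        return a, b, ra, rb

    def test_identical_sets_give_empty_contrasts(self, sim_grid):
        cfg = FociSimConfig(n_experiments=16,
                            truth_centers=[TruthCenter(0, 0, 0, 1.0, 5.0)],
                            n_noise_foci=5, seed=4)
        es, _ = gen_foci_dataset(cfg, sim_grid)
        res = cluster_fwe(es, sim_grid, n_sim=100, seed=1, min_experiments=2)
        a_gt_b, b_gt_a = contrast(es, es, sim_grid, res.thresholded,
                                  res.thresholded, n_perm=400, extent=5,
                                  seed=7, min_perm=100)
        assert not a_gt_b.any() and not b_gt_a.any()

    def test_disjoint_truth_centers_recover_in_correct_directions(self, sim_grid):
        a, b, ra, rb = self._sets(sim_grid)
        a_gt_b, b_gt_a = contrast(a, b, sim_grid, ra.thresholded, rb.thresholded,
                                  n_perm=400, extent=5, seed=7, min_perm=100)
        assert a_gt_b.any() and b_gt_a.any()
        for cmap, center in ((a_gt_b, np.array([-28.0, -16.0, 8.0])),
                             (b_gt_a, np.array([28.0, 16.0, -8.0]))):
            vox = np.array(np.nonzero(cmap)).T
            com = sim_grid.voxel_to_mm(vox.mean(axis=0)[None])[0]
            assert np.linalg.norm(com - center) < 15.0

    def test_swapping_sets_swaps_the_outputs_exactly(self, sim_grid):
        a, b, ra, rb = self._sets(sim_grid)
        kw = dict(n_perm=200, extent=5, seed=77, min_perm=100)
        ab = contrast(a, b, sim_grid, ra.thresholded, rb.thresholded, **kw)
        ba = contrast(b, a, sim_grid, rb.thresholded, ra.thresholded, **kw)
        np.testing.assert_array_equal(ab[0], ba[1])
        np.testing.assert_array_equal(ab[1], ba[0])

    def test_empty_set_is_an_error(self, sim_grid):
        with pytest.raises(ValueError, match="nonempty"):
            contrast([], [Experiment("s", "e", 10, [Focus(0, 0, 0)])],
                     sim_grid, np.zeros(sim_grid.shape), np.zeros(sim_grid.shape))


class TestContribution:
    def _cluster(self, grid):
        m = np.zeros(grid.shape, dtype=bool)
        c = np.rint(grid.mm_to_voxel(np.zeros((1, 3)))[0]).astype(int)
        m[c[0] - 2:c[0] + 3, c[1] - 2:c[1] + 3, c[2] - 2:c[2] + 3] = True
        return m & grid.mask

    def test_sole_driver_contributes_everything(self, sim_grid):
        driver = Experiment("s0", "e0", 20, [Focus(0, 0, 0)])
        distant = Experiment("s1", "e1", 20, [Focus(44.0, 30.0, 20.0)])
        table = contribution(self._cluster(sim_grid), [driver, distant], sim_grid)
        by_id = table.set_index("experiment_id")
        assert by_id.loc["e0", "percent_contribution"] == pytest.approx(100.0)
        assert by_id.loc["e1", "percent_contribution"] == pytest.approx(0.0, abs=1e-9)
        assert bool(by_id.loc["e0", "contributing"])
        assert not bool(by_id.loc["e1", "contributing"])

    def test_identical_experiments_contribute_equally(self, sim_grid):
        exps = [Experiment(f"s{i}", f"e{i}", 20, [Focus(2.0, -2.0, 2.0)])
                for i in range(2)]
        table = contribution(self._cluster(sim_grid), exps, sim_grid)
        pcts = table["percent_contribution"].to_numpy()
        assert pcts[0] == pytest.approx(pcts[1], rel=1e-10)

    def test_contributions_are_nonnegative(self, sim_grid, toy_experiments):
        exps = [Experiment(e.study_id, e.experiment_id, e.n,
                           [Focus(0, 0, 0)] + e.foci) for e in toy_experiments]
        table = contribution(self._cluster(sim_grid), exps, sim_grid)
        assert (table["percent_contribution"] >= -1e-12).all()

    def test_empty_cluster_is_an_error(self, sim_grid):
        with pytest.raises(ValueError, match="empty cluster"):
            contribution(np.zeros(sim_grid.shape, dtype=bool),
                         [Experiment("s", "e", 10, [Focus(0, 0, 0)])], sim_grid)
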