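import numpy as np
import pytest

from connload.abnormality import (
    ZScoreMatrix,
    abnormal_edge_mask,
    abnormality_load,
    default_ratio_grid,
    default_z_grid,
    fit_control_distributions,
    flip_profile,
    load_grid,
    node_abnormality,
    roiwise_comparison,
    select_threshold_pair,
    zscore_controls_loo,
    zscore_subject,
)
from connload.atlas import LOBES, N_ROIS
from connload.synthetic import (
    GeneratorConfig,
    draw_edge_params,
    generate_controls,
    make_scaffold,
)

from conftest import cohort_on_edges, matrix_from_edges


def _zmatrix(edge_z, subject_id="s"):
    z = np.zeros((N_ROIS, N_ROIS))
    scaffold = np.zeros((N_ROIS, N_ROIS), dtype=bool)
    for (i, j), v in edge_z.items():
        z[i, j] = z[j, i] = v
        scaffold[i, j] = scaffold[j, i] = True
    return ZScoreMatrix(subject_id, z, scaffold)


class TestFitControlDistributions:
    def test_hand_computed_mean_sd(self):
        controls = cohort_on_edges(
            {(0, 1): [0.4, 0.5, 0.6], (2, 3): [0.4, 0.5, 0.6]}
        )
        dists = fit_control_distributions(controls)
        assert dists.means[0, 1] == pytest.approx(0.5)
        assert dists.sds[0, 1] == pytest.approx(0.1)
        assert dists.means[2, 3] == pytest.approx(0.5)
        assert dists.n_controls == 3

    def test_identical_controls_flagged_degenerate(self):
        controls = cohort_on_edges({(0, 1): [0.5, 0.5, 0.5, 0.5]})
        dists = fit_control_distributions(controls)
        assert dists.degenerate_edges[0, 1]

    def test_too_few_controls_rejected(self):
        controls = cohort_on_edges({(0, 1): [0.4, 0.5]})
        with pytest.raises(ValueError, match="3 controls"):
            fit_control_distributions(controls)

    def test_monte_carlo_recovery(self, atlas):
        # estimates within 3 standard errors of the truth for >= 99% of edges
        cfg = GeneratorConfig(n_controls=400, scaffold_density=0.1, seed=41)
        sc = make_scaffold(cfg, atlas)
        params = draw_edge_params(cfg, sc)
        dists = fit_control_distributions(generate_controls(cfg, sc, params))
        iu, ju = np.triu_indices(N_ROIS, 1)
        on = sc[iu, ju]
        n = cfg.n_controls
        mean_err = np.abs((dists.means - params.means)[iu[on], ju[on]])
        sd_err = np.abs((dists.sds - params.sds)[iu[on], ju[on]])
        assert np.mean(mean_err <= 3 * cfg.edge_sd / np.sqrt(n)) >= 0.99
        assert np.mean(sd_err <= 3 * cfg.edge_sd / np.sqrt(2 * n)) >= 0.99


class TestZScoreSubject:
    def test_arithmetic(self):
        controls = cohort_on_edges({(0, 1): [0.45, 0.50, 0.55]})
        dists = fit_control_distributions(controls)
        assert dists.sds[0, 1] == pytest.approx(0.05)
        subject = matrix_from_edges({(0, 1): 0.35})
        z = zscore_subject(subject, dists)
        assert z.z[0, 1] == pytest.approx(-3.0)

    def test_mean_matrix_scores_zero(self, small_controls):
        dists = fit_control_distributions(small_controls)
        mean_matrix = matrix_from_edges({})
        mean_matrix.weights = dists.means.copy()
        z = zscore_subject(mean_matrix, dists)
        assert np.allclose(z.z, 0.0)

    def test_linearity_in_sd_units(self, small_controls):
        dists = fit_control_distributions(small_controls)
        subject = small_controls[0]
        z0 = zscore_subject(subject, dists)
        i, j = map(int, np.argwhere(np.triu(subject.scaffold, 1))[0])
        shifted = subject.weights.copy()
        k = 1.75
        shifted[i, j] += k * dists.sds[i, j]
        shifted[j, i] = shifted[i, j]
        z1 = zscore_subject(
            type(subject)(subject.subject_id, "MD", shifted), dists
        )
        assert z1.z[i, j] - z0.z[i, j] == pytest.approx(k)

    def test_scaffold_mismatch_rejected(self, small_controls):
        dists = fit_control_distributions(small_controls)
        other = matrix_from_edges({(0, 1): 0.5})
        with pytest.raises(ValueError, match="scaffold"):
            zscore_subject(other, dists)


class TestLeaveOneOut:
    def test_hand_oracle(self):
        values = [0.40, 0.50, 0.55, 0.60, 0.70]
        controls = cohort_on_edges({(0, 1): values})
        loo = zscore_controls_loo(controls)
        for i, zm in enumerate(loo):
            rest = np.delete(np.asarray(values), i)
            expected = (values[i] - rest.mean()) / rest.std(ddof=1)
            assert zm.z[0, 1] == pytest.approx(expected)
            assert zm.loo

    def test_identical_controls_degenerate_to_zero(self):
        controls = cohort_on_edges({(0, 1): [0.5] * 5})
        for zm in zscore_controls_loo(controls):
            assert zm.z[0, 1] == 0.0

    def test_perturbed_control_dominates(self):
        # jittered base values plus one strongly perturbed control
        rng = np.random.default_rng(3)
        base = 0.5 + 0.01 * rng.standard_normal(6)
        base[0] += 0.2
        controls = cohort_on_edges({(0, 1): base.tolist()})
        loo = zscore_controls_loo(controls)
        zs = np.array([zm.z[0, 1] for zm in loo])
        assert np.abs(zs[0]) > 3 * np.abs(zs[1:]).max()

    def test_deterministic(self, small_controls):
        a = zscore_controls_loo(small_controls)
        b = zscore_controls_loo(small_controls)
        for za, zb in zip(a, b):
            assert np.array_equal(za.z, zb.z)

    def test_too_few_rejected(self):
        controls = cohort_on_edges({(0, 1): [0.4, 0.5, 0.6]})
        with pytest.raises(ValueError, match="4 controls"):
            zscore_controls_loo(controls)

    def test_loo_mean_near_zero_monte_carlo(self, atlas):
        # E[z] = 0 by exchangeability; average over subjects and replicates
        sums = None
        count = 0
        for rep in range(6):
            cfg = GeneratorConfig(n_controls=29, scaffold_density=0.1, seed=600 + rep)
            sc = make_scaffold(cfg, atlas) if rep == 0 else sc  # noqa: F821
            params = draw_edge_params(cfg, sc)
            controls = generate_controls(cfg, sc, params)
            for zm in zscore_controls_loo(controls):
                sums = zm.z if sums is None else sums + zm.z
                count += 1
        mean_z = sums / count
        iu, ju = np.triu_indices(N_ROIS, 1)
        on = sc[iu, ju]
        assert np.all(np.abs(mean_z[iu[on], ju[on]]) < 0.2)


class TestAbnormalEdgeMask:
    def test_high_threshold_empty(self):
        zm = _zmatrix({(0, 1): 2.9, (1, 2): -3.0})
        assert not abnormal_edge_mask(zm, 3.5).any()

    def test_two_sided_enumeration(self):
        zm = _zmatrix({(0, 1): -3.0, (1, 2): -2.0, (2, 3): 2.6})
        mask = abnormal_edge_mask(zm, 2.5, "two_sided")
        assert mask[0, 1] and mask[2, 3] and not mask[1, 2]
        assert int(np.triu(mask, 1).sum()) == 2

    def test_one_sided_directions(self):
        zm = _zmatrix({(0, 1): -3.0, (1, 2): 3.0})
        dec = abnormal_edge_mask(zm, 2.5, "decrease_only")
        inc = abnormal_edge_mask(zm, 2.5, "increase_only")
        assert dec[0, 1] and not dec[1, 2]
        assert inc[1, 2] and not inc[0, 1]

    def test_mask_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        edges = {(i, i + 1): float(rng.standard_normal() * 3) for i in range(0, 40, 2)}
        zm = _zmatrix(edges)
        sizes = [
            int(np.triu(abnormal_edge_mask(zm, thr), 1).sum())
            for thr in np.linspace(0.5, 4.0, 8)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_bad_arguments(self):
        zm = _zmatrix({(0, 1): 1.0})
        with pytest.raises(ValueError):
            abnormal_edge_mask(zm, 0.0)
        with pytest.raises(ValueError):
            abnormal_edge_mask(zm, 2.0, "sideways")


class TestNodeAbnormality:
    def test_empty_mask_all_zero(self):
        zm = _zmatrix({(0, 1): 1.0, (1, 2): -1.0})
        prof = node_abnormality(np.zeros((N_ROIS, N_ROIS), dtype=bool), zm)
        assert np.all(prof.ratios == 0)

    def test_degree_four_one_abnormal(self):
        zm = _zmatrix({(0, 1): 4.0, (0, 2): 1.0, (0, 3): 1.0, (0, 4): 1.0})
        mask = abnormal_edge_mask(zm, 3.0)
        prof = node_abnormality(mask, zm)
        assert prof.degrees[0] == 4
        assert prof.ratios[0] == pytest.approx(0.25)

    def test_six_node_toy_one_third(self):
        # node B (index 1) has 3 connections of which 1 is abnormal -> 1/3
        zm = _zmatrix(
            {(0, 1): 4.0, (1, 2): 1.0, (1, 3): 0.5, (0, 2): 0.2,
             (3, 4): 0.1, (4, 5): 0.3}
        )
        mask = abnormal_edge_mask(zm, 3.0)
        prof = node_abnormality(mask, zm)
        assert prof.ratios[1] == pytest.approx(1 / 3)

    def test_mask_outside_scaffold_rejected(self):
        zm = _zmatrix({(0, 1): 1.0})
        mask = np.zeros((N_ROIS, N_ROIS), dtype=bool)
        mask[4, 5] = mask[5, 4] = True
        with pytest.raises(ValueError, match="scaffold"):
            node_abnormality(mask, zm)


class TestAbnormalityLoad:
    def _profile(self, ratios):
        zm = _zmatrix({(0, 1): 1.0})
        prof = node_abnormality(np.zeros((N_ROIS, N_ROIS), dtype=bool), zm)
        prof.ratios = np.asarray(ratios, dtype=float)
        return prof

    def test_strict_count(self, atlas):
        ratios = np.zeros(N_ROIS)
        ratios[:4] = [0.25, 0.0, 0.5, 0.1]
        load = abnormality_load(self._profile(ratios), 0.2, "whole_brain", atlas)
        assert load.load == 2

    def test_threshold_above_max_gives_zero(self, atlas):
        ratios = np.full(N_ROIS, 0.3)
        assert abnormality_load(self._profile(ratios), 0.31, "whole_brain", atlas).load == 0

    def test_lobewise_partition(self, atlas):
        rng = np.random.default_rng(12)
        for _ in range(5):
            prof = self._profile(rng.uniform(0, 0.3, N_ROIS))
            thr = float(rng.uniform(0.01, 0.2))
            whole = abnormality_load(prof, thr, "whole_brain", atlas).load
            lobes = sum(
                abnormality_load(prof, thr, lb, atlas).load for lb in LOBES
            )
            assert whole == lobes

    def test_left_right_split(self, atlas):
        rng = np.random.default_rng(13)
        prof = self._profile(rng.uniform(0, 0.3, N_ROIS))
        combined = abnormality_load(prof, 0.1, "temporal", atlas).load
        split = (
            abnormality_load(prof, 0.1, "temporal_left", atlas).load
            + abnormality_load(prof, 0.1, "temporal_right", atlas).load
        )
        assert combined == split

    def test_bad_threshold_rejected(self, atlas):
        with pytest.raises(ValueError):
            abnormality_load(self._profile(np.zeros(N_ROIS)), 0.0, "whole_brain", atlas)

    def test_unknown_region_rejected(self, atlas):
        with pytest.raises(Exception, match="region"):
            abnormality_load(self._profile(np.zeros(N_ROIS)), 0.1, "cerebellum", atlas)


class TestLoadGrid:
    def test_matches_direct_computation(self, small_controls, atlas):
        loo = zscore_controls_loo(small_controls)
        z_grid = np.array([1.5, 2.5])
        ratio_grid = np.array([0.05, 0.1])
        grid = load_grid(loo, z_grid, ratio_grid, atlas)
        for s, zm in enumerate(loo):
            for zi, z_thr in enumerate(z_grid):
                mask = abnormal_edge_mask(zm, float(z_thr))
                prof = node_abnormality(mask, zm)
                for ri, r_thr in enumerate(ratio_grid):
                    direct = abnormality_load(prof, float(r_thr), "whole_brain", atlas)
                    assert grid[s, zi, ri] == direct.load

    def test_monotone_in_both_thresholds(self, small_controls, atlas):
        loo = zscore_controls_loo(small_controls)
        grid = load_grid(loo, default_z_grid(), default_ratio_grid(), atlas)
        assert np.all(np.diff(grid, axis=1) <= 0)
        assert np.all(np.diff(grid, axis=2) <= 0)


class TestSelectThresholdPair:
    def test_unique_maximizer(self):
        z_grid = np.array([2.0, 3.0])
        ratio_grid = np.array([0.1, 0.2])
        loads_a = np.zeros((6, 2, 2))
        loads_b = np.zeros((6, 2, 2))
        rng = np.random.default_rng(0)
        loads_a += rng.normal(5, 2, loads_a.shape)
        loads_b += rng.normal(5, 2, loads_b.shape)
        # perfect separation only at (3.0, 0.2)
        loads_a[:, 1, 1] = [10, 11, 12, 13, 14, 15]
        loads_b[:, 1, 1] = [0, 1, 2, 0, 1, 2]
        assert select_threshold_pair(loads_a, loads_b, z_grid, ratio_grid) == (3.0, 0.2)

    def test_tie_broken_toward_smaller_thresholds(self):
        z_grid = np.array([2.0, 3.0])
        ratio_grid = np.array([0.1, 0.2])
        loads_a = np.tile(np.array([4.0, 5.0, 6.0])[:, None, None], (1, 2, 2))
        loads_b = np.tile(np.array([1.0, 2.0, 3.0])[:, None, None], (1, 2, 2))
        assert select_threshold_pair(loads_a, loads_b, z_grid, ratio_grid) == (2.0, 0.1)

    def test_all_zero_rejected(self):
        z_grid = np.array([2.0])
        ratio_grid = np.array([0.1])
        zeros = np.zeros((4, 1, 1))
        with pytest.raises(ValueError, match="zero"):
            select_threshold_pair(zeros, zeros.copy(), z_grid, ratio_grid)


class TestFlipProfile:
    def test_involution_and_permutation(self, atlas):
        zm = _zmatrix({(0, 1): 4.0, (0, 2): 1.0, (2, 3): 1.0})
        prof = node_abnormality(abnormal_edge_mask(zm, 3.0), zm)
        flipped = flip_profile(prof, atlas)
        perm = atlas.homologue_permutation()
        assert np.array_equal(flipped.ratios, prof.ratios[perm])
        back = flip_profile(flipped, atlas)
        assert np.array_equal(back.ratios, prof.ratios)
        assert np.array_equal(back.degrees, prof.degrees)


class TestRoiwiseComparison:
    def _profiles(self, ratios_rows, prefix="s"):
        out = []
        for k, row in enumerate(ratios_rows):
            zm = _zmatrix({(0, 1): 1.0})
            prof = node_abnormality(np.zeros((N_ROIS, N_ROIS), dtype=bool), zm)
            prof.subject_id = f"{prefix}{k}"
            prof.ratios = np.asarray(row, dtype=float)
            out.append(prof)
        return out

    def test_identical_groups_nothing_significant(self, atlas):
        rng = np.random.default_rng(4)
        rows = rng.uniform(0, 0.3, (5, N_ROIS))
        table = roiwise_comparison(self._profiles(rows), self._profiles(rows), atlas)
        assert not table["significant"].any()

    def test_single_separated_roi_survives_bh(self, atlas):
        # ROI 7 fully separated across groups of 10; all others identical.
        # Hand BH: p_min = 1/C(20,10), adjusted = 90 * p_min ~ 4.9e-4 < .05;
        # every other ROI is all ties (p = 1).
        base = np.full((10, N_ROIS), 0.1)
        rows_a, rows_b = base.copy(), base.copy()
        rows_a[:, 7] = np.linspace(0.5, 0.6, 10)
        rows_b[:, 7] = np.linspace(0.2, 0.3, 10)
        table = roiwise_comparison(self._profiles(rows_a), self._profiles(rows_b), atlas)
        from math import comb

        p_min = 1 / comb(20, 10)
        row = table.iloc[7]
        assert row["p_value"] == pytest.approx(p_min)
        assert row["p_adjusted"] == pytest.approx(min(1.0, 90 * p_min))
        assert row["significant"]
        assert table["significant"].sum() == 1

    def test_small_group_rejected(self, atlas):
        rows = np.full((2, N_ROIS), 0.1)
        with pytest.raises(ValueError, match="3 subjects"):
            roiwise_comparison(self._profiles(rows), self._profiles(rows), atlas)

    def test_adjusted_not_below_raw(self, atlas):
        rng = np.random.default_rng(9)
        a = self._profiles(rng.uniform(0, 0.3, (6, N_ROIS)))
        b = self._profiles(rng.uniform(0, 0.3, (6, N_ROIS)))
        table = roiwise_comparison(a, b, atlas)
        assert np.all(table["p_adjusted"] >= table["p_value"] - 1e-12)
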