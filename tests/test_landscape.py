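"""Landscape KDE, region membership, pathway classification, contact maps."""

import numpy as np
import pytest

from lassofold.fixtures import make_scripted_series
from lassofold.landscape import (ContactProbabilityMap, DEFAULT_REGIONS,
                                 classify_pathway, ensemble_contact_map,
                                 folding_time, kde_landscape,
                                 region_membership, select_special_contacts)


class TestKde:
    def test_single_cluster_minimum_at_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.normal([0.5, -0.3], 0.01, size=(500, 2))
        grid = kde_landscape(pts)
        a, b = np.unravel_index(np.argmin(grid.neg_log_density),
                                grid.neg_log_density.shape)
        assert grid.neg_log_density.min() == 0.0
        assert abs(grid.q_grid[a] - 0.5) < 0.01
        assert abs(grid.g_grid[b] + 0.3) < 0.01

    def test_two_equal_clusters_have_equal_minima(self):
        rng = np.random.default_rng(1)
        a = rng.normal([0.2, 0.0], 0.02, size=(400, 2))
        b = rng.normal([0.8, -0.7], 0.02, size=(400, 2))
        grid = kde_landscape(np.vstack([a, b]))
        nld = grid.neg_log_density
        q = grid.q_grid
        left = nld[q < 0.5].min()
        right = nld[q >= 0.5].min()
        assert abs(left - right) < 0.05

    def test_scott_bandwidth_scales_as_n_to_minus_sixth(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0.0, 1.0, size=(800, 2))
        h1 = kde_landscape(pts[:400]).bandwidths
        h2 = kde_landscape(pts).bandwidths
        sd1 = pts[:400].std(axis=0)
        sd2 = pts.std(axis=0)
        # remove the sample-σ factor: the residual ratio is exactly 2^{-1/6}
        assert h2[0] / sd2[0] / (h1[0] / sd1[0]) == pytest.approx(
            2 ** (-1 / 6), abs=1e-12)

    def test_zero_variance_rejected(self):
        pts = np.column_stack([np.full(200, 0.5),
                               np.linspace(-1, 0, 200)])
        with pytest.raises(ValueError):
            kde_landscape(pts)


class TestRegions:
    @pytest.mark.parametrize("point,expected", [
        ((0.6, -0.1), "IT"),     # -0.12 < -0.1 < 0.08
        ((0.4, -0.6), "IE-"),    # -0.688 < -0.6 < -0.538
        ((0.9, -0.7), "F"),
        ((0.2, 0.1), "U"),
        ((0.6, -0.5), None),
        ((0.45, 0.0), None),
    ])
    def test_printed_inequalities(self, point, expected):
        assert region_membership(point) == expected

    def test_boundaries_closed_for_boxes_strict_for_rhomboids(self):
        assert region_membership((0.375, 0.25)) == "U"      # box corner in
        assert region_membership((0.75, -0.5)) == "F"       # box corner in
        # rhomboid boundary excluded: g = -0.2 q exactly
        assert region_membership((0.6, -0.12)) is None

    def test_tse_interval(self):
        assert DEFAULT_REGIONS.in_tse(0.5)
        assert DEFAULT_REGIONS.in_tse(0.47) and DEFAULT_REGIONS.in_tse(0.53)
        assert not DEFAULT_REGIONS.in_tse(0.46)


class TestClassify:
    WINDOW = 25  # scripted fixtures use short dwell times

    def _series(self, script, seed=0):
        return make_scripted_series(script, seed=seed)

    @pytest.mark.parametrize("script,label", [
        ([("U", 120), ("IE-", 60), ("F", 120)], "fast_folding"),
        ([("U", 120), ("IT", 120), ("F", 120)], "threading"),
        ([("U", 120), ("IT", 120), ("U", 120), ("IE-", 60), ("F", 120)],
         "backtracking"),
        ([("U", 120), ("IT", 200)], "trapped"),
    ])
    def test_scripted_pathways(self, script, label):
        series = self._series(script)
        rec = classify_pathway(series, window=self.WINDOW)
        assert rec.label == label

    def test_jitter_stability_across_seeds(self):
        scripts = {
            "fast_folding": [("U", 120), ("IE-", 60), ("F", 120)],
            "threading": [("U", 120), ("IT", 120), ("F", 120)],
            "backtracking": [("U", 120), ("IT", 120), ("U", 120),
                             ("IE-", 60), ("F", 120)],
            "trapped": [("U", 120), ("IT", 200)],
        }
        for label, script in scripts.items():
            for seed in range(25):
                series = self._series(script, seed=seed)
                assert classify_pathway(series,
                                        window=self.WINDOW).label == label

    def test_invariant_to_prepended_unfolded_data(self):
        script = [("U", 120), ("IT", 120), ("F", 120)]
        base = classify_pathway(self._series(script), window=self.WINDOW)
        longer = classify_pathway(
            self._series([("U", 400)] + script), window=self.WINDOW)
        assert base.label == longer.label == "threading"

    def test_short_series_rejected(self):
        series = self._series([("U", 10)])
        with pytest.raises(ValueError):
            classify_pathway(series, window=555)


class TestFoldingTime:
    def _series(self, q, g):
        from lassofold.dynamics import ObservableSeries
        n = len(q)
        return ObservableSeries(step=np.arange(n), q=np.asarray(q, float),
                                gprime=np.asarray(g, float),
                                energy=np.zeros(n), rmsd=np.zeros(n),
                                formed=np.zeros((n, 0), bool))

    def test_block_crossing_time(self):
        n = 1000
        q = np.where(np.arange(n) < 500, 0.2, 0.9)
        g = np.where(np.arange(n) < 500, 0.0, -0.8)
        t = folding_time(self._series(q, g), mode="rd1")
        assert 400 <= t <= 650  # the first block whose means satisfy both

    def test_rd1_requires_both_coordinates(self):
        n = 1000
        q = np.full(n, 0.9)
        g = np.zeros(n)  # never entangled
        assert folding_time(self._series(q, g), mode="rd1") is None

    def test_sh3_mode_ignores_entanglement(self):
        n = 1000
        q = np.full(n, 0.9)
        g = np.zeros(n)
        assert folding_time(self._series(q, g), mode="sh3") == \
            pytest.approx(124.5)


class TestContactMaps:
    def test_all_native_gives_unit_probabilities(self, hairpin):
        topo, conf = hairpin
        cmap = ensemble_contact_map([conf] * 5, topo)
        assert np.allclose(cmap.probabilities, 1.0)

    def test_native_plus_stretched_gives_half(self, hairpin):
        from lassofold.forcefield import Conformation
        topo, conf = hairpin
        n = topo.n_residues
        straight = Conformation(np.column_stack(
            [np.arange(n) * 3.8, np.zeros(n), np.zeros(n)]))
        cmap = ensemble_contact_map([conf, straight], topo)
        assert np.allclose(cmap.probabilities, 0.5)

    def test_z_scores_population_sd(self):
        cmap = ContactProbabilityMap(contacts=[(0, 4), (1, 5), (2, 6)],
                                     probabilities=np.array([0.9, 0.5, 0.1]))
        z = cmap.z_scores()
        assert z == pytest.approx([1.2247, 0.0, -1.2247], abs=1e-4)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_select_special_contacts(self):
        contacts = [(0, 4), (1, 5), (2, 6), (3, 7)]
        ie = ContactProbabilityMap(contacts,
                                   np.array([0.95, 0.50, 0.30, 0.05]))
        it = ContactProbabilityMap(contacts,
                                   np.array([0.20, 0.90, 0.85, 0.80]))
        trap, first = select_special_contacts(ie, it,
                                              entangled_set=[(1, 5), (2, 6)])
        assert trap == [(0, 4)]
        assert first == [(1, 5)]  # z^IE > 0 among entangled

    def test_equal_maps_give_no_trap_avoiding(self):
        contacts = [(0, 4), (1, 5), (2, 6)]
        m = ContactProbabilityMap(contacts, np.array([0.9, 0.5, 0.1]))
        trap, _ = select_special_contacts(m, m, entangled_set=[])
        assert trap == []

    def test_zero_variance_raises(self):
        m = ContactProbabilityMap([(0, 4)], np.array([0.5]))
        with pytest.raises(ValueError):
            m.z_scores()
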