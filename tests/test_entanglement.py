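"""Gaussian entanglement: Gauss sums, thread search, Hill-weighted ⟨G′⟩."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_coil
from lassofold.entanglement import (HillParams, entanglement_indicator,
                                    gauss_pair_matrix, gaussian_entanglement,
                                    hill_weight, max_thread, count_entangled,
                                    native_contact_entanglements)
from lassofold.fixtures import (discrete_linking_number, make_linked_rings,
                                make_open_lasso)


def brute_force_max_thread(coords, loop):
    """Exhaustive O(N²) search over all admissible thread intervals."""
    i1, i2 = loop
    mat = gauss_pair_matrix(coords)
    nb = mat.shape[0]
    col = mat[i1:i2].sum(axis=0)
    prefix = np.concatenate(([0.0], np.cumsum(col)))
    best = (-1.0, None)
    for lo, hi in (((0, min(i1, nb))), ((i2, nb))):
        for j1 in range(lo, hi + 1):
            for j2 in range(j1 + 10, hi + 1):
                g = prefix[j2] - prefix[j1]
                if abs(g) > best[0]:
                    best = (abs(g), (g, j1, j2))
    return best[1]


class TestGaussPairMatrix:
    def test_kernel_symmetric_in_index_swap(self):
        rng = np.random.default_rng(0)
        coords = random_coil(15, rng)
        mat = gauss_pair_matrix(coords)
        assert np.allclose(mat, mat.T, atol=1e-14)

    def test_rigid_rotation_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(1)
        coords = random_coil(20, rng)
        rot = Rotation.from_euler("zyx", [0.5, 1.0, -0.7]).as_matrix()
        m0 = gauss_pair_matrix(coords)
        m1 = gauss_pair_matrix(coords @ rot.T + np.array([1.0, 2.0, 3.0]))
        assert np.abs(m0 - m1).max() < 1e-12

    def test_coplanar_parallel_bonds_vanish(self):
        # two parallel bonds separated along their own direction: triple
        # product of coplanar vectors is zero
        coords = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                          float)
        mat = gauss_pair_matrix(coords)
        assert np.abs(mat).max() == 0.0

    def test_coincident_midpoints_warn(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 0, 0], [1, 0, 0]],
                          float)
        with pytest.warns(UserWarning, match="self-intersecting"):
            mat = gauss_pair_matrix(coords)
        assert np.isfinite(mat).all()


class TestLinkingOracle:
    @pytest.mark.parametrize("linking", [0, 1, -1, 2, -2])
    def test_rings_converge_to_linking_number(self, linking):
        cp = make_linked_rings(200, linking)
        g = discrete_linking_number(cp.curve_a, cp.curve_b)
        assert abs(g - linking) < 0.01

    def test_orientation_reversal_flips_sign(self):
        cp = make_linked_rings(200, 1)
        g = discrete_linking_number(cp.curve_a, cp.curve_b)
        g_rev = discrete_linking_number(cp.curve_a, cp.curve_b[::-1])
        assert g_rev == pytest.approx(-g, abs=1e-12)

    def test_mirror_reflection_flips_sign(self):
        cp = make_linked_rings(200, 1)
        mirror = cp.curve_b * np.array([1.0, 1.0, -1.0])
        g = discrete_linking_number(cp.curve_a, cp.curve_b)
        g_mir = discrete_linking_number(cp.curve_a, mirror)
        assert g_mir == pytest.approx(-g, abs=1e-12)

    def test_convergence_is_monotone_on_doubling_ladder(self):
        errs = []
        for n in (50, 100, 200, 400):
            cp = make_linked_rings(n, 1)
            errs.append(abs(discrete_linking_number(cp.curve_a, cp.curve_b)
                            - 1.0))
        assert all(a >= b for a, b in zip(errs, errs[1:]))

    def test_hopf_link_as_single_chain_segments(self):
        """Treating both rings as portions of one chain, the open-curve
        double sum over their bonds recovers the linking number closely."""
        cp = make_linked_rings(200, 1)
        # wrap each ring once so every closure bond is included
        a = np.vstack([cp.curve_a, cp.curve_a[0]])
        b = np.vstack([cp.curve_b, cp.curve_b[0]])
        coords = np.vstack([a, b])
        g = gaussian_entanglement(coords, (0, len(a) - 1),
                                  (len(a), len(coords) - 1))
        # the single spurious a-end -> b-start bond adds a small error
        assert abs(g - 1.0) < 0.05


class TestOpenLasso:
    def test_pierced_lasso_strongly_entangled(self):
        coords, loop = make_open_lasso(pierce=True, chirality=1)
        rec = max_thread(coords, loop)
        assert rec.g_prime >= 0.9

    def test_unpierced_lasso_weakly_entangled(self):
        coords, loop = make_open_lasso(pierce=False)
        rec = max_thread(coords, loop)
        assert abs(rec.g_prime) < 0.2

    def test_chirality_mirror_negates(self):
        plus, loop = make_open_lasso(pierce=True, chirality=1)
        minus, _ = make_open_lasso(pierce=True, chirality=-1)
        g_plus = max_thread(plus, loop).g_prime
        g_minus = max_thread(minus, loop).g_prime
        assert g_minus == pytest.approx(-g_plus, abs=1e-9)


class TestMaxThread:
    def test_prefix_sum_equals_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            coords = random_coil(40, rng)
            i1 = int(rng.integers(0, 20))
            i2 = i1 + int(rng.integers(4, 15))
            rec = max_thread(coords, (i1, i2))
            brute = brute_force_max_thread(coords, (i1, i2))
            if brute is None:
                assert rec.degenerate
            else:
                g, j1, j2 = brute
                assert rec.g_prime == pytest.approx(g, abs=1e-12)
                assert rec.thread == (j1, j2)

    def test_short_chain_has_no_thread(self):
        rng = np.random.default_rng(3)
        coords = random_coil(14, rng)
        rec = max_thread(coords, (0, 13))
        assert rec.degenerate and rec.g_prime == 0.0 and rec.thread is None

    def test_loop_length_enforced(self):
        coords = random_coil(30, np.random.default_rng(0))
        with pytest.raises(ValueError):
            max_thread(coords, (5, 8))


class TestHillWeight:
    def test_weight_at_threshold_is_half(self):
        assert hill_weight(0.5) == pytest.approx(0.5, abs=1e-15)

    def test_weight_at_zero_is_zero(self):
        assert hill_weight(0.0) == 0.0

    def test_weight_at_one(self):
        assert hill_weight(1.0) == pytest.approx(1.0 / 1.125, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_entanglement(self, g):
        assert hill_weight(g * 1.01) > hill_weight(g)


class TestIndicator:
    def test_single_contact_indicator_equals_its_gprime(self, lasso):
        topo, conf = lasso
        i, j, _ = topo.contacts[0]
        snap = entanglement_indicator(conf.coords, [(i, j)])
        assert snap.indicator == pytest.approx(snap.records[0].g_prime,
                                               abs=1e-14)

    def test_no_contacts_flagged_zero(self):
        coords = random_coil(30, np.random.default_rng(5))
        snap = entanglement_indicator(coords, [])
        assert snap.empty and snap.indicator == 0.0

    def test_indicator_within_min_max_hull(self):
        rng = np.random.default_rng(8)
        coords = random_coil(60, rng)
        contacts = [(0, 10), (5, 20), (12, 30), (25, 45)]
        snap = entanglement_indicator(coords, contacts)
        gs = [r.g_prime for r in snap.records]
        if not snap.empty:
            assert min(gs) - 1e-12 <= snap.indicator <= max(gs) + 1e-12

    def test_mirror_reflection_negates_indicator(self, lasso):
        topo, conf = lasso
        contacts = [(i, j) for i, j, _ in topo.contacts]
        snap = entanglement_indicator(conf.coords, contacts)
        mirrored = conf.coords * np.array([1.0, 1.0, -1.0])
        snap_m = entanglement_indicator(mirrored, contacts)
        assert snap_m.indicator == pytest.approx(-snap.indicator, abs=1e-12)

    def test_lasso_native_is_entangled(self, lasso):
        topo, _ = lasso
        snap = native_contact_entanglements(topo)
        assert max(abs(r.g_prime) for r in snap.records) > 0.75

    def test_hairpin_native_not_entangled(self, hairpin):
        topo, _ = hairpin
        snap = native_contact_entanglements(topo)
        assert all(abs(r.g_prime) < 0.5 for r in snap.records)


class TestCountEntangled:
    def test_empty_records(self):
        assert count_entangled([], -0.75) == 0

    def test_threshold_modes(self, lasso):
        topo, _ = lasso
        snap = native_contact_entanglements(topo)
        n_abs = count_entangled(snap.records, 0.75, mode="abs")
        assert n_abs >= 1
        # the toy lasso entangles with positive chirality
        assert count_entangled(snap.records, -0.75, mode="below") == 0
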