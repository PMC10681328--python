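"""Go-model potential, analytic forces, Q and RMSD."""

import numpy as np
import pytest

from conftest import random_coil
from lassofold.forcefield import (Conformation, GoParameters, forces,
                                  fraction_native, kabsch_rmsd,
                                  potential_energy, rmsd_to_native)
from lassofold.structure_io import NativeTopology


def _pair_topology(r0):
    """Two beads with one native contact — isolates the contact term."""
    return NativeTopology(
        n_residues=2, ca_coords=np.array([[0.0, 0, 0], [r0, 0, 0]]),
        residue_labels=["A1", "A2"], bond_lengths_r0=np.array([r0]),
        angles_theta0=np.empty(0), dihedrals_phi0=np.empty(0),
        contacts=[(0, 1, r0)])


class TestPotential:
    def test_native_energy_is_minus_contact_count(self, hairpin, go_params):
        topo, conf = hairpin
        e, comps = potential_energy(conf, topo, go_params)
        assert comps["bond"] == pytest.approx(0.0, abs=1e-12)
        assert comps["dihedral"] == pytest.approx(0.0, abs=1e-12)
        assert comps["angle"] == pytest.approx(0.0, abs=1e-6)
        assert comps["native"] == pytest.approx(-topo.n_contacts, abs=1e-6)
        assert comps["nonnative"] == pytest.approx(0.0, abs=0.1)

    def test_components_sum_to_total(self, lasso, go_params):
        topo, conf = lasso
        rng = np.random.default_rng(2)
        c = Conformation(conf.coords + rng.normal(0, 0.2, conf.coords.shape))
        e, comps = potential_energy(c, topo, go_params)
        assert e == pytest.approx(sum(comps.values()), abs=1e-12)

    def test_lj_zero_crossing_at_sigma(self):
        r0 = 6.0
        topo = _pair_topology(r0)
        sigma = r0 * 2 ** (-1.0 / 6.0)
        conf = Conformation(np.array([[0.0, 0, 0], [sigma, 0, 0]]))
        # suppress the bond term by matching r0 to sigma
        topo.bond_lengths_r0 = np.array([sigma])
        _, comps = potential_energy(conf, topo)
        assert comps["native"] == pytest.approx(0.0, abs=1e-12)

    def test_native_term_truncated_beyond_cutoff(self):
        r0 = 6.0
        sigma = r0 * 2 ** (-1.0 / 6.0)
        topo = _pair_topology(r0)
        r = 2.6 * sigma
        topo.bond_lengths_r0 = np.array([r])
        conf = Conformation(np.array([[0.0, 0, 0], [r, 0, 0]]))
        _, comps = potential_energy(conf, topo)
        assert comps["native"] == 0.0

    def test_minimum_depth_at_r0_both_flavours(self):
        r0 = 6.0
        topo = _pair_topology(r0)
        conf = Conformation(topo.ca_coords.copy())
        for flavour in ("12-6", "12-10"):
            _, comps = potential_energy(conf, topo,
                                        GoParameters(lj_flavour=flavour))
            assert comps["native"] == pytest.approx(-1.0, abs=1e-12)

    def test_rigid_motion_invariance(self, lasso, go_params):
        from scipy.spatial.transform import Rotation
        topo, conf = lasso
        rot = Rotation.from_euler("xyz", [1.0, 0.2, -0.4]).as_matrix()
        moved = Conformation(conf.coords @ rot.T + np.array([3.0, -8.0, 1.0]))
        e0, _ = potential_energy(conf, topo, go_params)
        e1, _ = potential_energy(moved, topo, go_params)
        assert e1 == pytest.approx(e0, abs=1e-9)


class TestForces:
    @pytest.mark.parametrize("flavour", ["12-6", "12-10"])
    def test_matches_central_finite_differences(self, flavour, helix):
        topo, _ = helix
        params = GoParameters(lj_flavour=flavour)
        rng = np.random.default_rng(11)
        h = 1e-6
        worst = 0.0
        for _ in range(5):
            pos = topo.ca_coords + rng.normal(0, 0.3, topo.ca_coords.shape)
            f = forces(Conformation(pos), topo, params)
            for i in range(len(pos)):
                for d in range(3):
                    pp, pm = pos.copy(), pos.copy()
                    pp[i, d] += h
                    pm[i, d] -= h
                    ep, _ = potential_energy(Conformation(pp), topo, params)
                    em, _ = potential_energy(Conformation(pm), topo, params)
                    fd = -(ep - em) / (2 * h)
                    worst = max(worst,
                                abs(fd - f[i, d]) / max(1.0, abs(f[i, d])))
        assert worst < 1e-5

    def test_pair_at_minimum_has_zero_force(self):
        topo = _pair_topology(6.0)
        f = forces(Conformation(topo.ca_coords.copy()), topo)
        assert np.abs(f).max() < 1e-12

    def test_total_force_vanishes(self, lasso, go_params):
        topo, conf = lasso
        rng = np.random.default_rng(4)
        pos = conf.coords + rng.normal(0, 0.5, conf.coords.shape)
        f = forces(Conformation(pos), topo, go_params)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_forces_rotate_covariantly(self, hairpin, go_params):
        from scipy.spatial.transform import Rotation
        topo, conf = hairpin
        rng = np.random.default_rng(9)
        pos = conf.coords + rng.normal(0, 0.3, conf.coords.shape)
        rot = Rotation.from_euler("zxz", [0.7, 1.2, -0.3]).as_matrix()
        f0 = forces(Conformation(pos), topo, go_params)
        f1 = forces(Conformation(pos @ rot.T), topo, go_params)
        assert np.abs(f1 - f0 @ rot.T).max() < 1e-9


class TestFractionNative:
    def test_native_q_is_one(self, lasso):
        topo, conf = lasso
        q, formed = fraction_native(conf, topo)
        assert q == 1.0 and len(formed) == topo.n_contacts

    def test_stretched_chain_q_is_zero(self, hairpin):
        topo, _ = hairpin
        n = topo.n_residues
        straight = np.column_stack([np.arange(n) * 3.8,
                                    np.zeros(n), np.zeros(n)])
        q, formed = fraction_native(Conformation(straight), topo)
        assert q == 0.0 and formed == []

    def test_boundary_is_strict(self):
        """A contact at exactly 1.2 r0 is NOT formed (strict inequality)."""
        n = 10
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 3.8
        contacts = [(0, 4, 5.0), (0, 5, 5.0), (0, 6, 5.0), (0, 7, 5.0)]
        topo = NativeTopology(
            n_residues=n, ca_coords=coords, residue_labels=["A"] * n,
            bond_lengths_r0=np.full(n - 1, 3.8),
            angles_theta0=np.full(n - 2, np.pi),
            dihedrals_phi0=np.zeros(n - 3), contacts=contacts)
        pos = coords.copy()
        # place partners: three formed, one exactly at the 1.2 r0 boundary
        pos[4] = [2.0, 0, 0]
        pos[5] = [3.0, 0, 0]
        pos[6] = [4.0, 0, 0]
        pos[7] = [6.0, 0, 0]   # = 1.2 * 5.0 exactly
        q, _ = fraction_native(Conformation(pos), topo)
        assert q == 0.75

    def test_monotone_under_dilation(self, lasso):
        topo, conf = lasso
        centroid = conf.coords.mean(axis=0)
        q_prev = 1.0
        for scale in (1.0, 1.1, 1.3, 1.6, 2.5):
            pos = centroid + scale * (conf.coords - centroid)
            q, _ = fraction_native(Conformation(pos), topo)
            assert q <= q_prev + 1e-12
            q_prev = q


class TestRmsd:
    def test_native_to_native_is_zero(self, hairpin):
        topo, conf = hairpin
        assert rmsd_to_native(conf, topo) == pytest.approx(0.0, abs=1e-12)

    def test_superposition_invariance(self, hairpin):
        from scipy.spatial.transform import Rotation
        topo, conf = hairpin
        rot = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        moved = Conformation(conf.coords @ rot.T + np.array([10.0, 0, -4.0]))
        assert rmsd_to_native(moved, topo) == pytest.approx(0.0, abs=1e-9)

    def test_three_point_sets_match_quaternion_oracle(self):
        """Horn's closed-form quaternion solution as an independent oracle."""
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.normal(size=(3, 3))
            b = rng.normal(size=(3, 3))
            assert kabsch_rmsd(a, b) == pytest.approx(
                _quaternion_rmsd(a, b), abs=1e-6)


def _quaternion_rmsd(a, b):
    """Horn (1987) closed-form minimal RMSD via the 4x4 key matrix."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = ac.T @ bc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(key).max()
    sq = ((ac ** 2).sum() + (bc ** 2).sum() - 2.0 * lam) / len(a)
    return np.sqrt(max(sq, 0.0))
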