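import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilayerlab.structures import Configuration, Trajectory
from bilayerlab.synth import BilayerSpec, generate_bilayer
from bilayerlab.traj import (
    HbondCriterion,
    area_per_lipid,
    assign_leaflets,
    cluster_size_distribution,
    hydrogen_bonds,
    mass_density_profile,
    minimum_image,
    pp_thickness,
)
from conftest import random_hbond_configuration, random_solute_configuration
from oracles import brute_cluster_sizes, brute_hbond_count


def simple_bilayer_conf(n_per_leaflet=4, leaflet_z=1.685, box=(4.0, 4.0, 8.0),
                        shift=0.0):
    """Minimal lipid-only bilayer: one phosphorus per lipid."""
    pos, mols = [], []
    m = 0
    zc = box[2] / 2
    for sign in (1, -1):
        for i in range(n_per_leaflet):
            m += 1
            pos.append([0.5 + i, 0.5 + i, zc + sign * leaflet_z + shift])
            mols.append(m)
    n = len(pos)
    return Configuration(
        positions=np.array(pos), box=np.array(box), mol_ids=np.array(mols),
        mol_kinds=np.array(["lipid"] * n, dtype=object),
        roles=np.array(["phosphorus"] * n, dtype=object),
        masses=np.full(n, 30.974),
    )


class TestAreaPerLipid:
    def test_study_geometry(self):
        traj = generate_bilayer(BilayerSpec(jitter_sd=0.0), 2, seed=0)
        mean, sd = area_per_lipid(traj, 128)
        assert mean == pytest.approx(0.630, abs=5e-4)
        assert sd == 0.0

    def test_simple_arithmetic(self):
        spec = BilayerSpec(box=(8.0, 8.0, 9.0), jitter_sd=0.0)
        traj = generate_bilayer(spec, 1, seed=0)
        assert area_per_lipid(traj, 128)[0] == pytest.approx(1.0)

    def test_zero_or_odd_lipids_rejected(self):
        traj = generate_bilayer(BilayerSpec(), 1, seed=0)
        with pytest.raises(ValueError):
            area_per_lipid(traj, 0)
        with pytest.raises(ValueError):
            area_per_lipid(traj, 127)


class TestAssignLeaflets:
    def test_planted_even_split(self):
        conf = generate_bilayer(BilayerSpec(jitter_sd=0.0), 1, 0).frames[0]
        a = assign_leaflets(conf)
        assert a.n_upper == 64 and a.n_lower == 64
        assert not a.ambiguous

    def test_all_lipids_on_one_side_warns(self):
        conf = simple_bilayer_conf()
        conf.positions[:, 2] = 5.0  # every phosphorus on the midplane side
        with pytest.warns(UserWarning, match="degenerate"):
            a = assign_leaflets(conf)
        assert a.n_lower == 0 or a.n_upper == 0

    def test_near_plane_lipid_flagged_ambiguous(self):
        conf = simple_bilayer_conf()
        # place lipid 1 so its P ends up < 0.1 nm from the recomputed centre
        conf.positions[0, 2] = 3.80
        a = assign_leaflets(conf)
        assert 1 in a.ambiguous

    def test_lipid_without_phosphorus_rejected(self):
        conf = simple_bilayer_conf()
        conf.roles[0] = "other"
        with pytest.raises(ValueError, match="phosphorus"):
            assign_leaflets(conf)


class TestPpThickness:
    def test_planted_planes(self):
        traj = generate_bilayer(BilayerSpec(jitter_sd=0.0), 2, seed=0)
        mean, sd = pp_thickness(traj)
        assert mean == pytest.approx(3.370, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_thinned_planes(self):
        spec = BilayerSpec(leaflet_z=1.645, jitter_sd=0.0)
        traj = generate_bilayer(spec, 1, seed=0)
        assert pp_thickness(traj)[0] == pytest.approx(3.290, abs=1e-9)

    def test_jittered_mean_within_standard_error(self):
        spec = BilayerSpec(jitter_sd=0.05)
        traj = generate_bilayer(spec, 100, seed=3)
        mean, _ = pp_thickness(traj)
        tol = 3.0 * (0.05 / np.sqrt(64)) * np.sqrt(2)
        assert abs(mean - 3.370) < tol


class TestHydrogenBonds:
    def _triplet(self, d_xyz, h_xyz, a_xyz, box=(5.0, 5.0, 5.0)):
        return Configuration(
            positions=np.array([d_xyz, h_xyz, a_xyz]), box=np.array(box),
            mol_ids=np.array([1, 1, 2]),
            mol_kinds=np.array(["water"] * 3, dtype=object),
            roles=np.array(["donor", "hydrogen", "acceptor"], dtype=object),
            masses=np.ones(3))

    def test_collinear_inside_cutoffs(self):
        conf = self._triplet([1, 1, 1], [1.1, 1, 1], [1.3, 1, 1])
        assert hydrogen_bonds(conf)[0] == 1

    def test_distance_beyond_cutoff(self):
        conf = self._triplet([1, 1, 1], [1.1, 1, 1], [1.36, 1, 1])
        assert hydrogen_bonds(conf)[0] == 0

    def test_angle_beyond_cutoff(self):
        conf = self._triplet([1, 1, 1], [1, 1.1, 1], [1.3, 1, 1])  # 90°
        assert hydrogen_bonds(conf)[0] == 0

    def test_bond_across_periodic_boundary(self):
        conf = self._triplet([0.1, 1, 1], [0.0, 1, 1], [4.9, 1, 1])
        assert hydrogen_bonds(conf)[0] == 1  # min-image distance 0.2 nm

    def test_donor_without_hydrogen_names_molecule(self):
        conf = self._triplet([1, 1, 1], [1.1, 1, 1], [1.3, 1, 1])
        conf.roles[1] = "other"
        with pytest.raises(ValueError, match="molecule 1"):
            hydrogen_bonds(conf)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            conf = random_hbond_configuration(rng)
            assert hydrogen_bonds(conf)[0] == brute_hbond_count(conf)

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            HbondCriterion(r_max=-0.1)
        with pytest.raises(ValueError):
            HbondCriterion(theta_max=95.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10), st.floats(-10, 10))
    def test_translation_invariance(self, dx, dy, dz):
        conf = random_hbond_configuration(np.random.default_rng(5))
        ref = hydrogen_bonds(conf)[0]
        shifted = Configuration(
            positions=conf.positions + [dx, dy, dz], box=conf.box,
            mol_ids=conf.mol_ids, mol_kinds=conf.mol_kinds,
            roles=conf.roles, masses=conf.masses)
        assert hydrogen_bonds(shifted)[0] == ref


class TestMassDensityProfile:
    def test_uniform_filler_is_flat(self, rng):
        n = 4000
        box = np.array([4.0, 4.0, 6.0])
        pos = rng.uniform(0, 1, (n + 2, 3)) * box
        # two symmetric lipid anchors pin the recentring plane
        pos[-2] = [2, 2, 1.0]
        pos[-1] = [2, 2, 5.0]
        kinds = np.array(["water"] * n + ["lipid"] * 2, dtype=object)
        conf = Configuration(
            positions=pos, box=box, mol_ids=np.arange(n + 2),
            mol_kinds=kinds, roles=np.array(["other"] * (n + 2), dtype=object),
            masses=np.ones(n + 2))
        prof = mass_density_profile(Trajectory([conf]), kind="water",
                                    bin_width=0.5)
        expected = n / box.prod()
        lam = n / prof.z.size
        tol = 3 * np.sqrt(lam) / (box[0] * box[1] * 0.5)
        assert np.all(np.abs(prof.density - expected) < tol)

    def test_mass_conserved(self):
        traj = generate_bilayer(BilayerSpec(n_water=50), 3, seed=1)
        for kind in ("lipid", "solute"):
            prof = mass_density_profile(traj, kind=kind)
            sel = traj.frames[0].indices(kind=kind)
            total = traj.frames[0].masses[sel].sum()
            assert prof.total_mass() == pytest.approx(total, rel=1e-3)

    def test_leaflet_asymmetry_preserved(self):
        """Solute planted in one leaflet only must not appear mirrored."""
        traj = generate_bilayer(BilayerSpec(jitter_sd=0.0), 1, seed=0)
        prof = mass_density_profile(traj, kind="solute", bin_width=0.1)
        band = (prof.z >= 0.4) & (prof.z <= 1.2)
        mirror = (prof.z <= -0.4) & (prof.z >= -1.2)
        band_mass = prof.density[band].sum()
        assert band_mass > 0
        assert prof.density[mirror].sum() < 0.05 * band_mass

    def test_invalid_bin_width_rejected(self):
        traj = generate_bilayer(BilayerSpec(), 1, seed=0)
        with pytest.raises(ValueError):
            mass_density_profile(traj, kind="lipid", bin_width=0.0)


class TestClusterSizeDistribution:
    def test_all_monomer_plant(self):
        spec = BilayerSpec(planted_clusters=(1,) * 14)
        traj = generate_bilayer(spec, 1, seed=0)
        dist = cluster_size_distribution(traj)
        assert dist.molecule_histogram == {1: 14.0}
        assert dist.monomer_fraction == 1.0

    def test_planted_partition_recovered(self):
        traj = generate_bilayer(BilayerSpec(), 3, seed=2)
        dist = cluster_size_distribution(traj)
        assert dist.molecule_histogram == {1: 4.0, 3: 6.0, 4: 4.0}
        assert dist.monomer_fraction == pytest.approx(4 / 14)

    def test_chain_is_one_cluster_by_single_linkage(self):
        pos = np.array([[1.0, 1, 1], [1.2, 1, 1], [1.4, 1, 1]])
        conf = Configuration(
            positions=pos, box=np.array([5.0, 5.0, 5.0]),
            mol_ids=np.array([1, 2, 3]),
            mol_kinds=np.array(["solute"] * 3, dtype=object),
            roles=np.array(["other"] * 3, dtype=object), masses=np.ones(3))
        dist = cluster_size_distribution(Trajectory([conf]))
        assert dist.cluster_histogram == {3: 1.0}

    def test_molecule_count_conserved_every_frame(self):
        traj = generate_bilayer(BilayerSpec(), 3, seed=4)
        dist = cluster_size_distribution(traj)
        for hist in dist.per_frame:
            assert sum(s * c for s, c in hist.items()) == 14

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            conf = random_solute_configuration(rng)
            dist = cluster_size_distribution(Trajectory([conf]))
            sizes = sorted(
                s for s, c in dist.per_frame[0].items() for _ in range(c))
            assert sizes == brute_cluster_sizes(conf)

    def test_centroid_metric_differs_from_contact_metric(self):
        # two molecules touching via one atom pair but with far centroids
        pos = np.array([[1.0, 1, 1], [1.6, 1, 1],
                        [1.84, 1, 1], [2.44, 1, 1]])
        conf = Configuration(
            positions=pos, box=np.array([6.0, 6.0, 6.0]),
            mol_ids=np.array([1, 1, 2, 2]),
            mol_kinds=np.array(["solute"] * 4, dtype=object),
            roles=np.array(["other"] * 4, dtype=object), masses=np.ones(4))
        traj = Trajectory([conf])
        by_contact = cluster_size_distribution(traj, method="atom_min")
        by_centroid = cluster_size_distribution(traj, method="centroid")
        assert by_contact.cluster_histogram == {2: 1.0}
        assert by_centroid.cluster_histogram == {1: 2.0}

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(-7, 7), st.floats(-7, 7), st.floats(-7, 7))
    def test_translation_invariance(self, dx, dy, dz):
        conf = random_solute_configuration(np.random.default_rng(9))
        ref = cluster_size_distribution(Trajectory([conf])).cluster_histogram
        shifted = Configuration(
            positions=conf.positions + [dx, dy, dz], box=conf.box,
            mol_ids=conf.mol_ids, mol_kinds=conf.mol_kinds,
            roles=conf.roles, masses=conf.masses)
        got = cluster_size_distribution(Trajectory([shifted]))
        assert got.cluster_histogram == ref


class TestMinimumImage:
    def test_half_box_wrap(self):
        box = np.array([4.0, 4.0, 4.0])
        d = minimum_image(np.array([3.9, 0.1, -3.9]), box)
        assert np.allclose(d, [-0.1, 0.1, 0.1])
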