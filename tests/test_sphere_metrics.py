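"""Correspondence, sphere extraction and optimal superposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import grid_min_rmsd, sphere_membership
from rnasphere.fixtures import HelixParams, PerturbationSpec, generate_helix, perturb
from rnasphere.sphere_metrics import (
    ALL_ATOMS,
    CENTER_ATOMS_ONLY,
    CorrespondenceError,
    InsufficientAtomsError,
    SphereGap,
    SphereNeighborhood,
    SphereSpec,
    extract_sphere,
    global_rmsd,
    kabsch_superpose,
    match_atoms,
    sphere_rmsd,
)
from rnasphere.structure_io import Atom, Residue, Structure


def make_structure(points, names=None, chain="A"):
    """One residue per point unless names given: then one residue, many atoms."""
    if names is not None:
        residue = Residue(chain, 1, "", "G")
        for i, (name, p) in enumerate(zip(names, points)):
            residue.atoms.append(Atom(i + 1, name, name[0], "", 1.0, np.asarray(p, float)))
        return Structure(id="pts", residues=[residue])
    residues = []
    for i, p in enumerate(points):
        residue = Residue(chain, i + 1, "", "G")
        residue.atoms.append(Atom(i + 1, "C1'", "C", "", 1.0, np.asarray(p, float)))
        residues.append(residue)
    return Structure(id="pts", residues=residues)


class TestMatchAtoms:
    def test_identity_pairs_everything(self, helix10):
        corr = match_atoms(helix10, helix10)
        assert corr.n_pairs == helix10.n_atoms()
        assert corr.unmatched_reference == []
        assert corr.unmatched_model == []

    def test_missing_model_atom_reported_not_dropped(self, helix10):
        decoy = perturb(
            helix10,
            PerturbationSpec(
                kind="atom_deletion",
                target=(("A", 5, ""),),
                atom_names=("O2'",),
            ),
        )
        corr = match_atoms(helix10, decoy)
        assert corr.n_pairs == helix10.n_atoms() - 1
        assert corr.unmatched_reference == [("A", 5, "", "O2'")]
        assert corr.unmatched_model == []

    def test_disjoint_chains_fail(self, helix10):
        other = generate_helix(HelixParams(n_residues=10, seed=11, chain_id="B"))
        with pytest.raises(CorrespondenceError):
            match_atoms(helix10, other)


class TestExtractSphere:
    def test_tiny_radius_keeps_only_the_center(self, helix10):
        sphere = extract_sphere(
            helix10, ("A", 3, ""), SphereSpec(radius=0.5)
        )
        assert isinstance(sphere, SphereNeighborhood)
        assert sphere.member_atoms == [("A", 3, "", "C1'")]

    def test_huge_radius_covers_the_molecule(self, helix10):
        sphere = extract_sphere(helix10, ("A", 3, ""), SphereSpec(radius=1e4))
        assert sphere.member_atoms == helix10.atom_keys()

    def test_closed_ball_boundary(self):
        structure = make_structure(
            [[0, 0, 0], [2.9, 0, 0], [3.1, 0, 0]], names=["C1'", "P", "O3'"]
        )
        sphere = extract_sphere(structure, ("A", 1, ""), SphereSpec(radius=3.0))
        assert sphere.member_atoms == [("A", 1, "", "C1'"), ("A", 1, "", "P")]

    def test_center_only_mode_restricts_membership(self, helix10):
        sphere = extract_sphere(
            helix10,
            ("A", 3, ""),
            SphereSpec(radius=1e4, mode=CENTER_ATOMS_ONLY),
        )
        assert all(key[3] == "C1'" for key in sphere.member_atoms)
        assert len(sphere.member_atoms) == len(helix10.residues)

    def test_missing_center_atom_yields_gap(self, helix10):
        stripped = perturb(
            helix10,
            PerturbationSpec(kind="atom_deletion", target=(("A", 3, ""),), atom_names=("C1'",)),
        )
        gap = extract_sphere(stripped, ("A", 3, ""), SphereSpec(radius=5.0))
        assert isinstance(gap, SphereGap)
        assert gap.reason == "missing_center"

    def test_membership_monotone_in_radius(self, helix20):
        for r1, r2 in [(3.0, 8.0), (8.0, 20.0), (20.0, 300.0)]:
            small = extract_sphere(helix20, ("A", 10, ""), SphereSpec(radius=r1))
            large = extract_sphere(helix20, ("A", 10, ""), SphereSpec(radius=r2))
            assert set(small.member_atoms) <= set(large.member_atoms)

    def test_membership_matches_pairwise_distance_oracle(self, helix20):
        coords = np.array([a.coords for _, a in helix20.iter_atoms()])
        keys = helix20.atom_keys()
        center = helix20.get_residue(("A", 7, "")).get_atom("C1'").coords
        for radius in (3.0, 8.0, 20.0):
            sphere = extract_sphere(helix20, ("A", 7, ""), SphereSpec(radius=radius))
            expected = [k for k, m in zip(keys, sphere_membership(coords, center, radius)) if m]
            assert sphere.member_atoms == expected


class TestKabschSuperpose:
    def test_identical_sets_give_exact_zero_and_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        result = kabsch_superpose(pts, pts)
        assert result.rmsd == 0.0
        np.testing.assert_array_equal(result.rotation, np.eye(3))

    def test_rigid_motion_is_fully_recovered(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(7, 3)) * 4
        angle = np.pi / 2
        rot = np.array(
            [[np.cos(angle), -np.sin(angle), 0], [np.sin(angle), np.cos(angle), 0], [0, 0, 1]]
        )
        mov = (rot @ ref.T).T + np.array([5.0, -2.0, 7.0])
        result = kabsch_superpose(ref, mov)
        assert result.rmsd < 1e-9
        assert abs(np.linalg.det(result.rotation) - 1.0) < 1e-9

    def test_displaced_point_matches_grid_oracle(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(4, 3)) * 3
        mov = ref.copy()
        mov[2] += [1.5, -0.5, 0.8]
        result = kabsch_superpose(ref, mov)
        oracle = grid_min_rmsd(ref, mov)
        assert result.rmsd <= oracle + 1e-9
        assert abs(result.rmsd - oracle) < 1e-3

    def test_reflection_never_returned_even_when_it_fits_better(self):
        # a chiral 4-point set against its mirror image: the perfect fit is
        # improper, so the proper optimum must be strictly worse than zero
        ref = np.array(
            [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 1.0]]
        )
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        result = kabsch_superpose(ref, mirrored)
        assert abs(np.linalg.det(result.rotation) - 1.0) < 1e-9
        assert result.rmsd > 0.1
        oracle = grid_min_rmsd(ref, mirrored)
        assert abs(result.rmsd - oracle) < 1e-3

    def test_collinear_sets_are_flagged_degenerate(self):
        line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        result = kabsch_superpose(line, line + 1.0)
        assert result.degenerate
        assert result.rmsd < 1e-9
        assert abs(np.linalg.det(result.rotation) - 1.0) < 1e-9

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientAtomsError):
            kabsch_superpose([[0, 0, 0], [1, 1, 1]], [[0, 0, 0], [1, 1, 1]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_sets_never_beat_the_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ref = rng.normal(size=(n, 3)) * 3
        mov = rng.normal(size=(n, 3)) * 3
        result = kabsch_superpose(ref, mov)
        oracle = grid_min_rmsd(ref, mov)
        assert result.rmsd <= oracle + 1e-9
        assert abs(result.rmsd - oracle) < 1e-3

    def test_cross_check_against_biopython_superimposer(self):
        svd = pytest.importorskip("Bio.SVDSuperimposer")
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3)) * 5
        mov = ref + rng.normal(size=(10, 3)) * 0.7
        ours = kabsch_superpose(ref, mov)
        sup = svd.SVDSuperimposer()
        sup.set(ref, mov)
        sup.run()
        assert abs(ours.rmsd - sup.get_rms()) < 1e-9


class TestSphereRmsd:
    def test_self_comparison_zero_at_every_radius(self, helix10):
        corr = match_atoms(helix10, helix10)
        for radius in (3.0, 8.0, 300.0):
            result = sphere_rmsd(
                helix10, helix10, corr, ("A", 4, ""), SphereSpec(radius=radius)
            )
            assert result.rmsd == 0.0
            assert result.coverage == 1.0

    def test_rigid_motion_invisible(self, helix10):
        decoy = perturb(helix10, PerturbationSpec(kind="rigid_motion", magnitude=8.0, seed=9))
        corr = match_atoms(helix10, decoy)
        for radius in (3.0, 8.0, 300.0):
            result = sphere_rmsd(
                helix10, decoy, corr, ("A", 6, ""), SphereSpec(radius=radius)
            )
            assert result.rmsd < 1e-6

    def test_local_displacement_seen_only_by_spheres_that_reach_it(self, helix20):
        target = ("A", 10, "")
        decoy = perturb(
            helix20,
            PerturbationSpec(kind="residue_displacement", magnitude=2.0, target=(target,), seed=4),
        )
        corr = match_atoms(helix20, decoy)
        # a sphere far from residue 10 and too small to reach it: exact zero
        far = sphere_rmsd(helix20, decoy, corr, ("A", 1, ""), SphereSpec(radius=3.0))
        far_sphere = extract_sphere(helix20, ("A", 1, ""), SphereSpec(radius=3.0))
        assert all(key[:3] != target for key in far_sphere.member_atoms)
        assert far.rmsd == 0.0
        # a sphere mixing displaced and undisplaced atoms: positive, and
        # equal to the independent grid-search optimum
        near = sphere_rmsd(helix20, decoy, corr, target, SphereSpec(radius=8.0))
        near_sphere = extract_sphere(helix20, target, SphereSpec(radius=8.0))
        member_keys = set(near_sphere.member_atoms)
        assert any(key[:3] == target for key in member_keys)
        assert any(key[:3] != target for key in member_keys)
        assert near.rmsd > 0.05
        ref_atoms = helix20.atom_table()
        decoy_atoms = decoy.atom_table()
        ref_coords = np.array([ref_atoms[k].coords for k in near_sphere.member_atoms])
        mov_coords = np.array([decoy_atoms[k].coords for k in near_sphere.member_atoms])
        assert abs(near.rmsd - grid_min_rmsd(ref_coords, mov_coords)) < 1e-3

    def test_missing_center_and_sparse_pairs_are_gaps(self, helix10):
        no_center = perturb(
            helix10,
            PerturbationSpec(kind="atom_deletion", target=(("A", 2, ""),), atom_names=("C1'",)),
        )
        corr = match_atoms(no_center, helix10)
        gap = sphere_rmsd(no_center, helix10, corr, ("A", 2, ""), SphereSpec(radius=5.0))
        assert isinstance(gap, SphereGap) and gap.reason == "missing_center"

        sparse = perturb(
            helix10,
            PerturbationSpec(
                kind="atom_deletion",
                target=(("A", 5, ""),),
                atom_names=tuple(n for n in [a.name for a in helix10.residues[4].atoms] if n != "C1'"),
            ),
        )
        corr = match_atoms(helix10, sparse)
        gap = sphere_rmsd(helix10, sparse, corr, ("A", 5, ""), SphereSpec(radius=1.0))
        assert isinstance(gap, SphereGap) and gap.reason == "insufficient_pairs"

    def test_coverage_counts_unpaired_members(self, helix10):
        decoy = perturb(
            helix10,
            PerturbationSpec(kind="atom_deletion", target=(("A", 4, ""),), atom_names=("P", "OP1")),
        )
        corr = match_atoms(helix10, decoy)
        sphere = extract_sphere(helix10, ("A", 4, ""), SphereSpec(radius=6.0))
        deleted = {("A", 4, "", "P"), ("A", 4, "", "OP1")}
        inside = deleted & set(sphere.member_atoms)
        result = sphere_rmsd(helix10, decoy, corr, ("A", 4, ""), SphereSpec(radius=6.0))
        expected = (len(sphere.member_atoms) - len(inside)) / len(sphere.member_atoms)
        assert result.coverage == pytest.approx(expected)
        assert result.coverage < 1.0


class TestGlobalRmsd:
    def test_self_is_zero(self, helix10):
        corr = match_atoms(helix10, helix10)
        assert global_rmsd(helix10, helix10, corr).rmsd == 0.0

    def test_equals_sphere_at_covering_radius_bitwise(self, helix20, noisy_decoy):
        helix20_decoy = noisy_decoy
        corr = match_atoms(helix20, helix20_decoy)
        reference_value = global_rmsd(helix20, helix20_decoy, corr).rmsd
        for residue in helix20.residues:
            cell = sphere_rmsd(
                helix20, helix20_decoy, corr, residue.key, SphereSpec(radius=300.0)
            )
            assert cell.rmsd == reference_value  # identical atom set, same path

    def test_matches_grid_oracle_on_perturbed_fixture(self, helix10):
        decoy = perturb(helix10, PerturbationSpec(kind="gaussian_noise", magnitude=1.5, seed=12))
        corr = match_atoms(helix10, decoy)
        ours = global_rmsd(helix10, decoy, corr).rmsd
        ref = np.array([a.coords for _, a in helix10.iter_atoms()])
        mov = np.array([a.coords for _, a in decoy.iter_atoms()])
        assert abs(ours - grid_min_rmsd(ref, mov)) < 1e-3

    def test_center_only_mode_uses_one_atom_per_residue(self, helix10, noisy_decoy):
        decoy = perturb(helix10, PerturbationSpec(kind="gaussian_noise", magnitude=1.0, seed=2))
        corr = match_atoms(helix10, decoy)
        result = global_rmsd(helix10, decoy, corr, mode=CENTER_ATOMS_ONLY)
        assert result.n_atoms == len(helix10.residues)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_rigid_motion_invariance_property(seed):
    """Any proper rigid motion of a structure scores zero at every sphere."""
    helix = generate_helix(HelixParams(n_residues=8, seed=3))
    decoy = perturb(helix, PerturbationSpec(kind="rigid_motion", magnitude=10.0, seed=seed))
    corr = match_atoms(helix, decoy)
    for residue in helix.residues[::3]:
        for radius in (3.0, 20.0):
            cell = sphere_rmsd(helix, decoy, corr, residue.key, SphereSpec(radius=radius))
            assert cell.rmsd < 1e-6
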