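"""Geometry: SASA/burial, interfaces, cavities, superposition, profiling."""

import numpy as np
import pandas as pd
import pytest

from scamap import (
    DomainPartition,
    StructureModel,
    SyntheticStructureSpec,
    annotate_sectors,
    bfactor_summary,
    burial_fraction,
    compute_sasa,
    detect_cavities,
    gen_toy_structure,
    interface_area,
    per_residue_rmsd,
    perturb_conformer,
    rama_fractions,
    read_structure,
    site_depth,
    superpose,
    write_structure,
)
from scamap.sca import Sector, SectorSet
from scamap.structure import Superposition, _kabsch
from scamap.synthetic import _atom_array

R_C = 1.7  # carbon vdW radius from the shipped table
PROBE = 1.4


def atoms_at(coords, chain="A", names=None, elements=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(
        _atom_array(
            coords,
            [chain] * n,
            list(range(1, n + 1)),
            names or ["CA"] * n,
            elements or ["C"] * n,
        )
    )


class TestReadWrite:
    def test_three_atom_fixture_exact(self, tmp_path):
        s = atoms_at([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 2.25, -1.125]])
        p = tmp_path / "three.pdb"
        write_structure(s, p)
        back = read_structure(p)
        assert back.n_atoms == 3
        assert np.abs(back.atoms.coord - s.atoms.coord).max() <= 0.001

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.40 10.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(pdb)
        s = read_structure(p)
        assert s.n_atoms == 1
        assert s.atoms.coord[0, 0] == pytest.approx(0.0)

    def test_garbage_rejected(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("ATOM this is not a valid record\n")
        with pytest.raises(ValueError):
            read_structure(p)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = atoms_at([[0.0, 0.0, 0.0]])
        res = compute_sasa(s, probe=PROBE, n_points=960)
        expected = 4 * np.pi * (R_C + PROBE) ** 2
        assert res.atom_sasa[0] == pytest.approx(expected, rel=0.01)

    def test_distant_atoms_noninteracting(self):
        d = 2 * (R_C + PROBE) + 0.5
        s = atoms_at([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        res = compute_sasa(s)
        expected = 4 * np.pi * (R_C + PROBE) ** 2
        assert np.allclose(res.atom_sasa, expected, rtol=0.01)

    def test_overlapping_spheres_vs_monte_carlo(self):
        """Two overlapping spheres at 2 A vs a dense Monte-Carlo surface
        oracle (accessible fraction of each sphere's probe-extended
        surface)."""
        d = 2.0
        s = atoms_at([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        res = compute_sasa(s, n_points=960)
        centers = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        R = R_C + PROBE
        rng = np.random.default_rng(0)
        mc = []
        for i, c in enumerate(centers):
            pts = rng.standard_normal((1_000_000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = c + R * pts
            other = centers[1 - i]
            free = np.linalg.norm(pts - other, axis=1) > R
            mc.append(free.mean() * 4 * np.pi * R**2)
        assert np.allclose(res.atom_sasa, mc, rtol=0.02)

    def test_point_doubling_convergence(self, hollow_shell):
        shell, _ = hollow_shell
        a = compute_sasa(shell, n_points=960).atom_sasa.sum()
        b = compute_sasa(shell, n_points=1920).atom_sasa.sum()
        assert abs(a - b) / b <= 0.01

    def test_unknown_element_warns(self):
        s = atoms_at([[0.0, 0.0, 0.0]], elements=["QQ"])
        with pytest.warns(UserWarning, match="unknown element"):
            compute_sasa(s)


class TestBurial:
    def test_globule_core_fully_buried(self, globule):
        glob, truth = globule
        sasa = compute_sasa(glob)
        assert burial_fraction(truth["core_residues"], sasa) == 1.0

    def test_extended_peptide_fully_exposed(self):
        strand, _ = gen_toy_structure(
            SyntheticStructureSpec(kind="canonical-strand", n_residues=15)
        )
        sasa = compute_sasa(strand)
        assert burial_fraction(strand.residue_keys(), sasa) == 0.0

    def test_empty_set_flagged(self, globule):
        glob, _ = globule
        sasa = compute_sasa(glob)
        with pytest.warns(UserWarning):
            assert np.isnan(burial_fraction([], sasa))


class TestInterface:
    def test_separated_domains_zero(self):
        td, truth = gen_toy_structure(
            SyntheticStructureSpec(kind="two-domain", separation=26.0, domain_radius=6.0)
        )
        assert truth["interface_zero"]
        area = interface_area(td, truth["chain_a_residues"], truth["chain_b_residues"])
        assert abs(area["total_buried"]) <= 0.1

    def test_touching_domains_match_high_resolution_oracle(self):
        td, truth = gen_toy_structure(
            SyntheticStructureSpec(kind="two-domain", separation=13.0, domain_radius=6.0)
        )
        a = interface_area(td, truth["chain_a_residues"], truth["chain_b_residues"],
                           n_points=960)
        oracle = interface_area(td, truth["chain_a_residues"], truth["chain_b_residues"],
                                n_points=9600)
        assert a["total_buried"] > 50.0
        assert a["total_buried"] == pytest.approx(oracle["total_buried"], rel=0.02)
        assert a["one_sided"] == pytest.approx(a["total_buried"] / 2)

    def test_symmetric_in_sets(self):
        td, truth = gen_toy_structure(
            SyntheticStructureSpec(kind="two-domain", separation=13.0, domain_radius=6.0)
        )
        ab = interface_area(td, truth["chain_a_residues"], truth["chain_b_residues"])
        ba = interface_area(td, truth["chain_b_residues"], truth["chain_a_residues"])
        assert ab["total_buried"] == pytest.approx(ba["total_buried"], abs=1e-6)

    def test_overlapping_sets_rejected(self, globule):
        glob, _ = globule
        with pytest.raises(ValueError, match="overlap"):
            interface_area(glob, [("A", 1)], [("A", 1)])


class TestCavities:
    def test_solid_block_has_no_cavities(self):
        glob, _ = gen_toy_structure(
            SyntheticStructureSpec(kind="globule", globule_radius=8.0)
        )
        assert len(detect_cavities(glob)) == 0

    def test_hollow_shell_single_cavity_matches_oracle(self, hollow_shell):
        shell, truth = hollow_shell
        cs = detect_cavities(shell)
        assert len(cs) == 1
        cav = cs.cavities[0]
        oracle = truth["cavity_volume_oracle"]
        assert abs(cav.volume - oracle) / oracle <= 0.10
        assert len(cav.lining_residues) > 0
        assert cav.depth > 0

    def test_grid_convergence(self, hollow_shell):
        shell, _ = hollow_shell
        v05 = detect_cavities(shell, grid=0.5).cavities[0].volume
        v025 = detect_cavities(shell, grid=0.25).cavities[0].volume
        assert abs(v05 - v025) / v025 <= 0.10

    def test_volume_monotone_under_radius_inflation(self, hollow_shell):
        shell, _ = hollow_shell
        import scamap.constants as const

        base = detect_cavities(shell).cavities[0].volume
        original = const.VDW_RADII["C"]
        try:
            const.VDW_RADII["C"] = original + 0.3
            inflated_set = detect_cavities(shell)
        finally:
            const.VDW_RADII["C"] = original
        assert len(inflated_set) == 1
        assert inflated_set.cavities[0].volume <= base

    def test_too_coarse_grid_rejected(self, hollow_shell):
        shell, _ = hollow_shell
        with pytest.raises(ValueError):
            detect_cavities(shell, grid=2.0)


class TestSiteDepth:
    def test_bulk_point_zero(self, hollow_shell):
        shell, _ = hollow_shell
        assert site_depth(shell, [0.0, 0.0, 10.5]) == 0.0

    def test_shell_center_depth_matches_geometry(self, hollow_shell):
        shell, truth = hollow_shell
        depth = site_depth(shell, [0.0, 0.0, 0.0])
        # bulk solvent first reachable just outside the wall:
        # wall radius + carbon vdW, within one grid spacing
        expected = truth["wall_center_radius"] + R_C
        assert depth == pytest.approx(expected, abs=0.5 + 0.5)


class TestSuperposition:
    def test_rigid_motion_recovered_exactly(self, rng):
        from scipy.spatial.transform import Rotation

        ref = rng.standard_normal((50, 3)) * 10
        R = Rotation.from_euler("zyx", [10.0, -40.0, 75.0], degrees=True).as_matrix()
        t = np.array([1.0, -2.0, 3.0])
        mob = ref @ R.T + t
        sup = _kabsch(ref, mob)
        assert sup.rmsd < 1e-9
        assert np.allclose(sup.rotation @ R, np.eye(3), atol=1e-9)

    def test_reflection_suppressed(self, rng):
        ref = rng.standard_normal((30, 3))
        mob = ref.copy()
        mob[:, 0] *= -1  # mirrored
        sup = _kabsch(ref, mob)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_noise_rmsd_scale(self, rng):
        sigma = 0.3
        ref = rng.standard_normal((500, 3)) * 20
        mob = ref + rng.normal(0, sigma, ref.shape)
        sup = _kabsch(ref, mob)
        assert sup.rmsd == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_optimal_among_random_rigid_placements(self, rng):
        from scipy.spatial.transform import Rotation

        ref = rng.standard_normal((40, 3)) * 5
        mob = ref + rng.normal(0, 0.5, ref.shape)
        best = _kabsch(ref, mob).rmsd
        for _ in range(100):
            R = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(0, 2, 3)
            moved = mob @ R.T + t
            rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
            assert best <= rmsd + 1e-12

    def test_too_few_pairs_rejected(self, globule):
        glob, _ = globule
        with pytest.raises(ValueError, match="3 atom pairs"):
            superpose(glob, glob, atom_pairing=(np.zeros((2, 3)), np.zeros((2, 3))))


class TestPerResidueRmsd:
    def test_identity_profile_is_zero(self, globule):
        glob, _ = globule
        prof = per_residue_rmsd(glob, glob)
        assert prof.per_residue.max() < 1e-6
        assert prof.global_rmsd < 1e-6

    def test_constructed_displacement_recovered(self, globule):
        glob, _ = globule
        moved, truth = perturb_conformer(glob, {("A", 7): (0.0, 3.0, 0.0)}, sigma=0.0)
        anchor = [(c, r) for c, r, _ in glob.residue_keys() if r != 7]
        ref = glob.atoms.coord[glob.residue_mask(anchor)].astype(float)
        mob = moved.atoms.coord[moved.residue_mask(anchor)].astype(float)
        prof = per_residue_rmsd(glob, moved, superpose(glob, moved, (ref, mob)))
        assert prof.per_residue[("A", 7, "")] == pytest.approx(3.0, abs=1e-6)
        assert prof.per_residue.drop(("A", 7, "")).max() < 1e-6


class TestProfiles:
    def test_uniform_bfactor(self, globule):
        glob, _ = globule
        n = len(glob.residue_keys())
        part = DomainPartition({"all": [("A", 1, n)]})
        df = bfactor_summary(glob, part)
        assert df.loc[0, "mean_b"] == pytest.approx(20.0)
        assert df.loc[0, "z_score"] == 0.0

    def test_hot_domain_has_max_mean(self, globule):
        glob, _ = globule
        arr = glob.atoms.copy()
        bf = np.where(arr.res_id <= 50, 60.0, 20.0)
        arr.set_annotation("b_factor", bf)
        s = StructureModel(arr)
        n = len(s.residue_keys())
        part = DomainPartition({"hot": [("A", 1, 50)], "cold": [("A", 51, n)]})
        df = bfactor_summary(s, part).set_index("domain")
        assert df.loc["hot", "mean_b"] > df.loc["cold", "mean_b"]
        assert df.loc["hot", "z_score"] > 0 > df.loc["cold", "z_score"]

    def test_canonical_helix_all_alpha(self):
        s, _ = gen_toy_structure(
            SyntheticStructureSpec(kind="canonical-helix", n_residues=20)
        )
        part = DomainPartition({"all": [("A", 1, 20)]})
        df = rama_fractions(s, part)
        assert df.loc[0, "alpha_fraction"] == 1.0
        assert df.loc[0, "beta_fraction"] == 0.0

    def test_canonical_strand_all_beta(self):
        s, _ = gen_toy_structure(
            SyntheticStructureSpec(kind="canonical-strand", n_residues=20)
        )
        part = DomainPartition({"all": [("A", 1, 20)]})
        df = rama_fractions(s, part)
        assert df.loc[0, "beta_fraction"] == 1.0

    def test_partition_overlap_rejected(self):
        with pytest.raises(ValueError, match="two ranges"):
            DomainPartition({"a": [("A", 1, 10)], "b": [("A", 10, 20)]})


class TestAnchorsFromStructures:
    def test_conformer_pair_yields_monotonic_anchors(self, globule):
        from scamap import perturb_conformer
        from scamap.alignment import ReferenceMap
        from scamap.structure import anchor_pairing_from_structures

        glob, _ = globule
        moved, _ = perturb_conformer(glob, sigma=0.05, seed=2)
        n = len(glob.residue_keys())
        rm = ReferenceMap("x", {i: i + 1 for i in range(n)})
        ap = anchor_pairing_from_structures(glob, moved, rm, rm)
        assert len(ap.pairs) == n  # every residue pairs within 5 A
        a_cols, b_cols = zip(*ap.pairs)
        assert list(a_cols) == sorted(a_cols)
        assert list(b_cols) == sorted(b_cols)


class TestAnnotateSectors:
    def _sector(self, label, positions):
        return Sector(label, tuple(positions), {p: 1.0 for p in positions}, 0)

    def test_core_sector_fully_buried(self, globule):
        glob, truth = globule
        sasa = compute_sasa(glob)
        core_ids = [r for _, r in truth["core_residues"]]
        ss = SectorSet([self._sector("sector_1", core_ids[:20])], "test")
        rep = annotate_sectors(ss, None, glob, sasa)
        assert rep["sectors"]["sector_1"]["burial_fraction"] == 1.0

    def test_disjoint_cavity_overlap_zero(self, hollow_shell):
        shell, _ = hollow_shell
        sasa = compute_sasa(shell)
        cavities = detect_cavities(shell)
        # the shell's single cavity is lined by every atom; use positions that
        # do not exist on the structure for the disjoint case
        ss = SectorSet([self._sector("sector_1", [9000, 9001])], "test")
        rep = annotate_sectors(ss, None, shell, sasa, cavities=cavities)
        assert rep["sectors"]["sector_1"]["cavity_overlap"]["cavity_1"] == 0.0
        assert rep["sectors"]["sector_1"]["unmapped_positions"] == [9000, 9001]

    def test_bookkeeping_matches_generator_truth(self, globule):
        glob, truth = globule
        sasa = compute_sasa(glob)
        core_ids = [r for _, r in truth["core_residues"]][:15]
        surface = [
            r for _, r, _ in glob.residue_keys()
            if ("A", r) not in set(truth["core_residues"])
        ][:15]
        ss = SectorSet(
            [self._sector("sector_1", core_ids), self._sector("sector_2", surface)],
            "test",
        )
        n = len(glob.residue_keys())
        part = DomainPartition({"all": [("A", 1, n)]})
        rep = annotate_sectors(ss, None, glob, sasa, partition=part)
        assert rep["sectors"]["sector_1"]["size"] == 15
        assert rep["sectors"]["sector_1"]["burial_fraction"] == 1.0
        assert rep["sectors"]["sector_1"]["domain_composition"] == {"all": 15}
        assert rep["pairwise_overlap"][("sector_1", "sector_2")] == 0.0
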