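import numpy as np
import pytest

from fibrilkit._geom import dihedral, rotation_matrix
from fibrilkit.fibril_builder import build_peptide_chain
from fibrilkit.io_core import ChainTopology, Frame, Residue, Trajectory
from fibrilkit.structure_metrics import (
    assign_secondary_structure,
    backbone_and_sidechain_dihedrals,
    circular_stats,
    end_to_end_classify,
    helicity_profile,
    radius_of_gyration,
    residue_contact_map,
    spacing_metrics,
)
from fibrilkit.synthetic_data import perturb_fibril


def _peptide_traj(sequence, phi, psi, n_frames=1):
    coords, atoms = build_peptide_chain(sequence, phi, psi)
    top = ChainTopology(
        "A", [Residue(sequence[i], i + 1, atoms[i]) for i in range(len(sequence))]
    )
    frames = [Frame(coords.copy(), time=float(k)) for k in range(n_frames)]
    return Trajectory([top], frames)


class TestCircularStats:
    def test_wraparound_mean(self):
        assert circular_stats([179.0, -179.0]).mean == pytest.approx(180.0)

    def test_singleton(self):
        assert circular_stats([-65.0]).mean == pytest.approx(-65.0)

    def test_wrapped_normal_monte_carlo(self, rng):
        draws = rng.normal(136.0, 10.0, 10_000)
        draws = (draws + 180.0) % 360.0 - 180.0
        st = circular_stats(draws)
        assert st.mean == pytest.approx(136.0, abs=1.0)
        assert st.sd == pytest.approx(10.0, abs=1.0)
        assert st.mode == pytest.approx(136.0, abs=5.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            circular_stats([])


class TestDihedrals:
    def test_planar_zigzag_is_trans(self):
        # four atoms in a plane, zigzag: torsion exactly 180
        p = [[0, 0, 0], [1, 1, 0], [2, 0, 0], [3, 1, 0]]
        assert dihedral(*p) == pytest.approx(180.0)

    def test_terminal_residues_flagged_missing(self, bt_lattice):
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        dih = backbone_and_sidechain_dihedrals(traj)
        n_res = bt_lattice.topologies[0].n_residues
        assert np.isnan(dih.values["phi"][0, 0])  # first residue: no phi
        assert np.isnan(dih.values["psi"][0, n_res - 1])  # last: no psi

    def test_lattice_conformer_means(self, bt_lattice):
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        dih = backbone_and_sidechain_dihedrals(traj, lattice=bt_lattice)
        a = bt_lattice.interior_strand_residues("a")
        b = bt_lattice.interior_strand_residues("b")
        assert circular_stats(dih.select("psi", pairs=a)).mean == pytest.approx(136, abs=0.5)
        assert circular_stats(dih.select("chi1", pairs=b)).mean == pytest.approx(55, abs=0.5)

    def test_conformer_label_selection(self, bt_lattice):
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        dih = backbone_and_sidechain_dihedrals(traj, lattice=bt_lattice)
        vals = dih.select("chi1", conformer="a")
        assert circular_stats(vals).mean == pytest.approx(-65.0, abs=0.5)

    def test_missing_sidechain_gives_nan_chi(self):
        traj = _peptide_traj(["ALA"] * 4, [-140.0] * 4, [140.0] * 4)
        dih = backbone_and_sidechain_dihedrals(traj)
        assert np.isnan(dih.values["chi1"]).all()


class TestSpacing:
    def test_recovers_configured_spacings(self, bt_lattice):
        sm = spacing_metrics(bt_lattice)
        assert sm.strand_spacing == pytest.approx(4.8, abs=0.3)
        assert sm.sheet_spacing == pytest.approx(8.2, abs=0.3)

    def test_noise_keeps_means_adds_spread(self, bt_lattice):
        clean = spacing_metrics(bt_lattice)
        traj = perturb_fibril(bt_lattice, sigma=0.2, n_frames=10, seed=7)
        noisy = spacing_metrics(traj, strands=bt_lattice.strands)
        assert noisy.strand_spacing == pytest.approx(clean.strand_spacing, abs=0.1)
        assert noisy.sheet_spacing == pytest.approx(clean.sheet_spacing, abs=0.1)
        assert noisy.strand_spacing_sd > 0

    def test_single_sheet_flags_sheet_spacing(self):
        import warnings as w

        from fibrilkit.fibril_builder import ClashWarning, LatticeSpec, build_lattice

        with w.catch_warnings():
            w.simplefilter("ignore", ClashWarning)
            lat = build_lattice(
                LatticeSpec(model="BT", arrangement="A1", n_sheets=1,
                            n_chains_per_sheet=2)
            )
        sm = spacing_metrics(lat)
        assert sm.sheet_spacing is None
        assert sm.strand_spacing is not None


class TestSecondaryStructure:
    def test_ideal_helix(self):
        traj = _peptide_traj(["ALA"] * 12, [-57.0] * 12, [-47.0] * 12)
        ss = assign_secondary_structure(traj)
        assert (ss.states[0] == "H").sum() >= 8

    def test_two_residue_chain_all_coil(self):
        traj = _peptide_traj(["ALA"] * 2, [-57.0] * 2, [-47.0] * 2)
        ss = assign_secondary_structure(traj)
        assert set(ss.states[0]) == {"C"}

    def test_bt_lattice_strands_detected(self, bt_lattice):
        # strand residues pick up E via inter-strand bridges; linker residues
        # stay out of E (idealized rigid strands H-bond only partially, so the
        # per-chain E fraction sits below the nominal 12/16 strand content)
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        ss = assign_secondary_structure(traj)
        n_res = bt_lattice.topologies[0].n_residues
        states = ss.states[0].reshape(bt_lattice.n_chains, n_res)
        strand_res = [r for s in bt_lattice.strands[0] for r in s.residues]
        linker_res = [p for p in range(n_res) if p not in strand_res]
        e_per_chain = (states == "E").sum(axis=1)
        assert e_per_chain.mean() >= 4  # at least a third of strand residues
        assert not np.any(states[:, linker_res] == "E")

    def test_fractions_sum_to_one(self, bt_lattice):
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        ss = assign_secondary_structure(traj)
        total = sum(ss.per_residue_fraction(s) for s in "HETC")
        np.testing.assert_allclose(total, 1.0)

    def test_proline_never_donates(self):
        # helix geometry but all-PRO: no amide H, so no helix H-bonds
        traj = _peptide_traj(["PRO"] * 12, [-57.0] * 12, [-47.0] * 12)
        ss = assign_secondary_structure(traj)
        assert (ss.states[0] == "H").sum() == 0


class TestEndToEnd:
    def test_ideal_extended_strand(self):
        traj = _peptide_traj(["GLN"] * 16, [-139.0] * 16, [135.0] * 16)
        cls = end_to_end_classify(traj, (1, 16))
        assert cls.distances[0, 0] > 45.0
        assert cls.classes[0, 0] == "EXTENDED"

    def test_bt_hairpin_compact(self, bt_lattice):
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        cls = end_to_end_classify(traj, (1, 16))
        assert np.all(cls.distances < 15.0)
        assert set(cls.classes.ravel()) == {"COMPACT"}

    def test_identical_endpoints_zero(self):
        traj = _peptide_traj(["GLN"] * 4, [-139.0] * 4, [135.0] * 4)
        cls = end_to_end_classify(traj, (2, 2))
        assert cls.distances[0, 0] == pytest.approx(0.0)
        assert cls.classes[0, 0] == "COMPACT"

    def test_span_outside_chain_errors(self):
        traj = _peptide_traj(["GLN"] * 4, [-139.0] * 4, [135.0] * 4)
        with pytest.raises(ValueError, match="span"):
            end_to_end_classify(traj, (1, 99))


class TestContactMatrix:
    def _two_chain_traj(self, separation):
        tops = []
        coords = []
        for c, x0 in enumerate((0.0, separation)):
            tops.append(ChainTopology("AB"[c], [Residue("GLN", 1, (("CA", "C"),))]))
            coords.append([x0, 0.0, 0.0])
        return Trajectory(tops, [Frame(np.array(coords))])

    def test_contact_at_5A(self):
        m = residue_contact_map(self._two_chain_traj(5.0), "INTER", cutoff=6.0)
        assert m[0, 0] == 1.0

    def test_no_contact_at_7A(self):
        m = residue_contact_map(self._two_chain_traj(7.0), "INTER", cutoff=6.0)
        assert m[0, 0] == 0.0

    def test_symmetric_and_bounded(self, bt_lattice):
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        m = residue_contact_map(traj, "INTER", cutoff=6.0)
        np.testing.assert_allclose(m, m.T)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_matches_brute_force_on_five_chains(self, rng):
        n_chains, n_res = 5, 3
        tops = []
        coords = []
        for c in range(n_chains):
            tops.append(ChainTopology(
                "ABCDE"[c],
                [Residue("GLN", i + 1, (("CA", "C"), ("CB", "C"))) for i in range(n_res)],
            ))
            coords.append(rng.uniform(0, 15, (n_res * 2, 3)))
        traj = Trajectory(tops, [Frame(np.concatenate(coords))])
        m = residue_contact_map(traj, "INTER", cutoff=6.0)
        expected = np.zeros((n_res, n_res))
        for a in range(n_chains):
            for b in range(n_chains):
                if a == b:
                    continue
                for i in range(n_res):
                    for j in range(n_res):
                        da = coords[a][i * 2 : i * 2 + 2]
                        db = coords[b][j * 2 : j * 2 + 2]
                        d = np.linalg.norm(da[:, None] - db[None, :], axis=-1).min()
                        if d <= 6.0:
                            expected[i, j] = 1.0
        np.testing.assert_allclose(m, expected)


class TestProfilesAndRg:
    def test_all_coil_zero_helicity(self):
        traj = _peptide_traj(["ALA"] * 10, [-139.0] * 10, [135.0] * 10, n_frames=4)
        frac, sd, overall = helicity_profile(traj)
        assert np.all(frac == 0.0)
        assert overall["H"] == 0.0

    def test_half_helical_frames(self):
        helix = _peptide_traj(["ALA"] * 12, [-57.0] * 12, [-47.0] * 12)
        coil = _peptide_traj(["ALA"] * 12, [-139.0] * 12, [135.0] * 12)
        frames = []
        for k in range(8):
            src = helix if k % 2 == 0 else coil
            frames.append(Frame(src.frames[0].coordinates.copy(), time=float(k)))
        traj = Trajectory(helix.topologies, frames)
        frac, sd, _ = helicity_profile(traj)
        core = frac[3:9]
        np.testing.assert_allclose(core, 0.5)
        assert sd is not None

    def test_fractions_bounded(self, bt_lattice):
        traj = perturb_fibril(bt_lattice, 0.1, 4, seed=3)
        frac, _, overall = helicity_profile(traj)
        assert np.all((frac >= 0) & (frac <= 1))
        assert sum(overall.values()) == pytest.approx(1.0)

    def test_few_frames_skips_blocks(self):
        traj = _peptide_traj(["ALA"] * 6, [-139.0] * 6, [135.0] * 6, n_frames=2)
        with pytest.warns(UserWarning, match="block"):
            _, sd, _ = helicity_profile(traj)
        assert sd is None

    def test_rg_point_mass(self):
        top = ChainTopology("A", [Residue("GLN", 1, (("CA", "C"), ("CB", "C")))])
        traj = Trajectory([top], [Frame(np.zeros((2, 3)))])
        assert radius_of_gyration(traj)[0] == pytest.approx(0.0)

    def test_rg_two_unit_masses(self):
        top = ChainTopology("A", [Residue("GLN", 1, (("CA", "C"), ("CB", "C")))])
        traj = Trajectory([top], [Frame(np.array([[0, 0, 0], [2.0, 0, 0]]))])
        assert radius_of_gyration(traj)[0] == pytest.approx(1.0)

    def test_rg_matches_direct_formula(self, rng):
        from fibrilkit.io_core import ELEMENT_MASSES

        atoms = (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"))
        top = ChainTopology("A", [Residue("GLN", i + 1, atoms) for i in range(5)])
        coords = rng.uniform(-10, 10, (20, 3))
        traj = Trajectory([top], [Frame(coords)])
        masses = np.array([ELEMENT_MASSES[e] for _, e in atoms] * 5)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        expected = np.sqrt((masses * ((coords - com) ** 2).sum(1)).sum() / masses.sum())
        assert radius_of_gyration(traj)[0] == pytest.approx(expected)


class TestRigidMotionInvariance:
    def test_metrics_unchanged_by_rotation_translation(self, bt_lattice):
        traj = Trajectory(bt_lattice.topologies, [bt_lattice.frame])
        R = rotation_matrix([1, 2, 3], 37.0)
        moved = Frame(bt_lattice.frame.coordinates @ R.T + np.array([5.0, -3.0, 11.0]))
        traj2 = Trajectory(bt_lattice.topologies, [moved])

        ss1 = assign_secondary_structure(traj)
        ss2 = assign_secondary_structure(traj2)
        assert (ss1.states == ss2.states).all()

        rg1 = radius_of_gyration(traj)[0]
        rg2 = radius_of_gyration(traj2)[0]
        assert rg1 == pytest.approx(rg2)

        e1 = end_to_end_classify(traj, (1, 16)).distances
        e2 = end_to_end_classify(traj2, (1, 16)).distances
        np.testing.assert_allclose(e1, e2, atol=1e-9)
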