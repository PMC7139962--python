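"""Energy engine: oracle equivalence, closed-form limits, invariances,
aggregation and per-residue conservation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from ribostate import mmgbsa as mg
from ribostate.molsys import MolecularSystem, random_rotation, rigid_transform
from ribostate.reference_data import binding_energy_table
from ribostate.synthetic_data import make_energy_frames

from conftest import (
    K_COULOMB,
    make_atom,
    oracle_born_radii,
    oracle_coulomb_inter,
    oracle_coulomb_intra,
    oracle_gb_energy,
    oracle_lj,
    oracle_two_sphere_sasa,
    random_toy,
)


class TestCoulomb:
    def test_unit_charge_pair_at_3A(self):
        system = MolecularSystem([make_atom(0, charge=1.0), make_atom(1, charge=-1.0)])
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        e = mg.coulomb_energy(system, frame, [0], [1])
        assert e == pytest.approx(-K_COULOMB / 3.0)
        assert e == pytest.approx(-110.688, abs=5e-4)

    def test_zero_charges_zero_energy(self):
        system = MolecularSystem([make_atom(i) for i in range(3)])
        frame = np.eye(3) * 4.0
        assert mg.coulomb_energy(system, frame) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_double_loop(self, seed):
        system, frame = random_toy(seed, n_atoms=10)
        rec = np.arange(7)
        lig = np.arange(7, 10)
        assert mg.coulomb_energy(system, frame, rec, lig) == pytest.approx(
            oracle_coulomb_inter(system, frame, rec, lig), abs=1e-10
        )
        assert mg.coulomb_energy(system, frame) == pytest.approx(
            oracle_coulomb_intra(system, frame), abs=1e-10
        )

    def test_overlapping_groups_rejected(self, toy_complex):
        system, frame, rec, lig = toy_complex
        with pytest.raises(ValueError, match="disjoint"):
            mg.coulomb_energy(system, frame, rec, np.concatenate([lig, rec[:1]]))

    def test_coincident_atoms_singular(self):
        system = MolecularSystem([make_atom(0, charge=1.0), make_atom(1, charge=1.0)])
        frame = np.zeros((2, 3))
        with pytest.raises(ValueError, match="singular"):
            mg.coulomb_energy(system, frame, [0], [1])


class TestLennardJones:
    def test_minimum_at_rmin_equals_minus_epsilon(self):
        system = MolecularSystem(
            [make_atom(0, lj_rmin_half=1.7, lj_epsilon=0.3),
             make_atom(1, lj_rmin_half=1.5, lj_epsilon=0.12)]
        )
        rmin = 3.2
        eps = math.sqrt(0.3 * 0.12)
        frame = np.array([[0.0, 0, 0], [rmin, 0, 0]])
        assert mg.lj_energy(system, frame, [0], [1]) == pytest.approx(-eps, abs=1e-12)

    def test_vanishes_at_large_separation(self):
        system = MolecularSystem([make_atom(0), make_atom(1)])
        frame = np.array([[0.0, 0, 0], [1e6, 0, 0]])
        assert abs(mg.lj_energy(system, frame, [0], [1])) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_double_loop(self, seed):
        system, frame = random_toy(seed + 50, n_atoms=10)
        rec, lig = np.arange(6), np.arange(6, 10)
        assert mg.lj_energy(system, frame, rec, lig) == pytest.approx(
            oracle_lj(system, frame, rec, lig), abs=1e-10
        )


class TestBornRadii:
    def test_isolated_atom_radius_is_intrinsic_minus_offset(self):
        system = MolecularSystem([make_atom(0, gb_radius=2.09)])
        r = mg.effective_born_radii(system, np.zeros((1, 3)))
        assert r[0] == pytest.approx(2.0, abs=1e-12)

    def test_distant_pair_reduces_to_isolated_values(self):
        system = MolecularSystem([make_atom(0, gb_radius=1.6), make_atom(1, gb_radius=1.9)])
        frame = np.array([[0.0, 0, 0], [1e6, 0, 0]])
        r = mg.effective_born_radii(system, frame)
        np.testing.assert_allclose(r, [1.51, 1.81], atol=1e-9)

    def test_burial_monotonically_increases_effective_radius(self):
        """Adding shell neighbors increases descreening and the radius."""
        center = make_atom(0, gb_radius=1.7)
        radii_prev = 0.0
        for n_shell in (1, 2, 4):
            atoms = [center] + [make_atom(i + 1, gb_radius=1.7) for i in range(n_shell)]
            atoms = [make_atom(0, gb_radius=1.7)] + atoms[1:]
            shell = np.array(
                [[3.0 * math.cos(2 * math.pi * k / n_shell),
                  3.0 * math.sin(2 * math.pi * k / n_shell), 0.0] for k in range(n_shell)]
            )
            frame = np.vstack([[0.0, 0.0, 0.0], shell])
            r0 = mg.effective_born_radii(MolecularSystem(atoms), frame)[0]
            assert r0 > radii_prev
            radii_prev = r0
        assert radii_prev > 1.7 - 0.09

    def test_descreening_integral_matches_numeric_quadrature(self):
        """Closed-form pair integral vs direct 1-D quadrature of the
        1/r^4 shell-fraction integrand."""

        def numeric(rho, r, s):
            lo, hi = max(rho, r - s), r + s
            if hi <= rho:
                return 0.0

            def f(t):
                cosw = (t * t + r * r - s * s) / (2 * t * r)
                return min(1.0, max(0.0, (1 - cosw) / 2)) / t**2

            return quad(f, lo, hi, limit=200)[0]

        rng = np.random.default_rng(1)
        for _ in range(20):
            rho = rng.uniform(0.5, 2.0)
            s = rng.uniform(0.5, 2.0)
            r = rng.uniform(0.3, 5.0)
            closed = mg._descreen_integral(np.array([rho]), np.array([r]), np.array([s]))[0]
            assert closed == pytest.approx(numeric(rho, r, s), abs=1e-8)

    def test_nonpositive_radius_rejected(self):
        system = MolecularSystem([make_atom(0, gb_radius=0.0)])
        with pytest.raises(ValueError):
            mg.effective_born_radii(system, np.zeros((1, 3)))


class TestGBPolar:
    def test_single_ion_born_closed_form(self):
        system = MolecularSystem([make_atom(0, charge=1.0, gb_radius=2.09)])
        e = mg.gb_polar_energy(system, np.zeros((1, 3)))
        born = -0.5 * K_COULOMB * (1 - 1 / 80.0) * 1.0 / 2.0
        assert e == pytest.approx(born, abs=1e-9)
        assert e == pytest.approx(-81.98, abs=5e-3)

    def test_zero_charges_zero_energy(self, toy_complex):
        system, frame, _, _ = toy_complex
        for a in system.atoms:
            a.charge = 0.0
        assert mg.gb_polar_energy(system, frame) == 0.0

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_double_sum_oracle(self, seed):
        system, frame = random_toy(seed, n_atoms=3)
        assert mg.gb_polar_energy(system, frame) == pytest.approx(
            oracle_gb_energy(system, frame, range(3)), abs=1e-10
        )


class TestSASA:
    def test_isolated_atom_exact_sphere_area(self):
        system = MolecularSystem([make_atom(0, lj_rmin_half=1.6)])
        _, total = mg.sasa(system, np.zeros((1, 3)))
        assert total == pytest.approx(4 * math.pi * 3.0**2, abs=1e-9)

    def test_fully_buried_atom_has_zero_area(self):
        # small atom caged by six large overlapping spheres
        atoms = [make_atom(0, lj_rmin_half=0.5)] + [
            make_atom(i + 1, lj_rmin_half=2.5) for i in range(6)
        ]
        cage = 2.2 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
        )
        frame = np.vstack([np.zeros(3), cage])
        per_atom, _ = mg.sasa(MolecularSystem(atoms), frame)
        assert per_atom[0] == 0.0

    def test_two_sphere_case_matches_cap_formula(self):
        r1, r2, d = 1.7, 1.5, 2.4
        system = MolecularSystem(
            [make_atom(0, lj_rmin_half=r1), make_atom(1, lj_rmin_half=r2)]
        )
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        _, total = mg.sasa(system, frame)
        exact = oracle_two_sphere_sasa(r1, r2, d, 1.4)
        assert total == pytest.approx(exact, rel=0.02)

    def test_cross_check_against_independent_library(self):
        """Our sphere-point SASA vs biotite's on a random bead system."""
        biotite_struc = pytest.importorskip("biotite.structure")
        system, frame = random_toy(9, n_atoms=8)
        radii = system.array("lj_rmin_half")
        arr = biotite_struc.AtomArray(len(frame))
        arr.coord = np.asarray(frame, dtype=np.float32)
        arr.element = np.array(["C"] * len(frame))
        ref = biotite_struc.sasa(arr, probe_radius=1.4, vdw_radii=radii.astype(np.float32),
                                 point_number=2000)
        _, total = mg.sasa(system, frame)
        assert total == pytest.approx(float(ref.sum()), rel=0.02)

    def test_zero_radius_atom_rejected(self):
        system = MolecularSystem([make_atom(0, lj_rmin_half=0.0)])
        with pytest.raises(ValueError, match="radii"):
            mg.sasa(system, np.zeros((1, 3)))


class TestNonpolar:
    def test_linear_in_area_with_stated_defaults(self):
        assert mg.nonpolar_energy(0.0) == pytest.approx(0.92)
        assert mg.nonpolar_energy(1000.0) == pytest.approx(0.00542 * 1000 + 0.92)
        assert mg.nonpolar_energy(1000.0) == pytest.approx(6.34)
        p = mg.EnergyModelParams(gamma=0.0)
        assert mg.nonpolar_energy(12345.0, p) == pytest.approx(p.beta_const)


class TestRigidMotionInvariance:
    def test_all_terms_invariant_under_rotation_translation(self, toy_complex):
        system, frame, rec, lig = toy_complex
        rng = np.random.default_rng(7)
        rot = random_rotation(rng)
        moved = rigid_transform(frame, rot, np.array([11.0, -4.0, 2.5]))
        c0 = mg.snapshot_binding_components(system, frame, rec, lig)
        c1 = mg.snapshot_binding_components(system, moved, rec, lig)
        assert c1.e_ele == pytest.approx(c0.e_ele, abs=1e-9)
        assert c1.e_vdw == pytest.approx(c0.e_vdw, abs=1e-9)
        assert c1.g_pol == pytest.approx(c0.g_pol, abs=1e-9)
        # sphere-point SASA is rotation-covariant only in the infinite-
        # point limit; the residual shrinks with the point count
        dense = mg.EnergyModelParams(sasa_points=3840)
        d0 = mg.snapshot_binding_components(system, frame, rec, lig, dense)
        d1 = mg.snapshot_binding_components(system, moved, rec, lig, dense)
        assert abs(d1.g_nonpol - d0.g_nonpol) < abs(c1.g_nonpol - c0.g_nonpol)
        assert d1.g_nonpol == pytest.approx(d0.g_nonpol, abs=2e-3)
        # translation alone leaves the atom-centered grid untouched
        c2 = mg.snapshot_binding_components(
            system, frame + np.array([3.0, -7.0, 1.0]), rec, lig
        )
        assert c2.g_nonpol == pytest.approx(c0.g_nonpol, abs=1e-9)


class TestSnapshotComponents:
    def test_neutral_ligand_gives_zero_delta_ele(self, toy_complex):
        system, frame, rec, lig = toy_complex
        for i in lig:
            system.atoms[i].charge = 0.0
        comp = mg.snapshot_binding_components(system, frame, rec, lig)
        assert comp.e_ele == 0.0

    def test_vdw_delta_equals_intergroup_sum(self, toy_complex):
        system, frame, rec, lig = toy_complex
        comp = mg.snapshot_binding_components(system, frame, rec, lig)
        assert comp.e_vdw == pytest.approx(mg.lj_energy(system, frame, rec, lig), abs=1e-9)

    def test_single_and_three_trajectory_routes_agree_at_same_coords(self, toy_complex):
        """dE_ele/dE_vdw computed as inter-group sums must equal the
        explicit complex-minus-species difference."""
        from ribostate.molsys import extract_subsystem

        system, frame, rec, lig = toy_complex
        single = mg.snapshot_binding_components(system, frame, rec, lig)
        three = mg.binding_components_three_trajectory(
            system, frame,
            extract_subsystem(system, rec), frame[rec],
            extract_subsystem(system, lig), frame[lig],
        )
        assert three.e_int == pytest.approx(0.0, abs=1e-12)
        assert three.e_ele == pytest.approx(single.e_ele, abs=1e-9)
        assert three.e_vdw == pytest.approx(single.e_vdw, abs=1e-9)
        assert three.g_pol == pytest.approx(single.g_pol, abs=1e-9)

    def test_infinitely_separated_ligand_has_vanishing_deltas(self, toy_complex):
        system, frame, rec, lig = toy_complex
        # neutralize each fragment so no monopole term survives at 1e4 A
        for grp in (rec, lig):
            q = sum(system.atoms[i].charge for i in grp)
            for i in grp:
                system.atoms[i].charge -= q / len(grp)
        far = frame.copy()
        far[lig] += np.array([1e4, 0, 0])
        comp = mg.snapshot_binding_components(system, far, rec, lig)
        assert abs(comp.e_ele) < 1e-3
        assert abs(comp.e_vdw) < 1e-12
        assert abs(comp.g_pol) < 1e-6
        assert abs(comp.g_nonpol + 0.92) < 1e-9  # only the beta bookkeeping survives

    def test_empty_ligand_rejected(self, toy_complex):
        system, frame, rec, lig = toy_complex
        with pytest.raises(ValueError, match="ligand"):
            mg.snapshot_binding_components(system, frame, np.arange(system.n_atoms), [])

    def test_partition_required(self, toy_complex):
        system, frame, rec, lig = toy_complex
        with pytest.raises(ValueError, match="partition"):
            mg.snapshot_binding_components(system, frame, rec[:-1], lig)


class TestAggregateReplicas:
    def test_published_component_rows_recombine_to_printed_totals(self):
        """dG_bind = dH - TdS reproduces the printed cells, e.g. the
        strongest binder: dH=-29.40, TdS=-14.03 -> dG_bind=-15.37."""
        table = binding_energy_table()
        row = table.set_index(["ligand", "aptamer", "term"])["mean"]
        dh = row[("6AP", "AR", "dH")]
        tds = row[("6AP", "AR", "TdS")]
        assert dh - tds == pytest.approx(-15.37, abs=0.02)
        ele = row[("ADE", "GR(C74U)", "dE_ele")]
        pol = row[("ADE", "GR(C74U)", "dG_pol")]
        assert ele + pol == pytest.approx(4.06, abs=0.02)

    def test_constant_replicas_have_zero_sigma(self):
        groups = make_energy_frames(
            means={"dE_ele": -30.0, "dG_pol": 34.0}, sds={}, n_frames=5, n_replicas=10
        )
        res = mg.aggregate_replicas(groups, t_delta_s=-14.0)
        assert res["dE_ele"] == pytest.approx(-30.0)
        assert res["dG_bind"] == pytest.approx(-30.0 + 34.0 + 14.0)
        for term in ("dE_ele", "dG_pol", "dH"):
            assert res.sigma(term) == 0.0

    def test_derived_identities_exact(self):
        groups = make_energy_frames(
            means={"dE_ele": -31.48, "dE_vdw": -25.45, "dE_int": 1.42,
                   "dG_pol": 35.54, "dG_nonpol": -2.86},
            sds={"dE_ele": 1.0, "dG_pol": 1.2},
            n_frames=50, n_replicas=10, seed=4,
        )
        res = mg.aggregate_replicas(groups, t_delta_s=-13.31)
        m = res.means
        assert m["dH"] == pytest.approx(
            m["dE_ele"] + m["dE_vdw"] + m["dE_int"] + m["dG_pol"] + m["dG_nonpol"], abs=1e-12
        )
        assert m["dG_bind"] == pytest.approx(m["dH"] - m["TdS"], abs=1e-12)
        assert m["dG_ele_pol"] == pytest.approx(m["dE_ele"] + m["dG_pol"], abs=1e-12)
        assert m["dG_vdw_nonpol"] == pytest.approx(m["dE_vdw"] + m["dG_nonpol"], abs=1e-12)

    def test_sigma_is_replica_sd_over_sqrt_n(self):
        groups = make_energy_frames(
            means={"dE_ele": -30.0}, sds={"dE_ele": 0.0}, n_frames=3,
            n_replicas=10, seed=8, between_replica_sd={"dE_ele": 2.0},
        )
        rep_means = [np.mean([c.e_ele for c in g]) for g in groups.values()]
        expected = np.std(rep_means, ddof=1) / math.sqrt(10)
        res = mg.aggregate_replicas(groups)
        assert res.sigma("dE_ele") == pytest.approx(expected, rel=1e-12)

    def test_no_replicas_rejected(self):
        with pytest.raises(ValueError):
            mg.aggregate_replicas({})


class TestDecomposition:
    def test_columns_sum_to_system_deltas(self, toy_complex):
        system, frame, rec, lig = toy_complex
        comp = mg.snapshot_binding_components(system, frame, rec, lig)
        contribs = mg.per_residue_decomposition(system, frame, rec, lig)
        sums = {
            "ele": sum(c.ele for c in contribs),
            "vdw": sum(c.vdw for c in contribs),
            "pol": sum(c.pol for c in contribs),
            "nonpol": sum(c.nonpol for c in contribs),
        }
        assert sums["ele"] == pytest.approx(comp.e_ele, abs=1e-9)
        assert sums["vdw"] == pytest.approx(comp.e_vdw, abs=1e-9)
        assert sums["pol"] == pytest.approx(comp.g_pol, abs=1e-6)
        assert sums["nonpol"] == pytest.approx(comp.g_nonpol, abs=1e-6)

    def test_single_residue_receptor_collects_whole_delta(self):
        from ribostate.synthetic_data import ToySystemSpec, make_toy_system, receptor_ligand_split

        system, frame = make_toy_system(
            ToySystemSpec(n_atoms=6, n_ligand_atoms=3, atoms_per_residue=3, seed=21)
        )
        rec, lig = receptor_ligand_split(system)
        comp = mg.snapshot_binding_components(system, frame, rec, lig)
        contribs = mg.per_residue_decomposition(system, frame, rec, lig)
        total = sum(c.total for c in contribs)
        assert total == pytest.approx(comp.total_enthalpy(), abs=1e-6)
        assert len([c for c in contribs if c.residue_name == "RES"]) == 1

    def test_distant_neutral_residue_contributes_nothing(self):
        """A zero-charge nucleotide far from the ligand has |total| < 0.01."""
        from ribostate.synthetic_data import ToySystemSpec, make_toy_system, receptor_ligand_split

        system, frame = make_toy_system(
            ToySystemSpec(n_atoms=12, n_ligand_atoms=3, atoms_per_residue=3, seed=33)
        )
        rec, lig = receptor_ligand_split(system)
        far_res = [a.atom_id for a in system.atoms if a.residue_index == 0]
        frame = frame.copy()
        frame[far_res] += np.array([60.0, 0.0, 0.0])
        for i in far_res:
            system.atoms[i].charge = 0.0
        q = np.array([a.charge for a in system.atoms])
        keep = [i for i in range(system.n_atoms) if i not in far_res]
        # re-neutralize the remaining atoms so the toy stays well-posed
        shift = -q[keep].sum() / len(keep)
        for i in keep:
            system.atoms[i].charge += shift
        contribs = mg.per_residue_decomposition(system, frame, rec, lig)
        far = [c for c in contribs if c.author_resid == 1][0]
        assert abs(far.total) < 0.01
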