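"""SASA, relative accessibility, active/passive selection, AIR round-trips."""

import numpy as np
import pytest

from clampmap.io import StructureModel
from clampmap.restraints import (
    RestraintSet,
    compute_sasa,
    fibonacci_sphere,
    parse_air_restraints,
    relative_sasa,
    select_air_residues,
    write_air_restraints,
)
from clampmap.synthetic import gen_toy_structure


def make_structure(coords, radii, names=None, resnums=None, resnames=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(
        atom_names=np.array(names or ["X"] * n),
        residue_numbers=np.array(resnums or list(range(1, n + 1)), dtype=int),
        residue_names=np.array(resnames or ["ALA"] * n),
        chain_ids=np.array(["A"] * n),
        elements=np.array(["C"] * n),
        coords=coords,
        radii=np.asarray(radii, dtype=float),
    )


class TestSASA:
    def test_isolated_atom_matches_sphere_area(self):
        st = make_structure([[0, 0, 0]], [1.9])
        res = compute_sasa(st, probe_radius=1.4, n_points=960)
        exact = 4.0 * np.pi * 3.3**2  # 136.85 A^2
        assert res.per_atom[0] == pytest.approx(exact, rel=0.01)

    def test_fully_enclosed_atom_is_buried(self):
        shell = 2.0 * fibonacci_sphere(14)
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        st = make_structure(coords, [1.9] * len(coords))
        res = compute_sasa(st)
        assert res.per_atom[0] == 0.0

    def test_symmetric_pair_gets_equal_area(self):
        st = make_structure([[0, 0, 0], [2.0, 0, 0]], [1.7, 1.7])
        res = compute_sasa(st)
        assert res.per_atom[0] == pytest.approx(res.per_atom[1], abs=1e-6)
        assert res.per_atom[0] < 4.0 * np.pi * 3.1**2  # partially occluded

    def test_point_count_convergence(self, helix20):
        a = compute_sasa(helix20, n_points=960).total
        b = compute_sasa(helix20, n_points=1920).total
        assert abs(b - a) / a < 0.005

    def test_monte_carlo_ray_oracle(self):
        # independent random-sampling estimate of the same surface
        coords = np.array(
            [[0, 0, 0], [2.4, 0, 0], [0, 2.6, 0], [-1.8, -1.2, 1.0], [0.5, 0.8, -2.2]]
        )
        radii = np.array([1.7, 1.52, 1.55, 1.7, 1.8])
        st = make_structure(coords, radii)
        res = compute_sasa(st, n_points=10000)
        rng = np.random.default_rng(0)
        expanded = radii + 1.4
        for i in range(len(coords)):
            pts = rng.normal(size=(200000, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            pts = coords[i] + expanded[i] * pts
            free = np.ones(len(pts), dtype=bool)
            for j in range(len(coords)):
                if j != i:
                    free &= np.sum((pts - coords[j]) ** 2, axis=1) > expanded[j] ** 2
            mc = free.mean() * 4.0 * np.pi * expanded[i] ** 2
            assert res.per_atom[i] == pytest.approx(mc, abs=max(0.02 * mc, 0.35))

    def test_cross_check_against_independent_implementation(self, helix20):
        biotite_struct = pytest.importorskip("biotite.structure")
        arr = biotite_struct.AtomArray(len(helix20))
        arr.coord = helix20.coords
        arr.chain_id[:] = "A"
        arr.res_id = helix20.residue_numbers
        arr.res_name = helix20.residue_names
        arr.atom_name = helix20.atom_names
        arr.element = helix20.elements
        ref = biotite_struct.sasa(arr, probe_radius=1.4, point_number=1000,
                                  vdw_radii=helix20.radii)
        ours = compute_sasa(helix20, n_points=1000)
        assert ours.total == pytest.approx(float(np.nansum(ref)), rel=0.02)

    def test_coincident_atoms_rejected(self):
        st = make_structure([[0, 0, 0], [0, 0, 0]], [1.7, 1.7])
        with pytest.raises(ValueError, match="coincide"):
            compute_sasa(st)

    def test_parameter_validation(self, helix20):
        with pytest.raises(ValueError):
            compute_sasa(helix20, n_points=50)
        with pytest.raises(ValueError):
            compute_sasa(helix20, probe_radius=-1.0)


class TestRelativeSASA:
    def test_buried_and_reference_limits(self):
        st = make_structure([[0, 0, 0]], [1.9], resnums=[1], resnames=["GLY"])
        res = compute_sasa(st)
        # against a table whose max equals the computed area: exactly 100%
        rel = relative_sasa(res, {"GLY": res.per_residue[1]})
        assert rel[1] == pytest.approx(100.0, rel=1e-9)

    def test_table_lookup_arithmetic(self):
        st = make_structure([[0, 0, 0]], [1.9], resnums=[1], resnames=["GLY"])
        res = compute_sasa(st)
        res.per_residue[1] = 42.0  # pin the numerator
        rel = relative_sasa(res, {"GLY": 104.0})
        assert rel[1] == pytest.approx(100.0 * 42.0 / 104.0)

    def test_unknown_residue_type(self):
        st = make_structure([[0, 0, 0]], [1.9], resnames=["XXX"])
        res = compute_sasa(st)
        with pytest.raises(KeyError):
            relative_sasa(res)

    def test_default_table_on_toy_helix(self, helix20):
        rel = relative_sasa(compute_sasa(helix20))
        assert all(v >= 0 for v in rel.values())
        # chain termini are more exposed than the helix middle
        assert rel[1] > rel[10]


class TestSelection:
    def test_both_filters_applied(self, helix20):
        perturbed = {1: 0.15, 2: 0.12, 3: 0.08}
        rel = {1: 60.0, 2: 30.0, 3: 80.0}
        sel = select_air_residues(perturbed, rel, helix20)
        assert sel.active == {1}        # 2 fails accessibility, 3 fails CSP
        assert 3 in sel.passive          # accessible and adjacent to residue 1

    def test_accepts_prethresholded_set(self, helix20):
        sel = select_air_residues({1, 2}, {1: 60.0, 2: 60.0, 5: 60.0}, helix20)
        assert sel.active == {1, 2}

    def test_no_perturbed_residues_is_error(self, helix20):
        with pytest.raises(ValueError, match="active"):
            select_air_residues({}, {1: 60.0}, helix20)

    def test_monotone_in_both_thresholds(self, helix20):
        rng = np.random.default_rng(1)
        perturbed = {r: float(rng.uniform(0, 0.3)) for r in range(1, 21)}
        rel = {r: float(rng.uniform(0, 100)) for r in range(1, 21)}

        def active(csp_t, sasa_t):
            try:
                return select_air_residues(
                    perturbed, rel, helix20, csp_threshold=csp_t, sasa_threshold=sasa_t
                ).active
            except ValueError:
                return set()

        base = active(0.05, 30.0)
        assert active(0.10, 30.0) <= base
        assert active(0.05, 60.0) <= base
        assert active(0.10, 60.0) <= base

    def test_passive_radius_controls_adjacency(self, helix20):
        rel = {r: 60.0 for r in range(1, 21)}
        near = select_air_residues({10}, rel, helix20, passive_radius=6.5).passive
        wide = select_air_residues({10}, rel, helix20, passive_radius=15.0).passive
        assert near < wide


class TestAIRWriter:
    def test_single_active_pair_yields_two_blocks(self, tmp_path):
        rset = RestraintSet({99}, set(), {405}, set())
        path = tmp_path / "airs.tbl"
        write_air_restraints(rset, path)
        text = path.read_text()
        assert text.count("assign") == 2
        assert "(resid 99 and segid A)" in text
        assert "(resid 405 and segid B)" in text

    def test_empty_passive_emits_no_extra_selections(self, tmp_path):
        rset = RestraintSet({99}, set(), {405}, set())
        path = tmp_path / "airs.tbl"
        write_air_restraints(rset, path)
        # exactly one target selection per block
        assert path.read_text().count("resid") == 4

    def test_write_parse_round_trip(self, tmp_path):
        rset = RestraintSet(
            active_A={99, 102, 107}, passive_A={95, 110},
            active_B={405, 406, 407}, passive_B={403},
            distance_bounds=(2.0, 2.0, 0.0),
        )
        path = tmp_path / "airs.tbl"
        write_air_restraints(rset, path)
        back = parse_air_restraints(path)
        assert back.active_A == rset.active_A
        assert back.passive_A == rset.passive_A
        assert back.active_B == rset.active_B
        assert back.passive_B == rset.passive_B
        assert back.distance_bounds == rset.distance_bounds

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RestraintSet({1}, {1}, {2}, set())
        with pytest.raises(ValueError):
            RestraintSet(set(), set(), {2}, set())
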