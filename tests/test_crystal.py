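import math

import numpy as np
import pytest

from icsxrd.crystal import (
    AtomSite,
    CrystalStructure,
    MissingFormFactorError,
    NoDiffraction,
    Reflection,
    UnitCell,
    bragg_angle,
    d_spacing,
    enumerate_reflections,
    form_factor,
    load_cif,
    load_json,
    structure_factor,
    structure_factor_many,
    wavelength_A,
)


class TestUnitCell:
    def test_rejects_nonpositive_lengths_and_bad_angles(self):
        with pytest.raises(ValueError):
            UnitCell(0.0, 4.0, 4.0)
        with pytest.raises(ValueError):
            UnitCell(4.0, 4.0, 4.0, alpha=180.0)
        # angle combination violating the triangle-like metric condition
        with pytest.raises(ValueError):
            UnitCell(4.0, 4.0, 4.0, 10.0, 10.0, 170.0)

    def test_cubic_volume(self):
        assert UnitCell(4.0, 4.0, 4.0).volume == pytest.approx(64.0)

    def test_orthogonalization_consistent_with_metric(self):
        cell = UnitCell(5.2, 6.1, 7.3, 95.0, 101.0, 88.0)
        M = cell.orthogonalization_matrix
        assert M.T @ M == pytest.approx(cell.metric_tensor.T, rel=1e-10)


class TestDSpacing:
    def test_cubic_identity(self):
        assert d_spacing(UnitCell(1, 1, 1), (1, 0, 0)) == pytest.approx(1.0)

    def test_monoclinic_b_axis(self):
        # (0 2 0) probes only the k-axis term of the reciprocal metric
        cell = UnitCell(6.3, 14.583, 10.1, beta=109.5)
        assert d_spacing(cell, (0, 2, 0)) == pytest.approx(7.2915, abs=1e-4)

    def test_tetragonal_halving(self):
        cell = UnitCell(12.371, 12.371, 7.357)
        assert d_spacing(cell, (2, 0, 0)) == pytest.approx(6.1855, abs=1e-4)

    def test_zero_triple_rejected(self):
        with pytest.raises(ValueError):
            d_spacing(UnitCell(4, 4, 4), (0, 0, 0))

    @pytest.mark.parametrize("system", ["cubic", "tetragonal", "monoclinic"])
    def test_textbook_formulas_on_random_cells(self, system):
        """General metric-tensor route equals the specialized closed forms."""
        rng = np.random.default_rng(7)
        for _ in range(1000):
            h, k, l = rng.integers(-4, 5, 3)
            if (h, k, l) == (0, 0, 0):
                continue
            a, b, c = rng.uniform(3, 15, 3)
            if system == "cubic":
                cell = UnitCell(a, a, a)
                inv_d2 = (h * h + k * k + l * l) / a**2
            elif system == "tetragonal":
                cell = UnitCell(a, a, c)
                inv_d2 = (h * h + k * k) / a**2 + l * l / c**2
            else:
                beta = rng.uniform(91.0, 130.0)
                cell = UnitCell(a, b, c, beta=beta)
                sb, cb = math.sin(math.radians(beta)), math.cos(math.radians(beta))
                inv_d2 = (
                    h * h / (a * sb) ** 2
                    + k * k / b**2
                    + l * l / (c * sb) ** 2
                    - 2 * h * l * cb / (a * c * sb * sb)
                )
            assert d_spacing(cell, (h, k, l)) == pytest.approx(
                1.0 / math.sqrt(inv_d2), rel=1e-10
            )


class TestBraggAngle:
    def test_backscattering_limit(self):
        assert bragg_angle(1.0, 2.0) == pytest.approx(90.0)

    def test_25_keV_weddellite_200(self):
        lam = wavelength_A(25.0)
        assert lam == pytest.approx(0.49594, abs=2e-5)
        assert 2 * bragg_angle(6.1855, lam) == pytest.approx(4.60, abs=0.01)

    def test_no_diffraction_signal(self):
        with pytest.raises(NoDiffraction):
            bragg_angle(1.0, 2.5)

    def test_invalid_inputs_are_distinct_errors(self):
        with pytest.raises(ValueError):
            bragg_angle(-1.0, 1.0)
        with pytest.raises(ValueError):
            bragg_angle(1.0, 1.0, n=0)

    def test_monotone_in_d(self):
        lam = wavelength_A(25.0)
        ds = np.linspace(0.5, 8.0, 50)
        angles = [bragg_angle(d, lam) for d in ds]
        assert np.all(np.diff(angles) < 0)


def brute_force_reflections(structure, wavelength, two_theta_max, index_range=10):
    """Independent oracle: scan the whole hkl cube and apply the d cut."""
    d_min = wavelength / (2 * math.sin(math.radians(two_theta_max / 2)))
    out = set()
    rng = range(-index_range, index_range + 1)
    for h in rng:
        for k in rng:
            for l in rng:
                if (h, k, l) == (0, 0, 0):
                    continue
                d = d_spacing(structure.cell, (h, k, l))
                if d >= d_min:
                    out.add((h, k, l))
    return out


class TestEnumerateReflections:
    def test_vanishing_range_is_empty(self, toy_cubic):
        assert enumerate_reflections(toy_cubic, 0.5, 1e-6) == []

    def test_matches_brute_force_cube(self, toy_cubic):
        got = enumerate_reflections(toy_cubic, 0.5, 10.0)
        expect = brute_force_reflections(toy_cubic, 0.5, 10.0)
        assert {r.hkl for r in got} == expect

    def test_matches_brute_force_on_low_symmetry_cell(self, three_atom_cell):
        got = enumerate_reflections(three_atom_cell, 0.7, 12.0)
        expect = brute_force_reflections(three_atom_cell, 0.7, 12.0)
        assert {r.hkl for r in got} == expect

    def test_dmin_at_30_degrees(self, toy_cubic):
        lam = wavelength_A(25.0)
        d_min = lam / (2 * math.sin(math.radians(15.0)))
        assert d_min == pytest.approx(0.9582, abs=2e-4)
        got = enumerate_reflections(toy_cubic, lam, 30.0)
        assert min(r.d for r in got) >= d_min - 1e-9

    def test_sorted_by_angle(self, three_atom_cell):
        got = enumerate_reflections(three_atom_cell, 0.7, 12.0)
        ds = np.array([r.d for r in got])
        assert np.all(np.diff(ds) <= 1e-12)  # ascending 2theta = descending d


def direct_sum_f2(structure, hkl):
    """Independent complex-sum oracle for |F|^2."""
    d = d_spacing(structure.cell, hkl)
    stol2 = 1.0 / (4 * d * d)
    F = 0j
    for s in structure.sites:
        f0 = form_factor(s.element, np.array([stol2]))[0]
        phase = 2j * math.pi * (hkl[0] * s.frac_xyz[0] + hkl[1] * s.frac_xyz[1] + hkl[2] * s.frac_xyz[2])
        F += s.occupancy * f0 * math.exp(-s.b_iso * stol2) * np.exp(phase)
    return abs(F) ** 2


class TestStructureFactor:
    def test_forward_limit_is_total_electron_count(self, three_atom_cell):
        # at stol -> 0 every f0 -> Z and all phases are unity
        zs = {"C": 6, "O": 8, "Ca": 20}
        total = sum(zs[s.element] * s.occupancy for s in three_atom_cell.sites)
        # probe a reflection with tiny scattering vector via a huge cell
        cell_sites = [AtomSite(s.element, (0, 0, 0), s.occupancy) for s in three_atom_cell.sites]
        from icsxrd.crystal import CrystalStructure, UnitCell

        big = CrystalStructure("big", UnitCell(5000, 5000, 5000), cell_sites)
        assert structure_factor(big, (1, 0, 0)) == pytest.approx(total**2, rel=1e-4)

    def test_centrosymmetric_pair_is_real(self):
        from icsxrd.crystal import CrystalStructure, UnitCell

        x = (0.123, 0.456, 0.789)
        minus_x = tuple((-v) % 1.0 for v in x)
        s = CrystalStructure(
            "cs", UnitCell(6, 7, 8), [AtomSite("O", x), AtomSite("O", minus_x)]
        )
        for hkl in [(1, 2, 3), (2, 0, 1), (3, 1, 0)]:
            d = d_spacing(s.cell, hkl)
            f0 = form_factor("O", np.array([1.0 / (4 * d * d)]))[0]
            # F = 2 f0 cos(2 pi h.x) exactly for the inversion pair
            phase = 2 * math.pi * sum(h * v for h, v in zip(hkl, x))
            assert structure_factor(s, hkl) == pytest.approx(
                (2 * f0 * math.cos(phase)) ** 2, rel=1e-10
            )

    def test_matches_direct_sum_oracle(self, three_atom_cell):
        rng = np.random.default_rng(3)
        for _ in range(20):
            hkl = tuple(int(v) for v in rng.integers(-5, 6, 3))
            if hkl == (0, 0, 0):
                continue
            assert structure_factor(three_atom_cell, hkl) == pytest.approx(
                direct_sum_f2(three_atom_cell, hkl), rel=1e-10
            )

    def test_friedel_symmetry(self, three_atom_cell):
        rng = np.random.default_rng(5)
        hkls = rng.integers(-6, 7, size=(30, 3))
        hkls = hkls[np.any(hkls != 0, axis=1)]
        f2 = structure_factor_many(three_atom_cell, hkls)
        f2_bar = structure_factor_many(three_atom_cell, -hkls)
        np.testing.assert_allclose(f2, f2_bar, rtol=1e-10)

    def test_unknown_element_names_the_element(self):
        with pytest.raises(MissingFormFactorError):
            AtomSite("Xx", (0, 0, 0))


class TestStructureIO:
    def test_json_round_trip(self, tmp_path, three_atom_cell):
        import json

        blob = {
            "name": "random3",
            "cell": {"a": 5.2, "b": 6.1, "c": 7.3, "alpha": 95.0, "beta": 101.0, "gamma": 88.0},
            "sites": [
                {"element": s.element, "xyz": list(s.frac_xyz),
                 "occupancy": s.occupancy, "b_iso": s.b_iso}
                for s in three_atom_cell.sites
            ],
        }
        p = tmp_path / "s.json"
        p.write_text(json.dumps(blob))
        loaded = load_json(p)
        assert loaded.cell == three_atom_cell.cell
        got = structure_factor(loaded, (1, 2, 0))
        assert got == pytest.approx(structure_factor(three_atom_cell, (1, 2, 0)), rel=1e-12)

    def test_cif_symmetry_expansion(self, tmp_path):
        cif = """data_toy
_cell_length_a 4.0
_cell_length_b 5.0
_cell_length_c 6.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'P 21/c'
loop_
_symmetry_equiv_pos_as_xyz
'x, y, z'
'-x, y+1/2, -z+1/2'
'-x, -y, -z'
'x, -y+1/2, z+1/2'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
_atom_site_occupancy
C1 C 0.1 0.2 0.3 1.0
"""
        p = tmp_path / "toy.cif"
        p.write_text(cif)
        s = load_cif(p)
        assert len(s.sites) == 4
        assert s.site_formula() == {"C": 4.0}
        # the 2_1/c operations force the 0k0, k odd extinction
        assert structure_factor(s, (0, 1, 0)) == pytest.approx(0.0, abs=1e-18)
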