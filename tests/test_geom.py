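"""Dihedral arithmetic, nomenclature, rigid-rotor constants, superposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from confscape.geom import (
    AmbiguousBackboneError,
    Conformer,
    SpectroParams,
    TorsionSpec,
    classify_backbone,
    full_label,
    heavy_atom_rmsd,
    kabsch_rmsd,
    measure_dihedral,
    parse_zmatrix,
    phi_prime,
    read_xyz,
    rotational_constants_from_geometry,
    torsion_label,
    wrap_dihedral,
    write_xyz,
    zmatrix_masses,
    zmatrix_to_cartesian,
)

finite_angles = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


class TestWrap:
    @pytest.mark.parametrize(
        "raw, wrapped",
        [(190, -170), (-180, -180), (540, -180), (0, 0), (360, 0), (-190, 170)],
    )
    def test_examples(self, raw, wrapped):
        assert wrap_dihedral(raw) == pytest.approx(wrapped)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), -float("inf")])
    def test_rejects_non_finite(self, bad):
        with pytest.raises(ValueError):
            wrap_dihedral(bad)

    @given(finite_angles)
    @settings(derandomize=True)
    def test_idempotent_and_congruent(self, x):
        w = wrap_dihedral(x)
        assert -180.0 <= w < 180.0
        assert wrap_dihedral(w) == w
        assert math.isclose(math.cos(math.radians(w)), math.cos(math.radians(x)), abs_tol=1e-9)
        assert math.isclose(math.sin(math.radians(w)), math.sin(math.radians(x)), abs_tol=1e-9)

    @pytest.mark.parametrize("phi, expected", [(60, -180), (-120, 0), (0, 120)])
    def test_phi_prime(self, phi, expected):
        assert phi_prime(phi) == pytest.approx(expected)


class TestTorsionLabel:
    @pytest.mark.parametrize(
        "angle, label",
        [
            (44.1, "g"),      # serine Ig-g chi2
            (-55.9, "g-"),    # serine Ig-g chi1
            (177.3, "t"),
            (-6.2, "c"),
            (101.0, "g"),     # asparagine IIgg chi2, printed gauche
            (-29.5, "g-"),    # asparagine I'gg- chi2, printed gauche-minus
            (120.0, "s"),
            (-120.0, "s-"),
            (-150.0, "t"),
            (160.0, "t"),
        ],
    )
    def test_bins(self, angle, label):
        assert torsion_label(angle) == label

    @given(finite_angles)
    @settings(derandomize=True)
    def test_total_and_rewrap_stable(self, x):
        assert torsion_label(x) == torsion_label(wrap_dihedral(x))
        assert torsion_label(x) in {"c", "g", "g-", "s", "s-", "t"}


class TestBackboneClassification:
    @pytest.mark.parametrize(
        "angles, family",
        [
            ((-33.7, 21.9, -6.2), "II"),       # serine IIgg backbone
            ((95.1, -173.4, -180.0), "I'"),    # serine I'gg-
            ((-168.9, 67.2, -177.1), "III'"),  # serine III'gg
            ((159.3, 166.5, 177.3), "I"),
            ((169.6, 5.1, 167.2), "III"),      # aspartic IIItt
            ((180.0, 180.0, 0.0), "Ic"),
            ((90.0, 180.0, 10.0), "I'c"),
            ((180.0, 0.0, 20.0), "IIIc"),
            ((-90.0, 180.0, 180.0), "I'"),     # mirror prototype
            ((168.2, -51.1, -179.4), "III'"),  # threonine III'g-g (psi < 0)
        ],
    )
    def test_assignments(self, angles, family):
        assert classify_backbone(*angles) == family

    def test_equidistant_prototypes_raise(self):
        with pytest.raises(AmbiguousBackboneError):
            classify_backbone(135.0, 180.0, 180.0)  # midway between I and I'

    def test_equidistant_omega_raises(self):
        with pytest.raises(AmbiguousBackboneError):
            classify_backbone(180.0, 180.0, 90.0)

    def test_full_label_with_side_chain(self):
        assert full_label(-33.7, 21.9, -6.2, [59.4, 79.3]) == "IIgg"
        assert full_label(164.6, 162.4, 177.2, [-63.0, 38.8], chi3_cis=True) == "Ig-gc"


class TestDomainTypes:
    def test_torsion_spec_rejects_repeated_atoms(self):
        with pytest.raises(ValueError):
            TorsionSpec("phi", (0, 1, 1, 3))

    def test_conformer_wraps_and_checks_masses(self):
        c = Conformer(np.array([190.0, -190.0]))
        assert c.torsions == pytest.approx([-170.0, 170.0])
        with pytest.raises(ValueError):
            Conformer(np.zeros(1), coords=np.zeros((2, 3)), masses=np.ones(3))

    def test_spectro_params_ordering_and_trace(self):
        with pytest.raises(ValueError):
            SpectroParams(A=1.0, B=2.0, C=0.5)
        p = SpectroParams(chi_aa=-1.208, chi_bb=-0.343, chi_cc=1.551)
        assert p.quadrupole_trace() == pytest.approx(0.0, abs=1e-6)


def _brute_inertia_constants(coords, masses):
    """Independent oracle: inertia tensor via the dyadic identity."""
    coords = np.asarray(coords, float)
    m = np.asarray(masses, float)
    r = coords - np.average(coords, axis=0, weights=m)
    tensor = np.zeros((3, 3))
    for mi, ri in zip(m, r):
        tensor += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    moments = np.sort(np.linalg.eigvalsh(tensor))
    return np.sort(505379.0 / moments)[::-1]


class TestRotationalConstants:
    def test_diatomic_closed_form(self):
        a, b, c = rotational_constants_from_geometry(
            [[0, 0, 0], [1, 0, 0]], [1.0, 1.0]
        )
        assert math.isinf(a)
        assert b == pytest.approx(1010758.0)
        assert c == pytest.approx(1010758.0)

    def test_inverse_square_scaling(self, rng):
        coords = rng.normal(size=(6, 3))
        masses = rng.uniform(1, 16, size=6)
        base = rotational_constants_from_geometry(coords, masses)
        scaled = rotational_constants_from_geometry(2.0 * coords, masses)
        assert np.allclose(scaled, np.asarray(base) / 4.0)

    def test_matches_brute_force_oracle(self):
        coords = [[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.0, 0.9, 0.0]]
        masses = [15.999, 12.011, 1.008]
        got = rotational_constants_from_geometry(coords, masses)
        want = _brute_inertia_constants(coords, masses)
        assert np.allclose(got, want)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(5, 3))
        masses = rng.uniform(1, 32, size=5)
        rot = Rotation.from_euler("zyx", [31.0, -54.0, 12.0], degrees=True)
        moved = rot.apply(coords) + np.array([3.0, -7.0, 0.5])
        a = rotational_constants_from_geometry(coords, masses)
        b = rotational_constants_from_geometry(moved, masses)
        assert np.allclose(a, b, rtol=1e-9)


def _rotation_grid_rmsd(a, b, n_samples=4000):
    """Brute-force superposition oracle: best RMSD over sampled rotations."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    rots = Rotation.random(n_samples, rng=np.random.default_rng(7))
    best = np.inf
    for r in rots:
        d = a0 - r.apply(b0)
        best = min(best, np.sqrt((d**2).sum() / len(a)))
    return best


class TestHeavyAtomRmsd:
    def _conf(self, coords, masses):
        return Conformer(np.zeros(1), coords=np.array(coords, float),
                         masses=np.array(masses, float))

    def test_identity_and_symmetry(self, rng):
        coords = rng.normal(size=(4, 3))
        c1 = self._conf(coords, [12, 12, 16, 14])
        c2 = self._conf(coords + 0.1, [12, 12, 16, 14])
        assert heavy_atom_rmsd(c1, c1) == pytest.approx(0.0, abs=1e-12)
        assert heavy_atom_rmsd(c1, c2) == pytest.approx(heavy_atom_rmsd(c2, c1))

    def test_rigid_motion_gives_zero(self, rng):
        coords = rng.normal(size=(5, 3))
        rot = Rotation.from_euler("xyz", [10, 80, -33], degrees=True)
        moved = rot.apply(coords) + 5.0
        c1 = self._conf(coords, [12] * 5)
        c2 = self._conf(moved, [12] * 5)
        assert heavy_atom_rmsd(c1, c2) == pytest.approx(0.0, abs=1e-9)

    def test_hydrogens_excluded(self, rng):
        coords = rng.normal(size=(4, 3))
        other = coords.copy()
        other[0] += 10.0  # a hydrogen moved far away must not matter
        c1 = self._conf(coords, [1.008, 12, 12, 16])
        c2 = self._conf(other, [1.008, 12, 12, 16])
        assert heavy_atom_rmsd(c1, c2) == pytest.approx(0.0, abs=1e-9)

    def test_matches_rotation_grid_oracle(self, rng):
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(scale=0.2, size=(6, 3))
        exact = kabsch_rmsd(a, b)
        brute = _rotation_grid_rmsd(a, b)
        assert exact <= brute + 1e-12
        assert brute - exact < 0.02

    def test_mismatched_sets_rejected(self, rng):
        c1 = self._conf(rng.normal(size=(3, 3)), [12] * 3)
        c2 = self._conf(rng.normal(size=(4, 3)), [12] * 4)
        with pytest.raises(ValueError):
            heavy_atom_rmsd(c1, c2)


BUTANE_LIKE = """
C
C 1 1.54
C 2 1.54 1 111.0
C 3 1.54 2 111.0 1 180.0 @chi
"""


class TestZMatrix:
    @pytest.mark.parametrize("target", [60.0, -60.0, 180.0, -111.25, 0.0])
    def test_torsion_round_trip(self, target):
        rows = parse_zmatrix(BUTANE_LIKE)
        coords = zmatrix_to_cartesian(rows, {"chi": target})
        measured = measure_dihedral(*coords[[0, 1, 2, 3]])
        assert math.isclose(
            math.cos(math.radians(measured)), math.cos(math.radians(target)),
            abs_tol=1e-9,
        )
        assert math.isclose(
            math.sin(math.radians(measured)), math.sin(math.radians(target)),
            abs_tol=1e-9,
        )

    def test_bond_and_angle_round_trip(self):
        rows = parse_zmatrix(BUTANE_LIKE)
        coords = zmatrix_to_cartesian(rows)
        assert np.linalg.norm(coords[1] - coords[0]) == pytest.approx(1.54)
        v1 = coords[0] - coords[1]
        v2 = coords[2] - coords[1]
        ang = math.degrees(
            math.acos(np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2))
        )
        assert ang == pytest.approx(111.0, abs=1e-8)

    def test_against_independent_embedding(self):
        # right-angle chain embedded by hand: anti (180 deg) dihedral, 90 deg
        # angles, unit bonds
        zm = """
        C
        C 1 1.0
        C 2 1.0 1 90.0
        C 3 1.0 2 90.0 1 180.0
        """
        coords = zmatrix_to_cartesian(parse_zmatrix(zm))
        manual = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]], dtype=float
        )
        assert kabsch_rmsd(coords, manual) < 1e-6

    def test_undefined_reference_rejected(self):
        with pytest.raises(ValueError):
            parse_zmatrix("C\nC 3 1.5")

    def test_masses(self):
        rows = parse_zmatrix("N\nH 1 1.01")
        assert zmatrix_masses(rows) == pytest.approx([14.007, 1.008])


def test_xyz_round_trip(rng):
    symbols = ["C", "N", "O", "H"]
    coords = rng.normal(size=(4, 3))
    text = write_xyz(symbols, coords, "test molecule")
    s2, c2 = read_xyz(text)
    assert s2 == symbols
    assert np.allclose(c2, coords, atol=1e-7)
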