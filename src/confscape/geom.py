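"""Internal-coordinate geometry, dihedral arithmetic, and conformer nomenclature.

Gas-phase alpha-amino-acid conformers are labelled by their backbone
hydrogen-bond motif (families I, II, III and the primed/cis variants) plus
cis/gauche/skew/trans letters for the remaining soft torsions.  The backbone
angles are phi' (nitrogen lone pair - N - C-alpha - C'), psi
(N - C-alpha - C' - O(H)) and omega (C-alpha - C' - O - H); phi' is the
customary phi shifted by +120 degrees to track the amine lone pair instead of
one N-H bond.

All angles are degrees, wrapped to [-180, 180).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "TorsionSpec",
    "Conformer",
    "SpectroParams",
    "wrap_dihedral",
    "phi_prime",
    "torsion_label",
    "classify_backbone",
    "full_label",
    "rotational_constants_from_geometry",
    "heavy_atom_rmsd",
    "kabsch_rmsd",
    "measure_dihedral",
    "zmatrix_to_cartesian",
    "parse_zmatrix",
    "read_xyz",
    "write_xyz",
    "INERTIA_CONSTANT_MHZ_U_A2",
]

#: Conversion between a principal moment of inertia (u * Angstrom^2) and a
#: rotational constant (MHz): h / (8 pi^2) in these units.
INERTIA_CONSTANT_MHZ_U_A2 = 505379.0

# Default cis/gauche/skew/trans bin edges (degrees on |angle|).  Calibrated so
# that every self-consistent dihedral row printed for the seven amino acids
# reproduces its published letter (the amide-side-chain chi2 of asparagine IIgg
# sits at 101 deg and is published as gauche; the -29.5 deg chi2 of its I'gg-
# conformer is published as gauche-minus).
CIS_MAX = 25.0
GAUCHE_MAX = 110.0
SKEW_MAX = 150.0


def wrap_dihedral(angle: float) -> float:
    """Wrap an angle in degrees onto [-180, 180)."""
    if not math.isfinite(angle):
        raise ValueError(f"dihedral angle must be finite, got {angle!r}")
    return (angle + 180.0) % 360.0 - 180.0


def wrap_array(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("dihedral angles must be finite")
    return (a + 180.0) % 360.0 - 180.0


def circular_difference(a, b):
    """Signed shortest angular distance b - a, element-wise, in [-180, 180)."""
    return wrap_array(np.asarray(b, dtype=float) - np.asarray(a, dtype=float))


def phi_prime(phi: float) -> float:
    """Lone-pair-referenced backbone angle: phi' = phi + 120 (wrapped)."""
    return wrap_dihedral(phi + 120.0)


def torsion_label(
    angle: float,
    *,
    cis_max: float = CIS_MAX,
    gauche_max: float = GAUCHE_MAX,
    skew_max: float = SKEW_MAX,
) -> str:
    """Bin a wrapped torsion into c / g / g- / s / s- / t.

    cis and trans are unsigned (the sign is ill-defined near 0/180); gauche and
    skew carry a trailing ``-`` for negative angles.
    """
    a = wrap_dihedral(angle)
    mag = abs(a)
    if mag < cis_max:
        return "c"
    if mag >= skew_max:
        return "t"
    base = "g" if mag < gauche_max else "s"
    return base + ("-" if a < 0 else "")


# Backbone prototypes on the (phi', psi) torus.  The omega angle only selects
# the cis-carboxyl "c" variant and is handled separately, because folding it
# into the distance makes II and IIIc exactly equidistant from a
# (phi', psi, omega) = (0, 0, 0)-like input.  Families with two mirror-related
# wells get sign-mirrored prototypes.  The III' psi prototype sits at +-45 deg:
# the published III' conformers of the polar amino acids span |psi| = 24-86 deg
# while every published III has |psi| <= 5 deg, so the III/III' watershed lies
# near 22 deg rather than at the 45-90 deg midpoint a psi = 90 prototype
# would give.
_BACKBONE_PROTOTYPES: list[tuple[str, float, float]] = [
    ("I", 180.0, 180.0),
    ("II", 0.0, 0.0),
    ("III", 180.0, 0.0),
    ("I'", 90.0, 180.0),
    ("I'", -90.0, 180.0),
    ("III'", 180.0, 45.0),
    ("III'", 180.0, -45.0),
]

#: Families whose omega ~ 0 counterpart is a distinct published conformer.
_CIS_CAPABLE = {"I", "I'", "III"}


class AmbiguousBackboneError(ValueError):
    """Raised when two backbone prototypes are exactly equidistant."""


def classify_backbone(
    phi_prime_deg: float,
    psi_deg: float,
    omega_deg: float,
    *,
    tie_tol: float = 1e-9,
) -> str:
    """Assign the backbone hydrogen-bond family from (phi', psi, omega).

    Nearest-prototype assignment on the (phi', psi) torus; omega closer to 0
    than to 180 appends the cis-carboxyl ``c`` suffix for the I, I' and III
    families.  Exactly equidistant prototypes raise
    :class:`AmbiguousBackboneError` instead of picking silently.
    """
    pp = wrap_dihedral(phi_prime_deg)
    ps = wrap_dihedral(psi_deg)
    om = wrap_dihedral(omega_deg)

    dists = []
    for name, p0, p1 in _BACKBONE_PROTOTYPES:
        d = math.hypot(
            float(circular_difference(pp, p0)), float(circular_difference(ps, p1))
        )
        dists.append((d, name))
    dists.sort(key=lambda t: t[0])
    best_d, best_name = dists[0]
    runner = next((d for d, n in dists if n != best_name), None)
    if runner is not None and abs(runner - best_d) <= tie_tol:
        tied = sorted({n for d, n in dists if abs(d - best_d) <= tie_tol})
        raise AmbiguousBackboneError(
            f"backbone ({pp:.1f}, {ps:.1f}) equidistant from prototypes {tied}"
        )

    family = best_name
    if family in _CIS_CAPABLE:
        d0 = abs(float(circular_difference(om, 0.0)))
        d180 = abs(float(circular_difference(om, 180.0)))
        if abs(d0 - d180) <= tie_tol:
            raise AmbiguousBackboneError(
                f"omega {om:.1f} equidistant from 0 and 180"
            )
        if d0 < d180:
            family += "c"
    return family


def full_label(
    phi_prime_deg: float,
    psi_deg: float,
    omega_deg: float,
    chi_angles: Sequence[float] = (),
    *,
    chi3_cis: bool = False,
) -> str:
    """Backbone family plus one c/g/s/t letter per side-chain torsion.

    ``chi3_cis`` appends the trailing ``c`` used when a terminal carboxyl
    torsion is frozen cis (aspartic-acid convention).
    """
    fam = classify_backbone(phi_prime_deg, psi_deg, omega_deg)
    letters = "".join(torsion_label(c) for c in chi_angles)
    return fam + letters + ("c" if chi3_cis else "")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TorsionSpec:
    """One soft torsion: name, defining atom quadruple, backbone/side-chain role."""

    name: str
    atom_quad: tuple[int, int, int, int]
    role: str = "side-chain"  # "backbone" | "side-chain"
    stiff: bool = False

    def __post_init__(self):
        if len(set(self.atom_quad)) != 4:
            raise ValueError(f"torsion {self.name}: atom indices must be distinct")
        if self.role not in ("backbone", "side-chain"):
            raise ValueError(f"torsion {self.name}: unknown role {self.role!r}")


@dataclass
class Conformer:
    """A stationary point: soft-torsion vector, optional geometry, energies.

    ``energies`` maps a level-of-theory key (e.g. ``dE_rDSD``) to a relative
    energy in cm^-1, mirroring one row of the per-molecule energy tables.
    """

    torsions: np.ndarray
    coords: Optional[np.ndarray] = None
    masses: Optional[np.ndarray] = None
    label: str = ""
    energies: dict = field(default_factory=dict)

    def __post_init__(self):
        self.torsions = wrap_array(self.torsions)
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.masses is None:
                raise ValueError("coords without masses")
            self.masses = np.asarray(self.masses, dtype=float)
            if len(self.masses) != len(self.coords):
                raise ValueError("coords and masses differ in atom count")

    def heavy_coords(self, mass_cut: float = 3.0) -> np.ndarray:
        if self.coords is None:
            raise ValueError("conformer carries no geometry")
        return self.coords[self.masses > mass_cut]


@dataclass
class SpectroParams:
    """Rotational constants (MHz), 14N quadrupole couplings (MHz), dipoles (D)."""

    A: Optional[float] = None
    B: Optional[float] = None
    C: Optional[float] = None
    chi_aa: Optional[float] = None
    chi_bb: Optional[float] = None
    chi_cc: Optional[float] = None
    mu_a: Optional[float] = None
    mu_b: Optional[float] = None
    mu_c: Optional[float] = None

    def __post_init__(self):
        abc = [x for x in (self.A, self.B, self.C) if x is not None]
        if len(abc) == 3:
            a, b, c = self.A, self.B, self.C
            if not (a >= b >= c):
                raise ValueError(f"rotational constants not ordered A>=B>=C: {abc}")

    def quadrupole_trace(self) -> Optional[float]:
        chis = (self.chi_aa, self.chi_bb, self.chi_cc)
        if any(x is None for x in chis):
            return None
        return sum(chis)


# ---------------------------------------------------------------------------
# Rigid-rotor constants and superposition
# ---------------------------------------------------------------------------


def rotational_constants_from_geometry(
    coords, masses, *, linear_tol: float = 1e-10
) -> tuple[float, float, float]:
    """Principal rotational constants (MHz) of a rigid rotor, sorted A >= B >= C.

    A linear geometry has one (numerically) vanishing moment; the associated
    constant is returned as ``inf``.
    """
    xyz = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or len(m) != len(xyz):
        raise ValueError("coords must be (n, 3) with matching masses")
    if len(xyz) < 2:
        raise ValueError("need at least two atoms")
    com = np.average(xyz, axis=0, weights=m)
    r = xyz - com
    r2 = np.sum(r * r, axis=1)
    tensor = np.zeros((3, 3))
    for k in range(3):
        tensor[k, k] = np.sum(m * (r2 - r[:, k] ** 2))
    for i, j in ((0, 1), (0, 2), (1, 2)):
        val = -np.sum(m * r[:, i] * r[:, j])
        tensor[i, j] = tensor[j, i] = val
    moments = np.linalg.eigvalsh(tensor)  # ascending
    scale = max(moments[-1], 1.0)
    consts = [
        math.inf if mom < linear_tol * scale else INERTIA_CONSTANT_MHZ_U_A2 / mom
        for mom in moments
    ]
    consts.sort(reverse=True)
    return tuple(consts)


def kabsch_rmsd(coords_a, coords_b) -> float:
    """Minimum RMSD over rigid rotations + translations (optimal superposition)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    with warnings.catch_warnings():
        # align_vectors warns for degenerate (e.g. planar) sets; the rotation
        # it returns is still optimal for our symmetric weighting
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(a0, b0)
    d = a0 - rot.apply(b0)
    return math.sqrt(float(np.sum(d * d)) / len(a))


def heavy_atom_rmsd(conf_a: Conformer, conf_b: Conformer) -> float:
    """Kabsch RMSD over non-hydrogen atoms, input-order correspondence."""
    ha, hb = conf_a.heavy_coords(), conf_b.heavy_coords()
    if ha.shape != hb.shape:
        raise ValueError("conformers have different heavy-atom counts")
    return kabsch_rmsd(ha, hb)


# ---------------------------------------------------------------------------
# Internal coordinates
# ---------------------------------------------------------------------------


def measure_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, [-180, 180)) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return wrap_dihedral(math.degrees(math.atan2(y, x)))


@dataclass(frozen=True)
class ZMatrixRow:
    symbol: str
    mass: float
    bond_ref: int = -1
    bond: float = 0.0
    angle_ref: int = -1
    angle: float = 0.0
    dihedral_ref: int = -1
    dihedral: float = 0.0
    torsion_name: str = ""  # non-empty marks an overridable soft torsion


_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "F": 18.998, "Cl": 35.45, "P": 30.974, "X": 1.0,
}


def parse_zmatrix(text: str) -> list[ZMatrixRow]:
    """Parse the minimal Z-matrix dialect.

    One atom per line::

        SYM
        SYM  ref1  bond
        SYM  ref1  bond  ref2  angle
        SYM  ref1  bond  ref2  angle  ref3  dihedral  [@torsion_name]

    Atom references are 1-based line numbers of earlier atoms; ``@name`` tags a
    dihedral as a named soft torsion that may be overridden at build time.
    Lines starting with ``#`` are comments.
    """
    rows: list[ZMatrixRow] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        sym = parts[0]
        mass = _MASSES.get(sym)
        if mass is None:
            raise ValueError(f"unknown element symbol {sym!r}")
        n = len(rows)
        name = ""
        if parts and parts[-1].startswith("@"):
            name = parts[-1][1:]
            parts = parts[:-1]
        vals = parts[1:]
        if n == 0:
            if vals:
                raise ValueError("first atom takes no references")
            rows.append(ZMatrixRow(sym, mass))
            continue

        def ref(tok: str) -> int:
            i = int(tok) - 1
            if not (0 <= i < n):
                raise ValueError(f"atom {n + 1}: reference {tok} not yet defined")
            return i

        if n == 1:
            if len(vals) != 2:
                raise ValueError("second atom: expected 'ref bond'")
            rows.append(ZMatrixRow(sym, mass, ref(vals[0]), float(vals[1])))
        elif n == 2:
            if len(vals) != 4:
                raise ValueError("third atom: expected 'ref bond ref angle'")
            rows.append(
                ZMatrixRow(sym, mass, ref(vals[0]), float(vals[1]),
                           ref(vals[2]), float(vals[3]))
            )
        else:
            if len(vals) != 6:
                raise ValueError(
                    f"atom {n + 1}: expected 'ref bond ref angle ref dihedral'"
                )
            rows.append(
                ZMatrixRow(sym, mass, ref(vals[0]), float(vals[1]),
                           ref(vals[2]), float(vals[3]),
                           ref(vals[4]), float(vals[5]), torsion_name=name)
            )
    if not rows:
        raise ValueError("empty Z-matrix")
    return rows


def zmatrix_to_cartesian(
    rows: Sequence[ZMatrixRow], torsion_overrides: Optional[dict] = None
) -> np.ndarray:
    """Deterministic Cartesian embedding (natural-extension reference frame).

    ``torsion_overrides`` maps torsion names to dihedral values in degrees;
    unnamed dihedrals keep their Z-matrix value.
    """
    overrides = dict(torsion_overrides or {})
    known = {r.torsion_name for r in rows if r.torsion_name}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"overrides for undeclared torsions: {sorted(unknown)}")

    coords = np.zeros((len(rows), 3))
    for i, row in enumerate(rows):
        if i == 0:
            continue
        if i == 1:
            coords[1] = coords[row.bond_ref] + [row.bond, 0.0, 0.0]
            continue
        if i == 2:
            a = coords[row.bond_ref]
            b = coords[row.angle_ref]
            ab = b - a
            ab /= np.linalg.norm(ab)
            theta = math.radians(row.angle)
            # place in the xy plane
            perp = np.array([-ab[1], ab[0], 0.0])
            if np.linalg.norm(perp) < 1e-12:
                perp = np.array([0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            coords[2] = a + row.bond * (math.cos(theta) * ab + math.sin(theta) * perp)
            continue
        dih = overrides.get(row.torsion_name, row.dihedral) if row.torsion_name else row.dihedral
        coords[i] = _place_atom(
            coords[row.bond_ref], coords[row.angle_ref], coords[row.dihedral_ref],
            row.bond, row.angle, dih,
        )
    return coords


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """Position an atom at given bond/angle/dihedral from anchors a-b-c."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    ba = a - b
    cb = b - c
    n = np.cross(cb, ba)
    if np.linalg.norm(n) < 1e-12:
        raise ValueError("collinear reference atoms in Z-matrix")
    n /= np.linalg.norm(n)
    ba_hat = ba / np.linalg.norm(ba)
    m = np.cross(n, ba_hat)
    d = np.array(
        [
            -bond * math.cos(theta),
            bond * math.sin(theta) * math.cos(phi),
            -bond * math.sin(theta) * math.sin(phi),
        ]
    )
    frame = np.column_stack([ba_hat, m, n])
    return a + frame @ d


def zmatrix_masses(rows: Sequence[ZMatrixRow]) -> np.ndarray:
    return np.array([r.mass for r in rows])


# ---------------------------------------------------------------------------
# XYZ I/O (standard two-header-line dialect)
# ---------------------------------------------------------------------------


def read_xyz(text: str) -> tuple[list[str], np.ndarray]:
    lines = text.strip().splitlines()
    n = int(lines[0].strip())
    body = lines[2 : 2 + n]
    if len(body) != n:
        raise ValueError(f"XYZ declares {n} atoms but has {len(body)} coordinate lines")
    symbols, coords = [], []
    for line in body:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return symbols, np.asarray(coords)


def write_xyz(symbols: Sequence[str], coords, comment: str = "") -> str:
    xyz = np.asarray(coords, dtype=float)
    lines = [str(len(symbols)), comment.replace("\n", " ")]
    for s, (x, y, z) in zip(symbols, xyz):
        lines.append(f"{s:2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    return "\n".join(lines) + "\n"
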