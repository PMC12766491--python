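"""Crystal structures, d-spacings, Bragg angles and structure factors.

The powder forward model needs, for every reflection (h, k, l) inside the
measured angular range, the lattice-plane spacing d and the squared
structure-factor magnitude |F(hkl)|^2.  Both are computed from first
principles: d from the reciprocal metric tensor of the unit cell (exact for
all crystal systems) and F from a direct sum over the atomic sites with
tabulated sum-of-Gaussians atomic form factors (International Tables vol. C
parameterization, as shipped by gemmi).

Structures are read from CIF files (symmetry operators listed in the file
are applied to expand the asymmetric unit) or from a small JSON dialect
used in tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "AtomSite",
    "CrystalStructure",
    "Reflection",
    "NoDiffraction",
    "MissingFormFactorError",
    "d_spacing",
    "bragg_angle",
    "enumerate_reflections",
    "structure_factor",
    "load_cif",
    "load_json",
    "wavelength_A",
]

#: hc in keV * Angstrom, used to convert photon energy to wavelength.
HC_KEV_ANGSTROM = 12.398420


def wavelength_A(energy_keV: float) -> float:
    """Photon wavelength in Angstrom for an energy in keV."""
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    return HC_KEV_ANGSTROM / energy_keV


class NoDiffraction(Exception):
    """Raised when n*lambda > 2d, i.e. Bragg's law has no solution."""


class MissingFormFactorError(KeyError):
    """Raised when an element has no tabulated form factor."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell lengths in Angstrom and angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        # positive-definiteness of the metric shows up as a positive volume
        if self.volume <= 0 or not math.isfinite(self.volume):
            raise ValueError("cell angles do not define a valid lattice")

    @property
    def metric_tensor(self) -> np.ndarray:
        """Direct-space metric tensor G (Angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca = math.cos(math.radians(self.alpha))
        cb = math.cos(math.radians(self.beta))
        cg = math.cos(math.radians(self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    @property
    def reciprocal_metric_tensor(self) -> np.ndarray:
        """Reciprocal metric tensor G* = G^-1 (Angstrom^-2)."""
        return np.linalg.inv(self.metric_tensor)

    @property
    def volume(self) -> float:
        """Cell volume in Angstrom^3."""
        det = float(np.linalg.det(self.metric_tensor))
        return math.sqrt(det) if det > 0 else float("nan")

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with r_cart = M @ r_frac (Angstrom, standard PDB frame)."""
        a, b, c = self.a, self.b, self.c
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        cosal, cosbe, cosga = math.cos(al), math.cos(be), math.cos(ga)
        singa = math.sin(ga)
        v = self.volume
        return np.array(
            [
                [a, b * cosga, c * cosbe],
                [0.0, b * singa, c * (cosal - cosbe * cosga) / singa],
                [0.0, 0.0, v / (a * b * singa)],
            ]
        )


@dataclass(frozen=True)
class AtomSite:
    """One atom in the unit cell (fractional coordinates)."""

    element: str
    frac_xyz: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 0.0  # isotropic displacement, Angstrom^2

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in (0, 1]")
        el = gemmi.Element(self.element)
        if el.atomic_number == 0:
            raise MissingFormFactorError(self.element)


@dataclass
class CrystalStructure:
    """A crystal: unit cell plus the full (P1-expanded) site list."""

    name: str
    cell: UnitCell
    sites: list[AtomSite]
    formula: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("structure must contain at least one site")
        if not self.formula:
            self.formula = self.site_formula()

    def site_formula(self) -> dict[str, float]:
        """Element counts per cell implied by sites x occupancy."""
        out: dict[str, float] = {}
        for s in self.sites:
            out[s.element] = out.get(s.element, 0.0) + s.occupancy
        return out


@dataclass(frozen=True)
class Reflection:
    """A lattice reflection with spacing d (Angstrom) and |F|^2 (electron^2)."""

    hkl: tuple[int, int, int]
    d: float
    f2: float

    def two_theta_deg(self, wavelength: float) -> float:
        """Scattering angle 2-theta in degrees at the given wavelength."""
        return 2.0 * bragg_angle(self.d, wavelength)


def d_spacing(cell: UnitCell, hkl) -> float:
    """Lattice-plane spacing d(hkl) = 1/sqrt(h^T G* h), exact for any system."""
    h = np.asarray(hkl, dtype=float)
    if h.shape != (3,):
        raise ValueError("hkl must be a triple")
    if np.all(h == 0):
        raise ValueError("hkl = (0,0,0) has no lattice plane")
    inv_d2 = float(h @ cell.reciprocal_metric_tensor @ h)
    return 1.0 / math.sqrt(inv_d2)


def bragg_angle(d: float, wavelength: float, n: int = 1) -> float:
    """Bragg half-angle theta in degrees: n*lambda = 2 d sin(theta).

    Raises :class:`NoDiffraction` when ``n*wavelength > 2*d`` (physically no
    diffracted beam, distinct from an invalid argument).
    """
    if d <= 0 or wavelength <= 0:
        raise ValueError("d and wavelength must be positive")
    if n < 1 or int(n) != n:
        raise ValueError("reflection order n must be a positive integer")
    s = n * wavelength / (2.0 * d)
    if s > 1.0:
        raise NoDiffraction(f"n*lambda/(2d) = {s:.4f} > 1")
    return math.degrees(math.asin(s))


def _it92_coef(element: str) -> gemmi.IT92Coef:
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise MissingFormFactorError(f"no form factor for element {element!r}")
    return gemmi.IT92_get_exact(el, 0)


def form_factor(element: str, stol2) -> np.ndarray:
    """Atomic scattering factor f0 at (sin(theta)/lambda)^2 values (A^-2)."""
    coef = _it92_coef(element)
    stol2 = np.asarray(stol2, dtype=float)
    out = np.empty(stol2.shape)
    flat = stol2.ravel()
    res = out.ravel()
    for i, v in enumerate(flat):
        res[i] = coef.calculate_sf(float(v))
    return out if out.shape else float(out)


def enumerate_reflections(
    structure: CrystalStructure,
    wavelength: float,
    two_theta_max: float,
    two_theta_min: float = 0.0,
) -> list[Reflection]:
    """All reflections with 2-theta in (two_theta_min, two_theta_max].

    The full sphere of (h, k, l) is enumerated, so the multiplicity of
    symmetry-equivalent reflections is represented implicitly by repeated
    entries at the same d.  Output is sorted by ascending 2-theta, with a
    lexicographic hkl tie-break for determinism.
    """
    if not 0.0 < two_theta_max < 180.0:
        raise ValueError("two_theta_max must lie in (0, 180) degrees")
    d_min = wavelength / (2.0 * math.sin(math.radians(two_theta_max / 2.0)))
    cell = structure.cell
    gstar = cell.reciprocal_metric_tensor

    # conservative per-axis index bounds: |h_i| <= a_i* . . . via d >= d_min
    # |h| along axis i alone satisfies h^2 * G*_ii <= 1/d_min^2
    bounds = [int(math.floor(1.0 / (d_min * math.sqrt(gstar[i, i])))) for i in range(3)]
    hs = np.arange(-bounds[0], bounds[0] + 1)
    ks = np.arange(-bounds[1], bounds[1] + 1)
    ls = np.arange(-bounds[2], bounds[2] + 1)
    H = np.stack(np.meshgrid(hs, ks, ls, indexing="ij"), axis=-1).reshape(-1, 3)
    H = H[np.any(H != 0, axis=1)]
    inv_d2 = np.einsum("ij,jk,ik->i", H, gstar, H)
    d = 1.0 / np.sqrt(inv_d2)
    keep = d >= d_min * (1.0 - 1e-12)
    H, d = H[keep], d[keep]

    # apply the lower angular cut (default 0 keeps everything diffracting)
    sin_t = wavelength / (2.0 * d)
    keep = sin_t <= 1.0
    if two_theta_min > 0.0:
        keep &= sin_t > math.sin(math.radians(two_theta_min / 2.0))
    H, d = H[keep], d[keep]

    f2 = structure_factor_many(structure, H)
    two_theta = 2.0 * np.degrees(np.arcsin(wavelength / (2.0 * d)))
    order = np.lexsort((H[:, 2], H[:, 1], H[:, 0], two_theta))
    return [
        Reflection(hkl=(int(h[0]), int(h[1]), int(h[2])), d=float(dd), f2=float(ff))
        for h, dd, ff in zip(H[order], d[order], f2[order])
    ]


def structure_factor_many(structure: CrystalStructure, hkls: np.ndarray) -> np.ndarray:
    """|F|^2 for an (N, 3) array of reflections (vectorized direct sum)."""
    hkls = np.atleast_2d(np.asarray(hkls, dtype=float))
    cell = structure.cell
    gstar = cell.reciprocal_metric_tensor
    inv_d2 = np.einsum("ij,jk,ik->i", hkls, gstar, hkls)
    stol2 = inv_d2 / 4.0  # (sin(theta)/lambda)^2 = 1/(4 d^2)

    elements = sorted({s.element for s in structure.sites})
    f0 = {el: form_factor(el, stol2) for el in elements}

    xyz = np.array([s.frac_xyz for s in structure.sites])  # (M, 3)
    occ = np.array([s.occupancy for s in structure.sites])
    b = np.array([s.b_iso for s in structure.sites])
    fmat = np.stack([f0[s.element] for s in structure.sites], axis=1)  # (N, M)
    debye = np.exp(-np.outer(stol2, b))  # (N, M)
    phase = np.exp(2j * np.pi * (hkls @ xyz.T))  # (N, M)
    F = np.sum(occ[None, :] * fmat * debye * phase, axis=1)
    return np.abs(F) ** 2


def structure_factor(structure: CrystalStructure, hkl, wavelength: float | None = None) -> float:
    """Squared structure-factor magnitude |F(hkl)|^2 in electron^2.

    ``wavelength`` is accepted for interface symmetry but unused: the form
    factor argument sin(theta)/lambda equals 1/(2d) independent of lambda.
    """
    return float(structure_factor_many(structure, np.asarray(hkl, dtype=float))[0])


# ---------------------------------------------------------------------------
# structure input

def load_cif(path: str | Path, name: str | None = None) -> CrystalStructure:
    """Read a small-molecule CIF; symmetry operators expand the site list to P1."""
    small = gemmi.read_small_structure(str(path))
    cell = UnitCell(
        small.cell.a, small.cell.b, small.cell.c,
        small.cell.alpha, small.cell.beta, small.cell.gamma,
    )
    sites: list[AtomSite] = []
    for site in small.get_all_unit_cell_sites():
        b_iso = 8.0 * math.pi**2 * site.u_iso  # B = 8 pi^2 <u^2>; 0 if absent
        sites.append(
            AtomSite(
                element=site.element.name,
                frac_xyz=(site.fract.x % 1.0, site.fract.y % 1.0, site.fract.z % 1.0),
                occupancy=site.occ if site.occ > 0 else 1.0,
                b_iso=b_iso,
            )
        )
    return CrystalStructure(name=name or small.name or Path(path).stem, cell=cell, sites=sites)


def load_json(path: str | Path) -> CrystalStructure:
    """Read the JSON structure dialect used in tests.

    Schema::

        {"name": ..., "cell": {"a": ..., ..., "gamma": ...},
         "sites": [{"element": "C", "xyz": [x, y, z],
                    "occupancy": 1.0, "b_iso": 0.0}, ...]}
    """
    blob = json.loads(Path(path).read_text())
    cell = UnitCell(**blob["cell"])
    sites = [
        AtomSite(
            element=s["element"],
            frac_xyz=tuple(s["xyz"]),
            occupancy=s.get("occupancy", 1.0),
            b_iso=s.get("b_iso", 0.0),
        )
        for s in blob["sites"]
    ]
    return CrystalStructure(name=blob.get("name", Path(path).stem), cell=cell, sites=sites)


def builtin_structure_path(key: str) -> Path:
    """Path to a vendored mineral CIF: 'COM', 'COD' or 'UA'."""
    names = {
        "COM": "whewellite_model.cif",
        "COD": "weddellite_model.cif",
        "UA": "uricite_model.cif",
    }
    try:
        fname = names[key.upper()]
    except KeyError:
        raise KeyError(f"unknown material {key!r}; expected one of {sorted(names)}") from None
    return Path(__file__).parent / "data" / fname


def load_builtin(key: str) -> CrystalStructure:
    """Load one of the vendored kidney-stone mineral models (COM/COD/UA)."""
    return load_cif(builtin_structure_path(key), name=key.upper())
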