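"""Beer-Lambert transmission and coherent-scattering cross sections.

Two energy arguments drive the choice of a higher X-ray energy for
diffraction through tissue: the soft-tissue attenuation coefficient drops
steeply with energy (so transmission through centimetres of tissue rises
exponentially), while the coherent (Rayleigh) scattering cross section of
the stone mineral — the source of the diffraction signal — drops as well,
but more slowly in the forward direction.  This module quantifies both.

Soft-tissue attenuation comes from a vendored NIST-style reference table
(ICRU-44 composition) with log-log interpolation.  Elemental coherent cross
sections are computed in the independent-atom approximation by integrating
the Thomson differential cross section weighted with the tabulated atomic
form factor:

    sigma_coh(E) = pi * r_e^2 * Int_0^pi (1 + cos^2 th) |f(q)|^2 sin th dth

with q = 4 pi sin(th/2)/lambda.  Anomalous dispersion is neglected (light
elements, tens of keV).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .crystal import form_factor, wavelength_A

__all__ = [
    "MuTable",
    "AttenuationTable",
    "load_mu_table",
    "transmission",
    "mu_reduction",
    "transmission_gain",
    "coherent_cross_section",
    "coherent_cross_section_ratio",
    "parse_formula",
]

_DATA = Path(__file__).parent / "data"

#: classical electron radius squared, in barn (1 barn = 1e-24 cm^2)
R_E2_BARN = 0.0794078

#: default soft-tissue density in g/cm^3 used for mass -> linear conversion
SOFT_TISSUE_DENSITY = 1.06

_MATERIAL_FILES = {
    "soft_tissue": ("soft_tissue_mu.csv", SOFT_TISSUE_DENSITY),
    "silicon": ("silicon_mu.csv", 2.33),
    "air": ("air_mu.csv", 1.205e-3),
}


class CoverageError(ValueError):
    """Requested energy lies outside the tabulated grid."""


@dataclass(frozen=True)
class MuTable:
    """Linear attenuation coefficient mu(E) on a keV grid, log-log interpolated."""

    energy_keV: np.ndarray
    mu_cm1: np.ndarray
    material: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_keV, dtype=float)
        m = np.asarray(self.mu_cm1, dtype=float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("energy and mu must be congruent 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("mu must be positive")
        object.__setattr__(self, "energy_keV", e)
        object.__setattr__(self, "mu_cm1", m)

    def __call__(self, energy_keV) -> np.ndarray:
        e = np.asarray(energy_keV, dtype=float)
        lo, hi = self.energy_keV[0], self.energy_keV[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise CoverageError(
                f"energy outside {self.material or 'attenuation'} table range "
                f"[{lo:g}, {hi:g}] keV"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energy_keV), np.log(self.mu_cm1))
        )
        return out if out.shape else float(out)


def load_mu_table(material: str, density: float | None = None) -> MuTable:
    """Load a vendored mass-attenuation table and convert to linear mu.

    Known materials: ``soft_tissue``, ``silicon``, ``air``.
    """
    try:
        fname, default_rho = _MATERIAL_FILES[material]
    except KeyError:
        raise KeyError(
            f"unknown material {material!r}; expected one of {sorted(_MATERIAL_FILES)}"
        ) from None
    rho = default_rho if density is None else density
    data = np.loadtxt(_DATA / fname, delimiter=",", comments="#")
    return MuTable(energy_keV=data[:, 0], mu_cm1=data[:, 1] * rho, material=material)


def parse_formula(formula: str | dict[str, float]) -> dict[str, float]:
    """Stoichiometry dict from a formula like ``CaC2O4.H2O`` or ``C5H4N4O3``.

    Dot- or middot-separated fragments are added with an optional leading
    multiplier (``CaC2O4.2H2O``).  A dict passes through unchanged.
    """
    if isinstance(formula, dict):
        return dict(formula)
    total: dict[str, float] = {}
    for frag in re.split(r"[.·]", formula):
        frag = frag.strip()
        if not frag:
            continue
        m = re.match(r"^(\d+(?:\.\d+)?)(.*)$", frag)
        mult = 1.0
        if m and m.group(2):
            mult, frag = float(m.group(1)), m.group(2)
        pairs = re.findall(r"([A-Z][a-z]?)(\d*\.?\d*)", frag)
        if not pairs or "".join(a + b for a, b in pairs) != frag:
            raise ValueError(f"cannot parse formula fragment {frag!r}")
        for el, count in pairs:
            total[el] = total.get(el, 0.0) + mult * (float(count) if count else 1.0)
    if not total:
        raise ValueError(f"empty formula {formula!r}")
    return total


def transmission(mu: float, thickness: float) -> float:
    """Beer-Lambert transmitted fraction exp(-mu * d); mu in 1/cm, d in cm."""
    if mu < 0 or thickness < 0:
        raise ValueError("mu and thickness must be nonnegative")
    return math.exp(-mu * thickness)


def coherent_cross_section(element: str, energy_keV, n_quad: int = 512) -> np.ndarray:
    """Atomic coherent (Rayleigh) cross section in barn/atom.

    Thomson differential cross section integrated over solid angle with the
    squared atomic form factor; Gauss-Legendre quadrature in cos(theta).
    """
    energies = np.atleast_1d(np.asarray(energy_keV, dtype=float))
    if np.any(energies <= 0):
        raise ValueError("energy must be positive")
    u, w = np.polynomial.legendre.leggauss(n_quad)  # u = cos(theta)
    out = np.empty(energies.shape)
    for i, e in enumerate(energies):
        lam = wavelength_A(e)
        # form-factor argument sin(theta/2)/lambda; squared for IT92
        stol2 = (1.0 - u) / (2.0 * lam * lam)
        f = form_factor(element, stol2)
        integrand = (1.0 + u * u) * f * f
        out[i] = math.pi * R_E2_BARN * float(np.dot(w, integrand))
    return out if np.ndim(energy_keV) else float(out[0])


@dataclass
class AttenuationTable:
    """Soft-tissue mu and per-element coherent cross sections on one keV grid."""

    energy_keV: np.ndarray
    mu_tissue_cm1: np.ndarray
    coherent_barn: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energy_keV = np.asarray(self.energy_keV, dtype=float)
        self.mu_tissue_cm1 = np.asarray(self.mu_tissue_cm1, dtype=float)
        if not np.all(np.diff(self.energy_keV) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.mu_tissue_cm1 <= 0):
            raise ValueError("mu must be positive")
        self._mu = MuTable(self.energy_keV, self.mu_tissue_cm1, "soft_tissue")

    @classmethod
    def default(
        cls,
        elements: tuple[str, ...] = ("H", "C", "N", "O", "Ca"),
        density: float = SOFT_TISSUE_DENSITY,
    ) -> "AttenuationTable":
        """Vendored soft-tissue table plus computed cross sections for *elements*."""
        mu = load_mu_table("soft_tissue", density=density)
        coh = {el: coherent_cross_section(el, mu.energy_keV) for el in elements}
        return cls(mu.energy_keV, mu.mu_cm1, coh)

    def mu(self, energy_keV) -> np.ndarray:
        """Soft-tissue linear attenuation coefficient (1/cm), interpolated."""
        return self._mu(energy_keV)

    def sigma_coherent(self, element: str, energy_keV) -> np.ndarray:
        """Element's coherent cross section (barn/atom), log-log interpolated."""
        if element not in self.coherent_barn:
            raise KeyError(f"element {element!r} not tabulated in this AttenuationTable")
        tab = MuTable(self.energy_keV, self.coherent_barn[element], element)
        return tab(energy_keV)


def mu_reduction(table: AttenuationTable, e_lo: float, e_hi: float) -> float:
    """Fractional drop of mu from e_lo to e_hi: 1 - mu(e_hi)/mu(e_lo)."""
    return 1.0 - float(table.mu(e_hi)) / float(table.mu(e_lo))


def transmission_gain(
    table: AttenuationTable, e_lo: float, e_hi: float, thickness: float
) -> float:
    """Transmitted-intensity ratio T(e_hi)/T(e_lo) through *thickness* cm."""
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    return math.exp((float(table.mu(e_lo)) - float(table.mu(e_hi))) * thickness)


def coherent_cross_section_ratio(
    formula: str | dict[str, float],
    table: AttenuationTable,
    e_num: float,
    e_den: float,
) -> float:
    """Molecular coherent cross-section ratio sigma(e_num)/sigma(e_den).

    The molecular cross section is the stoichiometry-weighted sum of the
    tabulated atomic cross sections (independent-atom mixture rule).
    """
    stoich = parse_formula(formula)
    num = sum(n * float(table.sigma_coherent(el, e_num)) for el, n in stoich.items())
    den = sum(n * float(table.sigma_coherent(el, e_den)) for el, n in stoich.items())
    return num / den
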