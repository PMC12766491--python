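"""1-D powder diffraction patterns: monochromatic, polychromatic, mixtures.

A monochromatic pattern places, for every reflection within the angular
range, a unit-area pseudo-Voigt profile at its Bragg angle, scaled by
|F|^2 and the Lorentz-polarization factor for an unpolarized beam in
Debye-Scherrer geometry:

    LP(th) = (1 + cos^2 2th) / (sin^2 th cos th)

The polychromatic pattern of a quasi-monochromatic source is the
incoherent, intensity-weighted sum of monochromatic patterns over the
source spectrum's energy bins.  Multi-phase stones are weighted sums of
single-phase patterns (concentration fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .crystal import CrystalStructure, Reflection, enumerate_reflections, wavelength_A
from .spectrum import Spectrum

__all__ = [
    "Pattern1D",
    "MaterialWeights",
    "PeakSet",
    "default_grid",
    "lorentz_polarization",
    "pseudo_voigt",
    "mono_pattern",
    "poly_pattern",
    "mix_patterns",
    "find_peaks",
    "read_pattern",
    "write_pattern",
]

#: default angular grid matching the computed range of the study: 0-30 deg 2theta
DEFAULT_TT_MIN = 0.0
DEFAULT_TT_MAX = 30.0
DEFAULT_TT_STEP = 0.01

#: default spectrum discretization for the polychromatic sum, keV
DEFAULT_E_STEP = 0.05


def default_grid(step: float = DEFAULT_TT_STEP) -> np.ndarray:
    return np.arange(DEFAULT_TT_MIN, DEFAULT_TT_MAX + 0.5 * step, step)


@dataclass(frozen=True)
class Pattern1D:
    """Intensity versus scattering angle 2-theta (degrees)."""

    two_theta: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.two_theta, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != i.shape:
            raise ValueError("two_theta and intensity must be congruent 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("two_theta grid must be strictly increasing")
        if not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "two_theta", t)
        object.__setattr__(self, "intensity", i)

    def same_grid(self, other: "Pattern1D") -> bool:
        return (
            self.two_theta.shape == other.two_theta.shape
            and bool(np.allclose(self.two_theta, other.two_theta))
        )

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.two_theta))


@dataclass(frozen=True)
class MaterialWeights:
    """Concentration fractions of the phases making up a stone."""

    pairs: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(k), float(v)) for k, v in self.pairs)
        if any(w < 0 for _, w in pairs):
            raise ValueError("weights must be nonnegative")
        if abs(sum(w for _, w in pairs) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "pairs", pairs)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(k for k, _ in self.pairs)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.pairs)


@dataclass(frozen=True)
class PeakSet:
    """Located peaks: (position deg, height, prominence), ascending in angle."""

    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        pk = tuple((float(p), float(h), float(pr)) for p, h, pr in self.peaks)
        if any(pk[i][0] >= pk[i + 1][0] for i in range(len(pk) - 1)):
            raise ValueError("peaks must be sorted by ascending position")
        object.__setattr__(self, "peaks", pk)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p for p, _, _ in self.peaks])

    @property
    def heights(self) -> np.ndarray:
        return np.array([h for _, h, _ in self.peaks])

    def __len__(self) -> int:
        return len(self.peaks)


def lorentz_polarization(theta_deg, polarization: str = "unpolarized") -> np.ndarray:
    """Lorentz-polarization factor at Bragg half-angle theta (degrees).

    ``unpolarized`` uses (1 + cos^2 2th)/(sin^2 th cos th); ``none`` applies
    only the Lorentz part 1/(sin^2 th cos th).  The inverse-Compton beam's
    polarization state is not modelled further; the switch exists so the
    choice is explicit.
    """
    th = np.radians(np.asarray(theta_deg, dtype=float))
    lorentz = 1.0 / (np.sin(th) ** 2 * np.cos(th))
    if polarization == "unpolarized":
        return lorentz * (1.0 + np.cos(2.0 * th) ** 2) / 2.0
    if polarization == "none":
        return lorentz
    raise ValueError(f"unknown polarization model {polarization!r}")


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float = 0.5) -> np.ndarray:
    """Unit-area pseudo-Voigt: eta Lorentzian + (1 - eta) Gaussian."""
    hwhm = fwhm / 2.0
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gauss = np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * math.sqrt(2.0 * math.pi))
    lorentz = hwhm / (math.pi * ((x - center) ** 2 + hwhm**2))
    return eta * lorentz + (1.0 - eta) * gauss


def _deposit(
    grid: np.ndarray,
    centers: np.ndarray,
    amplitudes: np.ndarray,
    fwhm: float,
    eta: float,
) -> np.ndarray:
    """Sum amplitude-scaled unit-area pseudo-Voigts onto the grid (windowed)."""
    out = np.zeros_like(grid)
    if centers.size == 0:
        return out
    halfwin = 40.0 * fwhm  # Lorentzian wings carry weight far out
    step = grid[1] - grid[0] if grid.size > 1 else 1.0
    nwin = int(halfwin / step) + 1
    idx = np.searchsorted(grid, centers)
    for c, a, i in zip(centers, amplitudes, idx):
        lo, hi = max(i - nwin, 0), min(i + nwin, grid.size)
        if lo >= hi:
            continue
        out[lo:hi] += a * pseudo_voigt(grid[lo:hi], c, fwhm, eta)
    return out


def mono_pattern(
    structure: CrystalStructure,
    energy_keV: float,
    grid: np.ndarray | None = None,
    profile_fwhm: float = 0.1,
    eta: float = 0.5,
    polarization: str = "unpolarized",
    reflections: list[Reflection] | None = None,
) -> Pattern1D:
    """Monochromatic powder pattern at one photon energy.

    *reflections* may be passed to reuse an enumeration (their d and |F|^2
    are energy-independent; only the Bragg angles change with energy).
    """
    if energy_keV <= 0:
        raise ValueError("energy must be positive")
    if profile_fwhm <= 0:
        raise ValueError("profile FWHM must be positive")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    lam = wavelength_A(energy_keV)
    if reflections is None:
        reflections = enumerate_reflections(structure, lam, float(grid[-1]))

    d = np.array([r.d for r in reflections])
    f2 = np.array([r.f2 for r in reflections])
    sin_t = lam / (2.0 * d)
    ok = sin_t <= 1.0
    d, f2, sin_t = d[ok], f2[ok], sin_t[ok]
    theta = np.degrees(np.arcsin(sin_t))
    two_theta = 2.0 * theta
    inside = (two_theta >= grid[0]) & (two_theta <= grid[-1]) & (theta > 1e-9)
    two_theta, theta, f2 = two_theta[inside], theta[inside], f2[inside]
    amp = f2 * lorentz_polarization(theta, polarization)
    return Pattern1D(grid, _deposit(grid, two_theta, amp, profile_fwhm, eta))


def poly_pattern(
    structure: CrystalStructure,
    spectrum: Spectrum,
    grid: np.ndarray | None = None,
    profile_fwhm: float = 0.1,
    eta: float = 0.5,
    polarization: str = "unpolarized",
    energy_step: float = DEFAULT_E_STEP,
) -> Pattern1D:
    """Polychromatic pattern: spectrum-weighted incoherent sum over energies.

    The spectrum is re-binned to *energy_step* over its support (bins with
    vanishing weight are skipped) and each bin contributes its weight times
    the monochromatic pattern at the bin energy.
    """
    if spectrum.energy_keV.size == 0 or spectrum.integral() <= 0:
        raise ValueError("spectrum is empty")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)

    spacing = np.diff(spectrum.energy_keV)
    if spectrum.energy_keV.size == 1 or spacing.mean() >= energy_step:
        # already coarse (or a delta/few-line spectrum): bins used as-is
        energies = spectrum.energy_keV
        weights = spectrum.intensity / spectrum.intensity.sum()
        keep = weights > 0
        energies, weights = energies[keep], weights[keep]
    else:
        support = spectrum.intensity > 0
        e_lo = spectrum.energy_keV[support][0]
        e_hi = spectrum.energy_keV[support][-1]
        n = max(int(round((e_hi - e_lo) / energy_step)), 1) + 1
        egrid = np.linspace(e_lo, e_hi, n)
        reb = spectrum.rebinned(egrid)
        weights = reb.intensity / reb.intensity.sum()
        keep = weights > 1e-9
        energies, weights = egrid[keep], weights[keep]

    # reflections enumerated once at the highest energy: its small wavelength
    # sets the smallest d entering the range; d and |F|^2 are reused per energy
    lam_min = wavelength_A(float(energies.max()))
    reflections = enumerate_reflections(structure, lam_min, float(grid[-1]))
    total = np.zeros_like(grid)
    for e, w in zip(energies, weights):
        total += w * mono_pattern(
            structure, float(e), grid, profile_fwhm, eta, polarization,
            reflections=reflections,
        ).intensity
    return Pattern1D(grid, total)


def mix_patterns(patterns: list[Pattern1D], weights: MaterialWeights) -> Pattern1D:
    """Pointwise concentration-weighted sum of single-phase patterns."""
    if len(patterns) != len(weights.pairs):
        raise ValueError("one pattern per weight required")
    first = patterns[0]
    for p in patterns[1:]:
        if not first.same_grid(p):
            raise ValueError("patterns must share an identical 2-theta grid")
    total = np.zeros_like(first.intensity)
    for p, w in zip(patterns, weights.weights):
        total += w * p.intensity
    return Pattern1D(first.two_theta, total)


def find_peaks(pattern: Pattern1D, min_prominence: float = 0.05) -> PeakSet:
    """Local maxima with prominence above *min_prominence* x max intensity.

    Peak positions are refined by three-point parabolic interpolation around
    the grid maximum.  A flat pattern yields an empty set.
    """
    from scipy.signal import find_peaks as _scipy_find_peaks

    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must lie in (0, 1)")
    y = pattern.intensity
    top = float(y.max()) if y.size else 0.0
    if top <= 0 or y.max() == y.min():
        return PeakSet(())
    idx, props = _scipy_find_peaks(y, prominence=min_prominence * top)
    x = pattern.two_theta
    out = []
    for i, prom in zip(idx, props["prominences"]):
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            shift = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
        else:
            shift = 0.0
        step = x[min(i + 1, x.size - 1)] - x[max(i - 1, 0)]
        pos = x[i] + shift * (step / 2.0 if i not in (0, x.size - 1) else 0.0)
        out.append((float(pos), float(y[i]), float(prom)))
    out.sort(key=lambda t: t[0])
    return PeakSet(tuple(out))


# ---------------------------------------------------------------------------
# XY text IO

def write_pattern(pattern: Pattern1D, path: str | Path, comment: str = "") -> None:
    header = "two_theta_deg intensity"
    if comment:
        header = comment + "\n" + header
    np.savetxt(path, np.column_stack([pattern.two_theta, pattern.intensity]),
               header=header)


def read_pattern(path: str | Path) -> Pattern1D:
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    return Pattern1D(data[:, 0], data[:, 1])
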