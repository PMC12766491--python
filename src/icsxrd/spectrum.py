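"""Inverse-Compton source spectrum: representation, correction, synthesis.

An inverse-Compton source emits a quasi-monochromatic spectrum: a peak of a
few percent bandwidth with a sharp high-energy edge (the Compton edge of
head-on scattering) and a long low-energy tail from off-axis and off-energy
collisions.  The measured spectrum must be corrected for what the measuring
detector saw — absorption along the air path and the finite absorption
efficiency of the sensor — before it can weight the polychromatic powder
summation.  The corrected spectrum's low-energy part, where that division
amplifies noise, is replaced by an exponential fitted to a window on the
rising flank.

The synthetic generator emulates the measured source lineshape: a skewed
Gaussian core with a hard cutoff just above the peak plus an exponential
low-energy tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attenuation import MuTable, load_mu_table

__all__ = [
    "Spectrum",
    "ResponseModel",
    "correct_spectrum",
    "apply_response",
    "smooth_running_mean",
    "replace_low_energy_tail",
    "synth_spectrum",
    "read_spectrum",
    "write_spectrum",
]


@dataclass(frozen=True)
class Spectrum:
    """Relative spectral intensity on a strictly increasing keV grid."""

    energy_keV: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_keV, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if e.ndim != 1 or e.shape != i.shape or e.size < 1:
            raise ValueError("energy and intensity must be congruent 1-D arrays")
        if e.size > 1 and not np.all(np.diff(e) > 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(i < 0) or not np.all(np.isfinite(i)):
            raise ValueError("intensities must be finite and nonnegative")
        object.__setattr__(self, "energy_keV", e)
        object.__setattr__(self, "intensity", i)

    def integral(self) -> float:
        """Trapezoidal integral over the grid (equals the sole bin for size 1)."""
        if self.energy_keV.size == 1:
            return float(self.intensity[0])
        return float(np.trapezoid(self.intensity, self.energy_keV))

    def normalized(self) -> "Spectrum":
        """Unit-integral copy."""
        total = self.integral()
        if total <= 0:
            raise ValueError("cannot normalize a zero spectrum")
        return Spectrum(self.energy_keV, self.intensity / total)

    def rebinned(self, grid: np.ndarray) -> "Spectrum":
        """Integral-conserving trapezoidal re-binning onto a new grid.

        The spectrum is treated as a piecewise-linear density; each new bin
        receives the integral of that density over the bin, divided by the
        bin width, so the total integral is conserved up to edge clipping.
        """
        grid = np.asarray(grid, dtype=float)
        edges = np.empty(grid.size + 1)
        edges[1:-1] = 0.5 * (grid[1:] + grid[:-1])
        edges[0] = grid[0] - (edges[1] - grid[0])
        edges[-1] = grid[-1] + (grid[-1] - edges[-2])
        cum = _cumulative_trapezoid(self.energy_keV, self.intensity)
        ecl = np.clip(edges, self.energy_keV[0], self.energy_keV[-1])
        integ = np.interp(ecl, self.energy_keV, cum)
        out = np.diff(integ) / np.diff(edges)
        return Spectrum(grid, np.maximum(out, 0.0))


def _cumulative_trapezoid(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))
    return out


@dataclass(frozen=True)
class ResponseModel:
    """What the spectrum-measuring detector saw: air path plus sensor."""

    air_path_cm: float = 0.0
    sensor_thickness_um: float = 450.0
    sensor_material: str = "silicon"

    def __post_init__(self) -> None:
        if self.air_path_cm < 0 or self.sensor_thickness_um < 0:
            raise ValueError("path lengths must be nonnegative")

    def efficiency(self, energy_keV: np.ndarray,
                   air: MuTable | None = None,
                   sensor: MuTable | None = None) -> np.ndarray:
        """Air transmission x sensor absorption efficiency per energy."""
        energy_keV = np.asarray(energy_keV, dtype=float)
        eff = np.ones_like(energy_keV)
        if self.air_path_cm > 0:
            air = air or load_mu_table("air")
            eff = eff * np.exp(-air(energy_keV) * self.air_path_cm)
        if self.sensor_thickness_um > 0:
            sensor = sensor or load_mu_table(self.sensor_material)
            t_cm = self.sensor_thickness_um * 1e-4
            eff = eff * (1.0 - np.exp(-sensor(energy_keV) * t_cm))
        return eff


def apply_response(truth: Spectrum, response: ResponseModel,
                   air: MuTable | None = None,
                   sensor: MuTable | None = None) -> Spectrum:
    """Forward model: what the detector records for a true spectrum."""
    eff = response.efficiency(truth.energy_keV, air=air, sensor=sensor)
    return Spectrum(truth.energy_keV, truth.intensity * eff)


def correct_spectrum(raw: Spectrum, response: ResponseModel,
                     air: MuTable | None = None,
                     sensor: MuTable | None = None) -> Spectrum:
    """Undo air absorption and sensor efficiency: per-bin division.

    Exact inverse of :func:`apply_response` on the same grid.
    """
    eff = response.efficiency(raw.energy_keV, air=air, sensor=sensor)
    if np.any(eff <= 0):
        raise ValueError("response efficiency vanishes on the grid; cannot correct")
    return Spectrum(raw.energy_keV, raw.intensity / eff)


def smooth_running_mean(spectrum: Spectrum, window: int = 5) -> Spectrum:
    """Centered moving average; edges use shrinking (truncated) windows."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd bin count")
    if window == 1:
        return spectrum
    half = window // 2
    y = spectrum.intensity
    csum = np.concatenate([[0.0], np.cumsum(y)])
    n = y.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return Spectrum(spectrum.energy_keV, out)


def replace_low_energy_tail(
    spectrum: Spectrum, fit_lo: float = 21.51, fit_hi: float = 23.14
) -> Spectrum:
    """Replace bins below *fit_lo* with an exponential A*exp(k*E).

    A and k come from a linear least-squares fit of log intensity over
    [fit_lo, fit_hi]; default window endpoints follow the source
    characterization at the 25 keV working point.
    """
    e, y = spectrum.energy_keV, spectrum.intensity
    if fit_lo >= fit_hi:
        raise ValueError("fit_lo must be below fit_hi")
    if fit_lo < e[0] or fit_hi > e[-1]:
        raise ValueError("fit window must lie inside the energy grid")
    sel = (e >= fit_lo) & (e <= fit_hi)
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than two grid points")
    if np.any(y[sel] <= 0):
        raise ValueError("nonpositive intensity inside the fit window")
    k, log_a = np.polyfit(e[sel], np.log(y[sel]), 1)
    out = y.copy()
    below = e < fit_lo
    out[below] = np.exp(log_a + k * e[below])
    return Spectrum(e, out)


def synth_spectrum(
    peak_energy: float = 25.0,
    bandwidth_fwhm: float = 0.04,
    tail_decay: float = 0.25,
    grid: np.ndarray | None = None,
    tail_fraction: float = 0.08,
) -> Spectrum:
    """Synthetic inverse-Compton lineshape, normalized to unit integral.

    A skewed-Gaussian core at *peak_energy* whose measured FWHM equals
    ``bandwidth_fwhm * peak_energy``, a hard cutoff just above the peak
    (sharp Compton edge), and an exponential low-energy tail of relative
    amplitude *tail_fraction* decaying at *tail_decay* per keV.
    """
    if not 0.0 < bandwidth_fwhm < 0.2:
        raise ValueError("bandwidth must lie in (0, 0.2)")
    if grid is None:
        grid = np.arange(5.0, peak_energy * 1.15, 0.05)
    grid = np.asarray(grid, dtype=float)
    if not grid[0] < peak_energy < grid[-1]:
        raise ValueError("peak energy must lie inside the grid")

    fwhm = bandwidth_fwhm * peak_energy
    # bi-Gaussian: measured FWHM = 1.1774 * (sigma_lo + sigma_hi)
    sigma_hi = fwhm / 1.1774 / 2.3
    sigma_lo = 1.3 * sigma_hi
    core = np.where(
        grid <= peak_energy,
        np.exp(-0.5 * ((grid - peak_energy) / sigma_lo) ** 2),
        np.exp(-0.5 * ((grid - peak_energy) / sigma_hi) ** 2),
    )
    tail = tail_fraction * np.exp(tail_decay * (grid - peak_energy))
    tail[grid > peak_energy] = 0.0
    y = core + tail
    cutoff = peak_energy + 2.5 * sigma_hi  # hard edge just above the peak
    y[grid > cutoff] = 0.0
    return Spectrum(grid, y).normalized()


# ---------------------------------------------------------------------------
# two-column text IO

def write_spectrum(spectrum: Spectrum, path: str | Path, comment: str = "") -> None:
    header = "energy_keV intensity"
    if comment:
        header = comment + "\n" + header
    np.savetxt(
        path,
        np.column_stack([spectrum.energy_keV, spectrum.intensity]),
        header=header,
    )


def read_spectrum(path: str | Path) -> Spectrum:
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    return Spectrum(data[:, 0], data[:, 1])
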