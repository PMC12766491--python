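"""Frame-stack reduction: normalization, beam-center search, azimuthal integration.

The reduction mirrors the experimental analysis chain: frames are divided
by their exposure time and measured flux and averaged; the beam center is
found by an iterative coarse-to-fine grid search that maximizes the
sharpness of the azimuthally integrated profile (the sharpest rings win);
and the final profile is the per-2theta-bin mean over unmasked pixels.

Intensity units after normalization are counts s^-1 (ph/s)^-1; only
relative intensities are meaningful downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detector_sim import MASK_SENTINEL, DetectorGeometry, FrameStack

__all__ = [
    "RadialProfile",
    "average_normalize",
    "find_center",
    "azimuthal_integrate",
    "read_profile",
    "write_profile",
]

logger = logging.getLogger(__name__)

#: default azimuthal bin width in degrees 2-theta
DEFAULT_BIN_DEG = 0.05


@dataclass(frozen=True)
class RadialProfile:
    """Mean counts per valid pixel versus 2-theta bin center.

    Bins that received no valid pixel are flagged by ``n_pixels == 0`` and
    carry NaN intensity (absent, not zero).
    """

    two_theta: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.two_theta, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        n = np.asarray(self.n_pixels, dtype=int)
        if not (t.shape == i.shape == n.shape):
            raise ValueError("profile arrays must be congruent")
        object.__setattr__(self, "two_theta", t)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "n_pixels", n)

    def valid(self) -> np.ndarray:
        return self.n_pixels > 0

    def interp(self, two_theta) -> np.ndarray:
        """Linear interpolation over occupied bins."""
        v = self.valid()
        return np.interp(np.asarray(two_theta, dtype=float),
                         self.two_theta[v], self.intensity[v])


def average_normalize(stack: FrameStack) -> np.ndarray:
    """Mean over frames of frame / (exposure x flux); gaps stay sentinel."""
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    if np.any(stack.exposures_s <= 0) or np.any(stack.fluxes_ph_s <= 0):
        raise ValueError("exposures and fluxes must be positive")
    norm = stack.frames / (stack.exposures_s * stack.fluxes_ph_s)[:, None, None]
    out = norm.mean(axis=0)
    out[stack.mask == 0] = MASK_SENTINEL
    return out


def azimuthal_integrate(
    image: np.ndarray,
    center: tuple[float, float],
    geometry: DetectorGeometry,
    n_bins: int | None = None,
    mask: np.ndarray | None = None,
    solid_angle: bool = True,
) -> RadialProfile:
    """Per-bin mean intensity versus 2theta = atan(r * pitch / D).

    Pixels are assigned to their nearest bin (no splitting); bin edges are
    uniform in 2-theta over the detector's angular span.  Masked pixels
    (mask == 0 or sentinel-valued) are excluded.  With ``solid_angle`` the
    cos^3(2theta) flat-detector solid-angle factor is divided out, making
    the profile directly comparable to a 1-D pattern.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = (image != MASK_SENTINEL).astype(np.uint8)
    live = (mask != 0) & (image != MASK_SENTINEL)

    tt = geometry.two_theta_map(center)
    tt_max = float(tt.max())
    if n_bins is None:
        n_bins = max(int(np.ceil(tt_max / DEFAULT_BIN_DEG)), 1)
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    edges = np.linspace(0.0, tt_max, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if n_bins == 1:
        logger.warning("degenerate binning: all pixels fall into one bin")

    idx = np.clip(((tt / tt_max) * n_bins).astype(int), 0, n_bins - 1)
    vals = image.copy()
    if solid_angle:
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = vals / np.cos(np.radians(tt)) ** 3
    counts = np.bincount(idx[live].ravel(), minlength=n_bins)
    sums = np.bincount(idx[live].ravel(), weights=vals[live].ravel(), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(centers, mean, counts)


def _center_objective(
    image: np.ndarray,
    center: tuple[float, float],
    geometry: DetectorGeometry,
    n_bins: int,
    mask: np.ndarray,
) -> float:
    """Sharpness objective: maximum single-bin mean intensity."""
    prof = azimuthal_integrate(image, center, geometry, n_bins=n_bins,
                               mask=mask, solid_angle=False)
    v = prof.valid()
    return float(np.nanmax(prof.intensity[v])) if v.any() else float("-inf")


def find_center(
    image: np.ndarray,
    geometry: DetectorGeometry,
    coarse_span_px: float = 12.0,
    coarse_step_px: float = 3.0,
    final_step_px: float = 0.25,
    n_bins: int = 300,
    mask: np.ndarray | None = None,
    initial: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Iterative beam-center search by maximizing ring sharpness.

    Starting from *initial* (default: the geometry's nominal center), a
    square grid of candidate centers of half-width *coarse_span_px* and
    spacing *coarse_step_px* is scanned; the azimuthal integration is run
    for each candidate and the candidate whose profile has the largest
    single-bin intensity wins.  The grid is then re-centered and refined
    (step / 3 per round) until the step is <= *final_step_px*.
    Deterministic for fixed inputs.
    """
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = (image != MASK_SENTINEL).astype(np.uint8)
    live = (mask != 0) & (image != MASK_SENTINEL)
    vals = image[live]
    if vals.size == 0 or vals.max() == vals.min():
        raise ValueError("featureless image: center objective is degenerate")

    center = initial if initial is not None else geometry.beam_center
    span, step = coarse_span_px, coarse_step_px
    round_no = 0
    while True:
        round_no += 1
        offs = np.arange(-span, span + 0.5 * step, step)
        best, best_val = center, float("-inf")
        for dy in offs:
            for dx in offs:
                cand = (center[0] + dy, center[1] + dx)
                val = _center_objective(image, cand, geometry, n_bins, mask)
                if val > best_val:
                    best, best_val = cand, val
        logger.info(
            "center search round %d: step %.3f px -> center (%.3f, %.3f), objective %.6g",
            round_no, step, best[0], best[1], best_val,
        )
        center = best
        if step <= final_step_px:
            return center
        span, step = step * 1.5, max(step / 3.0, final_step_px)


# ---------------------------------------------------------------------------
# XY text IO

def write_profile(profile: RadialProfile, path: str | Path, comment: str = "") -> None:
    header = "two_theta_deg intensity n_pixels"
    if comment:
        header = comment + "\n" + header
    np.savetxt(
        path,
        np.column_stack([profile.two_theta, profile.intensity, profile.n_pixels]),
        header=header,
    )


def read_profile(path: str | Path) -> RadialProfile:
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    n = data[:, 2] if data.shape[1] > 2 else np.ones(data.shape[0])
    return RadialProfile(data[:, 0], data[:, 1], n.astype(int))
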