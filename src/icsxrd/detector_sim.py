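"""Synthetic Debye-Scherrer frames on a photon-counting pixel detector.

This is the package's synthetic-data generator: it projects a 1-D pattern
into the 2-D ring image a hybrid photon-counting detector would record
(Pilatus-200K-like geometry: 172 um pixels, two modules separated by a
horizontal gap band, sample-detector distance 100 mm), adds a smooth
soft-tissue scatter background peaking near 10 deg 2-theta, draws a
per-frame flux uniformly inside the range the source delivers
(0.78-1.33e10 ph/s), and applies Poisson counting noise.  Everything is
reproducible from an integer seed.

Masked (gap) pixels carry the sentinel value -1 in generated images and 0
in the 0/1 mask image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .powder import Pattern1D

__all__ = [
    "MASK_SENTINEL",
    "DetectorGeometry",
    "AcquisitionConfig",
    "TissueScatterModel",
    "FrameStack",
    "project_pattern_to_image",
    "tissue_background_pattern",
    "simulate_frames",
    "write_frames",
    "read_frames",
]

MASK_SENTINEL = -1.0


@dataclass(frozen=True)
class DetectorGeometry:
    """Pixel detector geometry; beam center in fractional pixel coordinates.

    Convention: pixel (0, 0) at the top-left, first coordinate is the row;
    radii are evaluated at pixel centers.  The beam center may lie outside
    the frame.  The default center sits deliberately a few pixels off the
    frame middle so that center finding is a non-trivial task.
    """

    shape: tuple[int, int] = (487, 407)
    pixel_pitch_um: float = 172.0
    distance_mm: float = 100.0
    beam_center: tuple[float, float] = (245.3, 198.7)
    gap_rows: tuple[int, int] = (235, 252)  # [start, stop) of the module gap band

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0 or self.distance_mm <= 0:
            raise ValueError("pitch and distance must be positive")

    @property
    def pixel_angular_resolution_deg(self) -> float:
        """Angular extent of one pixel at the beam axis: atan(pitch / D)."""
        return float(np.degrees(np.arctan(self.pixel_pitch_um * 1e-3 / self.distance_mm)))

    def beam_angular_resolution_deg(self, beam_size_mm: float) -> float:
        """Angular blur from a finite beam footprint: atan(s / D)."""
        return float(np.degrees(np.arctan(beam_size_mm / self.distance_mm)))

    def mask(self) -> np.ndarray:
        """0/1 validity mask (1 = live pixel, 0 = module gap)."""
        m = np.ones(self.shape, dtype=np.uint8)
        m[self.gap_rows[0] : self.gap_rows[1], :] = 0
        return m

    def two_theta_map(self, center: tuple[float, float] | None = None) -> np.ndarray:
        """Per-pixel scattering angle 2theta = atan(r / D), degrees."""
        cy, cx = center if center is not None else self.beam_center
        yy = np.arange(self.shape[0])[:, None] - cy
        xx = np.arange(self.shape[1])[None, :] - cx
        r_mm = np.hypot(yy, xx) * self.pixel_pitch_um * 1e-3
        return np.degrees(np.arctan(r_mm / self.distance_mm))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Per-scan acquisition statistics of the experiment."""

    exposure_s: float = 1.0
    n_frames: int = 300
    flux_range_ph_s: tuple[float, float] = (0.78e10, 1.33e10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure_s <= 0:
            raise ValueError("exposure must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        lo, hi = self.flux_range_ph_s
        if lo < 0 or hi < lo:
            raise ValueError("flux bounds must be nonnegative and ordered")


@dataclass(frozen=True)
class TissueScatterModel:
    """Broad soft-tissue scatter: smooth unimodal hump peaking near 10 deg.

    *attenuation_factor* is the Beer-Lambert factor the tissue applies to
    the stone's diffracted signal.  Whether tissue scatter grows with the
    beam footprint is an open modelling choice: with
    ``scale_with_beam_area`` the amplitude is multiplied by
    ``beam_area_mm2`` (relative to a 1 mm^2 beam); by default the amplitude
    is an independent parameter.
    """

    amplitude: float = 1.0
    plateau_center_deg: float = 10.0
    width_deg: float = 5.0
    attenuation_factor: float = 1.0
    scale_with_beam_area: bool = False
    beam_area_mm2: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not 0.0 < self.attenuation_factor <= 1.0:
            raise ValueError("attenuation factor must lie in (0, 1]")
        if self.width_deg <= 0:
            raise ValueError("width must be positive")
        if self.beam_area_mm2 <= 0:
            raise ValueError("beam area must be positive")

    @property
    def effective_amplitude(self) -> float:
        if self.scale_with_beam_area:
            return self.amplitude * self.beam_area_mm2
        return self.amplitude


@dataclass
class FrameStack:
    """Frames plus per-frame metadata and the shared validity mask."""

    frames: np.ndarray  # (n, rows, cols) counts; gap pixels = MASK_SENTINEL
    exposures_s: np.ndarray
    fluxes_ph_s: np.ndarray
    mask: np.ndarray  # 0/1, 1 = live

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.exposures_s = np.asarray(self.exposures_s, dtype=float)
        self.fluxes_ph_s = np.asarray(self.fluxes_ph_s, dtype=float)
        self.mask = np.asarray(self.mask)
        n = self.frames.shape[0]
        if self.exposures_s.shape != (n,) or self.fluxes_ph_s.shape != (n,):
            raise ValueError("one exposure and one flux per frame required")
        if self.mask.shape != self.frames.shape[1:]:
            raise ValueError("mask shape must match the frame shape")

    def __len__(self) -> int:
        return self.frames.shape[0]


def project_pattern_to_image(
    pattern: Pattern1D,
    geometry: DetectorGeometry,
    solid_angle: bool = True,
) -> np.ndarray:
    """Expected-counts image of a 1-D pattern on the detector.

    Each live pixel receives the pattern intensity at its scattering angle
    (linear interpolation), optionally scaled by the relative pixel solid
    angle cos^3(2theta) of a flat detector normal to the beam.  Gap pixels
    are set to the mask sentinel.
    """
    tt = geometry.two_theta_map()
    if tt.max() > pattern.two_theta[-1] + 1e-9 or tt.min() < pattern.two_theta[0] - 1e-9:
        raise ValueError("pattern does not cover the detector's angular range")
    img = np.interp(tt, pattern.two_theta, pattern.intensity)
    if solid_angle:
        img = img * np.cos(np.radians(tt)) ** 3
    img[geometry.mask() == 0] = MASK_SENTINEL
    return img


def tissue_background_pattern(
    model: TissueScatterModel, grid: np.ndarray
) -> Pattern1D:
    """Smooth, wide tissue-scatter profile with its maximum at the plateau.

    A log-normal-like bump in angle: zero at 0 deg, single broad maximum at
    *plateau_center_deg*, slow decay beyond — no structure sharper than a
    couple of degrees, mimicking the measured soft-tissue profile.
    """
    grid = np.asarray(grid, dtype=float)
    x = np.maximum(grid, 0.0) / model.plateau_center_deg
    s = model.width_deg / model.plateau_center_deg
    with np.errstate(divide="ignore"):
        lx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)
    y = np.exp(-0.5 * (lx / s) ** 2)
    y[~np.isfinite(y)] = 0.0
    return Pattern1D(grid, model.effective_amplitude * y)


def simulate_frames(
    pattern: Pattern1D,
    tissue: TissueScatterModel | None,
    geometry: DetectorGeometry,
    acq: AcquisitionConfig,
    counts_per_unit: float | None = None,
) -> FrameStack:
    """Poisson frames of (attenuated stone + tissue background) ring images.

    Per frame the flux is drawn uniformly inside ``acq.flux_range_ph_s``;
    the expected image is ``(att * stone + tissue) * exposure * flux *
    counts_per_unit`` and the recorded counts are Poisson draws from it.
    ``counts_per_unit`` converts pattern intensity units x seconds x ph/s
    into expected counts per pixel; by default it is chosen so the hottest
    pixel expects ~10 counts per frame at mid-range flux — a realistic
    counting regime for second-long exposures, and deterministic.
    """
    rng = np.random.default_rng(acq.seed)
    att = tissue.attenuation_factor if tissue is not None else 1.0
    combined = pattern.intensity * att
    if tissue is not None:
        combined = combined + tissue_background_pattern(tissue, pattern.two_theta).intensity
    expected_base = project_pattern_to_image(
        Pattern1D(pattern.two_theta, combined), geometry
    )
    live = geometry.mask() == 1
    base = np.where(live, expected_base, 0.0)

    if counts_per_unit is None:
        mid_flux = 0.5 * (acq.flux_range_ph_s[0] + acq.flux_range_ph_s[1])
        peak = float(base.max())
        denom = peak * mid_flux * acq.exposure_s
        counts_per_unit = 10.0 / denom if denom > 0 else 1.0

    fluxes = rng.uniform(*acq.flux_range_ph_s, size=acq.n_frames)
    frames = np.empty((acq.n_frames,) + geometry.shape, dtype=float)
    scale = acq.exposure_s * counts_per_unit
    for i, flux in enumerate(fluxes):
        lam = base * (flux * scale)
        frames[i] = rng.poisson(lam).astype(float)
        frames[i][~live] = MASK_SENTINEL
    return FrameStack(
        frames=frames,
        exposures_s=np.full(acq.n_frames, acq.exposure_s),
        fluxes_ph_s=fluxes,
        mask=geometry.mask(),
    )


# ---------------------------------------------------------------------------
# TIFF + JSON sidecar IO

def write_frames(stack: FrameStack, directory: str | Path, geometry: DetectorGeometry,
                 seed: int | None = None) -> None:
    """One single-page TIFF per frame plus a JSON sidecar; mask as 0/1 TIFF."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(len(stack)):
        tifffile.imwrite(directory / f"frame_{i:05d}.tif", stack.frames[i].astype(np.float32))
        sidecar = {
            "exposure_s": float(stack.exposures_s[i]),
            "flux_ph_s": float(stack.fluxes_ph_s[i]),
            "seed": seed,
            "geometry": {
                "shape": list(geometry.shape),
                "pixel_pitch_um": geometry.pixel_pitch_um,
                "distance_mm": geometry.distance_mm,
                "beam_center": list(geometry.beam_center),
                "gap_rows": list(geometry.gap_rows),
            },
        }
        (directory / f"frame_{i:05d}.json").write_text(json.dumps(sidecar, indent=1))
    tifffile.imwrite(directory / "mask.tif", stack.mask.astype(np.uint8))


def read_frames(directory: str | Path) -> tuple[FrameStack, DetectorGeometry]:
    """Read a frame directory written by :func:`write_frames`."""
    directory = Path(directory)
    tiffs = sorted(directory.glob("frame_*.tif"))
    if not tiffs:
        raise FileNotFoundError(f"no frame TIFFs in {directory}")
    frames, exposures, fluxes = [], [], []
    geo_blob = None
    for t in tiffs:
        frames.append(tifffile.imread(t).astype(float))
        sidecar = json.loads(t.with_suffix(".json").read_text())
        exposures.append(sidecar["exposure_s"])
        fluxes.append(sidecar["flux_ph_s"])
        geo_blob = sidecar["geometry"]
    mask_path = directory / "mask.tif"
    mask = tifffile.imread(mask_path) if mask_path.exists() else np.ones_like(frames[0], dtype=np.uint8)
    geometry = DetectorGeometry(
        shape=tuple(geo_blob["shape"]),
        pixel_pitch_um=geo_blob["pixel_pitch_um"],
        distance_mm=geo_blob["distance_mm"],
        beam_center=tuple(geo_blob["beam_center"]),
        gap_rows=tuple(geo_blob["gap_rows"]),
    )
    return (
        FrameStack(np.stack(frames), np.array(exposures), np.array(fluxes), mask),
        geometry,
    )
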