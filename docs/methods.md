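# Methods

`icsxrd` models a powder X-ray diffraction measurement of kidney-stone
minerals at an inverse-Compton (laser-Compton) X-ray source and provides the
reduction chain that turns recorded 2-D detector frames back into 1-D
patterns, including the correction for the scatter background of soft
tissue surrounding a stone. This note documents the models, the defaults
and the design decisions; everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`, not asserted from memory.

## Forward model

### Reflections and intensities

For a crystal with unit cell metric tensor `G`, the spacing of the (h k l)
lattice planes is `d = 1/sqrt(h^T G* h)` with `G* = G^-1`; this is exact for
all crystal systems and is checked against the specialized cubic,
tetragonal and monoclinic textbook formulas. Bragg's law `n·λ = 2d·sin θ`
gives the diffraction angle; reflection order `n > 1` is handled implicitly
by enumerating higher-index (h k l) rather than looping over `n` (the two
are equivalent; enumeration keeps the bookkeeping in one place). The full
sphere of (h k l) is enumerated, so symmetry multiplicities appear as
repeated entries at equal `d` instead of an explicit multiplicity factor.

Squared structure factors are direct sums over the P1-expanded cell,

    F(hkl) = Σ_j occ_j · f0_j(sinθ/λ) · exp(−B_j (sinθ/λ)²) · exp(2πi h·x_j),

with sum-of-Gaussians atomic form factors (International Tables vol. C
parameterization via gemmi). Anomalous dispersion is omitted: the minerals
contain only H/C/N/O/Ca and the working energies are ≥ 20 keV, far from
any relevant absorption edge. Displacement parameters default to B = 0 when
the structure file carries none; the pipeline compares peak positions and
relative heights, not absolute thermal damping.

### Peak profile and polychromatic summation

Each reflection deposits a unit-area pseudo-Voigt (η = 0.5) of configurable
FWHM scaled by |F|² and the Lorentz-polarization factor for an unpolarized
beam in Debye-Scherrer geometry, `LP = (1+cos² 2θ)/(sin² θ cos θ)`. The
polarization state of the inverse-Compton beam is not documented for the
measurement this package models, so the polarization term can be switched
off (`polarization="none"`); the default is the unpolarized form.

The instrumental FWHM combines in quadrature the per-pixel angular
resolution (0.1° for 172 µm pixels at 100 mm) and the beam-footprint blur
(0.6° for a 1 mm beam at that distance); the default profile FWHM is the
pixel term alone, so that spectral broadening — which the polychromatic
summation produces by construction — remains visible.

A polychromatic pattern is the incoherent sum of monochromatic patterns
weighted by the source spectrum, re-binned to 0.05 keV. Patterns are
computed on a 0–30° 2θ grid at 0.01° steps. Reflection `d` and |F|² are
energy-independent and are enumerated once at the highest contributing
energy.

Multi-phase stones are pointwise concentration-weighted sums of the
single-phase patterns. The composition of the two reference stone types is
deliberately *configuration*, not a constant: the reported compositions
assign 90/10 and 50/50 weight fractions but leave the minority phase of the
first stone and the second 50% phase of the second ambiguous, so the
pipeline requires the mapping to be spelled out in the run configuration.

### Source spectrum

An inverse-Compton source emits a quasi-monochromatic line: a few-percent
bandwidth peak with a hard high-energy edge and a long low-energy tail.
The synthetic generator produces a bi-Gaussian core (low-side width 1.3×
the high side) whose *measured* FWHM equals `bandwidth × peak_energy`, a
hard cutoff at 2.5 high-side sigma above the peak, and an exponential tail
(default amplitude 8% of the core, decay 0.25/keV). Defaults are 25 keV
peak and 4% bandwidth — the middle of the 3–5% band the source delivers.

Measured spectra are corrected by per-bin division through the response of
the measuring detector: transmission of the air path times the absorption
efficiency `1 − exp(−µ_Si t)` of the silicon sensor. The correction
amplifies noise at low energies, so bins below a fit window are replaced by
an exponential `A·exp(kE)` fitted by linear least squares on log intensity
over 21.51–23.14 keV (the characterized window at the 25 keV working
point). The running-mean smoothing window is exposed as a parameter
(default 5 bins; the value used in the original analysis is not
documented).

## Synthetic detector frames

The generator emulates a Pilatus-200K-like hybrid photon-counting detector:
487 × 407 pixels of 172 µm at 100 mm sample-detector distance, with a
17-row inter-module gap band. The exact module layout is configurable; any
two-module layout satisfies the masking contract. The default beam center
(245.3, 198.7) sits deliberately a few pixels off the frame middle so that
center finding is never trivially correct.

A 1-D pattern is projected radially: each pixel receives the pattern
intensity at `2θ = atan(r/D)`, scaled by the flat-detector solid-angle
factor `cos³ 2θ`; gap pixels carry the sentinel −1. Per frame, the flux is
drawn uniformly in 0.78–1.33 × 10¹⁰ ph/s (the documented range; only the
range is known, so a uniform draw is used), the expected image is
`(attenuation × stone + tissue) × exposure × flux × c`, and counts are
Poisson. The scale `c` defaults to putting the hottest pixel at ~10
expected counts per frame — second-long exposures in a realistic counting
regime — and is deterministic. Flat field and dark current are ideal
(photon-counting detector); charge sharing and point-spread are not
modelled.

The tissue scatter background is a smooth log-normal-shaped hump in angle
peaking at 10° 2θ (width 5°), matching the broad plateau shape of measured
soft-tissue scatter; it contains no structure sharper than ~2°. Whether
tissue background should scale with beam size is not documented; by
default the amplitude is an independent parameter, and an opt-in flag
(`scale_with_beam_area`) multiplies it by the beam footprint in mm².

## Reduction

Frames are divided by exposure × flux and averaged; masked pixels
propagate. The beam center is found by coarse-to-fine grid search (default
±12 px at 3 px step, refined by ×3 per round to ≤ 0.25 px) maximizing the
maximum single-bin intensity of the azimuthal profile — the sharpest rings
win. "Maximum of the resulting intensities" admits several readings; the
max-bin objective is the chosen one and is verified to peak at the true
center on noiseless synthetic images.

Azimuthal integration assigns each live pixel to its nearest 2θ bin (no
pixel splitting — the 0.1°/pixel resolution dominates any sub-bin effect)
and takes the per-bin *mean*, which is invariant under masking for
radially symmetric images; bins with no live pixel are flagged absent
(NaN), never zero. Default bin width 0.05°. The solid-angle factor is
divided out so profiles are directly comparable to 1-D patterns. Intensity
units after normalization are counts · s⁻¹ · (ph/s)⁻¹; only relative
intensities are meaningful.

## Tissue background correction

A tissue-only reference profile is registered to the composite
(stone-in-tissue) profile over a matching window containing the broad
tissue plateau, default 8.5°–11.5° around the 10° maximum (the window is a
package choice; only the criterion — matching the plateau — is documented
for the original analysis). Because the effective sample-detector distance
differs slightly between measurements, the reference's angular axis is
rescaled by a bounded factor (±10%, the small-angle equivalent of a
distance change), searched by golden-section; the intensity scale has a
closed-form least-squares solution at each candidate, making the fit
smooth, derivative-free and deterministic. Subtraction preserves negative
residuals — they diagnose background mismatch beyond ~10° and must not be
clipped. Peak amplitudes relative to a baseline level quantify how much
tissue attenuation weakens the stone signal; the front-versus-back
comparison is reproduced qualitatively (an attenuated synthetic stone's
relative amplitude drops by its Beer-Lambert factor), not as an absolute
number, because the exact path lengths entering the original comparison
are not fully specified.

## Attenuation utilities

Soft-tissue linear attenuation uses a vendored NIST-style mass-attenuation
table (ICRU-44 soft-tissue composition), log-log interpolated, converted
with density 1.06 g/cm³ (overridable). Quantities: `transmission
= exp(−µd)`, the fractional µ reduction between two energies, and the
transmitted-intensity gain `exp((µ_lo − µ_hi) d)`.

Elemental coherent (Rayleigh) cross sections are computed rather than
vendored: the Thomson differential cross section weighted by the squared
atomic form factor, integrated by Gauss-Legendre quadrature (512 nodes in
cos θ). This is the independent-atom approximation; it is adequate for
*ratios* between energies for light-element compounds, which is how the
package uses it (e.g. the 50 keV / 25 keV ratio for calcium oxalate).
Molecular cross sections use the stoichiometric mixture rule.

## Mineral structure models

The three vendored structures (whewellite CaC₂O₄·H₂O, weddellite
CaC₂O₄·2H₂O, uricite C₅H₄N₄O₃) carry published unit cells and space-group
packings (P2₁/n with Z = 8, I4/m with Z = 8, P2₁/a with Z = 4
respectively). Their atomic coordinates are **synthetic model
reconstructions**, not refined experimental determinations: rigid
chemically idealized fragments (planar oxalate ions, water oxygens, a
planar uric-acid molecule) were packed in the cell and the packing
parameters fitted so that the simulated powder line intensities
approximate the minerals' published experimental line lists. The
whewellite model additionally builds in the mineral's b/2
pseudo-translational symmetry (a Z = 4 subcell doubled with small
deterministic displacements), which reproduces the observed k-odd
near-extinctions; its n glide is what allows the strongest observed line,
(−1 0 1) at d = 5.93 Å. Peak *positions* therefore carry the full accuracy
of the published cells; relative peak *intensities* are approximate. The
CIF headers repeat this caveat. Consequences: the first-line positions of
the calculated patterns are reliable; fine intensity ratios between lines
are not guaranteed beyond the leading lines.

The two reference stone compositions are configuration, not constants.
Where a default is needed (the acceptance computation), the half-uric-acid
stone is modelled as 50% uricite + 50% whewellite — whewellite being the
most common stone mineral and the other reference stone's majority phase.

## What the synthetic data does and does not show

The generator reproduces the acquisition statistics of the modelled
experiment (frame counts, exposure, flux range, Poisson counting, module
gap, off-center beam) and the broad tissue background. It does not
reproduce: detector charge sharing, beam polarization effects, capillary
and air scatter (negligible in the modelled setup), texture/preferred
orientation, crystallite-size broadening, or intra-stone absorption.
Passing round-trip tests therefore demonstrates the correctness of the
reduction and correction algorithms under realistic counting statistics —
not the fidelity of the mineral intensity models to real stones.

## Numerical choices and degenerate inputs

- Pseudo-Voigt deposits are windowed at ±40 FWHM (Lorentzian wings).
- Spectrum re-binning conserves the integral (piecewise-linear density);
  spectra already coarser than the target bin are used point-wise.
- `find_peaks` refines positions by 3-point parabolic interpolation and
  returns an empty set (not an error) for flat patterns.
- Center search is deterministic: ties keep the first-scanned candidate;
  the objective is evaluated on a fixed 300-bin profile.
- A featureless image raises a degenerate-objective error in center
  finding; zero/negative exposure or flux raises a metadata error; energies
  outside a vendored table raise a coverage error rather than
  extrapolating.
- Background fit snaps the axis scale to exactly 1.0 when that is within
  numerical noise of optimal, so self-fits return exact identity scales.

## Problem sizes used in the checks

The test suite runs the full detector (487 × 407) only where the contract
demands it and otherwise uses a 180 × 160 detector with the same pitch,
distance and gap construction; frame counts in tests are 20–500. The
acceptance script uses the full-size detector with 300 frames for the
frame-level checks and the default 0–30° / 0.01° pattern grid. These sizes
are the package's own defaults for routine verification; all are
configurable upward.
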