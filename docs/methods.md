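# Methods

`cherensim` models the chain from megavoltage radiation delivery to the
Cherenkov light observable on a patient's skin during external-beam
radiotherapy (EBRT) of the larynx, at desk scale: every component runs in
minutes on one CPU core.  This note records the models, their assumptions,
the parameters that matter, and the choices made where the design was open.

## Geometry and phantoms

All positions are in millimeters in right-handed patient-like axes
(x toward the patient's left, y anterior, z superior; gravity is -y for a
supine patient).  Voxel indices are 0-based and positions address voxel
centers.

The synthetic neck phantom is a vertical cylinder: a skin shell (2 mm) over
an adipose layer (4 mm) over muscle bulk, with a central-anterior air lumen
(airway), a posterior bone cylinder standing in for the vertebral column,
and a tumor ellipsoid lateral to the lumen.  The default voxel pitch is
1.0 x 1.0 x 1.3 mm, the clinical CT resampling used in this class of
simulation.  Per-voxel densities are the tissue means with seeded Gaussian
jitter (sigma 0.02 g/cm^3) emulating CT-derived density maps; labels are a
deterministic function of the geometry.  The compact fixture used by the
shipped analyses (`compact_neck_geometry`) is a 40 mm-radius, 40 mm-tall
version with a 7 mm-semiaxis tumor at 12 mm depth; it keeps all anatomical
structure while keeping the optical Monte Carlo tractable.

The water calibration phantom is the 30 x 30 x 50 cm block at 2 mm pitch
with the beam along +z entering the z = 0 face.

What the synthetic anatomy does *not* emulate: real patient contours,
segmentation noise, heterogeneity inside organs, metal or cavities other
than the airway.  Tests passing on it show the pipeline's physics and
bookkeeping are right, not that a specific patient's light distribution is
predicted.

## Density-to-tissue mapping

The scanner calibration curve is replaced by a piecewise-constant table
(air <= 0.05 < adipose <= 0.95 < muscle <= 1.2 < bone, g/cm^3), with a
value exactly on a threshold taking the lower interval's label.  The
mechanism (density drives tissue assignment, density also enters dose and
attenuation scaling) matches the clinical pipeline; the curve itself is a
stand-in.

## Property tables

Optical tables cover 500-1200 nm on a 10 nm grid per tissue: absorption
mu_a, scattering mu_s (1/mm), Henyey-Greenstein anisotropy g, refractive
index n.  Shorter wavelengths are excluded because tissue absorption there
removes any contribution from depth.  The defaults are *qualitative
parameterizations* of the tissue-optics literature — a hemoglobin-like
absorption shoulder decaying from 500 nm, the ~975 nm water band and the
infrared rise, a 930 nm lipid bump in adipose, power-law scattering
(mu_s ~ lambda^-b) — not digitized measurements.  Tumor and adipose share
the same anisotropy curve, and the tumor index (1.39) follows esophageal
tumor values.  Everything is overridable programmatically or via CSV
(`OpticalTables.from_csv`); the analysis chain, not the property values, is
the artifact.

Radiological tables cover 0.01-6 MeV: Compton attenuation is the
Klein-Nishina total cross-section times electron density (rho N_A Z/A),
which is essentially exact for the dominant interaction channel;
photoelectric attenuation is a Z_eff^4.5 / E^3 power law anchored to water
at 10 keV (it only matters below ~0.1 MeV); electron collision stopping
power is a water reference table scaled by density and Z/A.  Attenuation
and stopping power scale linearly with the local voxel density at transport
time.

## Radiation transport

X-ray photons are tracked by sampling the number of attenuation lengths to
the next interaction (-ln u) and marching the ray voxel by voxel (3D DDA)
through the heterogeneous attenuation field until the depth is consumed or
the photon leaves the domain.  At an interaction, photoelectric absorption
versus Compton scattering is chosen by the component ratio at the local
energy; Compton angles follow Klein-Nishina by rejection sampling, the
scattered photon continues with E' = E / (1 + (E/m_e c^2)(1 - cos theta)),
and the recoil electron takes E - E' along the momentum-balancing
direction.  Photons below 10 keV (configurable) deposit locally.

Electrons slow down in straight lines in the continuous-slowing-down
approximation with 0.1 mm steps, depositing S(E) rho_rel per step, down to
a 10 keV cutoff deposited locally.  Multiple scattering, bremsstrahlung,
Rayleigh scattering and pair production are deliberately omitted — they
blur but do not drive the dose-to-light mechanism this package studies.
The omission biases the depth-dose shape (electrons travel too straight),
which is why the build-up maximum depth is reported, not asserted.

Dose is deposited energy divided by voxel mass (volume x local density);
per-history and per-run energy balance (deposited + escaped = input) is
exact to accumulation tolerance and tested.

## Cherenkov emission

An electron of kinetic energy E has speed ratio
beta = sqrt(1 - (m_e c^2/(E + m_e c^2))^2) and emits where beta n > 1; in
n = 1.4 soft tissue the threshold is 0.219 MeV (~0.2 MeV).  The expected
photon number per path length over a wavelength band [lam1, lam2] is the
closed-form band integral of the Frank-Tamm spectral density,

    dN/dx = (2 pi z^2 / 137.036) (1 - 1/(beta^2 n^2)) (1/lam1 - 1/lam2),

with z the charge number of the emitting particle (1 for electrons; the
package makes z configurable).  Per electron step the emitted number is
Poisson with this mean (analog mode), each photon drawn at the step
midpoint with wavelength from the 1/lambda^2 inverse CDF and direction on
the Cherenkov cone cos theta_c = 1/(beta n) about the electron direction.
The band-averaged refractive index per tissue is used for the emission
kinematics; the wavelength dependence of n over 500-1200 nm is a ~1%
effect.  Cherenkov photon energy (a few eV) is not subtracted from the
electron energy budget; it is orders of magnitude below the stopping-power
losses.

A thinning factor (`emission_fraction`) can reduce the number of photons
*stored* for optical tracing; the emission grid always counts every
generated photon, so thinning only trades optical statistics for runtime.

## Optical transport

Analog single-photon transport: exponential optical depth, DDA traversal
accumulating mu_t(lambda, tissue) per segment, absorption with probability
mu_a/mu_t at interactions, otherwise Henyey-Greenstein scattering with the
closed-form inverse CDF.  Internal tissue-tissue index mismatches are
ignored (indices are within a few percent of each other); at tissue-air
boundaries unpolarized Fresnel reflectance decides specular reflection
versus Snell refraction and exit (a free-escape mode is available via
`fresnel=False`).  Wavelength is fixed at birth.  A hard cap on scattering
events (10^6 by default) terminates pathological histories, counted
separately so that births = absorbed + exited + capped exactly.  Each
photon carries its birth position and birth tissue, which is what makes the
origin-of-surface-light analyses possible.

Validation: ballistic transmission through absorbing slabs matches
Beer-Lambert; the track-length fluence around an isotropic point source in
a homogeneous medium (mu_a = 0.002/mm, mu_s' = 1/mm) matches the
diffusion-approximation Green's function phi(r) = exp(-mu_eff r)/(4 pi D r)
within 15% over r = 5-20 mm.

## Treatment delivery

The linear-accelerator head is reduced to a point source at 1000 mm
source-axis distance with a parametric 6 MV spectrum (gamma-shaped
histogram, E exp(-E/0.9 MeV) truncated to 6 MeV, mean ~1.8 MeV — a
documented property of the chosen form, not a fitted vendor spectrum), and
the multileaf collimator to a binary aperture mask on a 2.5 mm grid in the
isocenter plane.  No electron contamination, leaf transmission or
tongue-and-groove.  A gantry angle is the angle between beam direction and
gravity: at 0 deg the source is anterior and the beam points along -y,
angles increasing toward the patient's left.

Shipped plan defaults carry the published delivery parameters: IMRT beams
at 90 deg (157.5 MU, 8 control points) and 278 deg (155.1 MU, 10 control
points); VMAT arcs of 114 control points at 100->260 deg (360.7 MU,
counter-clockwise) and 260->100 deg (306.6 MU, clockwise).  The arc span is
configurable because the source material states both 200 deg arcs and
100-260 deg ranges; the defaults follow the tabulated ranges.  MU is split
uniformly across control points unless per-point weights are given, and
source photons are allocated to beams and control points proportionally to
MU (largest-remainder rounding).

## Monitor-unit calibration

The clinical convention — 1 MU delivers 1 cGy at 1.5 cm depth on the beam
axis in water at SSD 100 cm with a 10 x 10 cm field — is simulated
directly, and N = 1 cGy / D_d converts per-particle quantities to physical
units (dose in Gy, photon counts) after multiplying by the beam MU.
Because the central field region is transversely flat, D_d is read as the
mean per-particle dose over voxels within 6 mm of the axis in the depth
slab nearest 1.5 cm; a single 2 mm voxel at desk-scale photon budgets is
shot-noise dominated (and can be empty), while the patch estimator is
unbiased in the flat region and stable.  The radius is configurable and 0
recovers the single-voxel readout.

## Surface analyses

The body surface is the axis-aligned exposed-face mesh (one element per
tissue-air voxel face), which keeps photon-exit bookkeeping exact; a
marching-cubes export exists for visualization only.  Surface maps are
exits per element divided by element area, optionally median filtered over
each element's ~3x3 surface neighborhood, then thresholded at 5% of the
maximum for the full 500-1200 nm band and 10% for the narrow 710-720 nm
band.  Element neighborhoods come from a KD-tree radius query
(1.5 x max spacing for the 3x3 stencil), a tolerant stand-in for exact
face adjacency on the voxel surface.

Spectra are wavelength histograms normalized to peak 1 (sum-to-1 available).

The tumor spot — the surface region where tumor-born light emerges — is
the largest connected component of elements at >= 50% of the maximum of
the tumor-born surface map.  The level set is taken on a
neighborhood-mean smoothed map (~5x5 stencil) restricted to elements that
received at least one tumor-born photon: per-element counts are Poisson at
finite budgets and an unsmoothed 50%-of-max component jumps between seeds,
while the smoothed spot is stable (pairwise Jaccard ~0.65 at the shipped
budget).  Fraction and smoothing are configurable; ties between equal
components go to the smaller minimum element id.

Reduced measurement areas are axis-aligned bands of given left-right width
(defaults 100 and 80 mm) centered on the spot's area-weighted centroid,
spanning the anterior surface.  Origin distributions are 3D histograms of
birth positions of the photons exiting through a region, and two origin
distributions are compared by histogram intersection after normalizing each
to unit sum — bounded in [0, 1], 1 exactly when the normalized
distributions coincide.

## Problem sizes and numerics

The shipped analyses use 45,000 source photons per treatment (~750,000
Cherenkov photons traced) on the compact phantom, and 100,000 photons for
the water calibration; at these sizes the full chain runs in about two
minutes per treatment on one core.  Monte Carlo kernels are numba-compiled,
single-threaded, and seeded once per call, so a fixed seed reproduces
histories bit for bit.  Table lookups are linear interpolations on
log-uniform (energy) and uniform (wavelength) grids, clamped at the edges.
Degenerate inputs are rejected early: photons starting in air, empty
apertures, zero-density voxels receiving energy, all-zero distributions in
similarity comparisons.

## Known limitations

* Electron transport is straight-line CSDA: lateral dose spread is
  underestimated and the build-up region is only qualitatively reproduced.
* Optical property values are literature-shaped, not patient- or
  sample-calibrated; absolute surface photon counts carry that uncertainty.
* The point source + binary aperture delivery model has no head scatter or
  leaf effects, so intensity modulation fidelity is limited to the aperture
  shape itself.
* The axis-aligned face mesh makes surface areas exact per face but
  overestimates the true smooth surface area of oblique regions.
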