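# Methods

`fibrilscatter` infers cellulose-microfibril structure from one-dimensional
fibre-diffraction profiles: equatorial wide-angle X-ray scattering (WAXS),
wide-angle neutron scattering of H/D-exchanged material (WANS), and
small-angle neutron scattering of D2O/H2O-hydrated material (SANS).  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## WAXS model

**Peak shapes.** The equatorial profile is modelled as a smooth background
plus reflections of the monoclinic hk0 lattice.  The overlapped 1-10 and
110 reflections are Gaussians; the 200 reflection uses a deliberately
asymmetric profile

    F(q) = F0(q)                          for q >= q0
    F(q) = F0(q) * (1 + 0.1 (q - q0)^2)   for q <  q0

with F0 a Gaussian and the asymmetry constant fixed at 0.1 nm^2 (not
fitted).  The low-q augmentation models the tail produced by thin
crystallites; the integral breadth delta-q = area/height is defined on the
symmetric part F0 only, so it is sigma*sqrt(2 pi) in closed form.  Widths
quoted as FWHM use FWHM = sigma * 2 sqrt(2 ln 2).

**Size/disorder separation.** The breadth of the m-th order of a reflection
family combines size and paracrystalline disorder:

    delta-q = delta-q0 + (pi/2) g^2 q^2 d

with d the family's fundamental spacing.  A plot of delta-q against q^2 d is
linear; the intercept gives the Scherrer dimension (mean column length)
L = 2 pi / delta-q0 and the slope gives the disorder parameter
g = sqrt(2 * slope / pi).  Only the 200/400 family enters the regression by
default: the 1-10/110 breadths sit well above the 200-family line and are
excluded (an opt-in flag exists).  With exactly two points the solve is
exact; with more, least squares.  A negative intercept is an error
(disorder dominates; L undefined); a negative slope warns and reports
g = 0.

**Background.** A power-law + constant fitted through anchor windows
(defaults 5–6.5 and 32–35 nm^-1, configurable and logged).  Anchor windows
necessarily sit in the tails of the outermost reflections, so
`analyze_equatorial` refits background and peaks *jointly* on the raw
profile, using the anchor subtraction only for initial values; the joint
fit is exact on noiseless synthetic data where sequential
subtract-then-fit leaves a small systematic.

**The overlapped pair and the monoclinic angle.** At the bamboo-like lattice
(gamma near 92 deg) the 1-10/110 separation is ~0.35 of their width; a free
two-Gaussian decomposition is ill-conditioned, and at 1% noise its angle
estimate scatters by several degrees with heavy outliers.
`analyze_equatorial` therefore:

* ties the pair positions to one monoclinic cell, with the intersheet edge
  a following from the fitted 200 position and the intrasheet repeat b held
  at the reference 0.820 nm (the pair cannot support a free b; b is the
  glucan-chain packing repeat within a hydrogen-bonded sheet and is the
  least variable cell parameter across celluloses);
* constrains the two Gaussians to one width (their separate widths are not
  identifiable);
* weights residuals by 1/intensity, matching the multiplicative noise model;
* optimises gamma from four fixed starts and lets it cross 90 deg during
  optimisation, folding gamma -> 180 - gamma afterwards (the two labels
  swap; folding removes the truncation bias a hard bound at 90 deg would
  introduce).

The free-position fit (`fit_equatorial`) remains available, with the
ordering q0(1-10) < q0(110) enforced by construction (the 110 position is
parameterised as an offset gap > 0).

**Azimuthal decomposition.** Orientation profiles are fitted as a narrow
plus a wide Gaussian over a constant; components are labelled by fitted
width.  On a 2D pattern, each q-column is decomposed this way and the
narrow component's area reconstructs an equatorial profile containing only
the well-oriented fraction; failed columns are interpolated from
neighbours and counted, with more than 20% failures an error.

## Lattice geometry

hk0 spacings of the oblique (monoclinic-projection) lattice follow

    1/d^2 = [h^2/a^2 + k^2/b^2 - 2 h k cos(gamma)/(a b)] / sin^2(gamma)

so d(200) = (a/2) sin(gamma).  `invert_cell` recovers (a, b, gamma) from a
(d_1-10, d_110, d_200) triple by a bracketed root solve in gamma
(tolerances at machine precision; round trips hold to 1e-9).  Because
gamma -> 180 - gamma merely swaps the 1-10/110 labels, cells are reported
on the convention gamma >= 90 (equivalently d(1-10) >= d(110)).

Chain counting uses the per-chain cross-section of the reference cell,
a*b*sin(gamma)/2 (two chains per hk0 cell; 0.317 nm^2), rescaled
proportionally to an observed intersheet spacing (0.330 nm^2 at d200 =
0.403 nm).  Counts round down — an envelope "allows space for" only whole
chains.  Rectangle and ellipse envelopes are supported; real microfibril
cross-sections are irregular, so the rectangle bounds the count from above.

## SANS model

A single Gaussian Bragg peak over a power-law + constant background, fitted
jointly.  The interfibril spacing is reported as d = 2 pi / q_peak — the
nominal centre-to-centre spacing; it does not necessarily correspond to any
form of global mean, since contrast favours fibrils just far enough apart
to admit D2O.  No Lorentz-type correction is applied before locating
q_peak (a deliberate choice; the fitted centre is used directly).
Detection requires the fitted amplitude to exceed 3 sigma of the fit
residuals (configurable), the centre to sit at least 0.1 nm^-1 inside the
measured range, and the width to stay below 0.8 nm^-1 — a broader
component is background curvature, not a Bragg peak.  The background
exponent is bounded to [2, 4.5], the usual mass/surface-fractal range for
cell-wall scattering, preventing peak/background degeneracy.

Scattering length densities use tabulated bound coherent scattering lengths
(b_H = -3.739, b_D = 6.671, b_C = 6.646, b_O = 5.803 fm) and
sld = (sum n_i b_i) * rho * N_A / M.  Cellulose C6H10O5 is assigned a
crystalline density of 1.6 g/cm3 (configurable); with H2O at 0.997 and D2O
at 1.105 g/cm3 the computed match composition is 35% D2O by volume.  The
contrast factor (delta-rho)^2 against a linear D2O/H2O mixture is a
parabola with its single root at the match fraction.

## WANS model

**Absorption.** The sample is a cuboid wider than the beam; for scattering
at angle 2theta in the equatorial plane, the transmission factor averages
exp(-mu * path) over the uniform depth of the scattering event, with the
outgoing path leaving through the back face.  The average is computed by
adaptive quadrature (relative error <= 1e-6; a Monte-Carlo path-sampling
oracle agrees to 3 decimals in tests) and reduces to exp(-mu t) at
2theta = 0.  Geometries where the exit ray would leave through a side face
are refused rather than mis-modelled.  The attenuation coefficient mu is a
user input in cm^-1; correction is applied pointwise after mapping q to
angle through the profile's wavelength, and double correction is refused.

**H/D differencing.** The D - H difference is formed on a common grid after
scaling H to equalise integrated intensity over a peak-free window
(default 20–22 nm^-1; total-intensity and no-normalisation modes exist).
Deuteration of accessible hydroxyls rescales reflection intensities without
moving them, so the difference shows a negative lobe where 1-10 loses
intensity and a positive one where 200 gains.

**Localising 1-10.** The single-Gaussian lobe fit
(`fit_difference_lobe`) returns the centroid of the blended dip; with the
default deuteration scales the weak 110 dip biases that centroid high by
just under 1%, an inherent property of the blend.  The sharper tool is
`fit_hd_pair`: H and D profiles fitted jointly on the hypothesis that
deuteration leaves positions unaltered — shared pair positions and width,
free per-form heights, per-form backgrounds, 1/intensity weighting.  The
two patterns are different height-mixtures of the same two peaks, which
makes the otherwise-degenerate pair separable; on noiseless synthetic data
the recovery is exact, and at 1% noise the 1-10 position is recovered to
~0.6% on average.  The H/D consistency table reports per-reflection
relative d-spacing differences; under the shared-position hypothesis the
pair rows are the constraint itself (exactly zero, flagged as such in the
report) while the 200/400 rows are genuine independent measurements.

**Meridional 00l.** Peaks are sought in windows centred at q = 2 pi l / c
(default fibre repeat c = 1.038 nm, configurable); the noise level is
estimated robustly (median absolute deviation) from samples outside all
windows and detection requires the baseline-relative amplitude to exceed
3 sigma.  In the synthetic data the 001/002 peaks exist only in the D
form, mirroring irregular longitudinal stagger of surface chains becoming
visible after exchange.

## Synthetic data

The generator (`simulate.GroundTruth` and the `generate_*` functions)
emulates the observable structure of the three experiments with a fully
known parameter set; its defaults are the bamboo reference conditions: monoclinic
cell with gamma = 92 deg and a chosen so d200 = 0.403 nm, b = 0.820 nm,
column length L = 3.84 nm, disorder g = 0.036, SANS spacings 2.96 nm (dry)
to 3.19 nm (25% D2O) with linear interpolation, orientation FWHMs
15/60 deg with narrow fraction 0.6, deuteration scales 0.5 (1-10), 0.9
(110), 1.1 (200), fibre repeat c = 1.038 nm, 1% relative noise.

Choices that are free parameters of the generator, made once and kept:

* q grids 5–35 nm^-1 at 0.02 (wide-angle) and 0.4–2.8 nm^-1 at 0.01
  (small-angle), resolving the narrowest synthetic peak with >= 20 points;
* relative peak heights 35/50/100/8 for 1-10/110/200/400 plus a weak 100
  shoulder at height 5 (all configurable) — chosen to look like a
  background-corrected equatorial profile of well-oriented cellulose;
* the 1-10/110/100 breadths are 1.5x the 200 breadth (their breadths are
  not separately measurable under the overlap, only clearly wider than
  the 200);
* wide-angle background 200 q^-1.5 + 2; SANS background 0.5 q^-3 + 0.5
  with peak amplitude 50 at full D2O contrast;
* noise is multiplicative Gaussian (sd = noise_fraction x intensity) —
  appropriate for azimuthally integrated arbitrary-unit data — with a
  Poisson option behind a flag.

The SANS peak amplitude is scaled by (delta-rho)^2 computed from the SLD
module, normalised to pure D2O, so it vanishes exactly at the match point
by construction.

Each generator draws from an independent, seeded stream; identical
`GroundTruth` (including seed) reproduces outputs bit for bit.

**What the synthetic tests do not show.**  The generator produces data the
analysis model can represent exactly (up to noise): real patterns have
non-power-law backgrounds, amorphous halos, preferred-orientation and
Lorentz-polarisation effects, detector artefacts, and peak shapes that are
only approximately Gaussian.  Parameter-recovery results therefore
demonstrate the correctness and conditioning of the inference chain, not
the accuracy of the models on instrument data.  In particular the
monoclinic-angle recovery (to about +/-1 deg at 1% noise) holds when the
true intrasheet repeat equals the reference b; if a real sample's b
deviated, the fixed-b constraint would bias gamma accordingly.

## Problem sizes in tests

Recovery suites use 20 seeded repeats for the WAXS size/disorder and SANS
spacing checks, 10 for the monoclinic angle, and 3 for the intersheet
spacing; 2D-grid reconstruction tests use a 0.1 nm^-1 q step.  These sizes
give stable means (standard error well under the asserted tolerances)
while keeping the full suite fast.

## Known limitations

* Equatorial analysis only; meridional wide-angle fitting is limited to
  00l detection in difference profiles.
* The absorption model covers the equatorial plane of a wide cuboid only;
  out-of-plane detector rows and side-face exits are out of scope.
* `mu` is not derived from elemental composition; supply it directly.
* No absolute-intensity calibration anywhere; all intensities are
  arbitrary units.
* The hk0 cell is two-dimensional; no c-axis refinement beyond the 00l
  positions.
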