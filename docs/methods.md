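# Methods

## Scope and model

The package reconstructs a GIWAXS analysis of hydrated vs dried primary
cell wall as a closed loop: a synthetic-pattern generator whose parameters
are the published fit values, the reduction/fitting/texture chain that
recovers them, and an independent Debye-equation calculator for atomistic
cellulose microfibril models.  Because the underlying detector images are
not publicly deposited, every quantitative claim the package tests is
either a worked example from printed values, a parameter-recovery
statement on synthetic data generated from printed values, or a
property/oracle identity.

## Synthetic patterns

A pattern is I(q_xy, q_z) = baseline(|q|) + Σ components, each component a
Gaussian in |q| times an optional Gaussian azimuthal kernel in
χ = atan2(|q_xy|, q_z) (χ = 0 is the out-of-plane q_z direction).
Generation happens directly in q-space; refraction shifts, Ewald
curvature and detector geometry are collapsed into an optional
missing-wedge mask (default half-angle 8° in the pipeline), because every
downstream quantity is defined on q-space profiles.

Preset parameters (generator ground truth):

| component | hydrated | dried |
|---|---|---|
| (110/1-10) center | 2π/5.57 Å⁻¹ | 2π/5.52 Å⁻¹ |
| (110/1-10) FWHM_q | 0.240 Å⁻¹ | 0.277 Å⁻¹ |
| (200) center | 2π/4.03 Å⁻¹ | 2π/4.02 Å⁻¹ |
| height ratio 110/200 | 0.52 | 0.86 |
| texture FWHM_χ (both reflections) | 38.3° | 40.0° |
| pectin ring center (isotropic) | 0.85 Å⁻¹ | 0.89 Å⁻¹ |
| cuticle ring center / FWHM | 1.41 / 0.77 Å⁻¹ | 1.41 / 0.54 Å⁻¹ |

Widths not printed anywhere — the (200) and pectin q-widths (0.22 and
0.35 Å⁻¹) — are fixture choices, as are the absolute amplitudes
(h200 = 400 counts hydrated, amorphous heights 230–260, baseline
150 − 40q).  Two deliberate amplitude choices:

- The dried cellulose amplitude is scaled by 0.514 relative to hydrated so
  that the sin(χ)-weighted crystallinity index is equal between states
  (closed-form calculation from the kernel widths and annulus means).
  This encodes the observation that drying leaves the oriented
  crystalline content unchanged; without it the index would trivially
  track the ratio change.
- `exposure` (default 5) sets counting statistics at
  observed = Poisson(I·exposure)/exposure, putting peak pixels at a few
  thousand detected photons — typical synchrotron statistics.  The printed
  replicate standard deviations describe sample-to-sample variation, so
  the generator keeps counting noise well below them.

The rocking-scan render is `scale` times the annulus-minus-background
azimuthal signal of the *full* pattern — texture kernels plus the
χ-constant residual that the isotropic components leave after the
0.5–0.6 Å⁻¹ background band is subtracted.  A rocking detector sees the
same amorphous scattering as the image, and only with this term is the
noiseless rocking profile proportional to the image-derived azimuthal
profile, which is what makes single-scalar stitching well-posed.  The
annulus means use the q-weighted Gaussian window integral (pixel density
in an annulus grows ∝ q), in closed form via erf.

What the generator does *not* emulate: reflectivity/Vineyard enhancement,
beam footprint, water scattering near 2.0 Å⁻¹, multiple texture
populations, paracrystalline (non-Gaussian) peak shapes, and detector
nonuniformity.  Passing recovery tests therefore demonstrates the
correctness and self-consistency of the analysis chain, not its
robustness to every artifact of real beamline data.

## Reduction

Sector and azimuthal profiles use pixel-center binning with equal-weight
averaging of unmasked pixels; no solid-angle or polarization corrections
are applied (none are part of the reference analysis).  |q| = √(q_xy²+q_z²),
χ is folded about the q_z axis by default.  Bins with no contributing
pixels are NaN-flagged and propagate as flags — never silently
interpolated.  Defaults: 500 bins over 0.2–2.2 Å⁻¹; baseline fitted on
1.9–2.2 Å⁻¹ and subtracted everywhere.  Whether the reference analysis
pixel-area-weighted its sector means is unknowable from the text;
equal weighting was chosen and is documented here.  Continuum identities
(isotropic images give χ-independent profiles, sector equality) hold to
pixel-sampling accuracy — about 1% per bin at the default 470×940 grid,
lumpiest in the first χ bins near the q_z pole.

## Peak deconvolution

Bounded nonlinear least squares (lmfit/least_squares).  Default model:
line + Gaussian pectin (center free, init 0.85, bounds ±0.15) + Gaussian
cuticle (center fixed 1.41) + two cellulose Gaussians (inits 1.13/1.56,
centers bounded ±0.15, widths capped at 0.45 Å⁻¹ — a crystalline
reflection wider than that would imply sub-nanometer coherence, and the
cap keeps the cellulose components from absorbing broad amorphous
misfit).  Heights initialize from local profile values.  Residuals are
weighted by 1/√(counts) approximated shift-invariantly from the profile
itself, so baseline-subtracted input is handled identically; this is the
statistically proper weighting for counting data and is what keeps the
robustness variants' trend signs stable.  Variants: cuticle center moved
to 1.2 Å⁻¹; pectin as a split (two-sided-width) Gaussian; or both
amorphous Gaussians replaced by one broad split-Gaussian background.
Noiseless renders are recovered to machine precision; the fit is exactly
invariant to intensity rescaling.

"Intensity" in the 110/200 ratio means peak height (the area ratio is
exposed separately).  The Scherrer length uses K = 0.9 and a quadrature
instrumental-broadening correction; the instrumental width is a required
input defaulting to 0 because the synthetic data has none and no value is
printed for the instrument.  In q units the formula collapses to
L = 2πK/β_q exactly (cos θ cancels), and the angular route is retained as
a cross-check.

## Pole figures

Stitching estimates a single scale s minimizing Σ(image − s·rocking)²
over an overlap window (default 8–15°, chosen to sit inside both the
image's valid range — above the 8° wedge — and the rocking coverage,
±20°); the reference stitching procedure itself is described only by
citation, so this least-squares reconstruction is our own and is
documented as such.  ± χ sides are folded by averaging.  The FWHM is
measured above a floor (median of the top-χ quartile) because the annulus
background convention leaves a χ-constant offset in the profile; when the
peak is truncated at the fold axis the width is twice the one-sided half
width.  The crystallinity integral ∫ sin(χ) I(χ) dχ is trapezoidal with χ
in radians; the pipeline subtracts the same floor before integrating so
the index reflects the oriented component rather than the offset.

## Fibril models and Debye scattering

The builder stacks glucan-chain layers along y with exact spacing d200
(default 4.0 Å), chains within a layer spaced a = d·s/√(s²−d²/4) apart so
that both diagonal plane families of the centered two-dimensional chain
lattice have spacing exactly d110_mean (default 5.57 Å); adjacent layers
are offset by a/2 laterally and by half a residue rise (5.19 Å, half the
10.38 Å cellobiose repeat) along the chain axis.  The half-rise stagger
cancels the spurious all-chain meridional coherence at 2π/5.19 ≈ 1.21 Å⁻¹
that perfectly aligned idealized chains would add next to the (110/1-10)
region.  Each residue is an idealized 21-atom anhydroglucose (C6H10O5)
with the ring roughly in the sheet plane (thin along the stacking axis);
fine atomic detail only has to be adequate for pair-distance statistics,
since the wide-angle peak positions are set by the lattice periodicities,
which are exact by construction.

Water placement is seeded rejection sampling.  Interior waters go on the
mid-planes between sheets on a jittered grid (O–O ≥ 2.4 Å, ≥ 1.5 Å from
fibril heavy atoms), distributed round-robin across all galleries — the
reference count (36) is explicitly arbitrary and no gallery assignment is
stated.  Monolayer waters sit at H-bond distance (2.8 Å) outward from
surface oxygens, which keeps the first hydration shell in lateral
registry with the surface lattice; candidates generated from interior
oxygens land too close to neighboring chains and are rejected
automatically.  This registry is what reproduces, in the Debye curves,
the higher normalized (110/1-10)-to-(200) intensity of monolayer-hydrated
models over dry ones; a fully random shell does not.  Presets 1–4 carry
the published compositions (18 chains × 4 residues = 72 glucose; 0, 102
outside, 36 inside, 36+108 waters).

The Debye sum uses q-independent scattering factors f = Z and a weighted
pair-distance histogram (default bin 0.01 Å); only peak positions and
relative orderings are claimed, for which electron counts suffice.  The
histogram agrees with the direct O(N²) double sum to <1% RMS and
converges as the bin shrinks.  Solvent subtraction and window-maximum
normalization are pointwise operations with the obvious identities
(v = 1 identity, v = 0 full subtraction, idempotent normalization).

## Orchestration and problem sizes

The pipeline runs each state × replicate as simulate → reduce → fit →
pole figure, with replicate seeds derived as
(base·1009 + state·101 + r) mod 2³¹.  Defaults: 470×940-pixel images,
500-bin profiles, 3 replicates per state — one full two-state run takes
about a second on one CPU, so the whole suite and the acceptance script
stay fast while the replicate means sit well inside the published
standard deviations.  Summary CSVs are written with fixed float
formatting, making repeated runs byte-identical.

## Known limitations

- The fibril atomic template is idealized; absolute Debye intensities and
  fine features below ~0.8 Å⁻¹ (cross-section detail) carry no meaning
  here, and no quantitative target is set for them.
- Texture is modeled only in the synthetic-image module; the Debye
  calculator is strictly orientation-averaged (powder).
- The paired t-test at n = 3 has little power; it is reported for
  completeness of the summary table, not as a strong inferential claim.
- Real-detector calibration (beam center, tilt, flat field) is out of
  scope; images enter the reduction already mapped to q-space.
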