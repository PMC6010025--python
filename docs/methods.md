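# Methods

This package studies how breast tissue structure distorts the focus of
high-intensity focused ultrasound (HIFU) and how that distortion can be
anticipated before treatment. It chains five stages: synthetic breast-MRI
phantoms, tissue segmentation, heterogeneous-media wave propagation, phased
array focus control, and focal-quality metrics.

## Phantom generator (`synthbreast`)

Real contrast-enhanced breast MRI of the kind this analysis needs (T1-weighted,
0.625 × 0.625 mm in-plane, 0.8 mm slices) is not publicly available, so the
generator produces brightness volumes with the statistical features the
downstream stages rely on:

- a semi-ellipsoidal breast (default radius 32 mm, protrusion 42 mm) on a
  chest plane, surrounded by air;
- a bimodal interior brightness histogram — fat N(200, 25), fibroglandular
  N(450, 55), air N(20, 6), plus additive noise (default sd 12) that
  exercises the median filter. The gland class is generated *brighter* than
  fat: raising the fat/gland threshold must convert gland into fat, which
  fixes the orientation (the opposite of the usual "fat is bright on T1"
  intuition);
- a connected, network-like gland compartment: a Gaussian-correlated random
  field (correlation length 1.5 mm, comparable to the 0.75 mm wavelength at
  2 MHz) plus an envelope of ducts radiating from the nipple and a bias
  toward the breast core. The field is thresholded by bisection on the size
  of the 26-connected component through the core; when a side lobe makes the
  component size jump discontinuously, the component is grown outward in
  score-ordered shells to land on the requested gland fraction exactly.
  Default gland fraction 0.335 = 1 − 0.665, the assumed breast fat
  percentage.

Everything is drawn from one `numpy` generator seeded by the recipe, so a
recipe is a complete, reproducible description of a phantom.

What the generator does *not* emulate: real ductal anatomy, pectoral muscle
and lung (targets are placed away from the chest wall), MRI physics (bias
fields, coil profiles, partial volume). Passing tests therefore demonstrate
that the method behaves correctly on media with the right statistics and
contrast, not that it reproduces any patient's anatomy.

## Segmentation (`segmentation`)

The image-based modelling chain: (1) 3×3×3 median denoise; (2) air/breast
threshold at the histogram valley between the first two local maxima —
256 equal-width bins, 5-bin moving average, ties toward the lower bin (the
binning is our choice; with well-separated modes the valley is a near-empty
plateau and the tie rule returns its low edge, which is equally valid — any
value on the plateau separates the classes); sub-threshold voxels are set to
0 (air); (3) interface detection at 50% of the mean breast brightness by
line scans marching inward along all six axis directions (interior cavities
are unreachable and stay unmarked); (4) a 1.5 mm skin shell grown from the
interface into the air region via a Euclidean distance transform
(equivalent to dilation along the surface normal for uniform thickness, and
robust on voxel data), written as the sentinel −1; sub-voxel thicknesses
round up to one voxel layer. The fat/fibroglandular threshold is the
brightness quantile that puts the requested fat fraction (default 66.5%)
strictly below it. Labels: 0 → water (the air region is treated as water,
as in a water-bath treatment), −1 → skin, below/above the fat threshold →
fat/gland.

Acoustic properties per tissue (density kg/m³, sound speed m/s, attenuation
dB/m/MHz): skin 1090/1615/–, gland 1032/1547/60, fat 985/1465/40, water
998.2/1482/0.22. The skin attenuation is not reported anywhere we know of
for this parameter set; the default borrows the fibroglandular value
(configurable — the shell is 1.5 mm thin and its absorption is immaterial
to the field ratios). Attenuation converts as α[Np/m] = α₀ · (f/MHz) ·
ln 10 / 20. Brightness volumes resample tri-linearly, label volumes by
nearest neighbour; out-of-domain queries fill with air/water.

## Wave propagation (`acoustics`)

First-order pressure–velocity acoustics for a lossy heterogeneous fluid
(shear waves in soft tissue are orders of magnitude slower and are
neglected):

    ρ ∂v/∂t = −∇p,    ∂p/∂t = −ρc² ∇·v,

discretised on a staggered grid with 6th-order central differences in space
(coefficients 75/64, −25/384, 3/640 at half-node offsets) and leapfrog time
stepping. Choices that matter:

- **Time step.** dt = CFL·dx/c_max, defaults CFL 0.4 (1-D/2-D) and 0.3
  (3-D), against the stability bound 1/(S√d) with S = Σ|coefficients| ≈
  1.2417. dt is rounded so a drive period is an integer number of steps.
- **Resolution.** The solver refuses grids under 6 points per wavelength in
  the slowest medium. The desk-scale 2-D default, dx = 0.12 mm, gives 6.1
  points per wavelength in fat; validation runs use 15 (dx = 0.05 mm).
- **Attenuation.** A matched loss term a = α·c applied to both pressure and
  velocity; a travelling wave then decays at exactly α Np/m with no
  phase-speed error, and the decay at the 2 MHz fundamental equals
  α₀ × 2 MHz by construction. The loss is frequency-independent, so
  harmonics generated under the optional nonlinearity are over- or
  under-attenuated relative to a power-law medium — a known simplification.
- **Dispersion.** The spatial scheme contributes < 0.01% phase-speed error
  at 15 points per wavelength (measured at CFL 0.1); at the production
  CFL 0.4 the second-order temporal term dominates and costs ~0.5–0.7%.
  All reported quantities are field ratios or cross-correlation phases
  relative to a reference element, which cancels a uniform speed bias.
- **Boundaries.** Split-field PML, 20 cells, cubic grading, terminal
  reflection target 10⁻⁶.
- **Staggered sampling.** Density is averaged harmonically onto velocity
  nodes; ρc² lives on pressure nodes.
- **Sources and receivers.** Additive ("soft") pressure sources on element
  footprint cells with a 3-cycle cosine ramp; element recordings are
  area-weighted footprint averages. ⟨p²⟩ and peak |p| accumulate over the
  final 5 full cycles. Soft sources keep the discrete system linear and
  reciprocal (verified to machine precision).
- **Nonlinearity.** An optional quadratic correction scales the stiffness
  term by (1 + (1 + B/2A)·p/ρc²). Default off: every reported metric is a
  ratio of quadratic field functionals, and the B/A values (water 5.2, fat
  9.9, gland 7.0, skin 7.9) are literature placeholders, not part of the
  measured property set.

A linear diffraction oracle provides the independent free-field reference:
the Rayleigh-type integral over the spherical cap (O'Neil's approximation),
evaluated by midpoint quadrature in (ring, azimuth) on an axisymmetric
(r, z) grid about the focus. The cap-with-hole field is the full cap minus
the inner cap; the on-axis field has the closed form
−(2πA/(ikz))(e^{ikd₂} − e^{ikd₁}), which the quadrature matches to < 0.5%.
A 2-D analogue superposes line-source Green's functions (i/4)H₀(kd) on the
same cells the FDTD arc source occupies; the FDTD focal amplitude profile
matches it to 0.4% RMS over the 10 mm disk at 15 points per wavelength.

## Phased array and time reversal (`transducer`)

The clinical geometry: 256 elements tiling the spherical cap of focal
distance 100 mm, aperture 120 mm, central hole 35 mm (f-number 5/6, active
area ≈ 1.160 × 10⁴ mm²). Rings are partitioned in equal cumulative area and
subdivided into sectors proportional to circumference, so all elements have
exactly equal area; the layout is deterministic. The 2-D cross-section
simulations use an arc analogue with the same f-number and hole-to-aperture
ratio at reduced focal distance.

Time-reversal focus control: a forward run with a point emitter at the
target records every element; each element's arrival lag relative to the
reference element (the one nearest the beam axis) is the argmax of their
cross-correlation over one drive period, refined by parabolic
interpolation. The drive phase is +2πf·lag — advance what arrived late —
which for a monochromatic drive is insensitive to whole-period ambiguity.
The drive amplitude is the element-to-reference RMS ratio, capped at 4:
physical time reversal re-emits in proportion to what was received, so
elements shadowed by strongly aberrating tissue contribute little. We also
evaluated the inverse convention (boosting shadowed channels to equalize
the aperture); it pumps energy into the scattering paths, lowers the
focusing ratio below the uncorrected drive, and can throw the global field
maximum tens of millimetres off target, so it is not used.

## Focal metrics (`metrics`)

With V_r and V_R concentric spheres of r = 2.5 mm and R = 10 mm about the
target (voxel-center membership, no partial-volume weighting; the membership
error is below 1% at the default metric resolutions):

- localized heating ratio β = ∫_{V_r} Q dV / ∫_{V_R} Q dV with
  Q = α·p̂²/(ρc) (p̂² = 2⟨p²⟩, the squared amplitude; the convention cancels
  in every ratio). Uniform heat gives β = (r/R)³ = 0.0156.
- focusing ratio φ: the same construction on p²/(ρc); Φ = φ/φ₀ normalizes
  by the free-field value. The linear diffraction value for the clinical
  geometry is φ₀ = 0.232.
- local acoustic inhomogeneity
  χ = √((1/V)∫_V |∇(ρc)|² dV) / (ρ_w c_w / λ_w), with the gradient by
  central differences on the impedance map (one-sided at domain edges). The
  region V is the truncated cone from the active aperture rim converging to
  a 2.5 mm apex at the target — the beam path. V includes the water on the
  path: water's interior gradient is zero, so it only dilutes the average.
  Restricting V to tissue voxels (available as an option) makes χ a
  *per-tissue-voxel* interface density; sparse-gland arrangements then have
  small regions dominated by the skin shell, χ rises exactly for the
  cleanest paths, and the anticorrelation with Φ that makes χ useful as an
  arrangement indicator is lost. For sharp tissue interfaces |∇(ρc)| scales
  as 1/h with the grid spacing h, so χ ∝ 1/√h; χ is therefore a comparative
  indicator at a fixed resolution, not an absolute material constant.

Pearson correlations use `scipy.stats.pearsonr`.

## Pipeline and study conditions (`pipeline`)

Ensemble runs are 2-D (the cross-section through the target), which keeps a
case on a workstation: arc focal distance 40 mm, aperture 48 mm, hole 14 mm
(f-number 5/6), 64 elements, 2 MHz, dx = 0.12 mm, 85 drive cycles
(≈ 1400 time steps on a ≈ 700 × 560 grid), PML 20 cells. The free-field
reference (φ₀ and peak) is computed once per configuration and cached by a
hash of the settings. The 3-D clinical geometry enters through the
diffraction oracle and the cap-array geometry checks.

The ensemble (10 cases) spans the four reference morphologies — gland near
the chest wall, gland reaching the nipple, sparse gland, dense gland — at
two transducer rotations each, plus a fine-grained dense variant and a very
sparse variant. Targets are lesion-like, i.e. placed in the fibroglandular
class (lesions segment as fibroglandular tissue); mixing fat-sited targets
into the ensemble makes β/φ bimodal through the α-weighting of V_r and
destroys the near-proportionality of the two ratios. The four time-reversal
fixture cases keep the fat/gland target contrast: a target in fat clear of
the gland and targets deep in the gland network.

The gland-removal ablation replaces fibroglandular properties with fat
properties on the same phantom and pose, isolating the gland network as the
aberration source. Re-segmenting the same phantom at fat fractions
46.5/66.5/86.5% probes the sensitivity of Φ to the segmentation threshold;
the direction of the change is not asserted (it need not be monotone).

## Known limitations

- 2-D ensemble dynamics understate out-of-plane scattering; the clinical
  3-D geometry is configuration-reachable but not a test target.
- Linear propagation by default; the nonlinear option exists but the loss
  model is frequency-flat.
- χ values are resolution- and dimension-specific (see above) and are
  interpreted only through orderings and correlations.
- The phantom generator is statistical, not anatomical; ensemble
  correlations characterize the method, not a patient population.
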