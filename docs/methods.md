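# Methods

paovox simulates 3D multiwavelength photoacoustic (PA) imaging of layered
skin and trains volumetric networks to recover vascular blood oxygen
saturation (sO2).  This note documents the models, the numerical choices,
and what the desk-scale experiments do and do not demonstrate.

## Image formation model

A PA image voxel at position `x` and excitation wavelength `λ` carries

    p0(x, λ) = μa(x, λ) · Γ(x) · Φ(x, λ; μa, μs, g)

with absorption coefficient `μa`, PA efficiency `Γ` (set to 1 throughout),
and the fluence `Φ`, which depends on the entire 3D optical-property
distribution.  Because `Φ` varies with wavelength, the spectral ratios in
the image are not those of the absorbers — this spectral coloring, plus
limited-view reconstruction artifacts and sensor noise, is what the
learned estimator must compensate.

## Tissue phantoms

Three planar layers (epidermis, dermis, hypodermis) over a voxel grid with
the sensor plane at z = 0, plus tubular vascular trees:

| parameter | distribution | unit |
| --- | --- | --- |
| epidermis thickness | U(0.1, 0.3) | mm |
| dermis thickness | U(1.3, 2.9) | mm |
| hypodermis thickness | U(0.8, 2.6), extended to the grid bottom | mm |
| melanosome fraction C_M | U(0.06, 0.40) | — |
| dermal blood fraction C_B | U(0.002, 0.07) | — |
| dermal blood sO2 | U(0.40, 1.00) | — |
| vessel sO2 | each body gets one of ≤ 3 values ~ U(0, 1) | — |

Layers deeper than the grid are clipped (on shallow desk-scale grids the
dermis often reaches the bottom; on the full 4 mm grid all three layers are
present).  Optical properties per tissue class follow standard skin
compilations: epidermal absorption is a melanin power law
`C_M · 6.6e11 λ^-3.33` plus the skin baseline
`0.244 + 85.3 exp(-(λ-154)/66.2)` (cm⁻¹, λ in nm); dermal absorption mixes
whole-blood absorption (fraction C_B) with the same baseline; reduced
scattering follows `a (λ/500)^-b` per tissue; hypodermis values are
interpolated linearly between measured anchors at 770 and 830 nm.
Whole-blood absorption is linear in sO2 between embedded Hb/HbO2 values at
784/796/808/820 nm (150 g/L total hemoglobin, overridable).  Anisotropy for
epidermis/dermis interpolates 0.95→0.8 over 700–1500 nm (≈0.937 in the NIR
window); blood g = 0.994, hypodermis g = 0.8.  All coefficients are stored
in mm⁻¹ on the grid; the optics module returns the source units (cm⁻¹).

The vascular trees are random-walk tubes (optional bifurcation) rasterized
as swept spheres, a parametric stand-in for tomographically measured
vessel geometries.  Radii (0.2–0.4 mm by default), counts and tortuosity
were chosen once to resemble superficial vasculature at the 0.1 mm grid
scale; bodies are rejected-and-redrawn until pairwise disconnected under
26-connectivity, so connected-component labeling recovers them exactly.

## Monte Carlo fluence

Voxel-stepping photon transport with Henyey–Greenstein scattering.
Absorption is treated as continuous weight attenuation along each straight
segment, and fluence uses the track-length estimator
`∫ w dl / (μa-free form when μa = 0)`; this makes the pure-absorber case
exactly Beer–Lambert and keeps the estimator defined at μa = 0.  The
steady-state estimator is equivalent to integrating the time-resolved flux
over any window long enough to capture the scattered photons (the domain
is a few mm; light crosses it in tens of ps).  Photons leaving the domain
are terminated and tallied as escaped; weights below 1e-6 are tallied as
terminated, so absorbed + escaped + terminated equals the launched weight
exactly (verified to 1e-6 relative).  Boundaries are refractive-index
matched; Fresnel effects at the surface are not modeled.  The beam is a
truncated Gaussian with waist 140 voxels scaled by (grid width / 120),
centered on the top face.  Randomness comes from counter-based splitmix64
streams keyed on (seed, photon index): bit-reproducible and
order-independent.

## Acoustics

Homogeneous lossless medium (c = 1500 m/s), first-order k-space
pseudospectral solver: spectral gradients on staggered grids with the
exact-propagator correction `sinc(c|k|Δt/2)`, split-field PML (10 voxels by
default, quartic profile, α = 2) emulating an open domain; the padded grid
is rounded up to FFT-friendly sizes with the surplus absorbed into the
PML.  Time step Δt = CFL·dx/c with CFL = 0.3; recording duration 1.5× the
grid-diagonal traversal time.  The first velocity update uses Δt/2 so all
recorded samples sit on half-integer time levels (`times_us`).

The detector is an ideal point-sensor array covering the full top plane
(no directivity, no bandwidth limit).  Before propagation the background
(non-vessel) signal in the top three voxel planes is zeroed — the bright
superficial layers would otherwise dominate the traces; vessel voxels are
preserved.  Gaussian noise with standard deviation `c · max|trace|`
(c = 1% by default, maximum taken per wavelength over all traces of one
image) is added to the time series.  Time reversal enforces the recorded
traces, reversed, as a Dirichlet pressure condition on the sensor voxels
of the same solver; the field after the earliest sample is the
reconstruction.  Full-enclosure validation (sensors on all six faces)
recovers a smooth source to ~1% relative L2 error on a 32³ grid; the
planar limited view reaches only ~0.85 correlation even for shallow
sources and degrades with depth — this is the physics the networks exploit
and must be robust to, not a solver defect.

## SNR measurement

The chain (fluence → p0 → forward → noise → time reversal) is repeated R
times (R = 20) on one fixed phantom with independent Monte Carlo and noise
seeds.  Per voxel, the mean μ and unbiased SD σ over repeats give
SNR = 20·log10(|μ|/σ); the summary is the arithmetic mean over voxels
(the per-voxel SNR sum is normalized by the voxel count).  Voxels with
|μ| below 1% of the volume maximum are excluded so the mean is not
dominated by the logarithm of pure background noise; the floor is
configurable and reported.  At desk scale (16×20×20 grid, 1e5 photons)
the measured mean SNR is ≈ 23 dB at 1% noise — the same order as the
≈ 21 dB obtained at full scale, with Monte Carlo shot noise contributing
alongside the sensor noise at this photon budget.

## Networks

Two identical 3D encoder–decoder networks with skip connections map the
normalized 4-channel image set to one output volume: network A regresses
the per-voxel sO2, network B the binary vessel map (trained with the same
squared-error loss so its output keeps a confidence interpretation).  Per
scale: two 3×3×3 convolutions + ReLU, 2× max-pool down, 2× transposed
convolution up, concatenation skips, 1×1×1 output head; channels double
per scale from `base_channels`.  The default (3 scales, 16 base channels,
ReLU, no normalization layers) is deliberately smaller than a classic
U-Net to limit the receptive field.  Image sets are normalized by one
global maximum so the inter-wavelength ratios — the spectral information —
survive; per-channel normalization would destroy them.

No deep-learning framework is used: forward and backward passes are
written directly against numpy GEMMs (shifted-kernel convolutions with
explicit gradients), verified against central finite differences to 1e-7
relative.  Training uses Adam (lr 1e-4, batch 5) with early stopping on a
small validation set (patience 10–15, unstated in the source conditions
and config-exposed).  Max-pool gradients are split evenly across ties.
Everything is deterministic given the seeds, so training runs are
bit-reproducible on CPU.

## Output processing and evaluation

The segmentation output V is thresholded at 0.2 (empirical, removes the
faint film connecting vessels), labeled into 26-connected bodies L,
re-thresholded at 1.0 to keep only confident voxels, and masked labels Lv
retain each surviving voxel's original body id — a body split by the
confidence cut still pools into one mean.  Mean sO2 per body is the
arithmetic mean of the (clipped to [0, 1]) network-A output over the
body's voxels; the true mean uses the same voxels on the ground-truth
volume.  Voxels at exactly the threshold are kept; bodies of any size
are retained.  Reports pool bodies across all test images and give the
mean and SD of |Δ| and of the signed Δ in percentage points, for the
segmentation-masked and ground-truth-masked variants, plus a depth-binned
error profile with a Spearman trend statistic.  The naive baseline
performs per-voxel linear least-squares unmixing of the raw reconstructed
image amplitudes against the Hb/HbO2 absorption spectra, ignoring fluence
and artifacts.

## Problem sizes

Presets trade physical scale for runtime; the generator's distributions
and noise level are identical across presets.

| preset | grid | split | photons | network | purpose |
| --- | --- | --- | --- | --- | --- |
| full | 40×120×120 | 500/5/40 | 1e9 | 3 scales × 16 ch | full-scale conditions (days of CPU) |
| scaled | 24×48×48 | 200/5/40 | 1e7 | 3 × 8 | desk-scale replica (hours) |
| mini | 16×24×24 | 20/3/7 | 1e5 | 2 × 8, 100 epochs | test-suite end-to-end runs (minutes) |
| ci | 16×16×16 | 2/1/1 | 2e4 | 2 × 4, 3 epochs | smoke/reproducibility checks |

The mini preset additionally uses a 6-voxel PML and 0.2–0.3 mm vessel
radii so vessels fit the shallower grid.  The test suite runs the complete
experiment at the mini scale and asserts orderings, not absolute
accuracy: training converges, the segmentation-masked per-vessel error is
smaller than the ground-truth-masked one, and both beat linear unmixing.
At this scale the absolute errors (~20 pp) are dominated by the tiny
training set and short training; they are expected to approach the
full-scale figures (≈ 4 pp seg-masked, ≈ 17 pp gt-masked) only with the
scaled/full presets.

## Known limitations

- Planar layers, homogeneous optical properties within each layer, no
  curvature or intra-layer texture; results on real skin require transfer.
- Synthetic random-walk vessels approximate, but do not match, measured
  vascular morphology.
- No acoustic absorption, heterogeneity, sensor directivity or bandwidth.
- Pressure-only Dirichlet time reversal; model-based or iterative
  reconstruction would reduce (not remove) limited-view artifacts.
- The Hb/HbO2 table covers only the four excitation wavelengths; other
  wavelengths require supplying a custom chromophore table.
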