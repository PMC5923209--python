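# Methods

`cardiohelix` maps cardiomyocyte orientation in the left ventricle (LV) from
two modalities — diffusion-tensor MRI (DTI) and structure-tensor analysis of
tissue-cleared light-sheet volumes — and quantifies the helical wall
architecture through helix-angle transmurality (HAT). Because no raw images
from the motivating ex vivo study are publicly available, the package ships a
ground-truthed synthetic phantom generator and validates the whole pipeline
end to end against known truth.

## Coordinate conventions

Volumes are indexed `(x, y, z)` with the long axis along +z (base to apex);
short-axis slices are xy planes. Physical coordinates are
`index * spacing` in micrometres. At each myocardial voxel the cardiac basis
is radial `r̂` (blood-pool centroid → voxel, in-plane), longitudinal
`ℓ̂` (+z), circumferential `ĉ = ℓ̂ × r̂`. The helix angle (HA) is the signed
angle of the fiber's projection onto the (ĉ, ℓ̂) tangent plane, measured
from ĉ toward ℓ̂, reported in (−90°, 90°]; positive HA is a right-handed
(subendocardial) helix. Fibers are axial (sign-free); the projection's
ĉ-component is canonicalized to be non-negative. Fibers whose tangent-plane
projection norm falls below 0.1 (nearly radial fibers) have no meaningful
helix angle and are flagged undefined. Transmural depth (TD) runs 0 % at the
endocardium to 100 % at the epicardium, measured along in-plane radial rays
per slice (the reference analysis works slice-wise; 3D wall normals are out
of scope). Endo/epicardial crossings are located with sub-voxel (midpoint)
precision; rays whose wall cross-section is not a single run (infarct
thinning) are excluded.

## Diffusion tensor estimation

The signal model is `S(b, g) = S0 exp(−b gᵀ D g)` with b in s/mm² and D in
µm²/ms (the 10⁻³ unit factor is absorbed in the design matrix). Taking logs
gives a linear system in (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz), solved by
ordinary (unweighted) least squares per voxel; the same pseudoinverse serves
every voxel, which makes the fit a single matrix product. Non-positive
signals are clamped to `1e−6 · max(S0)` before the log; voxels where at
least half the volumes are non-positive are masked out rather than repaired.
Negative fitted eigenvalues are not repaired either — such voxels are simply
excluded from HA statistics (flagging, not silent correction). The
b-matrix is `b · g gᵀ` exactly; no imaging-gradient cross terms are modeled.

The default protocol is one b = 0 volume plus 12 directions at
b = 1000 s/mm², the 12 directions coming from a seeded electrostatic
repulsion of antipodal charge pairs (the reference acquisition does not
publish its direction table, so a standard quasi-uniform scheme is used and
is configurable). The primary eigenvector e1 (largest eigenvalue) is the
fiber direction; mean diffusivity is trace/3. Eigendecomposition uses
`numpy.linalg.eigh` with e1 canonicalized into the hemisphere of the local
circumferential direction. Voxels with λ1 ≈ λ3 are flagged degenerate.

## Structure-tensor orientation

Optical volumes are differentiated with normalized 3×3(×3) separable Sobel
kernels (unit ramp → unit gradient) and the gradients rescaled to physical
units, which keeps through-plane angles unbiased on anisotropic voxels. The
structure tensor is the Gaussian-windowed average of gradient outer
products; the texture (fiber) direction is the eigenvector of the smallest
eigenvalue — second of two in 2D, third of three in 3D. Coherence
`(λmax − λmin)/(λmax + λmin)` below 0.1 flags the orientation undefined, as
do voxels within ~2 window sigmas of a volume face (window statistics there
are boundary-contaminated). The window sigma defaults to 4 voxels; the
reference work does not state its window, so this is an explicit
configuration knob echoed in output metadata.

Light-sheet shadow stripes (elongated along the illumination axis)
concentrate spectral energy on the `k_axis = 0` plane; a Gaussian notch
damps that plane while a complementary low-pass factor protects DC and the
smooth background. On objects with genuine azimuthally symmetric texture
some signal unavoidably shares the notch band, so destriping is applied
only when shadow artifacts are present.

The mirror-section validation statistic Θ is the signed in-plane angle
between the 2D orientation and the axis `u` orthogonal to `v`, where `v`
joins the LV and RV cavity centres of mass.

## HAT quantification

Per slice, HA is sampled along 20 equidistant radial projections at 8
equally spaced TD stations (the virtual transmural blocks), by
nearest-voxel lookup; each sample is paired with that voxel's own TD value
(duplicates collapse), which reduces rasterization bias in the slope.
An OLS line `HA = a + s·TD` is fitted per profile (≥ 4 samples, ≥ 10 %TD
spread required); the global HAT is the unweighted mean of the accepted
slopes, reported signed (negative for the control convention
+endo/−epi ramp) and as a magnitude. Regional summaries: the AHA 16-segment
model (basal 6 / mid 6 / apical 4 by slice thirds; segment 1 anchored at
the +x reference azimuth — real data should supply the RV-insertion
anchor), and 100 azimuthal segments of 3.6° pooled across slices. MD zoning
uses the published thresholds — infarct MD > 1.12 µm²/ms (excluded from all
HAT statistics), peri-infarct 0.9–1.12, remote ≤ 0.9; the count-weighted
mean of radial-segment HATs equals the global HAT on complete data by
construction.

## FACT tractography

Seeds subdivide each masked voxel into 10³ sub-voxels. Tracking follows the
nearest voxel's e1 (held constant within the voxel), bidirectionally, with
the axial sign flipped per step for forward continuity; termination on mask
exit, inter-voxel turning angle > 60°, or 5000 steps. Step size defaults to
half the smallest voxel dimension. Tracking is deterministic; it serves
visualization and sub-voxel HA rendering, not quantitative tract metrics.

## Cross-modality comparison

Optical volumes are block-average downsampled onto the DTI grid
(physical-coordinate binning; masks by majority vote; the grid mean is
conserved). Myocardium masks are aligned by mutual-information affine
registration (SimpleITK; moments initialisation, masks blurred into soft
edge images, multi-resolution descent, and the initialisation kept if the
optimizer worsens the Dice overlap). Affine-only registration suffices for
phantom cohorts that share geometry; the interface accepts externally
computed deformations for real data. Agreement statistics: Bland-Altman
bias and limits `bias ± 1.96·SD(d)` (sample SD, differences DTI − optical),
single-measure ICCs from the two-way ANOVA mean squares (both
absolute-agreement ICC(A,1) and consistency ICC(C,1) are reported, as the
variant choice is often left unstated in the field), Spearman correlation
with midranks, linear R², Wilcoxon rank-sum for independent groups,
signed-rank / paired t for paired regions; all tests two-sided at α = 0.05.
Outputs label mean, SD and SE explicitly.

## The phantom generator

The phantom is an annular myocardium (defaults: endo/epi radii 1250/3250 µm
— configurable; grids of 48–64 voxels at 125 µm are used throughout the
tests) around a blood pool, with helix angle ramping linearly in TD from
`ha_endo` (+60° default) to `ha_epi` (−60°), i.e. a true global HAT of
−1.2 °/%TD. The per-voxel tensor has λ1 along the fiber and (λ2, λ3) =
(0.7, 0.5) across, giving a remote MD of 0.8 µm²/ms; an ischemic-like
lesion is an angular sector whose eigenvalues are scaled ×1.5 (core
MD 1.2 µm²/ms > the 1.12 infarct threshold) and whose HA is multiplied by a
flattening factor, both fading over a cosine taper that produces a
peri-infarct ring crossing the 0.9–1.12 window. DWI noise is Rician
(magnitude MRI); a zero-signal background lets the Rayleigh mean σ√(π/2)
be verified directly. All randomness flows from `numpy.random.Generator`
seeded by the spec, so outputs are bit-reproducible.

### Optical texture

The optical volume renders stripes that run along the local fiber. Because
the stripe-normal field of a helical ramp has curl, no single smooth global
grating can follow it; the texture therefore uses the phase
`ψ = C (z − r tan(HA) Δφ)` whose iso-surfaces are helical sheets containing
the fiber, anchored within azimuthal sectors blended by a cos² partition of
unity. Two discretization hazards shape the anchoring:

* the intra-window phase drift (radial derivative of ψ) must keep the local
  wavenumber below `max_drift × k0`, or the grating aliases;
* a window must span several azimuthal stripe periods, or the window
  envelope stays phase-locked to the carrier and the windowed structure
  tensor acquires a systematic in-plane bias.

Both bounds depend on radius and on the local helix slope, so the sector
count is chosen per radial shell (125 µm shells, independent random
azimuthal anchor offsets; radial seams are harmless because the radial
direction already lies in the gradient span). Concentric laminar layers
(`cos(2πr/λ_r)`, emulating sheet-like radial intensity variation) break the
single-grating degeneracy so the fiber is the unique direction of least
variation. Optional global shadow stripes emulate light-sheet illumination
artifacts. A nominal stripe wavelength of 250 µm at 31.25 µm synthesis
voxels keeps every local wavelength above 3 voxels; wavelengths below
3 voxels are rejected.

What the phantom does not emulate: histological texture (nuclei, vessels),
papillary muscles, the right ventricle (beyond a second pool for the Θ
axis test), fiber dispersion, partial-volume myocyte mixtures, swelling or
deformation between modalities (both modalities share geometry, so
registration is exercised on synthetic displacements instead). Passing
tests therefore demonstrate correctness of the estimators under the stated
geometry and noise models, not performance on real tissue.

## Numerical choices and problem sizes

Tolerances: tensor-fit round trip at machine precision (< 1e−8 µm²/ms);
noise-free HAT recovery within 0.05 °/%TD on the DTI path and 0.1 on the
optical path (structure-tensor windowing contributes a small multiplicative
bias, ~2–4 % of the slope, dominated by boundary-window truncation of the
ramp). The standard validation phantom is 64³ voxels at 125 µm (8 mm heart,
16-voxel wall) with 4× refined optical synthesis (256³ at 31.25 µm); the
cohort study uses 48×48×16 phantoms with a 12-voxel wall, 7 control-like +
8 ischemic-like samples, DWI σ/S0 = 0.02, matching group |HAT| means of
1.31 ± 0.20 (control) and 0.79 ± 0.13 °/%TD (ischemic). These sizes keep a
full validation run in a few minutes on one CPU while leaving every wall
thick enough for 8 TD stations.

Degenerate inputs: empty masks, coincident LV/RV centres, non-unit
gradient directions, fewer than 6 unique directions, rank-deficient
designs, wavelengths below Nyquist, upsampling requests, and zero-variance
rater pairs all raise explicit errors or flags rather than propagating
silently.

## Known limitations

* The optical path's HAT carries a small systematic multiplicative bias
  from window truncation at the wall surfaces; it is documented, bounded in
  tests, and shared by any windowed orientation estimator.
* TD uses in-plane rays, so strongly tilted walls (apex) are out of scope.
* Registration is affine-only; deformable alignment must be supplied
  externally.
* The AHA segment anchor is the +x axis for phantoms; anatomical anchoring
  requires the RV insertion point.
* Streeter's helix-angle definition admits variants; the tangent-plane
  projection form used here is documented rather than claimed to be the
  reference implementation's exact form.
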