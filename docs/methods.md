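# Methods

`datspect` simulates how brain atrophy biases the semi-quantitative analysis
of dopamine-transporter SPECT ([123I]FP-CIT, "DaTscan"), end to end: a
labelled digital head phantom is progressively atrophied, imaged with a
simplified SPECT acquisition model, reconstructed by filtered back-projection
(FBP), and analysed with the Bolt/Southampton specific binding ratio (SBR).
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments can and cannot show.

## The quantity under study

The Southampton SBR uses a striatal volume of interest (VOI) deliberately
much larger than the striatum, so that counts blurred out of the striatum by
the limited system resolution are still counted:

    SBR = (Cs_total / Cr - Vs_VOI) / Vs

with `Cs_total` the total counts in the striatal VOI, `Cr` the mean count
concentration (counts/cm3) of a nonspecific reference region, `Vs_VOI` the
VOI volume and `Vs` the assumed striatal volume. On an idealised
two-compartment image (uniform background, striatum at `ratio x` background)
the algebra gives `SBR = ratio - 1` exactly; the package's analysis path
reproduces this identity to machine precision (see
`tests/test_acceptance.py`). The bias mechanism under study is that, in an
atrophic brain, CSF spaces (ventricles, sulci, fissures) enlarge inside both
the striatal VOI and the reference region; because the striatal VOI also
contains the unchanged striatal signal while the reference does not, the
reference mean `Cr` falls faster than the striatal count `Cs`, and the SBR —
a ratio of the two — is overestimated.

## Synthetic head phantom (`datspect.phantom`)

The generator builds a labelled voxel head (default 256 x 256 x 128 voxels
at 1.1 x 1.1 x 1.4 mm) from geometric primitives:

* brain: an ellipsoid (base semi-axes 66 x 92 x 60 mm) whose scale is
  calibrated by bisection so the background region — parenchyma minus
  ventricular/sulcal CSF — hits its target volume (default 1387.41 cm3, a
  normal adult whole-brain reference value) within 3 %;
* cortical sulci: two orthogonal families of parallel clefts (default
  spacing 36 mm, width 1.8 mm) confined to the outer 30 % of the brain
  radius, slightly tilted against the voxel grid;
* deep fissures: an interhemispheric (longitudinal) midsagittal cleft,
  complete above the corpus callosum and confined to the outer brain below
  it, and bilateral sylvian clefts superolateral to the insula. These are
  mandatory neuroanatomy: without them all CSF clefts sit within ~20 mm of
  the surface and the deep reference region would be implausibly insensitive
  to atrophy;
* ventricles: lateral, third and fourth ventricles as a union of ellipsoids
  (about 25 cm3 total);
* striatum: per side a caudate-head ellipsoid plus a putamen ellipsoid
  lateral to the lateral ventricle, jointly scaled by bisection to the
  bilateral target (default 17.92 cm3);
* skull: an ellipsoidal shell (7 mm) at a 2 mm CSF gap outside the brain.

The construction is deterministic for a fixed parameter set. A raw-format
reader for the MRI-derived Zubal head phantom (headerless uint8, legend as
configuration) is provided so the same pipeline can run on that volume when
a copy is available; the shipped default legend is a best effort and must be
checked against the legend of the specific distribution.

What the generator does **not** emulate: realistic cortical folding
topology, gray/white uptake contrast (the tracer's nonspecific binding is
modelled as uniform, matching the simulated study design), hemispheric
asymmetry, and partial-volume (mixed-tissue) label fractions. Conclusions
from the synthetic experiment are therefore about the analysis pipeline's
response to CSF-space enlargement, not about any particular patient anatomy.

## Atrophy model (`datspect.atrophy`)

Atrophy level `k` erodes the background region by `(k - 1) * 0.5` reference
pixels (1.1 mm in-plane, i.e. 0.55 mm per level step); level 1 is the
unprocessed phantom. The reference pixel is fixed at 1.1 mm regardless of
the grid a phantom is sampled on, so scaled-down test phantoms experience
the same physical atrophy as the full-resolution conditions.

Erosion thresholds the Euclidean distance transform in physical units,
measuring distance to the complement *region* (voxel cubes, i.e. the
centre-to-centre distance minus half a voxel). With that convention a
0.5-pixel erosion removes the face-connected boundary layer and a 1.0-pixel
erosion additionally the diagonal layer — reproducing the classic
rank-filter erosions at those radii (a large first volume step, then a
smaller increment) while remaining defined at any fractional distance. The
striatum lies interior to the background mask, so erosion at these depths
never touches it; eroded voxels join the CSF class. Erosion is 3D by
default; a per-slice 2D mode is available (`mode="2d"`).

On the default phantom the background volume falls 1393.5 -> 1213.6 ->
1175.1 cm3 over levels 1-3.

## Acquisition model (`datspect.spect_sim`)

Photon-history Monte Carlo is deliberately replaced by an expectation model
plus Poisson sampling: the analysis endpoints (VOI means and their ratios)
depend only on the first two moments of the counts, which this chain
reproduces at a small fraction of the cost.

* Source map: 3.60 kBq/ml in the background (the clinical concentration a
  few hours after injection), `ratio x 3.60` in the striatum (ratios 8, 6, 4
  span normal to strongly reduced DAT binding), zero in CSF, bone and air.
* Attenuation: two compartments at 159 keV — bone 1.22 g/cm3, all other
  in-head tissue 1.04 g/cm3 — times mass-attenuation coefficients
  interpolated log-log from standard photon cross-section tables (soft
  tissue 0.1464, cortical bone 0.1444 cm2/g).
* Projector: parallel-beam rotate-and-sum. Volumes are resampled onto the
  cubic 3.2 mm detector grid (world-centred trilinear), rotated to each of
  90 views (4 degree steps) and summed along the ray axis with the
  attenuation line integral accumulated from each voxel to the detector
  (midpoint rule). In-plane rotation uses the three-shear (Paeth)
  decomposition with quarter-turn reduction: each shear is a per-line 1D
  linear-interpolation shift, so the rotation — and hence the whole
  projector — is exactly linear in the activity and conserves mass away
  from the grid border. Vacuum view totals are conserved to < 0.1 %.
* Collimator-detector response: Gaussian with
  `FWHM(d) = sqrt(3.8^2 + (0.044 d)^2)` mm (conventional LEHR values, both
  config), applied per depth plane; planes are grouped into 0.25-pixel sigma
  bins so each group is blurred once.
* Scatter: an effective in-window fraction (default 0.25) of a broad
  Gaussian (default 50 mm FWHM) copy of each view, renormalised per view.
  Energy window and acquisition time are carried as metadata only.
* Counting: the expectation is rescaled to the prescribed total (default
  1.5e6 counts) and Poisson replicates are drawn from per-replicate
  substreams (`SeedSequence((seed, replicate))`), individually reproducible.

The rotation radius (150 mm) is a conventional head-orbit value and is
config. Septal penetration, crystal depth effects, dead time and the
high-energy 123I emissions are out of scope.

## Reconstruction (`datspect.fbp_recon`)

Per-view rows are filtered in the frequency domain with a ramp times a
Butterworth low-pass window (amplitude convention
`1/sqrt(1 + (f/fc)^(2n))`; cutoff 0.5 cycles/cm, order 8), then
back-projected slice by slice over the full 360-degree view set
(`skimage.transform.iradon` with its filter disabled). Frequencies are
physical: with 3.2 mm bins the cutoff sits at 0.32 of Nyquist
(1.5625 cycles/cm). Rows are zero-padded to twice their length to suppress
interperiod wrap-around, and the `2|f|` ramp pairs with the backprojector's
`pi/(2 N)` normalisation so a full angle set reconstructs at unit gain (an
analytic uniform-disk sinogram comes back within 2 % in the interior).
No attenuation or scatter correction is applied — requesting either raises
`NotImplementedError`, so the omission is explicit. Reconstructed axial
slices whose projections carry no counts are left zero.

## Bolt analysis (`datspect.bolt_sbr`)

* Striatal VOIs: axis-aligned boxes of fixed volume (nominal 141.56 cm3
  bilateral, split evenly per side) centred on the true striatal centroids
  (phantoms are generated pre-aligned, so no re-orientation step exists).
  Box dimensions are kept odd so mirrored centroids give mirror-symmetric
  VOIs. The default aspect (1.0, 1.75, 1.0) encloses the striatum (about
  23 x 49 x 24 mm per side) with near-equal spill margins in every
  direction (~34 x 60 x 35 mm edges) — the large-VOI principle: a box with
  thin margins in any direction loses blurred striatal counts and inflates
  the SBR's sensitivity to noise in `Cr`.
* Reference region: values outside the VOIs are smoothed with a normalised
  masked Gaussian (default 8 mm FWHM); the threshold is 50 % of the maximum
  of that field outside the striatal area (the VOIs dilated by 20 mm, so
  system-resolution spill cannot inflate the maximum). The threshold
  delineates the whole-brain outline — the filled silhouette of the
  above-threshold region; holes are filled per axial slice first because
  uncorrected attenuation depresses the deep brain and can open the
  silhouette at the poles. The outline is regularised (0.5 level set of its
  Gaussian-smoothed indicator, same FWHM) because the 20 mm margin is
  defined from a segmentation surface, and a ragged noisy boundary would
  let the margin erosion cut channels deep into the region. The reference
  is the outline eroded 20 mm inward minus the VOIs; interior low-count
  structures (ventricles, fissures) remain inside it — which is exactly
  what makes `Cr` sensitive to atrophy.
* Quantities: `Cs_total` sums raw reconstructed values per VOI; `Cr` is the
  mean masked-smoothed value in the reference divided by the voxel volume.
  In Eq. form the per-side `Vs_VOI` is the achieved voxelised VOI volume
  (so the uniform-image SBR = 0 identity is exact on a discrete grid);
  `Vs` is the configured 17.92/2 cm3 per side. Left and right SBRs are
  averaged into the output measure.

## Experiment (`datspect.experiment`)

`run_grid` runs levels x ratios x replicates. Two structural facts are
exploited: the attenuation map is identical across levels and ratios
(eroded voxels attenuate as soft tissue either way), and the projector is
exactly linear — so per level only the background compartment is projected,
the striatal compartment once globally, and each ratio's expectation is
composed as `background + ratio x striatum`, with bitwise-identical results
at one ninth of the projector cost.

Acquisition is time-based, as in a fixed-duration clinical scan: the count
level is calibrated once per ratio so the least atrophic model acquires
1.5e6 counts, and more atrophic models (less total activity) detect
proportionally fewer. Rates of change are computed on replicate means
relative to level 1; trends are ordinary least squares of the three level
means against background volume (three-point fits — slopes are reported
with their R2 but carry no uncertainty estimate); significance tests are
two-sample pooled-variance (Student) t-tests against level 1, two-sided,
with no multiple-testing correction. Per-condition random substreams are
derived from the master seed as `SeedSequence((seed, level, 16*ratio))`.

On the default phantom (seeds 1-3) the experiment reproduces the expected
pattern: Cs falls to ~94-97 % and Cr to ~92-95 % of level 1, Cr always
below Cs, and the mean SBR is overestimated by ~4-18 % depending on ratio
and level; SBR trend slopes against background volume are negative with
high R2, Cs/Cr slopes positive.

## Problem sizes and profiles

The default experiment (full-resolution phantom, 9 conditions, 5 replicates,
45 reconstructions) completes in a few minutes on one CPU; the test suite
uses a half-resolution phantom (2.2 x 2.2 x 2.8 mm) for unit fixtures and
the full profile only in the headline end-to-end test.
`ExperimentConfig.ci_profile()` (quarter-resolution phantom, one ratio,
three replicates, reduced counts) exercises the full stack in under two
minutes for continuous testing.

## Known limitations

* The synthetic anatomy is geometric; absolute rate-of-change magnitudes are
  phantom-specific. Only directions and approximate magnitudes transfer.
* The 50 %-of-maximum threshold makes the reference region an extreme-value
  statistic of a noisy field; its replicate-to-replicate variability is a
  genuine property of the method (raising the count level or the reference
  smoothing width stabilises it).
* The effective scatter model has no energy dependence and the PSF no
  septal penetration tails; both flatten, slightly, the attenuation cupping
  a full transport code would produce.
* The Zubal legend ships as configuration; reproducing published volumes
  from that phantom depends on matching its label ids to tissue classes.
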