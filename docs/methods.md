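# Methods

## Problem and system overview

`petseg` segments and quantifies hot lesions in 3-D PET volumes. The system
follows a classic detect-and-quantify architecture: a preprocessing stage,
three parallel segmentation routes (intensity thresholding, K-means
clustering, and a multilayer perceptron applied in either the spatial or the
Haar-wavelet domain), a selection stage that keeps the route with the fewest
misclassified voxels on validation data, and a quantification stage
(computed volume, absolute relative error, maximum caliper diameter,
confusion matrix, ROC).

Because no public PET data with voxel-level ground truth accompanies this
problem, the package ships a first-class synthetic-phantom module; every
claim the tests make is made against simulated volumes with known geometry.

## Synthetic phantoms

**NEMA-like image-quality phantom.** A 168x168x66 grid of
4.07 x 4.07 x 5 mm voxels containing a warm elliptical cylinder
(background activity 1.0) and six hot spheres of inner diameters 37, 28,
22, 17, 13 and 10 mm (analytic volumes 26.52 ... 0.52 ml) on a ring of
radius 57.2 mm in the central axial plane. Sphere activity defaults to 8x
background; the activity ratio is configurable because the real phantom
filling ratio is a per-experiment choice.

**Lung phantom.** 128x128 slices (5.0625 x 5.0625 x 2.425 mm voxels, 180
slices) with a body ellipse, two cooler lung ellipses (0.4x background) and
three tumours of 2, 3 and 2 voxels at slices 68, 57 and 74. In-plane the
tumour voxels form a 4-connected run straddling a 2x2 block boundary, so an
n-voxel lesion occupies n cells of the half-resolution wavelet grid — the
configuration consistent with a 2-voxel tumour appearing as 2 cells of a
64x64 map.

**Degradation model.** The activity map is convolved with a Gaussian of
5 mm FWHM (the scanner's reconstruction post-filter) and additive Gaussian
noise with sigma expressed as a fraction of background activity (default
5%) is applied, then negative values are clipped. Poisson counting noise,
scatter, attenuation and reconstruction artefacts are *not* modelled; the
noise in iteratively reconstructed PET images is approximately Gaussian,
and nothing downstream depends on the exact noise law. Identical specs
(including the seed) generate bit-identical volumes.

**Ground truth and partial volume.** The binary label mask uses the
voxel-centre-in-sphere rule. Activity, however, is rendered with
antialiased edges: each voxel's foreground fraction is estimated on a 4^3
subvoxel grid, and boundary voxels take proportional activity. This matters
quantitatively: the binary mask's volume deviates from the analytic sphere
volume by up to ~6% for the 37 mm sphere (a pure rasterisation artefact),
while the fractional occupancy map integrates to the analytic volume within
1% even for the 10 mm sphere. The occupancy map is attached to the ground
truth and serves as the regression target for partial-volume-aware
quantification (below).

## Haar multiresolution analysis

The 2x2 block transform is O = H^T I H with H = 1/2 [[1,1],[1,-1]], i.e.
the 1/2 normalisation rather than the orthonormal 1/sqrt(2). Consequence:
the approximation coefficient is exactly the 2x2 block mean, so
wavelet-domain features live on the same [0,1] intensity scale as spatial
voxels and one network architecture serves both domains. Both decomposition
orders are implemented (pyramid/nonstandard, which recurses on the
approximation only, and standard, which applies the full multi-level 1-D
transform to rows then columns); they coincide at one level. Slices are
reflect-padded once to a multiple of 2^levels and cropped after
reconstruction; reconstruction is exact to 1e-10 for 1-3 levels in both
orders. Only level-1 approximation coefficients feed the network by default
(84x84 for NEMA slices, 64x64 for lung slices); detail subbands are
retained in the decomposition object.

## Network and training

The classifier is a feedforward perceptron with 144 inputs (a flattened
12x12 window), 70 tangent-sigmoid hidden units and one linear output.
Weights initialise uniformly in +-1/sqrt(fan-in) from a seeded generator.
Trainers: full-batch gradient descent (optionally with the MATLAB-style
adaptive rate: grow 1.05 on improvement, reject and shrink 0.7 when the
MSE worsens by more than 4%) and Levenberg-Marquardt with the standard
Marquardt schedule (lambda_0 = 1e-3, x10 up on rejection, /10 on
acceptance). The LM Jacobian is explicit; when the sample count n is below
the parameter count p (~10 221 for 144-70-1) the step solves the
equivalent dual system (JJ^T + lambda I_n) of size n, which keeps each
iteration at O(n^2 p) instead of O(p^3). Early stopping monitors validation
MSE with patience 6. Data splits are 70/15/15 by *slice* (46/10/10 for 66
slices), so windows from one slice never straddle partitions.

Training-set construction samples windows densely and labels each window by
its **centre** voxel. A window-level any-tumour-in-window rule is also
provided for tile-level detection targets, but it is unsuitable for
per-voxel maps: under dense scanning with score averaging, a background
voxel adjacent to a lesion is covered almost exclusively by
positive-labelled windows, which dilates every lesion by about half a
window and makes zero-misclassification segmentation of separable phantoms
impossible. Centre labelling makes the per-voxel map answer the question
actually evaluated per voxel.

The sample is balanced: all foreground-centred windows, **all** background
cells within 2 cells of the foreground (the blur halo — without these hard
negatives the regressor extrapolates positive scores into the halo and
neighbouring spheres merge into one detected component), and a fixed number
of random far-background windows per slice.

Two target codings are used:

* **presence** (default): centre-cell binary label, any-voxel down-sampling
  to the wavelet grid; label maps threshold the linear output at 0.5.
* **occupancy**: the centre cell's tumour *fraction* (block mean of the
  continuous occupancy map). The network then regresses partial-volume
  occupancy, and lesion volume is estimated as the raw score sum over the
  detected component dilated by one cell, times the cell volume
  (in-plane scale factor squared; the slice axis is never down-sampled).
  Raw summation rather than clipping lets symmetric regression errors
  cancel; the one-cell dilation recovers fringe cells whose occupancy falls
  below the detection threshold. Detection thresholds occupancy scores at
  0.125 — half the smallest nonzero block occupancy (one voxel in a 2x2
  block = 0.25).

## Study protocols and problem sizes

* **NEMA quantification**: default phantom (8:1 contrast, 5% noise), no
  denoising (see below), per-volume normalisation; occupancy network
  trained with LM for up to 25 outer iterations on the 46 training slices
  (roughly 600 windows after balancing); dense scan of all 66 slices.
  Typical result (seed 0): all six spheres detected; ARE 0.2-0.9% for
  spheres 1-5 and ~9% for the 10 mm sphere, whose blurred contrast is
  lowest.
* **Lung detection**: the network trains on the slices of two tumours plus
  20 random tumour-free slices and is evaluated on the held-out tumour's
  slice (cross-slice generalisation, not train-on-test). A perfectly
  segmented 2-voxel tumour yields a 64x64 confusion matrix with 2 tumour
  cells and 4094 background cells.
* **Trainer comparison / hidden-size sweep**: shared window tasks built
  from a few central NEMA slices; LM vs GD is compared seed-matched at
  equal epochs, and the sweep averages final MSE over repeats per hidden
  size. These reproduce orderings (LM far below GD), not the absolute MSE
  values of any particular hardware/run.

Iteration budgets of 25-30 LM steps are a deliberate desk-scale choice: on
these separable synthetic tasks LM converges to MSE below 1e-5 within a
dozen steps, and longer budgets only polish decimals.

## Preprocessing choices

Per-volume (not per-slice) min-max normalisation keeps slice intensities
comparable and bounds the sigmoid inputs. The denoise operator defaults to
a 3x3 in-plane median when invoked directly, but the demo pipelines run
with denoising off: a 3x3 median annihilates lesions smaller than about 3
voxels across — precisely the 2-voxel tumours and the 10 mm sphere the
study targets — and the simulated volumes are already smoothed by the
resolution blur. The choice is configurable and logged.

## Numerical and degenerate-case decisions

* Thresholding at exactly f = T maps to background (the rule is "larger
  than").
* Otsu runs on a 256-bin histogram of the whole volume; ties break toward
  the lower threshold; constant volumes are an error.
* K-means re-seeds an empty cluster at the voxel farthest from its centre
  (logged); clusters are relabelled by ascending centre so labels are
  stable; the ROI is the highest-centre cluster.
* Constant volumes normalise to all zeros with a warning.
* GD aborts with a diagnostic when the MSE becomes non-finite; LM stops on
  iteration budget, gradient tolerance, or lambda overflow (1e12).
* Windows at slice borders use reflect padding (tiling pads at the
  bottom/right; centred scans pad 5 before and 6 after for the even 12x12
  window, placing the centre at offset (5,5)).

## What the synthetic studies do and do not show

The phantoms share the geometry, voxel grids, contrast regime and
resolution blur of the physical/simulated originals, and the degradations
are seeded and reproducible. They do not model Poisson counting statistics,
scatter/attenuation residuals, reconstruction texture, respiratory motion
or anatomical background heterogeneity. Passing tests therefore demonstrate
the correctness of the algorithms and the behaviour of the pipeline under
controlled degradation — not clinical performance. The sub-percent ARE
values on the larger spheres reflect the separability of the synthetic
task; on real scanner data the same pipeline would face partial-volume and
texture effects the generator deliberately leaves out.

## Known limitations

* The LM trainer materialises the full Jacobian; it is intended for window
  sets up to a few thousand samples, not for stochastic large-scale
  training.
* Wavelet-domain maps quantify in-plane at half resolution; sub-cell
  accuracy comes only from occupancy regression, and lesions below ~1 cell
  remain detection-only.
* K-means clusters scalar intensities; no spatial regularisation or texture
  features.
* The decomposition is 2-D per slice; no 3-D wavelets, and the slice axis
  keeps its native resolution in all domains.
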