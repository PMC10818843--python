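# Methods

This note documents the models, numerical choices, and limitations
behind `eit_smdr`.

## Forward model

The sensor is a disk of radius *r* = 1 m with 16 boundary electrodes of
5 cm arc width, evenly spaced, electrode 1 centred at angle 0 with
counterclockwise numbering.  The governing equation is
∇·(σ∇u) = 0 with current injected through electrode pairs.

**Electrode model.**  We use the *gap model*: the drive current enters
as a uniform flux density over the electrode arc, and the electrode
potential is the arc average of the boundary potential.  The gap model
was chosen over the complete electrode model because it keeps the
discrete problem symmetric — reciprocity (drive/measure exchange) and
the conductivity scaling law U(cσ) = U(σ)/c then hold to machine
precision and serve as test oracles.  Contact impedance is not
modelled; see Limitations.

**Discretization.**  Linear (P1) triangles on a structured Delaunay
mesh: interior nodes on concentric rings with isotropic spacing,
boundary nodes placed so that each electrode spans a whole number of
boundary edges with endpoints exactly at the electrode edges.  Default
≈ 2000 elements, configurable.  The Neumann nullspace is removed by a
zero-mean constraint over the boundary nodes (a symmetric Lagrange
multiplier), and the augmented sparse system is solved by LU
factorization with 16 right-hand sides (one per adjacent pair); the
same 16 fields serve as drive and measurement adjoints.

For a homogeneous disk the gap-model solution has a closed Fourier
series (uniform arc flux expanded mode by mode, arc-averaged
potentials); the FEM solution converges to it at ~1.4%/0.8%/0.3%
relative error for ~800/1800/3600 elements, which bounds the
discretization error of the default mesh at around 1%.

**Protocol.**  Adjacent drive and measurement: 16 drive pairs × 13
measurement pairs = 208 values per frame, drive pairs in ascending
order, measurement pairs ascending within each drive, measurement
pairs never sharing an electrode with the drive pair.

**Sensitivity matrix.**  Rows are measurements, columns conductivity
unknowns (the printed convention in part of the EIT literature is the
transpose; we fix rows = measurements so that ΔU ≈ SΔσ type-checks).
For P1 elements the derivative of the gap-model voltage with respect to
an element conductivity is exactly −A_e ∇u_d·∇u_m (unit drive
currents), with no quadrature error.  It is verified entrywise against
a central finite-difference oracle (δ = 1e−6 S/m): agreement is
~3e−4 relative, with entries below 1e−4 of the largest compared
against that floor because the finite difference itself carries ~1e−9
absolute round-off there.  Differentiating the scaling law at c = 1
gives the conservation identity Σ_e S[i,e]·σ0_e = −U0_i, which holds
to ~1e−14 in the element basis and to ~0.5% in the pixel basis
(binning error, see below).

## Pixel grid and rasterization

Reconstruction operates on a 64×64 pixel grid over [−r, r]², masked to
pixels whose centres lie strictly inside the disk (M = 3228 interior
pixels).  Pixel (0,0) is top-left, row-major, centres at
(−r + (j+0.5)·2r/64).

Because default elements are larger than pixels, element-to-pixel
transfer uses equal-weight quadrature on a regular barycentric
subdivision (16 points per triangle) binned into pixels:
conductivity-like fields take the area-weighted average per pixel;
Jacobian columns distribute each element's entry over the pixels it
overlaps in proportion to overlap area, so the pixel-basis matrix is
the derivative with respect to per-pixel perturbations and
ΔU ≈ S_pix Δσ_pix carries over (relative linearization residual ~0.1
at 1.2:1 contrast, shrinking with contrast).  Rare interior pixels
without samples are filled from the nearest element and logged.

## Phantoms and noise

Two-phase phantoms: circular (one square) inclusions at 2 S/m on a
1 S/m background.  A six-case library covers the usual benchmark
layouts (three separated circles; two near-centre plus one peripheral;
centre plus ring; four circles; ten small circles; square plus circle);
the exact coordinates are this package's own choices.  Random phantoms
draw 1–3 non-overlapping circles with radii U(0.10, 0.25) m and 0.05 m
clearance margins — sizes chosen to resemble the benchmark layouts
while spanning central and peripheral positions.  All generators are
pure functions of their seed.

Noise is zero-mean additive white Gaussian, *signal-independent*: one
global standard deviation per frame equal to rms(ΔU)·10^(−SNR/20),
SNR in dB (30–70 dB is the standard range).  Note the scale is the
rms of the *difference* signal; at 30 dB the noise is 3.2% of rms(ΔU),
which is small compared to the linearization error at 2:1 contrast —
reconstructions are therefore very noise-robust across this range (the
mean CC varies within ±0.002 from 70 to 30 dB; visible degradation
starts below ~20 dB).  A consequence is that monotone CC-vs-SNR trends
inside 30–70 dB sit below the Monte-Carlo resolution of studies with
tens of phantoms; only the endpoint contrast is a stable summary.
Drop-type data (non-conductive objects in conductive saline) are
handled by negating the frame upstream so that objects are always
positive conductivity changes.

## Regularization and λ selection

Tikhonov with L = I, solved from the thin SVD of S (208×M), never by
explicit inversion; the decomposed working-area solves use the
algebraically identical dual form Sᵀ(SSᵀ + λI)⁻¹ΔU, sized by the
measurement count.

`lam="auto"` selects λ from a log grid by generalized cross-validation.
Two design points matter:

* **The grid is relative.**  Grid bounds are in units of ‖S‖₂² (the
  squared spectral norm), because the absolute scale of an EIT Jacobian
  is arbitrary (‖S‖₂² ≈ 8e−4 for the default setup).  A fixed numeric
  `lam` is always absolute.
* **The default grid is 1e−3…1 (20 points).**  GCV on an
  underdetermined full-row-rank system can chase a zero residual on
  clean data and select vanishing λ; below λ_rel ≈ 1e−4 the SMDR
  differential step degenerates, because the Artifact-only working area
  alone can reproduce the frame and the difference of the two solves is
  dominated by null-space components.  The differential cancellation —
  the core of the method — presumes non-vanishing regularization, so
  the search window is floored at 1e−3, inside the regime where the
  decomposed solves are meaningfully smoothed.  Within the window GCV
  still moves λ up under heavy noise.

Algorithm-wide, one λ (the one resolved for the initial image) is
reused for both decomposed solves.

## SMDR pipeline details

* **Clustering features**: by default the first clustering runs on the
  location-compensated initial image (pixel values scaled by r − d_i),
  not the raw one.  EIT amplitudes are depth-biased: a near-boundary
  object can dominate the raw image so strongly that central objects
  fall into the Artifact cluster — which the differential step then
  subtracts, deleting them from the reconstruction.  On randomized
  phantom studies the raw-feature variant leaves the mean CC advantage
  over Tikhonov at ≈ 0 (sign flips between phantom sets) while
  compensated features give a stable +0.06…+0.09; the RE advantage is
  large either way.  Only the clustering features are compensated; the
  decomposed solves, the output image, and the post-hoc metric
  compensation are unchanged.  `compensate_clustering=False` restores
  raw-feature clustering.
* **k-means**: Lloyd's algorithm on the scalar pixel values, k = 4,
  seeded k-means++ initialization, assignment ties to the lowest
  cluster index, emptied clusters re-seeded at the farthest point, stop
  when assignments no longer change (cap 300 iterations).  Clusters are
  relabelled by descending centre: 1 = Object, 2 = Artifact–Object
  Mixture, 3 = Artifact, 4 = Background.  Images with fewer than four
  distinct values collapse to the distinct-value partition with
  NaN-padded centres; decomposition parts for empty clusters are zero.
  Clustering runs on interior-mask pixels only.  The post-processing
  clustering uses the same seed policy as the first.
* **Decomposition** is an exact column partition (S₁+S₂+S₃+S₄ = S₀
  entrywise).
* **Degenerate frames**: an all-zero frame yields an all-zero initial
  image; the pipeline short-circuits and flags the object as absent
  (`object_absent=True`), as does a differential image with no positive
  values.

## Evaluation

CC (Pearson, interior pixels) and RE (Euclidean norm ratio, interior
pixels) against the rasterized truth.  Every reconstruction is
location-compensated — each pixel scaled by (r − d_i) — just before
scoring; compensation is *not* applied inside the SMDR loop (a flag on
the CLI applies it to any output image).  Because SMDR images are
normalized to [0, 1] while truth is in S/m, RE for normalized images is
computed after rescaling the compensated image and the truth to unit
maximum; Tikhonov images are scored raw.  CC is invariant under these
rescalings.

The noise-sweep harness pairs noise across SNR levels (one standard
normal direction per phantom/seed, scaled per level) so that
level-to-level comparisons are common-random-number paired, and is
reproducible bit-for-bit from its seed list.

## Problem sizes

Defaults used throughout the tests and the acceptance script: ~2000
elements for simulation and reconstruction studies, 600 elements for
the finite-difference Jacobian cross-check, 21 random phantoms × 3 SNR
levels for the accuracy study, 12 seeds for noise-endpoint
comparisons.

## Limitations

* 2D circular domains only; no 3D, no complete electrode model, no
  contact impedance, no complex (frequency-dependent) conductivity.
* Simulation and reconstruction share the forward model (the classical
  inverse-crime caveat); noise and the pixel-basis projection decouple
  them only partially.  Conclusions about real tank data require
  independently measured frames.
* The λ policy is a pragmatic stand-in for unsupervised per-frame
  optimization; L-curve and discrepancy-principle selection are not
  implemented.
* The phantom library approximates typical benchmark layouts; it is
  not a reproduction of any particular published geometry, so absolute
  CC/RE values are comparable only within this package.
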