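# Methods

## Physical model and assumptions

The head is a quasi-static volume conductor: piecewise-homogeneous,
isotropic compartments, capacitive and inductive effects neglected.  Neural
activity is represented by equivalent current dipoles; cortical patch
sources are coherent sums of per-vertex dipoles oriented along the outward
surface normal (the orientation of pyramidal-cell populations).  All
simulations are noise-free and single-source: exactly one dipole or one
patch is active at a time, amplitudes are fixed at 1 nA·m per dipole, and
scalp potentials are reported with an average reference.  Bipolar channel
amplitudes |V_i − V_j| are invariant to the reference, which is why the
exhaustive pair search is a reference-free sensitivity measure.

The default conductor has three concentric shells — brain+CSF (0.33 S/m,
80 mm), skull (0.0042 S/m, 85 mm), skin (0.33 S/m, 92 mm).  Brain and CSF
are merged because both carry the same conductivity value in this
three-compartment reading; the skull:soft-tissue contrast is ≈ 1:79.  The
coordinate convention is +x anterior, +y left, +z superior, origin at the
shell center, meters throughout.

## Forward solvers

**Multilayer-sphere series (production engine).**  Per Legendre degree n,
the potential in shell k is A_k rⁿ + B_k r^−(n+1) times the angular
harmonic; the dipole contributes its infinite-medium multipole expansion in
the innermost shell.  Continuity of V and σ ∂V/∂r at each interface and
zero normal current at the scalp yield a (2N−1)-unknown linear system per
degree, solved with each shell's radial basis normalized at its own outer
radius so all matrix entries stay O(1) up to degree 200.  The per-degree
transfer factors depend only on the shell model and are cached, so a
lead-field column costs one Legendre recurrence over the electrodes.
Truncation: terms are accumulated until the geometric bound on the
remaining tail (successive terms shrink by ≈ b/r₁) falls below the relative
tolerance (default 1e−6, cap 200 terms; non-convergence raises with the
dipole eccentricity).  A centered dipole reduces to the n = 1 closed form
3|m|cosθ/(4πσR²) exactly, and equal conductivities collapse any number of
shells to the homogeneous solution to ~1e−16.

**Collocation BEM (independent cross-check).**  The double-layer surface
potential equation is discretized with constant potentials per triangle,
collocated at centroids, with analytic van Oosterom–Strackee solid-angle
element integrals; a flat triangle subtends zero solid angle at its own
centroid, so diagonals carry only the jump term (σ⁻+σ⁺)/2.  The rank-1
constant-potential nullspace is removed by adding a uniform rank-1
deflation term, the system is LU-factorized once, and solutions are
re-zero-meaned.  Electrode values are interpolated barycentrically within
the containing triangle from vertex-averaged triangle values.  On level-4
icospheres the two engines agree to < 0.5% relative RMS for eccentricities
up to 0.7, both homogeneous and with a mild 3-layer contrast.  Plain
collocation degrades at the realistic 1:79 skull contrast (the classical
isolated-skull correction is intentionally not implemented, to keep the
solver small and honest about its accuracy class), so the sphere series —
which handles any contrast — drives all sensitivity analyses and the BEM
serves as the geometric cross-check.

## Synthetic head generators

The generators reproduce the *structure* the analysis depends on, not any
individual anatomy:

| parameter | default | why |
| --- | --- | --- |
| shell radii / σ | 80/85/92 mm, 0.33/0.0042/0.33 S/m | standard 3-compartment adult-head reading |
| cortex base radius | 65 mm | keeps the folded surface ≥ 5 mm inside the brain shell |
| fold amplitude | 0.15 (of base radius) | strong orientation variability without self-intersection |
| fold degree band | spherical-harmonic degrees 8–16 | centimeter-scale undulations, gyrus/sulcus-like |
| cortex mesh | level-4 icosphere, 2562 vertices | desk-scale source space with stable statistics |
| volume grid | 5 mm spacing, 5 mm margin | isotropic grid for free-orientation dipoles |
| cap | 128 electrodes, Fibonacci lattice, elevation ≥ −30° | quasi-uniform dense-cap coverage |
| ear grid | 10 electrodes on an open ellipse, 35 × 25 mm semi-axes, 90° anterior gap | C-shaped around-ear array; taller than wide, so vertical pairs span more |
| montage jitter | 1 mm tangential SD | electrode-placement variability across seeds |
| parcellation | 50 patches, region y < 10 mm excluded | left-lateral region of interest without the medial strip |
| source amplitude | 1 nA·m | reported channel amplitudes land in nV |

The folded cortex is an icosphere with radius r(θ,φ) = r₀(1 + A·f), f a
seeded band-limited random combination of real spherical harmonics
rescaled to max |f| = 1; on the default head 66% of vertex normals tilt
more than 20° from radial.  Ear-grid labels run L1…L8 with the posterior
L4 position flanked by L4a/L4b, ordered from the anterior-superior tip
over the top and down the back; the named single channels are
horizontal = (L1, L4b) and vertical = (L3, L6).  Left and right grids are
exact mirror images before jitter.  The parcellation grows patches from
farthest-point-sampled seeds, always extending the smallest patch first,
giving connected patches with area CV ≈ 0.14.

What the generators do **not** emulate: real cortical geometry (no
hemispheric asymmetry, no deep sulci with opposing walls at sub-centimeter
distance), real 10–5 cap positions, ear canal / concha anatomy, CSF as a
separate thin layer, skull thickness variation, and measurement noise.
Consequently the pipeline's *orderings and structure* (which montage loses
more, how amplitude decays with depth, where gain occurs) are meaningful,
while its absolute percentages are specific to the synthetic geometry —
e.g. patches here average 5.2 cm², roughly a third of a real left-lateral
50-patch parcellation, and the mean ear-grid loss (≈ 47%) is accordingly
milder than on a real head.

## Analyses and numerical choices

*Patch analysis*: each patch's vertex dipoles are summed coherently (same
sign along outward normals), so partial cancellation across a folded patch
is an intended, emergent property.  For each source the best bipolar pair
is found by exhaustive vectorized search; ties break to the first pair in
lexicographic order so histograms are deterministic.  Sources whose best
cap amplitude falls below 1e−3 of the montage's maximum are flagged
uninformative rather than ranked.  The winning-pair histogram includes
only patches with below-average loss, because for high-loss patches all
bipolar amplitudes are near zero and the winner's identity is meaningless.

*Sweeps*: the probe dipole sits on the volume-grid point nearest the left
ear-grid centroid.  Its orientation triplet comes from the least-squares
electrode plane (normal signed outward, in-plane anterior and dorsal
directions orthonormalized to 1e−12).  Position shifts that would leave
the brain are clipped to the largest feasible displacement along the same
direction, with a logged warning — on the default head the nominal 4.5 cm
shifts clip to ≈ 3.2 cm (anterior) and ≈ 2.7 cm (dorsal), because a
straight 4.5 cm chord from a source 1 cm under an 80 mm spherical brain
surface necessarily exits the sphere.  Depth offsets move the dipole
along the inward radial (medial) direction.

*Determinism*: all randomness (cortex folding, parcellation seeding,
montage jitter) derives from one seed through named substreams; artifacts
are written with fixed float formatting, so re-running any stage with the
same config and seed is byte-identical.

## Problem sizes

The default analyses use a 2562-vertex cortex, 50 patches, 128 + 20
channels and a ~14,000-point volume grid; both lead fields assemble in a
few seconds and the full pipeline (head, lead fields, patch analysis,
whole-surface map, sweeps) completes in well under a minute.  The BEM
cross-check uses level-4 icospheres (5120 triangles per surface, 15,360
unknowns for the 3-layer case).

## Known limitations

Constant collocation limits the BEM to homogeneous/mild contrasts; the
sphere series is exact for concentric shells only (no realistic BEM
anatomy path); no noise model, so reported losses compare ideal
amplitudes; the discrete vertex normals of the synthetic cortex converge
to the analytic direction only first-order in mesh size (≈ 6e−3 maximum
deviation at level 4 on an unperturbed sphere).
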