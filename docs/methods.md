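# Methods

`potkit` implements a five-stage system for organizing video collections of
an articulated object class: a motion descriptor built from ordered pairs of
dense point trajectories, temporal partitioning of shots into single-behavior
intervals, unsupervised clustering of those intervals into behaviors,
extraction of consistent motion pairs (CMPs) between intervals of the same
cluster, and pixel-level spatial alignment of each CMP with homographies and
time-varying thin-plate splines. This note records the models, the defaults,
and the design choices made where the design was genuinely open.

## Pair-of-trajectories (PoT) descriptor

A PoT is an *ordered* pair of trajectories tracked over `n` consecutive
frames. The anchor is the member whose velocity stays close to the object's
median foreground velocity (estimated per frame as the per-axis median of the
optical flow over the mask); the swing deviates from it. With `r^k` the
anchor-to-swing vector at frame k and `d^k = r^k − r^(k−1)`, the descriptor
is

    P = (θ, d²/D, …, dⁿ/D),    D = Σ‖d^k‖,   θ = atan2(r¹),

of dimension `2(n−1)+1 = 19` for the default `n = 10`. Differencing the
`r^k` cancels any common motion, so P is exactly invariant to camera
panning; recording only the angle of the initial offset (not its length) and
normalizing by D makes it scale invariant. Pairs with `D = 0` (rigid pairs)
carry no articulation signal and are dropped rather than emitted as zero
vectors.

**Extraction.** Trajectories with any point off the foreground mask are
removed (strict rule — a conservative reading of background removal).
Frames are scored by `s(f)`, the mean over the PoT window of σ, the standard
deviation of flow magnitudes over mask pixels divided by their mean; frames
with `s(f) < θ_F = 0.1` yield no PoTs. When the mean flow magnitude is below
1e−6 px (a still frame) σ is defined as 0. Remaining frames score all
ordered candidate pairs with

    S(a, s) = Σ_k ‖v_s^k − v_m^k‖ − ‖v_a^k − v_m^k‖

over the n window frames (per-trajectory velocities are frame-to-frame
displacements; the window's final frame reuses the last displacement, and
the per-frame median velocity of the final shot frame reuses the previous
transition) and keep the top `θ_P = 0.15` fraction per start frame, ties
broken by `(anchor_id, swing_id)`. The production path is vectorized but
must agree *bitwise* with the per-operation reference functions
(`score_candidates`, `select_pots`, `pot_descriptor`); the test suite
asserts this equivalence on scenes of ≤ 30 trajectories.

## Temporal partitioning

Two motion cues split a shot into single-behavior intervals.

**Pauses** are maximal runs of ≥ 3 frames with σ below θ_F; pause frames are
dropped from the output (they carry no articulated motion by definition).

**Periodicity.** Each codeword of the PoT codebook gives a per-frame count
series (a PoT counts toward its start frame); the magnitude spectra of all
series are summed, the DC bin removed, and the spectrum normalized to unit
total. A sliding window (lengths growing geometrically ×1.5 from 15 frames,
stride 5) is labeled periodic when its best admissible peak (period ≥ 5
frames, ≥ 3 cycles) reaches `θ_H = 0.1`. The scalar threshold alone cannot
reject aperiodic content in *short* windows — a 15-frame window has only 7
non-DC bins, so even a flat spectrum concentrates ≈ 0.14 in its largest bin
— so a window must additionally have a peak ≥ 2.5× the median non-DC
magnitude (`min_peak_ratio`), a criterion that is scale-free in the window
length. Greedy recursion labels the best window and reprocesses the
remainders for other periods.

**Boundary reconciliation.** A frame's bag-of-words covers the window
`[f, f+n)`, so changes in BoW space *lead* the behavior change by about
n/2 frames. Gaps between two periodic windows are absorbed at a changepoint
cut: gap frames are compared (histogram intersection) against the two
windows' mean BoW profiles, the best separating cut found, and shifted by
n/2. Edge gaps shorter than the minimum analyzable window (15 frames) extend
the adjacent window; longer ones stay as their own aperiodic interval.
Adjacent windows whose periods agree within 20% merge. On scheduled
synthetic shots this recovers behavior boundaries within ±2 frames, both for
pause-separated and for gait-change (walk→run) transitions.

## Behavior clustering

A k-means codebook (`V = 800` by default, Euclidean distance, best of 8
restarts by within-cluster sum of squares, at most 10⁶ sampled descriptors)
quantizes PoT descriptors; an interval is its L1-normalized BoW histogram.
Pairwise distance is `d(u,v) = −exp(−(1 − HI(b_u, b_v)))`, bounded in
[−1, −e⁻¹]; the multichannel form divides each channel's `(1 − HI)` by its
dataset mean before summing, and reduces to the single-channel form for one
channel with unit normalizer. The normalizers are computed on the collection
being clustered. Intervals cluster by complete-linkage agglomeration cut at
k clusters (a fourth of the interval count unless stated); exact merge ties
follow the linkage library's deterministic scan order — real-valued HI
distances make exact ties measure-zero. Intervals with empty BoWs are
excluded and reported.

## CMP extraction

Per-frame BoWs (PoT channel; optionally an MBH channel — 8-bin orientation
histograms of the spatial derivatives of each flow component in a 16×16
patch at each trajectory point, quantized against a dedicated codebook) give
a frame-distance matrix `d_ij` between two same-cluster intervals; frames
with empty BoWs in either interval are maximally dissimilar (−e⁻¹). A
candidate pair of T-frame subsequences (`T = 10`) scores
`Σ_t d_(i+t)(j+t)`, preserving temporal order; there are `(n−T)(m−T)`
candidates for intervals of n and m frames. The most negative pairs are
kept (10 per interval pair by default) with near-duplicate suppression:
a candidate whose offsets both lie within T/2 of an already selected pair
is discarded; ties break by `(i, j)`.

## Homography alignment

Trajectories spanning the CMP and starting at its first frame are matched
across sequences by nearest neighbor on a trajectory-shape descriptor
augmented with the scale-normalized offset to the foreground center of mass
(length `2(T−1)+2`); the offset term disambiguates trajectories with
identical shape, e.g. points on a rigidly translating torso. RANSAC then
fits `u = H v`:

* **IM** samples 4 point correspondences per iteration and counts point
  inliers;
* **TM** samples 4 trajectory matches, solves the 4T-point least-squares
  system, and calls a match an inlier only when more than half of its point
  correspondences reproject within threshold.

The inlier threshold defaults to 0.05× the mean foreground-box diagonal of
sequence 1 (scale-adaptive); iteration count is adaptive at 0.99 confidence
with a 2000 ceiling; degenerate (collinear) samples are resampled; the fit
ends with a least-squares refit on all inliers. With foreground
regularization the per-frame bounding-box corner correspondences enter every
least-squares objective with unit weight; with no matches at all this
degenerates to the box-only fit. A result whose outlier fraction exceeds the
`max_outlier_fraction` knob is rejected — sweeping that knob traces the
precision–recall curve. H is stored at unit Frobenius norm with positive
bottom-right element.

## TPS, TPS-RPM and temporal TPS

A thin-plate spline `f` is an affine part plus a radial warp minimizing
`Σ w_i‖u_i − f(v_i)‖² + λ‖L(f)‖` with `L` the integrated squared second
derivatives; the weighted closed form solves
`[[K + λW⁻¹, P], [Pᵀ, 0]]`. For λ→0 the fit interpolates; for λ→∞ it
collapses to the weighted affine least-squares fit (the convergence *rate*
in λ depends on the coordinate scale through the kernel `r² log r`, so the
affine-limit check is stated on unit-scale data). Singular systems fall back
to a ridge-regularized solve with a warning.

TPS-RPM alternates a softassign correspondence update — `m_ij ∝
exp(−‖u_i − f(v_j)‖²/2T)` with constant outlier bins at `exp(−k²/2)`,
`k = 2`, doubly normalized by 10 Sinkhorn sweeps — with a TPS refit to the
correspondence-weighted targets, inside deterministic annealing: the
temperature starts at the mean squared nearest-neighbor distance, anneals
×0.93 down to 1 px², with 5 inner alternations per temperature and
`λ = λ₀·T` (λ₀ = 1). At a *fixed* temperature each full alternation is a
descent step on the annealed free energy (correspondence energy plus the
temperature-scaled entropy barrier); the test suite asserts this with the
Sinkhorn scaling run to convergence. Across temperature changes the
objective itself changes, so no global monotonicity is claimed.

**Foreground edges.** The edge provider is pluggable; the default is the
normalized Sobel gradient magnitude of the image (for synthetic scenes, of
the shaded part rendering, which yields both the silhouette and internal
part boundaries). Each point's strength is multiplied by
`exp(−dist/(0.1·bbox diagonal))` of the distance transform to the mask —
on-mask points keep their strength, clutter decays on a scale-free ramp —
points scoring ≤ 0.2 are pruned and the rest subsampled to ≤ 1000 (seeded).
Edge points advect through the flow by bilinear sampling; backward steps
invert the forward flow by fixed-point iteration, and points whose inversion
does not converge to 0.5 px (no consistent pre-image, e.g. at motion
discontinuities) are retired, as are points leaving the image.

**TTPS.** One TPS per frame, all frames sharing a single correspondence
set: edges extracted at an anchor frame τ are advected to every frame, so a
correspondence at τ stays one everywhere (the temporal constraint holds by
construction). Per candidate τ: TPS-RPM runs on the frame-τ sets
(initialized by pre-warping with the coarse homography, which is composed
into the result); the correspondences are then *hardened* — each control
point keeps its argmax counterpart with its soft weight, columns with
weight ≤ 0.05 drop — before the other frames are fit. A soft matrix would
mix target points that are adjacent at the anchor but diverge under motion,
which measurably corrupts the non-anchor fits. The candidate with the lowest
total energy (weighted residual + λ·bending, summed over frames, at the
final annealing λ) is returned, and the argmin over all T candidates is
asserted exhaustively in tests. Reverse application of a TPS uses a numeric
inverse fit on a grid.

## Evaluation

Purity and the adjusted Rand index score interval clusterings against
majority frame labels (ARI via the standard chance-corrected formula; random
assignments average ≈ 0). Uniformity of an interval is the fraction of its
frames carrying its most frequent label; behavior counts increase at most
once per (shot, behavior) so splitting one behavior into pieces earns no
credit. The landmark alignment error maps each co-visible landmark both
ways, normalizes each directional distance by the *object scale of its
target frame* (the maximum pairwise distance among visible landmarks) and
averages; an alignment is correct iff error < 0.18 and the IOU of the
visible-landmark name sets of the two sequences (per sequence, over all its
frames — the stricter reading) exceeds 0.5, which refuses credit for
accidental alignments of a few landmarks. A CMP is *alignable* when the
homography fit directly to the ground-truth landmark correspondences passes
that rule. Precision–recall sweeps the allowed outlier fraction; precision
at zero returns is 1 by the curve-endpoint convention, and average precision
integrates by trapezoid over recall.

## Synthetic scenes

The generator renders a 2-D side-view quadruped of 11 rigid capsules (torso,
neck, head, four two-segment legs) with joint angles driven by behavior
programs: `walk` (period 12 frames, 1.5 px/frame, 0.45 rad leg swing),
`run` (period 6, 3 px/frame, 0.55 rad), `pause` (all rest), `head_turn`
(period 16 neck/head oscillation), `sit` (aperiodic torso/knee ramp). Gait
phasing is a 4-beat footfall (each leg a quarter cycle apart), which removes
the half-period left/right symmetry a trot would have, so the visual period
equals the full gait cycle. One gait period translates the body by an
integer pixel count that is a multiple of the seeding grid, making the
rendered scene at `t + period` an exact translate of the scene at `t`.

Every derived channel comes from the same kinematics: masks are capsule
unions; each pixel is owned by the topmost capsule containing it (otherwise
the nearest), and the flow at a pixel is the rigid frame-to-frame motion of
its owner, defined on a 2 px band around the body and zero elsewhere; the
shaded rendering gives each segment a contrasting gray level so internal
part boundaries produce image edges. Trajectories are *advected through the
generated flow* (seeded on a fixed grid inside the eroded mask, terminated
when they leave the body), so flow/trajectory consistency is exact by
construction, and limb trajectories on unoccluded (near-side) legs are
periodic to ~1e−13 px. Far-side leg points can be captured by the occluding
near leg — exactly as real trackers drift to the occluder — so strict
periodicity is a property of visible limbs only. Landmarks (nose, eye,
shoulder, hip, 4 knees, 4 feet) come from forward kinematics. Degradation
knobs (mask erosion/dilation, flow noise) exist for robustness experiments
and default to clean data.

`warp_scene` maps a scene through any invertible plane warp: trajectories
and landmarks directly (plus optional i.i.d. Gaussian noise), masks and
images by inverse resampling, and flow as `warp(p + f(p)) − warp(p)` — so a
warped scene satisfies the same flow-consistency invariant. Invertibility is
verified by a grid round-trip (< 0.5 px).

**What the generator does not emulate:** appearance texture and lighting,
3-D articulation and out-of-plane rotation, estimation noise in flow and
masks (unless the knobs are turned), tracker drift other than
occlusion capture, and background motion. Passing tests therefore show
correctness of the algorithms under exact inputs and stated noise levels,
not robustness to real video degradation.

## Problem sizes and study conditions

The test suite and the reproduction script run at desk scale, chosen so the
full suite completes in minutes: shots of 24–100 frames, ~70–250 trajectories
alive per frame, codebooks of 32–128 words (800 remains the library
default), 150–300 edge points per frame for TPS-RPM, and a six-shot
two-behavior collection for the end-to-end run. Nonrigid warp-recovery
fixtures use the head-turn program: its flow is slow and smooth, so edge
propagation (including backward flow inversion) is well posed, whereas
backward tracking through fast occluding legs is not — gait scenes exercise
the homography and end-to-end paths instead. The TTPS-vs-homography
comparison uses a 3×3-grid TPS warp with 10 px control-point displacements,
strong enough that an 8-dof homography cannot express it; in TPS/TTPS
accuracy statements "scene scale" means the image diagonal, while the
evaluation module's normalized error uses the object scale as defined above.

## Known limitations

* Backward edge propagation is ill-posed across motion discontinuities; the
  retirement rule drops such points rather than guessing.
* TPS-RPM accuracy on contour-like point sets plateaus near the edge
  subsampling spacing (tangential sliding along contours is weakly
  constrained); internal part edges mitigate but do not remove this.
* The spectral periodicity test needs ≥ 3 cycles in a window and a period
  ≥ 5 frames; shorter or slower patterns fall back to pause-based cuts.
* Complete-linkage clustering is quadratic in intervals and the CMP search
  quadratic in interval length; both are fine at the intended scale
  (hundreds of intervals).
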