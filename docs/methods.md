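# Methods

## Apparatus model and world frame

The arena is a vertical glass tube observed by one fixed pinhole camera
and, via two planar mirrors behind the tube, by two virtual cameras.  The
world frame has its origin at the centre of the tube base with z up (the
gravity/climbing axis); the camera sits on the −y axis at 95 mm from the
tube axis, at tube mid-height, looking along +y with a 50° horizontal
field of view at 640×480.  The two mirror planes contain vertical lines,
meet at a vertical edge 25 mm behind the tube axis, and each makes 39°
with the chamber back wall (the x–z plane), opening toward the camera.
Pixel coordinates are continuous; integer coordinates address pixel
centres with the origin at the top-left pixel centre.  No lens distortion
is modelled.

The tube defaults to 10 mm radius × 50 mm height (a ~20 mm inner-diameter
vial).  These dimensions are deliberate: with this camera and mirror
arrangement they are close to the largest tube for which (a) the whole
tube is inside all three view frusta (the VGA vertical field of view
covers only ±33 mm at 95 mm) and (b) the three tube images occupy
disjoint pixel strips, which the view-assignment step requires.  Both
properties are validated at runtime (`view_strip_boundaries` raises on
overlap) and by tests.

## Projection, back-projection and triangulation

A mirror view of a fly is, optically, the fly seen from the mirror image
of the camera.  Projection into a mirror view therefore reflects the
world point about the mirror plane and projects with the real camera;
back-projection builds the real camera ray through the pixel and reflects
its origin and direction about the plane.  Reflection is the exact
involution `p − 2((p−q)·n̂)n̂`, so image handedness is handled implicitly
and no second projection model exists.

Two rays from distinct views are intersected by the closest-approach
construction for skew lines; the reconstruction is accepted when the
minimum pairwise crossing distance is within the crossing tolerance
(0.1 mm = 100 μm by default, configurable).  Two of three views suffice.
The reported point is the midpoint of the closest pair, or the centroid
of the three pair midpoints when all three pairs agree.  Parallel rays
return their perpendicular offset and a midpoint at matched parameters —
never an exception — so degenerate pairs cannot abort a tracking loop.
Noiseless round-trips recover positions to better than 1e−6 mm; at
0.2 px detection noise the median crossing distance stays below the
100 μm budget (1 px ≈ 0.14 mm at the tube).

## Detection

Flies are dark blobs on a light background.  A temporal-median background
(every 5th frame by default) removes the static scene; absolute
differencing makes the detector polarity-free.  Connected components of
`|frame − background| > threshold` (threshold defaulting to 25% of the
frame's intensity range) with area ≥ 4 px² are emitted with
intensity-weighted sub-pixel centroids, which keeps the median centroid
error below 0.3 px — necessary, since a full pixel of error would exceed
the triangulation budget.  Touching flies merge into one detection and
are not split; the tracker tolerates the resulting dropouts.  Views are
assigned by the static pixel-strip partition derived from the geometry.

## Cross-view matching

All detections of a frame are back-projected; every cross-view pair
crossing within tolerance is a candidate, and every triple in which at
least two of the three pairs cross within tolerance is a three-view
candidate (a triple with only one consistent pair is just a pair plus an
unrelated detection and is not promoted).  Candidates outside the tube
volume plus a 2 mm margin are discarded as triangulation ghosts.
Conflicts — a detection claimed by several candidates — are resolved
exactly: the accepted set maximises the number of detections explained
(so three-view candidates beat the two-view candidates embedded in them)
and, among such sets, minimises total crossing distance.  The conflict
graph is split into connected components; small components are solved by
exhaustive search, large ones as a small integer program (HiGHS via
scipy).  Ties are broken deterministically toward the lexicographically
first combination.  Tests verify agreement with an independent
brute-force enumeration on instances up to 4 flies.

## Linking and the walking gate

Per frame, active trajectory heads and candidates are assigned
one-to-one by the Hungarian algorithm on Euclidean displacement;
assignments above the gate (2.0 mm per frame) are forbidden.  Unmatched
candidates open new trajectories; a trajectory unmatched for more than
`max_gap` frames (default 0 — no gap bridging) is closed.  Only
trajectories with ≥ 2 samples are returned and the gate bound is asserted
on every output.  At 7–10 fps the gate passes walking (≤ 20 mm/s) and
excludes flight and falling, which move faster; this is the mechanism by
which only walking behaviour enters the record.  Positional gating cannot,
however, resolve a genuine coincidence: if a falling fly passes within the
gate of another fly whose detection dropped out in that frame, a single
fall sample can be adopted as a trajectory endpoint.  Fall *segments*
(consecutive fall samples) can never be linked, and such single-sample
identity errors are rare (observed at well under the 5% identity-switch
bound the tracker is tested against).

## Session segmentation

Motion energy is the mean absolute intensity difference between
consecutive frames — parameter-free and invariant to global additive
lighting offsets.  Frames with energy above 5× the median form
high-energy runs (runs closer than 5 s merge); each run is one tap, timed
at its last frame so the analysis window starts once the flies have just
landed at the tube bottom.  Each tap opens a 15 s window, labelled t0,
t1, t2, …, truncated at the next tap or the end of the session.  On
simulated sessions the recovered window starts are within one frame
(0.1 s) of ground truth.

## Descriptors and cohort statistics

* **speed**: per-step distance over elapsed time, mm/s.
* **persistence length**: end-to-end distance over total path length,
  in [0,1]; undefined (and excluded from cohort means) for zero total
  distance.
* **turn tightness**: median dot product of adjacent *unit* step vectors,
  in [−1,1]; zero-length steps are skipped; undefined with fewer than two
  non-zero steps.  Normalisation makes the descriptor the cosine of the
  turning angle, hence speed-invariant and bounded; the raw unnormalised
  dot product is available via a flag for comparison.
* **cohort summary**: density-normalised pooled speed histogram over
  0–20 mm/s in 40 bins with overflow accumulated in the last bin; pooled
  mean speed; cohort mean of per-trajectory 95th-percentile speed (the
  "maximum velocity" statistic — the 95th percentile is robust to
  single-frame triangulation glitches).
* **decline rate**: least-squares slope of cohort mean speed against age
  (mm/s per day), requiring ≥ 3 ages.
* **fractional signal difference**: (control − test)/control on a chosen
  cohort metric for age-matched cohorts; negative values (test faster)
  are allowed.
* **group comparison**: two-sided Wilcoxon rank-sum on per-trajectory
  values, the trajectory being the unit of replication.

Persistence length and turn tightness are invariant under rigid motions;
speeds are invariant under rotation/translation and scale linearly with
spatial scale.  All invariants are property-tested.

## Synthetic cohorts

The simulator emulates what the assay actually elicits: flies walk on the
inner glass surface, so their state is (azimuth, height) on the cylinder.
Each frame the fly steps `speed × dt` along its surface heading; the
heading diffuses with Gaussian noise (σ = 0.4 rad/step) and, for 15 s
after each tap, is pulled toward vertical (negative geotaxis — the flies
climb after being knocked down).  Per-step speed is drawn from a normal
distribution with mean μ(age) and CV 0.3, clipped to 0–20 mm/s; the
healthy control mean is 10 mm/s, giving a broad distribution with median
≈ 10 mm/s over the observed 0–20 mm/s range.  Heading reflects at the
tube ends so realised step lengths are preserved.

Phenotypes decline linearly after an onset age:
`μ(a) = μ0 · max(0, 1 − r·max(0, a − a0))`.  Defaults: control and an
innocuous Aβ40-like genotype do not decline; an Aβ42-like genotype loses
5%/day after day 2; an aggressive Aβ42-arctic-like genotype loses 12%/day
after day 2, making it grossly impaired by day 7–10 and essentially
immobile by day 14.  All rates are configuration, not conclusions.

Falls are Poisson events (default 0.5/min per fly) during which the fly
drops at 80 mm/s to the floor; flight bursts (default off) dash at
60 mm/s.  Samples are labelled `fall`/`flight` only while the motion on
*both* sides of the sample exceeds the 2 mm gate (falls start only above
5 mm; descent samples below 2.5 mm count as landing), so the labelling
itself guarantees that gated linking isolates those samples.

Rendering projects each fly into all three views, either directly to a
detections table (Gaussian pixel noise, optional per-view miss
probability) or to frames: a textured light background, dark Gaussian
blobs (σ = 1.5 px, amplitude 120), sensor noise (σ = 2), and a 0.5 s
whole-frame shake with boosted noise at each tap so the motion-energy
trace saturates exactly as a real tap does.

What the simulator does *not* model: fly appearance and pose, wing/leg
kinematics, inter-fly interactions (real flies touch and occlude far more
richly), photometric drift, and the real shape of the per-fly speed
distribution (only its range and median are constrained).  Passing tests
therefore demonstrate the correctness of the geometry, gating, assignment
and statistics under realistic noise and crowding — not detector
performance on real video.

## Problem sizes and numerical choices

Test and acceptance runs use full 90 s sessions at 10 fps with 10 flies
(900 frames, ≈ 27 000 detections) and cohorts of ≥ 50 trajectories per
condition; the decline-rate check spans five ages from day 2 to day 14
with five sessions per age.  Tolerances: reflection/back-projection
round-trips 1e−9 mm; noiseless triangulation 1e−6 mm; crossing tolerance
0.1 mm; linking gate 2.0 mm (boundary inclusive); window starts within
0.3 s.  Determinism: a single integer seed fixes every simulation; the
matcher and linker break ties deterministically, so identical inputs give
identical outputs byte for byte.

## Known limitations

* Merged blobs are not split, so trajectories fragment when flies cluster
  at the tube bottom after a tap; statistics are per-step and unaffected,
  but trajectory counts overestimate fly-path counts.
* No gap bridging by default: a single missed detection ends a
  trajectory (configurable via `tracking.max_gap`).
* The 100 μm criterion is applied literally to ray-pair distance, not to
  reprojection error.
* View assignment assumes the three tube images do not overlap in pixel
  space; very wide tubes or small mirror angles violate this and are
  rejected at configuration time.
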