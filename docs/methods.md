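# Methods

## Problem and model

A bitewing radiograph shows the crowns and crestal bone of the upper
(maxillary) and lower (mandibular) arches in one frame. Alveolar
crestal height (ACH) — the distance from the cemento-enamel junction
(CEJ) to the alveolar bone crestal level (ABCL) of a tooth flank — is
the standard radiographic proxy for periodontal bone loss; ACH at or
above 5 mm is read as severe. `achkit` is the deterministic
post-processing stage of a detection-based ACH system: its inputs are
two point-landmark sets (from two complementary detectors), two teeth
segmentation masks, one bone-crest (ABCL) mask, and a scalar
calibration in mm/px; its outputs are per-tooth-site ACH values and
severity calls.

The coordinate frame is the raster frame: x = column, y = row, y
increasing downward. Landmarks are continuous points; masks are
boolean rasters. All iteration orders are fixed, so the pipeline is
bit-reproducible.

## Pipeline stages and the choices behind them

**Landmark fusion.** The two detectors' outputs are united and
deduplicated by greedy non-maximum suppression per class: candidates
sorted by descending confidence (ties: first detector, lower x, lower
y), a candidate suppressed when a kept same-class point lies strictly
closer than the radius (default 30 px — half the 60 px annotation-box
scale of crestal-landmark labels). Selection, not averaging, was
chosen: it is deterministic, keeps the better detector's localization,
and is verifiable against an exhaustive suppression oracle. A pair at
exactly the radius survives (strict inequality).

**Arch partition.** The separating line is the ordinary least-squares
regression of y on x over all ABCL-mask foreground pixels. Bitewings
are landscape: the crest pixels form two roughly horizontal bands, one
per arch, so the pooled OLS line runs between them. Orthogonal
regression was rejected as unnecessary — x-spread dominates. A
landmark exactly on the line counts as upper (tie-break).

**Arch curves.** Per arch and landmark class, a least-squares
polynomial y(x), default degree 2: enough for the mild occlusal curve
without oscillation. With fewer distinct x values than degree + 1 the
degree is reduced to (distinct − 1) with a logged warning rather than
failing; below 2 distinct x values the curve is dropped and the arch
skipped. Coefficients are stored in ascending order; the curve is only
ever evaluated inside the x-range of its fitting points (its support).

**Tooth instances.** The two teeth masks are united pixel-wise
(each network covers the other's misses), then labelled as 8-connected
components; components under 200 px are discarded as noise. The
outline is the set of foreground pixels with at least one background
4-neighbour, with off-image treated as background. Instances are
ordered by x_min, then y_min (upper and lower teeth can share a column
range), and tooth ids follow that order — the phantom generator uses
the same rule so predictions and ground truth join on tooth_id. Each
tooth is assigned to the arch containing the majority of its pixels
relative to the partition line (tie: upper).

**Crossing gate.** A tooth is measured only if its outline crosses
both of its arch's curves. "Crosses" combines a tolerance band (an
outline pixel within 1 px of the curve, inside its support) with a
sign-change test (the curve's y strictly between the tooth's min and
max y at some column), so a constant curve grazing a flat outline is
handled deterministically. Both clauses restrict to the curve support;
extrapolated polynomial values are never used.

**ACH measurement.** Per tooth side — left and right flank in the
image frame, proxies for mesial/distal (true labels would need tooth
numbering, out of scope) — a window of ±fusion_radius_px columns
around the flank column selects candidate landmarks. Among candidates
of each class, the one nearest the tooth outline (Euclidean; ties by
|x − flank|, then x, then y) is chosen. Nearest-to-outline rather than
nearest-to-column is deliberate: crestal landmarks lie on the tooth
flank, so a spurious detection at an arbitrary row loses to an
on-flank point even when its column falls in the window. If both a
CEJ and an ABCL are found, ACH is the Euclidean distance between them
— matching a ruler measurement between two anatomic points, rather
than a vertical drop or an arc length along the curve — converted to
mm by the calibration. A side lacking either landmark emits nothing
(logged).

**Severity.** severe ⇔ ACH ≥ threshold (default 5 mm). The strict
variant (>) is selectable because both conventions circulate; the two
disagree only at exactly the threshold.

**Calibration** has no default. Sensor pixel spacing varies between
units and a silently assumed value would corrupt every millimeter
output; mm/px must come from the user or config file.

## Phantom generator

The phantom emulates what the pipeline actually consumes: two arches
of teeth with known landmark geometry, not radiographic physics. Teeth
are rounded-corner rectangles (default 120 × 260 px, 4 per arch in an
869 × 1200 frame — the working resolution of the pipeline) placed on a
mild parabolic occlusal curve (amplitude 20 px) with a 60 px
inter-arch gap. Per flank, the CEJ sits 25 px apically from the crown
edge and the ABCL a further *loss*/mm_per_px pixels along the flank;
flanks are vertical, so the Euclidean CEJ–ABCL distance equals the
drawn loss exactly and every site's ground-truth ACH is exact by
construction. Phantom calibration defaults to 0.1 mm/px — an explicit
synthetic choice, not a sensor claim.

Bone loss is drawn per site from a 50/50 mixture of Uniform(2, 4.5)
and Uniform(5.5, 8) mm: it straddles the 5 mm threshold with both
classes equally represented while leaving the (4.5, 5.5) band empty,
so severity is unambiguous unless a boundary case is pinned
explicitly via `bone_loss_mm`. The ABCL mask marks a 2 px disk at each
true crest point; the background gets low-amplitude Gaussian texture.

What the phantom does **not** model: anatomical crown shapes,
interproximal contacts and overlap, radiographic scatter or contrast
variation, correlated detector errors, and anatomically biased false
positives. Passing phantom tests therefore validates the geometry and
bookkeeping of the measurement chain — fusion, partition, fitting,
gating, pairing, calibration, classification — not detector quality on
clinical images.

## Oracle detector

The oracle converts phantom truth into the contract any detector pair
must provide. Per channel (independent sub-seeds — the worst case for
fusion, since duplicates never coincide): each true point is dropped
with probability `dropout_rate`, else jittered by N(0, σ²) per axis
and clipped to the frame; Poisson(`false_positive_rate`) spurious
landmarks fall uniformly over the image with confidence in
[0.1, 0.6); true detections carry confidence 1.0, so the zero-noise
limit reproduces the truth identically on both channels. Optional
erosion roughens the teeth masks; the ABCL point-marks pass through
unchanged (erosion would annihilate 2 px disks). Everything is
deterministic given the seed.

## Evaluation statistics

Accuracy, severe-class sensitivity and specificity are computed pooled
and per image from (gold, predicted) severity pairs joined on
(image, tooth, site); sensitivity/specificity are reported as absent
when the gold standard has no site of the class. Pooled accuracy
equals the site-weighted mean of per-image accuracies by construction.
Display rounding is half-up to integer percent; full precision is kept
in files.

The intraclass correlation uses the two-way, absolute-agreement,
single-measurement form ICC(A,1) (McGraw & Wong): for n subjects
rated on k = 2 occasions,

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)).

Absolute agreement is the right default for intra-rater reliability —
a constant bias between occasions should reduce the coefficient — and
the consistency form ICC(C,1) is selectable where bias should be
ignored. Degenerate inputs (n < 3, zero total variance) raise rather
than returning a conventional value.

## Numerical choices and problem sizes

Polynomial fits use the numpy least-squares path; unit tests verify
agreement with exact rational-arithmetic normal equations to 1e-8
relative tolerance (n ≤ 50, degree ≤ 4). Floats in the measurement
CSV are written to 6 decimals; round-trips are tested at that
precision. The acceptance script uses 20 noiseless and 100 noisy
phantom scenes with two detection occasions each — large enough for
stable error statistics at this geometry while keeping a single-CPU
run in the tens of seconds.

The pipeline's test-retest ICC (same scenes re-detected under
independent noise) reported by the acceptance script is dominated by
rare landmark-substitution outliers — a spurious detection occasionally
wins a side window when both channels drop the true point — which
inflate the error mean square well beyond what the jitter alone would
give. This is a property of the simulated detector noise, not of the
agreement statistic.

## Known limitations

Tooth numbering (and hence true mesial/distal labels), periapical and
panoramic geometries, DICOM handling, and any learned detection are
out of scope. The side-window pairing assumes interproximal landmark
spacing larger than the window (true for the phantom geometry; very
crowded dentitions could alias neighbouring flanks). The gate requires
both arch curves, so an arch with fewer than two distinct landmark
columns yields no measurements for its teeth.
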