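# Methods

## Model and assumptions

The center of tracer distribution (COD) is the per-bin arithmetic mean of
event localization coordinates, one value per axis per 1-s bin, in mm from
the scanner FOV center (x lateral, y anterior-posterior, z
superior-inferior). Bins are half-open `[t, t+Δ)` anchored at scan start;
an event exactly on a boundary belongs to the later bin. Each bin's random
component is Gaussian by the central limit theorem over the events in the
bin, with SD proportional to 1/√(counts); counts decay with the isotope
half-life, so the noise floor grows over the scan. Empty bins are masked,
not zero-filled — a zero would be a fake centroid — and every downstream
residual computation skips masked bins.

Between instantaneous rigid motions the trace is assumed constant up to
noise and slow tracer redistribution. Detection is therefore a
piecewise-constant mean segmentation under a Gaussian L2 cost. Motions that
violate the step assumption (continuous drift, oscillation faster than the
changepoint budget) are not detected as MTPs; they surface either as an
unreachable target error (flagged) or as residual intra-frame variation
caught by the frame-pruning gate.

## Changepoint engines

Two engines compute E_min(n), both exact for what they return:

* **Segment-neighborhood DP** (`engine="dp"`): O(n_max·T²), returns the
  global optimum for *every* n in 0..n_max. Default for traces up to 2000
  unmasked bins. Ties between equal-cost placements are broken toward the
  earlier changepoint index, making results deterministic.
* **PELT penalty sweep** (`engine="pelt"`): PELT solves min E + βn exactly
  (identical to un-pruned optimal partitioning, with pruning); a
  CROPS-style recursive sweep over β collects every solution on the lower
  convex hull of E_min(n). Off-hull n have no penalty that attains them;
  their curve values are filled by linear interpolation and flagged
  `interpolated-not-attained`, and n_tar selection considers attained n
  only (an interpolated value has no realizable MTP set). The segmentation
  feeding the no-motion prediction is the attained n closest above n_max.

Masked bins are compressed out before the prefix sums are built; changepoint
indices are mapped back to the bin grid (an MTP at bin k separates bins k−1
and k). A candidate segment containing no unmasked bin is impossible by
construction on the compressed array.

### Numerical choices

Segment costs use prefix sums of globally mean-centered values (the RSS is
shift-invariant, and centering removes the dominant cancellation term).
Residual cancellation error in a cost is bounded by roughly T·ε·ΣC²; costs
below `4·max(256, T)·ε·ΣC²` are snapped to zero, and single-bin segments
cost exactly zero by definition. Consequently a noise-free
piecewise-constant trace yields E = 0 *exactly* at the true changepoint
count, and the full segmentation (one changepoint per remaining sample)
yields exactly zero error. Reported per-MFF statistics are recomputed with
the two-pass mean-then-deviations formula rather than the prefix-sum
shortcut. In the frame gate, per-bin SDs below 1 nm are treated as zero —
sub-nanometer "variation" is floating-point residue, never motion.

## Self-calibrated target error

The scan is tiled into equal partitions (default 300 s; a shorter trailing
remainder is kept as its own partition — the prediction scales by the
partition's own bin count N_PART,s, so unequal partitions are handled
naturally). Within each partition the P = 2 longest MFFs of the
n_max segmentation estimate the noise-plus-drift error rate:
RSS_NM,s = N_PART,s·ΣRSS_LONG/ΣN_LONG. An MFF extending beyond the
partition contributes its within-partition portion, refit with the
portion's own mean (this reduces to the whole-MFF ratio when one MFF covers
the partition). Partitions with no unmasked bins contribute zero and are
flagged. E_tar = α·E_NM; n_tar is the smallest n with E_min(n) ≤ E_tar
(first crossing of a non-increasing step curve). If even n_max misses the
target, detection returns n_max with a `target_unreachable` warning.

**Bias of the estimator, and the role of α.** On pure i.i.d. Gaussian noise
the estimator is biased low: the n_max segmentation's optimized boundaries
over-fit noise, and selecting the *longest* MFFs preferentially picks
stretches where noise happened to be flat. Measured on synthetic traces,
the recovered fraction of the true noise RSS T·σ² is ≈0.79 at the default
changepoint density (average segment ≈18 bins) and rises to ≈0.94/0.96 at
average segments of ≈70/≈130 bins. This multiplicative gap between
estimated and true no-motion error is precisely what the inflation factor
α ≥ 1 absorbs; α is a per-run configuration value (1.0 FDG-like, 1.6
raclopride-like; 1.6 is an acceptable single choice for both), never
estimated at run time. A visible consequence on the synthetic study
conditions at α = 1.0: E_tar sits below the true noise floor, so n_tar
lands well above the planted step count and many 1-bin noise splits appear
among the MTPs. These cost scan time (shorter frames) but no correctness —
detectability of real steps is unaffected, and the pooled 2-mm
detectability stays at 100% on the default conditions.

## Frame pruning

An MFF is discarded when, on any axis, its within-frame COD SD (√(RSS/N),
unmasked bins) strictly exceeds twice the predicted no-motion SD
√(RSS_NM,s/N_PART,s) of its host partition; an MFF spanning partitions uses
the unmasked-count-weighted average of the spanned partitions' predictions.
The any-axis (OR) trigger reflects that motion on one axis suffices to
corrupt a frame. MFFs with fewer than two unmasked bins have no SD and pass
this rule; the count rule governs them. The count rule then re-flags kept
frames whose summed counts fall below a threshold (2 million true
coincidences for real scanner data; configurable and scaled down for
synthetic work). Statuses are final in that order, so a frame failing both
reports intra-frame motion.

## Synthetic data

The trace-level generator emulates the statistics that matter to the
detector: per-axis Gaussian noise with σ(t) = σ₀·2^(t/2T½) (σ₀ default
0.5 mm — chosen to visually match published raw COD traces — with the F-18
half-life 109.77 min), smooth mono-exponential settling drift (≤1 mm over
the scan, time constant duration/4.5), and planted instantaneous rigid
steps. Default study conditions: 90-min scans, 1-s bins, ten steps at
random seconds (≥30 s apart, ≥60 s from the scan edges — subjects do not
move twice within a second), isotropic random directions, amplitudes
uniform in 2–8 mm. Step amplitude is quoted as the mean displacement of the
eight vertices of a 10-cm cube centered in the FOV, which equals the
translation norm for pure translations and therefore coincides with the
ground-truth per-second displacement metric used for thresholds.

The event-level generator samples annihilation points from Gaussian
activity blobs under an inhomogeneous Poisson process with half-life decay,
moves them with the rigid schedule, and localizes each event by a TOF blur
along a random LOR direction (FWHM_mm = c·FWHM_ps/2, 580 ps ≈ 87 mm) or by
the midpoint of the chord through the bore cylinder (non-TOF), with limited
axial acceptance. Attenuation, scatter, randoms, detector normalization and
reconstruction are deliberately not modeled. What passing tests therefore
show is that the detector meets its claims when its statistical assumptions
hold; real scanner traces add autocorrelated tracer kinetics, count-rate
dips and localization artifacts that only the tracer-drift term gestures
at, so α calibration on real data remains the user's responsibility.

## Evaluation conventions

Ground-truth MTPs: the head location series (mean of reference-point
positions, natively 20 Hz) is resampled to 1 Hz by 20-sample averaging;
a second with displacement Δl_t above the threshold registers an MTP at the
second where the new position first holds. Matching is one-to-one greedy
nearest within ±1 s (ties toward earlier truth times); one detection
validates at most one truth MTP, so a detection burst cannot claim a single
truth point repeatedly. Detectability is the pooled matched fraction across
studies (undefined for empty truth); the false-positive rate is the
unmatched fraction of detections (zero for empty detection sets) — its
denominator is the detection count, a documented convention. The MDE
averages Euclidean distances between truth-moved and estimate-moved ROI
centers, over ROIs first and then over the 1-s sample grid.

## Problem sizes used in the checks

The bundled checks run at desk scale by design: detectability uses 50
simulated 90-min studies with the penalty-sweep engine; engine-equivalence
oracles enumerate exhaustively at ≤25 bins and n ≤ 4 and compare PELT to
un-pruned optimal partitioning at ≤500 bins; the no-motion calibration uses
200 replicates of 15-min traces in the long-MFF regime (n_max = 12,
average segment ≈70 bins) where the estimator's selection bias is within
the 10% band — at the full detection density the bias is ≈21% and is
absorbed by α, as described above.

## Known limitations

* Continuous (non-step) motion violates the piecewise-constant model;
  slow drift is absorbed into E_NM rather than detected.
* The per-axis-then-union design cannot pool sub-threshold evidence spread
  across axes; a joint multivariate cost is out of scope by design.
* MTPs live on the 1-s bin grid; sub-second motion timing is not resolved,
  and the union does not merge MTPs 1 s apart on different axes.
* On noise whose variance the estimator under-predicts (see above), α = 1.0
  over-segments; users preferring longer frames should raise α.
* The event simulator's non-TOF chord midpoints use an infinite cylinder
  and uniform azimuth — adequate for the qualitative TOF/non-TOF contrast,
  not for scanner-specific sensitivity patterns.
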