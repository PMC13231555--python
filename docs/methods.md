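# Methods

This note records the models, conventions and numerical choices behind
`vesselrad`, and what the synthetic validation does and does not show.

## Geometry and coordinate conventions

A mask is a 3-D label grid (0 background, 1 artery, 2 vein) with strictly
positive per-axis spacing in mm. Voxel indices are 0-based and world
position = origin + index × spacing. Direction cosines are not modelled:
radii and volumes are purely metric, so orientation cannot affect them;
volumes with non-identity orientation are accepted with a warning and
processed in index/spacing space. A plain binary mask is treated as
all-artery unless the caller remaps labels.

## Distance transform and its bias

The EDT assigns each foreground voxel its distance to the nearest
*background voxel center* (scipy's anisotropic-sampling transform). This
center-to-center convention overestimates the radius of a continuous tube
by up to half a voxel: on a 1 mm grid a 4 mm cylinder's axis voxel sees
its nearest background center at √17 ≈ 4.123 mm. The optional
`edge_correction` flag subtracts half the mean spacing; it is **off by
default** because the correction is only appropriate for tubes several
voxels wide. For thin branches (radius ≲ 2 voxels) skeleton-position
quantization already biases centerline radii slightly *low*, and
subtracting another half voxel overshoots — we measured a −20% to −25%
median error on 0.9–1.3 mm-radius branches with the correction on,
versus −4% to −5% with it off. Document-and-default-off is therefore the
safer policy; the bias is visible and bounded rather than silently
half-corrected.

## Centerline extraction

Skeletonization is topology-preserving 3-D thinning (scikit-image) on the
26-connected foreground of one compartment. The thinning operates on the
index grid and is spacing-agnostic; for the moderately anisotropic grids
of thoracic CT this displaces the skeleton by less than a voxel, which
the propagation constraint absorbs. Every skeleton voxel receives
radius = EDT at that voxel, exactly (asserted in tests). Any 26-connected
component that thinning would leave without a skeleton voxel — isolated
voxels in particular — contributes its maximal-EDT voxel instead, so
every component can be propagated.

## Radius propagation

For a non-centerline foreground voxel v, candidates are centerline points
c with ‖v − c‖ < r(c), *strictly*: v must lie inside the maximal
inscribed sphere at c. The closest candidate donates its radius
(provenance `constrained`). If no sphere reaches v — possible near sharp
bends, caps and junction shadows — the globally nearest centerline point
is used and the voxel is flagged `fallback`, so validation can bound the
fraction (≤ 5% on a 90° bent tube; ~2% on straight cylinders). Leaving
such voxels unassigned would break the coverage invariant that every
foreground voxel carries exactly one radius.

Ties at equal distance prefer the larger radius (the physiologically
conservative choice at junctions, where a voxel shared by parent and
child belongs to the parent), then the lexicographically smallest
centerline voxel index. With this total order the KD-tree-accelerated
implementation is *bit-identical* to an exhaustive (voxel ×
centerline-point) scan: the tree only shortlists donors, and the final
selection recomputes exact squared distances with the same floating-point
expression in both code paths. The shortlist is provably sufficient — the
k-th neighbor distance must strictly exceed the best candidate distance
(with a 1e-9 relative guard) or the radius maximum before the search
stops — so acceleration never changes a result, only its cost.

Arteries and veins are skeletonized and propagated independently; an
arterial voxel never inherits a venous radius.

Provenance is exported as uint8 {0 background, 1 centerline,
2 constrained, 3 fallback}; a dense volume needs the background code, so
the three assignment classes are shifted up by one.

## Diameter bins and volumes

Per-voxel diameter d = 2r falls into (0.8, 1.6], (1.6, 2.4], (2.4, 3.2],
(3.2, 4.0] or (4.0, ∞) mm — strict lower, inclusive upper — with
d ≤ 0.8 mm kept in a separately reported sub-threshold bin, reflecting
0.8 mm as the minimum diameter CT can reliably resolve. Sub-threshold
voxels are excluded from the headline TIPVV/IPVVa/IPVVv totals by
default (`include_subthreshold` reverses this, keeping the choice
auditable). Volumes are voxel-count based — the mask includes wall plus
lumen — and all volumes derive from integer bin counts, so conservation
(Σ bin counts = foreground count, per compartment) is exact by
construction; TIPVV is computed as IPVVa + IPVVv so additivity is an
identity. A lung-ROI mask, when supplied, is intersected before counting;
this is how hilar vessels are excluded, since no algorithmic hilum
definition exists at the mask level. BSA normalization divides every
volume by the DuBois area W^0.425·H^0.725·0.007184 and commutes with
summation. Display label volumes use red for 0.8 < d ≤ 3.2 mm
(subsegmental vessels), yellow for 3.2 < d ≤ 4.0, blue for d > 4.0, with
the same inclusive-upper rule.

## Phantoms

Tubes are rasterized by the voxel-center-in-tube rule, matching the
binary character of segmentation masks; there is no partial-volume
modelling, so phantom validation says nothing about sub-voxel surface
effects. Free segment ends are capped flat — a lone segment is a true
cylinder whose discrete volume converges to πr²L, and a depth-0 tree
degenerates exactly to a cylinder — while ends meeting another segment
keep rounded (capsule) caps so junctions are filled. Tree ground truth
assigns each voxel the radius of the nearest generating segment, ties to
the larger (parent) radius, mirroring the propagation tie-break. Sub-voxel
tubes (radius < max spacing) are rejected, as is any branching depth whose
leaf radius would fall below that limit.

**Cap artifact and phantom aspect ratio.** Near a flat cap the EDT sees
the end plane, so a rim annulus about one voxel thick and ~0.75 r deep at
each cap legitimately receives radii below the nominal r; interior voxels
recover essentially perfectly at every radius and spacing we test. The
artifact's volume fraction scales like r/L, so recovery phantoms use
length = 30 × radius: across r ∈ {2, 4, 6} mm on 1 mm and 0.5 mm
isotropic and (0.6, 0.6, 1.0) mm anisotropic grids, 95.3–100% of voxels
land within 15% of truth and the median bias stays inside the half-voxel
band. Real vessels end by tapering or at organ boundaries, not at free
flat caps, so the cap region is a phantom artifact, not a property the
algorithm is expected to handle.

## Cohort simulator

Per-subject, per-bin volumes are drawn from log-normal distributions —
the natural choice for positive, right-skewed volume data summarized as
median (IQR) — with σ = ln(Q3/Q1)/(2·0.6745) per bin; control-group
medians and IQRs follow the values in `phantom.COHORT_BASELINE`
(≈ 4–18 mL·m⁻² per bin). Demographics (height, weight, age, sex mix) are
drawn per group from truncated normals around typical adult values, and
BSA is computed, not drawn. The `effect` parameter multiplies patient-bin
medians; 1.0 (the default) makes the groups exchangeable, which is the
null configuration used for calibration. Totals are sums of bins, so
IPVVa + IPVVv = TIPVV holds in the simulated tables by construction. The
simulator emulates the *distributional shape* of cohort measurements, not
their anatomical origin: bins are drawn independently (no inter-bin
correlation), volumes are independent of the demographics, and no
scanner/segmentation noise is modelled, so passing statistics tests shows
calibration and power of the workflow, not clinical validity.

## Statistics

Normality is gated per group by Shapiro–Wilk at α = 0.05 (the
conventional test at cohort sizes of tens to hundreds); both groups
normal → two-sample t (pooled if Levene accepts equal variances, Welch
otherwise) with mean ± sd summaries, else Mann–Whitney U with
median (Q1, Q3) summaries. The U test is an exact full enumeration over
all C(n+m, n) rank splits (midranks for ties; two-sided by deviation of U
from nm/2) when both groups have n ≤ 8, and otherwise the tie-corrected
normal approximation with the standardized Z reported; the continuity
correction is off by default, with a flag. Calibration on null simulated
cohorts (n = 50/group) gives an empirical type-I rate of 0.053 ± 0.003
over 5000 replicates — nominal within Monte-Carlo error. The adjusted
analysis is OLS of a volume outcome on group (patient = 1), age, sex
(female = 1) and BSA with HC3 robust standard errors by default (HC0–HC3
and classical selectable); rank-deficient designs are rejected with the
collinear columns named. No multiple-testing adjustment is applied, and
reports footnote this.

## Degenerate inputs and edge cases

Empty masks are legal everywhere (empty distance maps, centerlines and
reports, not errors); an all-foreground mask has no boundary and is
rejected; a non-empty mask with an empty centerline cannot be propagated
and raises. Equal-valued groups give p = 1; groups smaller than 2 are
rejected. All randomness flows through explicit integer seeds, and fixed
seeds give bit-identical phantoms, radius fields, cohort tables and
reports across runs.

## Known limitations

* Radii are EDT-based maximal-inscribed-sphere estimates; no sub-voxel
  surface modelling, mesh fitting or vessel-tracking graph extraction.
* Skeletonization ignores anisotropy; strongly anisotropic grids (ratio
  well beyond the ~1.7 tested) may displace centerlines.
* The hilum can only be excluded via a caller-supplied ROI mask.
* Lobar decomposition, %CSA-style planar metrics, and any clinical
  interpretation of cohort differences are out of scope.
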