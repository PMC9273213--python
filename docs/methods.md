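# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitoloc`, and what the synthetic validation does and does not show
about real data.

## Measurement model

The mislocalization metric is the plain Pearson correlation coefficient
(PCC) between the reporter and mitochondrial channels, computed pixel-wise
per cell over the pseudo-cell mask minus the nucleus. No Costes-style
thresholding or Manders variant is applied: every pixel of the measurement
region enters the correlation. Both channels are preprocessed identically
(average z-projection first, then background correction), and the PCC is
computed on those corrected intensities. An undefined correlation (a
constant channel within the region) yields an exclusion flag rather than a
value of 0, because imputing 0 would bias condition means. All exclusions
(`too_few_pixels`, `zero_variance`, `no_mito_mask`, `not_transfected`)
travel with the per-cell records into the output CSV.

The projection is always an average, never a maximum. Projection happens
before background correction; the reverse order would require correcting
every z-plane separately for no measurable benefit at the flat z-profiles
this pipeline targets.

## Segmentation

**Nuclei.** Global threshold (Otsu by default, fixed value selectable),
hole filling, area filter (default 120–6000 px for ~9–14 px nucleus radii),
optional distance-transform watershed declumping (off by default; the
synthetic nuclei never touch). A blank image yields zero labels, not an
error.

**Cell bodies by seeded propagation.** Each foreground pixel of the
guidance channel is assigned to the nucleus seed with the smallest
accumulated cost along 8-connected paths, one step from p to q costing
`|I(p) − I(q)| + λ·steplength` on the min–max-normalized guidance image.
λ (default 0.05) trades image-geodesic growth against plain Euclidean
growth; at λ→∞ the partition tends to a Voronoi diagram, at λ=0 it follows
intensity ridges only. The implementation runs one multi-source Dijkstra
per seed (scipy's sparse-graph engine) and takes the per-pixel argmin, so
ties resolve deterministically toward the lower seed label. Distances use
chamfer steps (1, √2), the standard raster approximation of Euclidean path
length.

The guidance channel defaults to the mitochondrial stain — the only
broadly cytoplasmic signal in this channel set — Gaussian-smoothed with
sigma 8 px before thresholding. The smoothing is essential: the raw stain
is a sparse filament network, and propagation over its raw threshold would
label only filament pixels rather than cell bodies. The foreground cut is
a scaled Otsu threshold (scale 0.5) on the smoothed image; both the sigma
and the scale sit in `SegmentationParams` and should shrink proportionally
for cells much smaller than the ~40 px default radius.

**Transfection gate.** Integrated (summed) marker intensity per cell,
compared against a manually chosen threshold. The gate deliberately has no
default value — it is an explicit, manual analysis choice. For the default
synthetic cells, 3e5 sits between the untransfected noise-residual mode
(~1.5e5 at the top) and the transfected expression mode (≥ ~5e5);
`suggest_marker_threshold` (Otsu on log integrated intensities) and
`marker_intensity_histogram` help locate such a valley on other data.
Raising the gate can only remove cells, never add them.

**Pseudo-cell mask.** Within each gated cell, the thresholded mitochondrial
signal is binary-closed (disk, default radius 10 px — enough to bridge
inter-filament gaps wider than the 3 px filament width) and hole-filled,
then restricted to its parent propagated mask. Closing uses zero-padded
binary morphology, so the mask never spills beyond the dilation envelope.
A cell with no mitochondrial foreground is flagged `no_mito_mask` and
excluded; the run continues.

The nucleus subtracted from the measurement region is the raw nucleus
mask; `nucleus_dilation_px` (default 0) dilates it for users who prefer a
safety margin around the nuclear rim.

## Statistics

Condition summaries are the mean and SEM (sample standard deviation over
√n; undefined for n=1) of per-cell PCCs over non-excluded records only.

The Mann-Whitney U statistic is #{(i,j): aᵢ > bⱼ} + ½·#ties, computed from
average ranks. For tie-free samples with nₐ+n_b ≤ 16 the two-sided p-value
is exact: the full null distribution of U is built by the standard
dynamic-programming recurrence over rank subsets, and p = min(1, 2·P(U ≤
min(u, nₐn_b − u))). Otherwise a normal approximation with tie-corrected
variance and a 0.5 continuity correction is used; when the tie-corrected
variance is zero (indistinguishable groups) p is 1. Two-sided tests were
chosen throughout, and no multiple-testing correction is applied across
condition pairs — pairwise tests are reported individually.

The expression–mislocalization association is a Spearman rank correlation
between integrated marker intensity and per-cell PCC (Pearson selectable),
with the t-approximation p-value flagged as approximate below n = 10.
Spearman was chosen because transient-transfection expression is strongly
right-skewed; the rank statistic is invariant under any monotone rescaling
of either variable.

## Synthetic scene generator

The generator emulates the four-channel live-cell assay with explicit
per-cell ground truth. Defaults define the study scale: 512×512 px fields
(EMCCD-style geometry), 15 fields per condition, 3–4 cells per field
(uniform), giving ~50 cells per condition.

Per cell: an elliptical body (radius 34–46 px, axis ratio 0.8–0.95), a
disk nucleus (radius 9–14 px, small random offset, strictly inside the
cell), a mitochondrial network of 7 persistent random-walk filaments of 70
steps dilated to 3 px width and confined to the cytoplasm, and a compact
perinuclear Golgi arc (120° span, 7 px thick, 4 px off the nuclear rim).
Cells are placed by rejection sampling with a 3 px exclusion margin; a
crowded field raises a structured placement error naming the field. The
Golgi mask is carved disjoint from the mitochondrial mask so that the
reporter photon mass partitions exactly.

The reporter channel places fraction θ (`misloc_fraction`) of each cell's
photon mass (default 2.5e5 counts) uniformly on its mitochondrial mask and
1−θ on its Golgi mask. θ is the single generative knob for
mislocalization: θ=0 gives disjoint reporter/mitochondria supports and a
negative per-cell PCC, θ=1 gives pixel-wise proportional channels and PCC
1, and the condition mean rises strictly monotonically in between — which
is what makes parameter recovery testable. Optionally θ follows expression
monotonically (`theta_coupling=(lo, hi)` maps the lognormal expression CDF
into [lo, hi]), emulating dominant-negative dose dependence.

Marker expression is lognormal (μ=5.7, σ=0.6 in log-counts, i.e. a median
of ~300 counts/px) for transfected cells (probability 0.75) and exactly 0
for the untransfected subpopulation, reproducing the wide, skewed,
bimodal integrated-intensity histogram the manual gate relies on. Nuclei
and mitochondria render at 400 and 500 counts/px. All channels share one
background plane, offset 30 with gentle x/y tilts (8, 5 counts across the
field); per-channel planes were omitted as they add configuration surface
without changing any testable property. Poisson shot noise is applied to
the expectation image, then Gaussian read noise (sd 3), then clipping at
zero. Acquisition parameters with no stated real-world counterpart
(photon-count scaling, z-depth) are invented defaults; z-stacks are
rendered as independent noisy realizations of the same plane, with no
defocus model.

Determinism: field i of a condition uses an RNG derived from
`SeedSequence(entropy=seed, spawn_key=(i,))`; identical parameters give
byte-identical arrays. In a pipeline run, all per-condition seeds derive
from the single config seed.

**What the synthetic validation does not show.** The generator has flat
intensity profiles within organelle masks, no point-spread function, no
cell-to-cell contact, no out-of-focus light, no photobleaching and no
spectral bleed-through. Passing its tests demonstrates that the
measurement chain is correct and well-calibrated — not that segmentation
parameters tuned here transfer to any particular microscope; on real data
the gate threshold, guidance smoothing and closing radius must be chosen
against the images at hand.

## Numerical choices and degenerate inputs

- PCC in float64 via centered dot products; affine invariance, symmetry
  and the [−1, 1] range hold to 1e−12 and are asserted in tests.
- Background polynomial fit: coordinates normalized to [−1, 1],
  least squares on below-median pixels (subsampled above 20k pixels),
  order capped at 3. The opening method rejects structuring elements
  larger than the image. Corrected images are clipped at 0.
- Otsu thresholds fall back to "no signal" (empty masks) for contrast-free
  images instead of erroring.
- Tie-breaks: propagation ties go to the lower seed label; recovery
  matching is greedy by descending IoU with one-to-one assignment.
- Validation sizes: tests run the default 512×512 scale where the property
  being checked concerns the study conditions (recovery, monotonicity,
  contrast), and 128–160 px scenes for replicate-heavy calibration (200
  null comparisons) and unit-level checks.

## Known limitations

- Propagated cell masks over-extend by roughly the guidance smoothing
  radius; IoU against truth is ~0.55–0.75, comfortably above the 0.5
  matching criterion but not boundary-accurate. Boundary-accurate
  segmentation is out of scope.
- The exact Mann-Whitney path is limited to 16 combined observations;
  beyond that the continuity-corrected normal approximation is slightly
  conservative (measured null rejection ~0.045 at α=0.05 with 15 cells per
  group).
- Field-level nesting is ignored: per-cell PCCs are treated as independent
  across fields of a condition, which matches the generator (cells are
  independent) but understates uncertainty if real fields share focus or
  staining artifacts. Mixed-effects modeling is a non-goal.
- TIFF I/O covers single-file multi-channel stacks and per-channel files
  with a JSON description tag; OME-XML metadata is not parsed.
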