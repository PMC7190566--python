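# Methods

## Stain model and color deconvolution

Brightfield H-DAB imagery is modeled by the Beer–Lambert law. A pixel with
hematoxylin concentration `c_H` and DAB concentration `c_D` transmits, per RGB
channel `c`,

    I_c = I0_c · 10^−(c_H · M_H,c + c_D · M_D,c) + ε_noise,

where `M_H`, `M_D` are unit optical-density absorption vectors and `I0` the
blank-slide intensity (default 255 per channel). The defaults are the standard
published H-DAB vectors (hematoxylin ≈ (0.65, 0.70, 0.29), DAB ≈ (0.27, 0.57,
0.78), normalized); both are configurable since scanner/stain combinations
vary.

Deconvolution inverts this model: `OD = −log10((I + ε)/I0)` clipped below at
0, followed by a per-pixel least-squares projection of the OD 3-vector onto
the two stain vectors (the residual direction is discarded; negative
concentrations are clipped to 0). `ε` guards `log(0)` on quantized counts: it
defaults to 1 for integer-dtype tiles and 0 for floating-point tiles, which
keeps the transform an exact inverse of the forward model on synthetic data.
With two exactly known stain vectors the unmixing is exact to numerical
precision; on real slides the vectors are only approximate and the recovered
concentrations are correspondingly biased — the round-trip tests certify the
algebra, not stain-vector estimation.

## Candidate detection

- **DAB threshold** (default 0.15 OD concentration units): the original
  selection procedure does not publish its threshold, and whether it was
  applied in OD or RGB space is unknown. A fixed concentration threshold is
  the reproducible default; an Otsu helper is provided for data-driven use.
  On the synthetic tiles any threshold between the background leakage (~0)
  and the minimum object DAB (0.4) gives identical results, so the tests pin
  the convention, not a tuned value.
- **Grouping**: connected components under 8-connectivity (the more inclusive
  convention for few-pixel objects). Object ids are assigned in raster order
  of each component's first pixel, making labeling deterministic.
- **Morphological closing** (physical disc radius, default 0 = off): exposed
  because gap-bridging is a common post-processing step, but disabled by
  default as no such step is described for the original algorithm.
- **Area filter**: 25 ≤ area ≤ 5000 µm², inclusive on both ends ("between 25
  and 5000" is read inclusively; the tests fix the convention). Area is
  pixel count × pixel-size², with the study's 0.24 µm pixel pitch as default.
- **Coordinates**: 0-based pixel indices; µm frame with origin at the tile's
  top-left pixel corner, x along columns; pixel centers at half-integer
  offsets. Centroids are unweighted binary-mask centroids ("center of mass"
  of the object mask, not intensity-weighted).

## Synthetic tiles

Objects are rendered as rotated ellipses with uniform DAB concentration per
object. To control area to sub-pixel accuracy, pixels are ranked by
elliptical radius and exactly `round(area/pixel_area)` innermost pixels are
kept, so ground-truth area ≡ pixel count × pixel area by construction.
Placement is rejection sampling (default 1000 tries) with a 2-px clearance so
planted objects remain disjoint 8-connected components; larger classes are
placed first to keep rejection tractable. Default scene (per 1536² px ≈ 369 ×
369 µm tile): 3 artifacts (5–20 µm²), 8 buds (30–900 µm²), 2 PDC-scale
objects (1100–4500 µm²), 1 oversize cluster (5500–6500 µm²), DAB drawn
uniformly from 0.5–1.2, hematoxylin counterstain 0.3 everywhere, Gaussian
camera noise with sd 2 counts added in transmitted-intensity space after the
forward model and clipped to [0, I0] (noise-free variants set `noise_sd=0`).

What the simulator does **not** model: nuclei (the "visible nucleus"
criterion exists only as a latent class in the rating simulator, not as an
image feature), tissue texture, inflammation, staining gradients, H&E
appearance, or the morphology of pseudo-bud debris. Passing detection tests
therefore certify the deconvolution/segmentation/measurement chain under the
stated model, not detector performance on clinical slides.

## Rating panels and consensus

Each synthetic panel draws a latent class per object from a prevalence vector
(default 0.5/0.1/0.4 for TB/PDC/NEITHER, rounded from the observed
study-level marginals) and passes it through a per-rater 3×3 row-stochastic
confusion matrix (default symmetric with 15 % off-diagonal mass; identity and
uniform matrices are provided for the calibration extremes). Panels are
complete — every rater scores every object — matching the study design of a
constant 7 (IHC) or 11 (H&E) scores per object; incomplete panels are
rejected rather than imputed. Panels with per-rater object subsets (NaN
cells) are supported as long as the per-object rating count is constant.

The consensus threshold is the smallest integer `t` with `t/n ≥ fraction`
(default 0.7), reproducing 5-of-7 and 8-of-11. Fractions ≤ 0.5 are rejected:
for any fraction > 0.5 at most one class can reach the threshold (pigeonhole),
so fused labels are unique — verified exhaustively for all vote triples up to
n = 12. Summary tables count objects per tier (uniform / 70 % majority /
no-agreement) and class. Per-rater count summaries use the sample (n−1)
standard deviation (the usual convention for small observer groups; the
population variant is not exposed because nothing downstream consumes it);
single-rater groups report sd 0 with a degeneracy flag.

## Agreement statistics

Fleiss kappa uses the classical count-matrix formula; Cohen kappa the
two-rater contingency form with marginal chance agreement; both are
implemented directly in-package so their degenerate-case semantics are fixed,
and are cross-checked in the tests against independent brute-force oracles
and against `statsmodels.stats.inter_rater`. Conventions:

- A panel in which every object is unanimous (including single-class panels)
  returns κ = 1 exactly, short-circuiting the vanishing denominator; the
  statistic is uninformative there and flagged as such by construction.
- Pairwise Cohen kappas are computed on the objects both raters scored; rater
  pairs with no shared objects are reported as undefined (NaN), not 0 —
  absence of data is not agreement.
- Landis–Koch bands use upper-inclusive intervals: poor (−∞, 0.20], fair
  (0.20, 0.40], moderate (0.40, 0.60], good (0.60, 0.80], very good
  (0.80, 1]. The published band list is ambiguous at 0.40; this choice is
  consistent with group kappas of 0.42 and 0.51 being read as moderate.
- No confidence intervals or weighted kappa (nominal 3-class data only).

The study's own kappa values cannot be recomputed because the raw
per-observer ratings were never published; the package instead verifies
parameter recovery on synthetic panels (identity confusions → κ = 1 exactly;
uniform confusions → |κ| < 0.05 at 10⁴ objects across 20 seeds).

## Sampling, patches, coordinate transfer

Stratified sampling is uniform without replacement within area strata; the
boundary value 1000 µm² is assigned to the large stratum (the source phrasing
"<1000" / ">1000" leaves it unassigned; one convention must be fixed and
tested). Group splitting is a uniform random partition into exact sizes.
Both are pure bookkeeping: outputs are subsets/partitions of the input,
reproducible per seed.

Review patches default to 256 µm squares (1067 px at 0.24 µm) centered on the
candidate CoM, padded with background intensity at tile edges, with a 2-px
open marker outline of area 0.03 mm². The patch-side figures 256 µm and
0.25 mm both appear in the source and are treated as the same quantity; the
0.03 mm² marker (side ≈ 173 µm, most of the patch) is reproduced as stated —
both are configuration defaults, flagged here rather than resolved.

Coordinate transfer to a co-registered restained image applies a supplied
2×3 affine (µm → µm) to the centroid only; areas and pixel data are carried
unchanged. No image registration is performed — the restaining protocol keeps
the section in place, and registration fidelity is the caller's
responsibility.

## Pipeline and problem sizes

`run_pipeline` composes file-backed stages (simulate → detect → sample →
patches → panel → consensus → agreement) under a single master seed from
which per-stage streams are spawned, making every tabular output byte-stable
across reruns. Stage errors surface with the stage name and leave a
`FAILED_<stage>` marker beside the partial outputs.

Test and acceptance workloads use study-scale panels (3000 × 7, 150 × 11,
10⁴-object calibration panels) but reduced imaging scenes — 1536² px tiles
(≈ 0.136 mm², versus 0.785 mm² clinical hotspots) and tens of objects — since
detection fidelity is resolution-dependent, not field-size-dependent. The
end-to-end pipeline demonstrations sample tens of candidates rather than
2200; the sampling counts themselves are exercised at full scale on synthetic
pools.

## Known limitations

- Stain vectors are assumed known; no vector estimation from data.
- The simulator's uniform per-object DAB and elliptical shapes make
  segmentation essentially noiseless at the default threshold; threshold
  sensitivity on real slides is untested and untestable here.
- Rater confusion matrices are object-independent (no difficulty structure,
  no size-dependent confusion), so synthetic kappas calibrate the statistics,
  not pathologist behavior.
- Whole-slide pyramid I/O, hotspot detection and any nucleus-based rules are
  out of scope; hotspots enter only as ROI rectangles.
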