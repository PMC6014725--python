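# Methods

## The model

The package treats a stretch of basal dendrite as a cylinder of radius
*R* (default 0.35 µm) along the x axis, with the optical axis along z.
Each spine is a cylindrical neck plus a spherical head, attached at
position *x* and azimuth φ in the y–z plane (φ = 0 points along the
optical axis, φ = π/2 lies in the focal plane). "Length" is the
shaft-surface-to-tip distance, so the tip sits at radius *R + L*. Head
volume uses the spherical convention V = (π/6)·d³ₘₐₓ; the generative
"mean head diameter" equals dₘₐₓ because the head is a sphere. Azimuths
are uniform on [0, 2π) — this is the core assumption behind the
blind-zone extrapolation and is made explicit rather than left implicit.

### Morphology distributions

All morphological features are lognormal. Defaults (median, log-sd):
head diameter 0.36 µm, 0.45 (median volume ≈ 0.024 µm³); neck diameter
0.15 µm, 0.30, clipped to never exceed the head; length 1.0 µm, 0.35.
These place the population at the scale reported for hippocampal basal
dendrites (median head volumes 0.02–0.03 µm³, neck widths around
150 nm). Neck and length distributions are plausibility choices — the
source measurements report only medians and interquartile ranges for a
three-feature subset — and are isolated in `MorphParams` so they can be
swapped without touching any analysis code.

### Turnover

Between sessions each spine survives independently with probability
s(V) = 1/(1+exp(−(loss_a + loss_b·log₁₀V))); new spines arrive as a
Poisson process along the dendrite with small-biased head sizes
(lognormal median 0.30 µm). Defaults loss_a = 4.884, loss_b = 2.0 were
calibrated once, numerically, so that the mean per-interval loss under
the default morphology is 21 %, and gain_rate = 0.60 µm⁻¹ holds density
stationary over a three-session series at ~3 spines/µm true density.
loss_b > 0 encodes that large spines are more stable, which is what
makes persistent spines larger than transient ones downstream. A lost
identity never returns; a spine reappearing at an old position is a new
spine. Positional jitter between sessions defaults to zero so the
500 nm matching gate is exercised only in explicit scenarios.

## The imaging forward model

The PSF is a separable anisotropic Gaussian. Scenes are rasterized at
4× (xy) / 2× (z) supersampling, convolved, block-summed onto the voxel
grid (conserving total emission), and optionally given Poisson photon
noise over a constant background. Two deliberate choices:

- **Gaussian PSF, Lorentzian readout.** Measured profiles are fitted
  with Lorentzians, following the field's convention for STED line
  profiles; the forward model stays Gaussian. The best-fit Lorentzian of
  a Gaussian-like profile reads a few percent *below* the Gaussian FWHM
  (and depends mildly on the fit window, which is fixed at ±3 lateral
  FWHM for beads). The preset PSF widths are therefore calibrated so the
  *bead-readout* lands on the standard values: PSF 53.85 nm → a 40 nm
  bead fits at 54 nm (STED), PSF 354.2 nm → 325 nm (2P). Axial FWHMs
  (600/1200 nm) are representative and configurable.
- **Exact z-antialiasing.** The z step (250 nm supersampled) is much
  coarser than a 40 nm bead or a 150 nm neck, so binary center-sampling
  would drop such structures entirely. Instead each primitive's occupied
  fraction of every z slab is computed in closed form (sphere, shaft
  cylinder, and radial neck cylinder all reduce to interval overlaps in
  z), making total emission exact in z while x and y stay center-sampled
  at 5–10 nm. Rasterization is additive, so rendering is linear over
  disjoint structures.

Bead fields place all beads in one focal plane with ≥ 4 lateral FWHM
separation, mirroring nanosphere calibration slides; bead images use
10 nm pixels (STED) and 40 nm pixels (2P), both comfortably past
Nyquist for their PSFs.

## The geometric observer

Counting operates on ground-truth geometry, not on segmented pixels:
the published counting rules are geometric ("protrudes laterally by
more than 200 nm", "closely clustered spines appear merged"), and
applying them as explicit geometry makes the detection model auditable
and lets every observer property be tested exactly. Rendered stacks
remain available for visual validation and all FWHM work.

Rule 1 (protrusion): detected iff e = (R+L)·|sin φ| − R ≥ d_min, with
d_min = 200 nm. Undetected spines are labelled `masked_axial`
(|sin φ| < 0.5) or `below_threshold` — a cosmetic split mirroring the
two described failure modes; both count as undetected. The projected
(not 3-D) protrusion is used, consistent with the blind-zone concept.

Rule 2 (merging): provisionally detected spines on the same side of the
shaft merge when |Δx| < the mode's lateral resolution (54 nm STED,
325 nm 2P) — a Rayleigh-like criterion — under transitive closure. The
representative is the largest head (ties: smaller x); the reported
position is the head-volume-weighted mean. With the default density the
two rules yield ~30–36 % more STED-observed than 2P-observed spines,
the mechanism behind the detection gap.

## Blind zone and density correction

With uniform azimuths the hidden fraction is
f = (2/π)·arcsin(min(1, (R+d_min)/(R+L))), clamped to [0,1], and the
corrected density is measured/(1−f). Defaults R = 0.35 µm, L = 1.0 µm,
d_min = 0.2 µm give f ≈ 0.267 and reproduce the in vivo correction
2.13 → 2.91 µm⁻¹; these are calibrated, anatomically plausible values,
not derived ones. PSF blur is *not* added to the silhouette by default;
an optional variant adds lateral_fwhm/2 inside the arcsin. For length
distributions, `hidden_fraction_lognormal` averages f over quantile
nodes of the length law; using the scalar f(mean length) instead
introduces a small bias, which is why the recovery tolerance is 5 % at
fixed lengths and 8 % at lognormal lengths. Merging is disabled in the
recovery experiment so that it isolates the blind-zone effect. The
analogous fixed-tissue correction (2.68 → 3.15 µm⁻¹) is out of scope:
its implied model parameters differ from the in vivo case and are not
recoverable.

## Turnover statistics

Matching between consecutive sessions is greedy nearest-neighbour on
observed positions under a 500 nm gate (ties: smaller distance, then
smaller position), mirroring chronological manual scoring. Greedy
matching is maximal — never below half the optimal assignment and in
randomized tests equal to it in > 90 % of instances; chain
configurations where it falls one short are accepted as part of the
emulated procedure. When ground-truth identities are available the
matcher is bypassed and ids are intersected directly.

Denominators: the "total number of spines N(t)" is ambiguous for
losses, since the spines lost "on day t" are no longer present at t.
F_lost uses the earlier session's count and F_new the current one; this
keeps both well-defined and makes 100 − F_lost(day 2) line up with the
day-2 survival fraction. Survival requires continuous presence.
The dendrite is the unit of analysis; aggregation is mean ± sem
(ddof = 1), with sem undefined (NaN, warned) for a single dendrite.

## Morphometry and clustering

Line profiles are bilinear samples averaged over two parallel
1-px-offset lines ("two-pixel profiles"); fits are least-squares
Lorentzians offset + A·γ²/((x−c)²+γ²) with FWHM = 2γ, initialized from
the peak and half-max crossings, and flagged (excluded from aggregates)
when the peak-to-edge ratio is < 2 or the width hits a bound.

Persistence: ">2 days" = present in all three sessions, measured at the
last session; otherwise "≤2 days", measured at first appearance (new
spines) or last presence (lost spines).

Clustering standardizes (population variance) the head/neck ratio,
maximum head diameter and length — exactly the three-feature set used
for the published cluster analysis; head volume is reported but not
clustered — then applies Ward's minimum-variance linkage on Euclidean
distances (scipy's Lance–Williams implementation, verified in tests
against a from-scratch O(n³) agglomerator) and cuts at k = 3. k is
fixed, matching the published three-cluster solution; the dendrogram is
exported for inspection but no automatic k selection is done. Labels
are deterministic, ordered by ascending cluster-mean maximum head
diameter, so cluster 3 is always the large-headed "mushroom" class.
Group comparisons use the two-sided Mann–Whitney U (exact enumeration
for tie-free groups of ≤ 12, otherwise normal approximation with
midrank ties and continuity correction), verified against exhaustive
permutation enumeration.

## Seeds and problem sizes

One master seed expands into named, CRC-tagged substreams per stage
(scene, evolution, rendering, beads, each dendrite), so stages are
independently reproducible and a study's manifest (seed + config hash)
determines every CSV byte-for-byte. Default study size is 14 dendrites
× 20 µm × 3 sessions; the density-recovery experiment uses 100
dendrites × 20 µm, the Monte-Carlo check 10⁶ azimuth samples, and bead
calibrations 17 beads per mode — sizes chosen to put Monte-Carlo error
well below the tolerances being tested while keeping any run in
seconds.

## What the synthetic data does and does not show

The generator emulates the *statistical structure* the analysis
assumes: Poisson spine placement with uniform azimuths, lognormal
morphologies, size-dependent loss balanced by gain, and the geometric
detectability of each spine. It does not emulate pixel-level
segmentation, depth-dependent aberrations, motion, deconvolution, spine
growth/shrinkage dynamics, branching dendrites, or observer error in
manual counting. Passing tests therefore validate the *analysis
machinery* — the detection rules, the blind-zone algebra, the turnover
bookkeeping, the FWHM and clustering pipelines — and the internal
consistency of the published corrections, not the biological values
themselves, which require the original image data. Real-data headline
numbers (78.1 %/60.8 % survival, 21.2 %/24.7 % lost, 20.4 %/21.9 % new,
densities 1.61/2.13/2.31 µm⁻¹, neck widths 147/369 nm, cluster
proportions 50 %/7 %) serve only to calibrate generator defaults and to
set direction/threshold checks (STED > 2P on every scene; persistent >
transient volumes in ≥ 95 % of seeds; mushroom enrichment; rank-sum
p < 10⁻⁴).

## Known limitations

- The geometric observer has no intensity model: a dim spine that a
  human would miss is still "detected" if it clears the protrusion rule.
- The blind-zone correction assumes a representative spine length (or
  its distribution) is known; in practice it must be estimated from the
  visible population, which is itself length-biased.
- The Lorentzian-fit FWHM depends a few percent on the fit window when
  the underlying profile is Gaussian-like; windows are fixed conventions
  (±3 lateral FWHM for beads, ±2 for broad profiles) rather than free
  parameters.
- Greedy matching can undercount matches by one in rare chain
  configurations (see above).
- Simulated neck-width readouts reflect the generator's 150 nm median
  necks, not the published 147/369 nm means, which average over the real
  neck population.
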