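# Methods

## The measurement model

The positional-ratio statistic assumes a capillary-loop wall sectioned
nearly perpendicular to the imaging plane, so that three markers — a basal
basement-membrane marker, an apical surface marker, and the target protein —
appear as roughly parallel curvilinear bands. Along any line crossing the
wall perpendicularly, each channel's intensity is unimodal with its peak at
the band center, and the target's peak lies between the other two. The ratio
b/a (target→basal distance over apical→basal distance) is then a
unit-free coordinate on the apicobasal axis that is invariant to
magnification, intensity scaling, and the line's direction of travel.

Everything the package computes rests on that geometry, which is why the
simulator renders exactly it: each channel is
`background + amplitude · exp(−d²/2σ²)`, where `d` is the pixel's distance
to the band's centerline offset by 0, f·a, or a (µm) along the outward
normal. For circular centerlines the distance field is analytic
(`|r − (R + offset)|`); for general polylines the offset curve is resampled
at 0.2 px and distances are nearest-neighbor queries against it (a k-d
tree), which converges to the true distance transform at sub-pixel error
and keeps the bands parallel by construction for any curvature.

## Pipeline stages and their numerical choices

**Profile sampling.** Bilinear interpolation at uniformly spaced points,
default step 0.5 px, distances in µm. Bilinear sampling is exact on affine
intensity fields (the basis of one acceptance check) and matches the
behaviour of the common "plot profile" tools this step re-implements. The
end point is included when the segment length is a whole number of steps;
otherwise the grid stops at the last step before it, keeping spacing exactly
uniform. Lines are single-pixel by default; a `line_width_px` option
averages over parallel offset lines for users whose annotations assume a
wide line.

**Region QC.** Real measurements use regions picked by eye for parallel
marker bands. The automated stand-in estimates each channel's dominant band
orientation inside a window around the line as the principal axis of the
intensity-weighted coordinate covariance (window median subtracted, clipped
at zero, so background and background noise do not dilute the estimate) and
accepts the window only if all pairwise orientation differences are ≤ 15°
(`max_angle_deg`). Rejections are recorded per line with reasons, making
the selection auditable rather than manual.

**Peak detection.** The peak is the global maximum of the channel's profile
— not the first local maximum — because QC guarantees a single wall
crossing; shoulder bumps from noise then cannot capture the peak. Exact
ties break toward the smaller distance. When the maximum is interior and a
strict local maximum, a three-point parabolic fit refines the position; the
offset is clamped to ± half a step. On noiseless Gaussian bands sampled at
0.5 px this recovers off-grid centers to well under 0.05 px, which is what
makes the ratio nearly independent of the sampling step. Profiles whose
peak-to-trough range is below 10⁻⁹ of their magnitude are treated as
constant (`no_peak`) — this absorbs interpolation round-off on
background-only lines.

**Ratio QC.** A measurement is rejected as `degenerate` when the
basal–apical separation a falls below `min_separation_steps` (default 3)
sampling steps — ratios on near-coincident peaks are numerically
meaningless — and as `misordered` when the target peak lies outside the
basal–apical interval. Misordered lines are rejected rather than clamped:
clamping would pull group means toward the interval ends and bias the
comparison. Accepted ratios are therefore always in [0, 1]. An optional
`peak_window_um` restricts the peak search to a window around the basal
maximum for lines that cross a loop twice; the planned perpendicular lines
cross once by construction, so it defaults to off.

**Colocalization.** Pearson R over matched samples, computed from the
definition with the result clipped to [−1, 1] against round-off. Line mode
correlates profile samples; band mode correlates raw pixels within a
boundary-band mask. No thresholding or background masking is applied by
default, and group comparisons test the R values directly (a Fisher
z-transform option exists but is off, matching the plain workflow the
package reproduces).

**Morphometry.** A foot-process width is the arc distance between
successive junction positions, so widths always sum to the covered arc
length (the conservation property). Input positions must be strictly
increasing; nm input is converted with an explicit unit tag. Site sampling
is uniform without replacement from a seeded generator, with the selection
canonicalized to arc order.

**Statistics.** The Mann–Whitney U statistic counts pairwise wins plus half
the ties. Exact mode enumerates all C(m+n, m) assignments of the pooled
mid-ranks to the first group, so it is exact conditional on the observed
tie pattern; the two-sided p is the doubling rule min(1, 2·min(P(U ≤ u),
P(U ≥ u))), chosen because it is the standard convention and degrades
gracefully to p = 1 for perfectly balanced data. Auto mode uses exact
enumeration when min(m, n) ≤ 10 and the data are tie-free (C(20,10) =
184,756 assignments, milliseconds), otherwise the normal approximation with
tie-corrected variance and continuity correction; the two differ by < 0.02
at m = n = 10. The t test defaults to Welch — the "t test" in this kind of
analysis is rarely accompanied by an equal-variance check, and Welch costs
nothing when variances happen to be equal — with Student's pooled variant
available. Zero-variance degenerate inputs use the documented convention
p = 1 (equal means) / p = 0 (unequal). Summaries are mean ± SEM with the
n−1 standard deviation; significance is declared at p < 0.05, strictly.

## The simulator's defaults, and what they emulate

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.05 µm/px | SIM-class sampling (~50 nm pixels) |
| wall thickness a | 1.0 µm | basal-to-apical marker separation of a capillary wall at this resolution |
| band σ | 0.08 µm | band cross-section consistent with a super-resolution PSF (~190 nm FWHM) |
| amplitude / background | 1000 / 100 | 16-bit-range fluorescence with a dim diffuse background |
| noise | none; "SNR 10" = Gaussian sd 100 | noise is a study condition, not an estimate of any instrument |
| lines per scene | 30 | the 30-measurement-points-per-group design the ratio analysis mirrors |
| cell-scene q | 0.5 | equal split between junctional and stress-fiber pools |
| morphometry widths | lognormal, control mean 0.25 µm / effaced 0.60 µm, CV 0.3 | right-skewed positive widths; healthy foot processes a few hundred nm wide vs flattened effaced processes |
| sites per group | 20 | the 20-randomly-selected-sites morphometry design |

In cell scenes the target channel is a mixture `q·J + (1−q)·F` of
unit-integral junction and fiber images on a fixed intensity scale, so the
junctional share of integrated signal equals q exactly and the junctional
band brightness grows linearly with q; fibers are kept ≥ 3σ_junction +
2σ_fiber away from boundaries so the partition survives rendering to within
1%. The partner channel is purely junctional by default (q_partner = 1).

**What the simulator does not emulate:** optics (no PSF convolution, no SIM
reconstruction artifacts), 3-D sectioning, autofluorescence, chromatic
misregistration, marker-specific labeling stoichiometry, or EM texture —
foot-process widths are simulated as numbers, not segmented from images.
Passing tests therefore demonstrate that the measurement chain recovers
known geometry and effect sizes under idealized but noisy conditions; they
do not certify performance on real micrographs, where band asymmetry,
double walls and out-of-plane tilt are handled only insofar as the QC gates
reject such lines.

## Determinism and problem sizes

One top-level integer seed drives everything; per-scene and per-replicate
streams are derived through `numpy.random.SeedSequence` spawning, so any
subset of an experiment is reproducible in isolation, and two runs with the
same config+seed produce byte-identical CSVs (floats are written with
round-trippable formatting). The validation runs use 256×256 px scenes,
30 lines per scene, 100 replicates for the two power estimates and 200
datasets for the exact-test cross-check — sizes chosen so the complete
suite and the acceptance script each finish in well under a minute on one
CPU while leaving the power estimates' binomial error at the percent level.

## Known limitations

- The ratio presumes exactly one wall crossing; loops sectioned obliquely
  produce broadened, asymmetric bands the parabolic refinement does not
  model (such lines are typically rejected by the orientation gate).
- The exact U test enumerates combinations; above min(m, n) = 10 it defers
  to the normal approximation rather than a network algorithm.
- The alignment gate estimates one dominant orientation per window; windows
  containing two walls of a hairpin loop can pass while individual lines
  still fail peak-order QC.
- TIFF output quantizes to 16-bit integers; simulated intensities are
  integral at the default amplitudes, so round trips are lossless there,
  but custom fractional amplitudes round.
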