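# Methods

## The experimental design model

The design module enumerates the factorial structure as data: 6
experimental days × 2 crystallisation chambers × 6 samples per chamber × 4
technical replicates = 288 plates, 48 per day. Chamber and batch are
confounded by construction (chamber 1 ↔ batch 2109, chamber 2 ↔ batch
2204), so `batch` enters the statistical models and `chamber` never does;
the ANOVA layer rejects aliased factor pairs rather than silently fitting
a rank-deficient model. Subspecies is a deterministic function of host
tree (pine → VAAu, apple/oak → VAA), which is why the subspecies
sensitivity test pools apple+oak (192 plates) against pine (96) and the
deciduous test drops the pine plates entirely (192 = 96 apple + 96 oak).

The three sensitivity tests differ only in row subset and factor set:

| test | rows | four factors | contrast |
|---|---|---|---|
| subspecies | 288 | day, batch, blending, subspecies | VAA vs VAAu (192 vs 96) |
| deciduous | 192 | day, batch, blending, host_tree | apple vs oak (96 vs 96) |
| blending | 288 | day, batch, host_tree, blending | machine vs hand (144 vs 144) |

## Synthetic fingerprints

No quantitative morphology statistics of real CCC plates are available to
calibrate against, so the simulator is built for *controllability*, not
visual fidelity: its job is to give every downstream measurement a known
ground truth.

**Direct mode** draws the seven analysis variables from the linear model
value = baseline + Σ contrast shifts + day offset + batch offset +
N(0, σ). A standardised effect d on a two-level contrast adds ±d·σ/2 to
the two levels, so the population Cohen's d equals d exactly. Defaults:
σ = 1, all offsets 0. Per-plate RNG streams are derived from
(master seed, CRC-32 of plate id), so adding plates never perturbs
existing draws and every output is bit-reproducible.

**Image mode** grows needles as unit-step random walks with angular
diffusion (0.09 rad/step) from seeds placed on a ring at 8–18 % of the
plate radius, oriented outward. A side branch nucleates with probability
`branch_prob` per step at ±0.65 rad (jitter SD 0.2), inheriting 40–80 % of
the parent's remaining length. Needle lengths are lognormal
(median `length_scale` = 26 px, σ = 0.35 by default — within the range
the 19.2/22 px bin edges of the named length variables are designed to
resolve). This growth model was chosen over diffusion-limited aggregation
because it has a *direct* length parameter, which is the quantity the
structure variables measure. Rendering stamps the walk pixels, dilates to
`needle_width`, applies multiplicative Gaussian-correlated speckle
(amplitude 0.08, correlation length 2 px) so that texture variables
respond to `texture_grain`, quantises to 8 bits, and forces pixels outside
the plate radius to the background level. Contrast effects on latent
parameters act multiplicatively (log-scale shifts), and day/batch offsets
act on log(length_scale), keeping relative effects scale-free.

What the simulator does **not** emulate: evaporation physics, nucleation
thermodynamics, radial density gradients, centre coordination, plate-edge
artefacts, scanner calibration, or any colour information. Passing tests
therefore demonstrate that the measurement and inference chain recovers
known structure of this generative family — not that the method separates
real mistletoe extracts.

## Texture features

The co-occurrence matrix accumulates pair counts over the (0,1) and (1,0)
offsets, counts each pair in both orders (symmetrisation), requires both
pixels inside the circular ROI, and normalises to sum 1. Grey values are
linearly binned to 32 levels by default: the source analyses do not state
a level count, and 32 keeps a plate-sized ROI's matrix well populated
while preserving contrast structure (configurable). Entropy uses the
natural log; the base is a pure scale choice.

Two of the four named variables have no single canonical formula in the
field, so their definitions are package decisions, documented here and
fixed by tests: `kappa` is Cohen's chance-corrected agreement applied to
the GLCM diagonal, (P₀−Pₑ)/(1−Pₑ) with P₀ = Σᵢp(i,i), Pₑ = Σᵢpₓ(i)p_y(i) —
a consistency measure that is 1 for a perfectly diagonal matrix and 0 at
independence (defined as 0 and flagged when Pₑ = 1, i.e. a single-level
image). `diagonal_moment` is Σ|i−j|(i+j−μₓ−μᵧ)p(i,j): |i−j| measures
local roughness and the centred brightness term signs it, so positive
values mean rough bright areas and smooth dark areas. The other eleven
variables are the standard Haralick second-order set.

## Structure features

Binarisation uses Gaussian-weighted local thresholding (window =
plate_radius/8, rounded odd; offset −10 grey levels) inside ROI 0–90 %,
which makes the foreground map invariant to smooth illumination ramps.
The map is thinned to an 8-connected skeleton; needles are maximal
skeleton paths between nodes (pixels of degree ≠ 2), traced by explicit
pixel walking; branch pixels are shared between segments and pure cycles
become single closed segments. Lengths are step sums (1 axial, √2
diagonal); widths are 2× the Euclidean distance transform averaged along
the path. Segments shorter than 2 px are pruned as thinning spurs
(configurable).

The 15 length bins are anchored on the two defining edges 19.2 and 22.0
px; the remaining 13 lower edges continue the same geometric ratio
r = 22/19.2 ≈ 1.146 downward, so every bin shares one relative-width
convention. Bins are right-open except the top bin, so a needle of length
exactly 22.0 px counts in `l250`, not `l220`. Width bins reuse the length
edges divided by 4, matching the 1–6 px widths that rendered needles
actually take. `lend` counts degree-1 skeleton pixels, independent of the
segment decomposition.

## Randomisation search

Systematic-control values are normalised by division by their
(variable, day) mean — ratios, not differences, so variables of different
scales are commensurable before aggregation. Candidate schemes are random
partitions of the 24 used positions into 6 blocks of 4; each is scored by
the mean over variables of the SD of the six block means (max-over-
variables available as an alternative), and candidates are ranked
ascending. The selected scheme is the best-ranked one for which one-way
ANOVAs of every variable across blocks all give p > α (default α = 0.05;
α = 0 disables the filter). The default search size is 2 × 10⁶
candidates; the search is vectorised and bounded in memory by retaining
the 1000 best candidates. The 43-position layout keeps ring labels and a
configurable used-position subset, since the original used-position
assignment is a property of the laboratory. The rotation is a uniform-ish
random Latin square obtained by permuting rows, columns and symbols of
the cyclic square — sufficient for counterbalancing, though not uniform
over all 6×6 Latin squares.

## Statistical evaluation

ANOVA uses sum-to-zero factor coding and Type-II sums of squares (via
ordinary least squares): on the balanced blending/deciduous layouts this
coincides with Type I (asserted to 10⁻⁸ in tests), and on the unbalanced
subspecies pooling Type II gives the main-effects-focused decomposition
appropriate when interactions are screened, not modelled as primary. Day
is treated as a fixed factor. A zero-residual fit (possible on degenerate
fixtures) reports F = +∞ with p = 0 rather than failing. Single-level
nuisance factors (e.g. day in a one-day run) are dropped from the model
with a warning; a single-level factor of interest is an error.

Protected LSD: pairwise t comparisons on the model's MSE and residual df,
computed only when the factor's F-test has p < 0.01. Cohen's d uses the
pooled-SD definition on raw (not day-normalised) values, pooled over all
other factors; computing d per stratum instead is possible but the
pooled convention is the package default. Interaction flags report the
partner factor of any first-level interaction with the factor of interest
at p < 0.01, using the letters d (day), b (batch), p (blending), h (host
tree); a flagged day interaction triggers a per-day two-sample t
drill-down of the contrast.

The correlation filter is greedy: while any candidate pair has Pearson
|r| > 0.7, the member of the worst pair with the larger mean |r| to the
remaining pool is dropped; constant columns are removed first with a
warning.

## Problem sizes and numerics

The test suite and the acceptance script run everything at the full
design size (288 plates) for direct-mode statistics; image-mode tests use
64–96 px plate radii and ≤ 48 plates, which exercise the identical code
paths at smaller rasters. Effect-size recovery uses 200 replicates per
contrast (replicate SE of the mean ≈ 0.01); the type-I calibration uses
600 null replicates against a 3·SE band around 0.01. Scheme searches in
tests use 10³–2×10⁴ candidates; the 2 × 10⁶ default is a library default,
not a test setting. GLCM normalisation is asserted to 10⁻⁹; the
brute-force GLCM oracle must agree exactly (10⁻¹²).

## Known limitations

- The simulator's needle-length distribution and speckle model are
  convenient fictions; no claim is made that recovered texture effect
  sizes transfer to scanner data.
- `kappa` and `diagonal_moment` follow the package's stated definitions;
  other software lineages may normalise differently (scale-only
  differences for entropy bases, potentially structural ones for
  diagonal moments).
- The skeleton decomposition treats diagonal contacts between branches as
  nodes; very dense patterns can fragment into more, shorter segments
  than a human tracing would produce. Bin totals remain conserved.
- Latin squares are not sampled uniformly; block-search scoring assumes
  the SC table covers all used positions on every day.
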