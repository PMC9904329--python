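# Methods

This note documents the models implemented in `hiddenum`, the choices
made where the experimental descriptions leave the design open, and what
the synthetic-data generators do and do not emulate.

## Scene geometry and the constant-density expectation

The board is a grid of `rows × cols` cells (default 13 × 9 = 117) with
pixel dimensions proportional to the 390 × 507 px reference board; pieces
are disks of 21 px diameter centred in cells, and all dimensions scale
multiplicatively (standard scales 1, 0.75, 0.5, rounded to whole pixels).

A cell is **hidden** when a piece centred in it would be completely
covered by occluder material. This is evaluated literally, on a
rasterised occluder mask at native pixel resolution: every pixel of the
piece disk must lie under material (inside the occluder footprint, in no
hole). The visible/hidden cell counts `N_v`, `N_h` double as the areas
`S_v`, `S_h` (cell-count units), and the constant-density expectation is

    n_h = n_v * S_h / S_v.

Two conventions need flagging:

- **Mesh hole layout.** The original hole coordinates are not published;
  only the constraints are (12 holes, 6 small + 6 large, mirror-symmetric
  about the vertical midline, two pattern variants). We place holes on a
  4 × 3 lattice inside the 280 × 407 px footprint with sizes alternating
  in a checker pattern (which is automatically mirror-symmetric);
  `pattern_id=2` swaps the size classes. Consequently the *computed*
  area ratios of the menu occluders need not equal the published ones
  (e.g. the (40, 60) mesh yields S_h/S_v ≈ 0.26 here vs the published
  0.27). Wherever an analysis depends on the published ratios, they are
  accepted as inputs (`OcclusionGeometry.from_ratio`, flagged
  `ratio_source="published"`); geometry-derived ratios are the default
  otherwise.
- **Bar occluders.** Two vertical bars cover two full columns each
  (columns 3–4 and 6–7, 1-based) or two horizontal bars three full rows
  each (rows 4–6 and 8–10): symmetric, clear of the board edges. Only
  the covered counts (4 of 9 columns; 6 of 13 rows) enter the math; the
  vertical-bar geometry gives N_h/N_v = 52/65 = 0.8 exactly.

### Trial designs

`enumerate_trials` reproduces the five published designs exactly:
352 / 279 / 231 / 150 / 189 rows (including demonstration trials flagged
`analyzed=False` — obscured boards, and swapped standard/comparison
roles in the discrimination task). Menus (numerosities, conditions,
repetitions, scales, occluders) are data, overridable per call.

### Piece placement

Irregular scatters resample until no three pieces occupy contiguous
collinear cells in any grid direction. A stricter "no three anywhere on
a shared line" rule is unsatisfiable at the published numerosities
(twelve pieces on the five visible columns of the vertical-bar board
force three into one column), so line-ness is judged on contiguous runs —
the reading consistent with pieces "not forming a line" perceptually.

Regular arrangements use grid lines: *across* fills lines perpendicular
to the bars (each used line crosses the occluded region), *outside*
fills fully visible lines parallel to the bars. No single straight line
on the board holds ten visible cells while crossing a bar, so when one
line is full the placement continues on the adjacent parallel line. For
numerosities that fill whole lines (5 and 10 with vertical bars, 7 and
14 with horizontal bars) the occluded cells spanned by the across-lines
equal the constant-density expectation exactly; for 12 the match is
approximate (9.6 expected is not an integer cell count).

## Night-sky synthesis

Scenes are 500 × 500 RGB composites of a gradient sky (light blue
(49, 87, 133) to dark blue (10, 25, 44), upper-left to lower-right), a
flat 255 cloud layer, and a star layer:

    I = (1 - w_cloud) * [(1 - w_star) * I_sky + w_star * I_star]
        + w_cloud * I_cloud.

`w_cloud` comes from a Brownian (1/f² power) noise map — complex white
noise shaped by a 1/f amplitude filter with the DC term zeroed, inverse
FFT, min–max normalised to [0, 1] — shifted down by an offset (default
0.6) and clamped at zero. Normalising before the subtraction is our
choice: without a defined noise scale the fixed subtraction is
ill-posed. A pixel counts as cloud-covered when `w_cloud > τ` with
τ = 0.05; near-zero weights leave stars visibly intact, and τ is exposed
in the API. Because the experiments vary cover from 0.3 to 0.7 while the
subtraction constant is fixed, cover is controlled by calibrating the
offset: the covered fraction is monotone non-increasing in the offset, so
a quantile read-out plus bisection reaches any target within ±0.005.

Stars are 2 × 2 (luminance 213) or 3 × 3 (luminance 171) stamps in
balanced numbers, placed only where `w_cloud ≤ τ`; `w_star` is the union
of stamps smoothed with a Gaussian kernel of variance 0.9 (small) or 1.2
(large) in pixel units, clipped to [0, 1]. No stars are placed under
clouds: the ground truth for hidden stars is defined through the
constant-density rule, not through actually rendered occluded stars.

## Synthetic observers

- **2AFC choices**: Bernoulli draws with success probability
  Ψ(Δn; α, β, γ, λ), Δn = standard − comparison numerosity.
- **Confidence**: Bernoulli draws with P(high) = 1 − a·exp(−½((Δn−µ)/σ)²).
- **Linear estimator**: round(p₁·n + p₂ + ε) with Gaussian ε, clamped to
  the 0–40 drop-down menu (round-half-up; menus force integers).
- **Bayesian estimator**: posterior readout of the hidden count (below),
  plus optional Gaussian response noise (default sd 0, so model-fit
  checks are clean), same discretization.

The generators share one seeded `numpy` Generator per call and are
bit-reproducible. They emulate the *structure* the analysis assumes —
independent trials, stationary parameters, binomial response noise. They
do not emulate sequential effects, learning, strategy switches, lapses
of attention correlated across tasks, or individual differences beyond
the parameters supplied; passing recovery tests therefore validates the
estimation machinery, not the behavioural realism of the generator.

## Curve fitting

Both curve fits minimise the *unweighted* sum of squared deviations of
per-level proportions (the conventional least-squares treatment of
binned psychophysical data; a binomial-likelihood mode was considered
and left out to keep the objective the one the summaries report).
Optimisation is bounded least squares (trust-region reflective, analytic
Jacobians) from a grid of 27 starts (3 locations × 3 spreads × 3
amplitudes/lapses), tie-broken by lowest RSS then smallest |location|.
Bounds: β, σ ∈ [0.1, 50]; λ ∈ [0, 0.25]; a ∈ [0, 1]; location within the
level range ± one range-width. Convergence tolerance 1e-9, 500
iterations per start. Degenerate data (constant proportions, or
saturated confidence) leave the location unidentified; fits are returned
with `converged=False`.

## Bayesian observer

Pieces dropped uniformly on distinct cells make the visible count
hypergeometric (evaluated via `scipy.stats`). The posterior over the
total count `n` given `n_v` lives on the integer support
[n_v, n_v + N_h]; the prior is a Gaussian density evaluated at the
integers and renormalised — over `n` directly (*constant-total*) or over
`n − n_v` (*constant-hidden*, the only reading under which "a constant
number of hidden objects" is invariant to the visible count). The model
prediction is the posterior mean of the hidden count (the readout is not
pinned down by the published analysis; the mean is smooth in the
parameters and standard for least-squares fitting of mean estimates;
the mode is available as an option).

Prior parameters (mean, sd) are fitted by least squares to
condition-mean estimates over the design cells (the 9 numerosities × 2
occluders = 18 cells of the estimation design), with L-BFGS-B from a
6 × 5 start grid, bounds mean ∈ (0, 117], sd ∈ [0.1, 50]. The per-cell
hypergeometric likelihoods are cached across objective evaluations.
Model comparison uses the Gaussian-error BIC, n·ln(RSS/n) + k·ln(n) with
k = 2, and relative weights exp(−Δᵢ/2)/Σexp(−Δⱼ/2); an RSS of exactly
zero is floored at machine-tiny with a warning.

## Descriptive layer

Linear fits are ordinary least squares with R² = 1 − RSS/TSS (clamped at
zero, flagged). The coefficient of variation uses the sample sd (n − 1).
The cover-proportion report of the sky task is read as hidden area over
*total* area, so the hidden/visible ratio is p/(1 − p) and the
subjective expectation of hidden stars is `est_visible · p/(1 − p)`;
the maximum-hidden-pieces report of the area-estimation task is
converted to a proportion by dividing by all 117 cells (the slider
maximum). Inferential tests (ANOVAs, t-tests) are deliberately not
reimplemented; the summaries expose the per-condition quantities they
would consume.

## Validation problem sizes

The closed-loop recovery harnesses use the full published 2AFC design
(11 difference levels × 10 repetitions) with 2000 simulated observers —
enough to pin the replicate-mean location to ± ~0.015 pieces (the
Monte-Carlo SE) against the 0.1-piece recovery criterion. Prior recovery
uses the 18-cell estimation design with noiseless readout, where the
closed loop is exact to optimizer precision. Property tests use small
urns (≤ 12 cells) so the likelihood can be checked against exhaustive
enumeration of placements.

## Known limitations

- Board renderings are flat-colour diagnostics; shading, highlights and
  luminance calibration of the original stimuli are out of scope.
- The mesh-hole lattice is a reconstruction; analyses tied to the
  published area ratios should pass them explicitly (`from_ratio`).
- The regular-across arrangement at numerosity 12 cannot match the
  constant-density expectation exactly (see above).
- BIC from RSS assumes homoskedastic Gaussian residuals on condition
  means; with very few cells the weights are sensitive to that choice.
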