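# Methods

## Problem and conventions

A hemispherical canopy photograph is reduced to its blue color plane (8-bit,
values 0–255) and binarized with a single global threshold `t`: gray value
`g <= t` is vegetation, `g > t` is sky. All seven algorithms, the accuracy
statistics and the simulator share this convention; class 0 always means
vegetation. Analysis can be restricted to the circular fisheye field of view
with a configurable mask; histograms are always built over mask-true pixels
only, since out-of-circle border pixels are not part of the hemisphere and
would distort every histogram-shaped objective. The mask defaults to the
full frame, and gap fraction is the unweighted whole-photo sky proportion
(canopy openness), with no zenith-annulus weighting.

Pixel coordinates are 0-based `(x=column, y=row)`, origin top-left.

## Threshold algorithms

All candidate thresholds 0–255 are scanned exhaustively; whenever several
candidates attain the optimum the smallest is returned (a deterministic rule
is needed for exact oracle tests, and objectives are frequently flat over
empty gray ranges). Candidates leaving a class empty are inadmissible
everywhere.

* **Otsu** maximizes `w0*w1*(mu0-mu1)^2` computed from cumulative moments.
* **IsoData** scans `t` upward from the lowest occupied gray value and stops
  at the first `t >= (mu0(t)+mu1(t))/2` — the Ridler–Calvard fixed point. If
  no fixed point exists below the last occupied value (possible when the
  histogram is concentrated at the bright end) the final candidate is
  returned with `converged=False`.
* **Maximum Entropy** maximizes `H0+H1` with `H0 = ln P0 - (1/P0)·sum(p ln p)`
  over the lower class; empty bins contribute zero.
* **Minimum Error** minimizes the Kittler–Illingworth criterion
  `J(t) = 1 + w0·ln(var0) + w1·ln(var1) - 2(w0·ln w0 + w1·ln w1)` by
  exhaustive scan rather than the original iterative update, removing its
  initialization dependence. Candidates need both class variances positive
  (floor 1e-9 against float cancellation). When the minimizer leaves a class
  with < 1% of the pixels, the result is flagged `converged=False` with a
  warning — the criterion's known collapse on near-unimodal histograms.
* **Minimum** repeatedly smooths the histogram with a 3-point moving average
  (reflective boundaries, float accumulation, pass cap 10,000) until exactly
  two local maxima remain, then returns the unique minimum between them.
  Local extrema are counted on run-length-compressed values so a plateau is
  one extremum (each run compared strictly against its nearest differing
  neighbor per side); a flat valley returns the floor of its middle gray
  value. Once the mode count drops below two it can never rise again under
  linear smoothing, so unimodal inputs fail fast with a non-convergence
  error.
* **Minimum Histogram** re-bins the counts at widths w = 1, 2, 3, …
  (first bin's left border always at gray 0) until the binned histogram has
  exactly two modes, then returns the floor of the middle gray value of the
  valley bin. Width is capped at 128, since a wider bin cannot hold two
  modes plus a valley inside 256 gray values. When the raw histogram already
  has a unique valley between exactly two modes, Minimum (at 0 smoothing
  passes) and Minimum Histogram (at w=1) agree by construction.
* **Edge Detection** evaluates, for every candidate `t`, the mean absolute
  gray difference over all 4-neighbor pixel pairs (both inside the mask)
  that straddle the threshold, and maximizes it. The mean rather than the
  sum is used so the objective is not trivially won by thresholds creating
  many low-contrast boundary pairs; pair counts and difference sums are
  accumulated once with difference arrays, making the full 256-candidate
  scan O(pixels). An optional stride subsamples the pixel grid for very
  large rasters (default 1 = exact).

## Accuracy assessment

Reference pixels are drawn by stratified simple random sampling without
replacement: 16 strata of 16 consecutive gray values, 24 pixels per stratum
(384 total) by default, so rare gray ranges are represented. Strata with
fewer eligible pixels than requested are exhausted and flagged. The operator
labels each pixel vegetation or sky from a magnified context chip.

Because sampling is stratified by gray value and the algorithm classifies by
gray value, raw sample proportions misrepresent photo-wide probabilities.
Each stratum's 2x2 confusion matrix (rows = operator, columns = algorithm)
is therefore bias-corrected by the image marginal proportions:
`p_jk = W_k · n_jk / n_·k`, where `W_k` is the fraction of the stratum's
*population* the algorithm assigned to class k. Cells with `n_·k = 0`
contribute zero — exact when `W_k = 0`, conservative in the (rare) case a
present class was missed by the sample.

* `PC_h = p_VV + p_SS`, with the stratified binomial variance
  `sum_k W_k^2 · q_k(1-q_k)/max(n_·k - 1, 1)`, `q_k = n_kk/n_·k`.
* `kappa_h = (p_o - p_e)/(1 - p_e)` from the corrected cells, with the
  delta-method large-sample variance (the theta-1..4 form) over the
  corrected proportions, divided by `n_h`. When `p_e = 1` the stratum is
  single-class and kappa is reported as 0 with an explicit degeneracy flag.
* Overall estimates are `N_h/N`-weighted averages of the per-stratum values,
  with variance `sum (N_h/N)^2 var_h` and symmetric normal 95% CIs.
  Empty-population strata get weight 0.
* `GF_ref = sum_h (N_h/N)(s_h/n_h)` (s_h = sky labels) is the
  design-unbiased stratified estimator of the photo's sky proportion;
  `misestimation = GF_pic / GF_ref`.

A structural consequence worth knowing: under a global threshold, every
stratum that does not contain `t` has `W_V` exactly 0 or 1, so its corrected
confusion matrix is single-column and its kappa is 0 (or degenerate). The
weighted overall kappa of a well-binarized photo is therefore near zero even
when PC is near 1 — kappa here discriminates only within the stratum the
threshold cuts through. PC, whose bias correction handles single-class
strata exactly, is the informative overall measure in this design.

Downstream cross-photograph inference (ANOVA and the like) is deliberately
out of scope; reports are exported as CSV/JSON for any statistics
environment.

## Synthetic scenes

The generator produces the gray-value phenomenology the estimators respond
to, not leaf optics:

* **Truth**: Gaussian-smoothed white noise thresholded at the quantile
  giving the requested canopy cover (default 0.7, a closed canopy;
  smoothing length 8 px sets gap size). 4-neighbor boundary pixels are
  converted to mixed pixels with uniform vegetation fraction `alpha` until
  5% of all pixels are mixed (defaults; boundary exhausts first on sparse
  scenes).
* **Rendering**: per pixel, `alpha·V + (1-alpha)·S` with
  `V ~ N(40, 12)` and `S ~ N(200, 18)` gray levels — dark foliage and
  bright sky on the blue plane — plus a radial gradient of 30 gray levels
  peaking at the image center (the zenith). *Histogram exposure* rescales
  linearly so the brightest pixel is exactly 255 (no clipped mass);
  *auto exposure* adds 60 gray levels (`clip_excess`) before clamping, so a
  sizeable share of sky saturates at 255, forming the overexposure spike.
* **Blooming**: vegetation/mixed pixels within 3 px of a saturated pixel
  are raised toward 255 with weight `1 - d/(radius+1)`. Truth is never
  modified — blooming corrupts recorded values, not classes, and a bloomed
  vegetation pixel stays vegetation in the reference.
* **Census scoring**: mixed pixels enter the census as vegetation when
  `alpha >= 0.5` (`alpha_rule="half"`, default) or are dropped
  (`"exclude"`); the same rule generates reference labels when ground truth
  stands in for the operator.

All randomness flows from one seed through named substreams, so the whole
generate→render→bloom chain is reproducible bit-for-bit.

What the simulator does *not* contain — and hence what passing tests do not
show about real photographs: within-class gray values are spatially
uncorrelated (real foliage shading and sky luminance vary smoothly), there
is no sun disc, no lens vignetting or projection geometry, no JPEG
compression or camera gamma, and reflection highlights on leaves are absent.
One visible consequence: isolated dark outlier pixels, which real photos
rarely isolate, can hijack Edge Detection's mean-contrast objective at very
low thresholds on some seeds, so its synthetic-scene accuracy understates
its field behavior.

## Exposure effect, as tested

Overexposure degrades the histogram-clustering algorithms through the whole
chain — global brightening shifts the vegetation mode up, clipping collapses
the sky mode into a spike at 255, and blooming drags boundary vegetation
toward it. The suite asserts this full-chain direction: on matched scene
pairs, the gap-fraction misestimation |GF_pic/GF_truth − 1| of
Otsu/IsoData/MaxEntropy is larger under auto exposure than under histogram
exposure in at least 18 of 20 seeds, and the valley-seeking algorithms
(Minimum, Minimum Histogram) retain higher census PC than the clustering
algorithms under auto exposure in aggregate. The narrower claim that merely
*adding* a 255 spike to a fixed bimodal histogram cannot decrease the
resulting sky proportion on the unclipped pixels is **not** asserted: direct
computation shows the added bright mass raises the upper-class mean and
frequently moves the Otsu/IsoData optimum upward, i.e. the spike-only
abstraction has the opposite sign of the full effect.

## Numerical and design choices

* Exhaustive 256-candidate scans everywhere; no iterative schemes, so no
  initialization sensitivity and exact agreement with brute-force oracles.
* Ties break to the smallest threshold; plateaus count as one extremum;
  "middle" of an even-width bin or flat valley is the floor of the
  arithmetic middle (thresholds must be integers).
* Objective traces are retained on the result objects (NaN at inadmissible
  candidates) for audit and plotting.
* Binary masks are written as lossless PNG with vegetation=0, sky=255,
  outside=128, plus a JSON sidecar declaring the convention; round-trips
  are bit-exact.
* JPEG input is accepted as-is; compression artifacts and camera gamma are
  not undone (a known limitation of the imagery this tool targets).
* Problem sizes in the test suite and acceptance script (512x512 census
  scenes, 500 resamples, 20-seed exposure comparisons, 100-histogram oracle
  sweeps) were chosen so the full validation runs in a few minutes on one
  core while keeping Monte-Carlo error well below the asserted margins.
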