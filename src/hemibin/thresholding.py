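"""Global threshold selection and binarization.

Seven classic global-threshold algorithms used by canopy-photo software are
implemented against a shared convention: given a threshold ``t``, every pixel
with gray value **less than or equal to** ``t`` is classified vegetation and
every brighter pixel sky.  All objectives below are expressed in this
convention, with class 0 = vegetation = values <= t.

Six algorithms operate on the 256-bin gray-value histogram
(Otsu, IsoData, Maximum Entropy, Minimum Error, Minimum, Minimum Histogram);
Edge Detection needs the image itself because its objective is the contrast
across vegetation|sky boundaries the candidate threshold induces.

Deterministic tie-breaking: whenever several thresholds attain the optimum,
the smallest is returned.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .image_io import GrayHistogram, GrayImage

__all__ = [
    "VEGETATION",
    "SKY",
    "OUTSIDE",
    "BinaryMap",
    "ThresholdResult",
    "NonConvergenceError",
    "binarize",
    "gap_fraction_picture",
    "threshold_otsu",
    "threshold_isodata",
    "threshold_max_entropy",
    "threshold_min_error",
    "threshold_minimum",
    "threshold_minimum_histogram",
    "threshold_edge_detection",
    "compute_threshold",
    "HISTOGRAM_METHODS",
    "ALL_METHODS",
]

#: In-memory class codes for :class:`BinaryMap`.
VEGETATION = np.int8(0)
SKY = np.int8(1)
OUTSIDE = np.int8(-1)

#: Minimum admissible class variance for the Minimum Error criterion.
_MIN_VARIANCE = 1e-9
#: Class-weight fraction below which a Minimum Error solution is flagged unstable.
_MIN_ERROR_WEIGHT_WARN = 0.01
#: Smoothing-pass cap for the Minimum algorithm.
_MINIMUM_MAX_PASSES = 10_000
#: Bin-width cap for the Minimum Histogram algorithm; wider bins cannot hold
#: two modes plus a valley within 256 gray values.
_MIN_HISTOGRAM_MAX_WIDTH = 128


class NonConvergenceError(RuntimeError):
    """Raised when an iterative threshold procedure cannot reach its stop rule."""


@dataclass(frozen=True)
class BinaryMap:
    """Per-pixel vegetation/sky classification of a :class:`GrayImage`.

    ``classes`` holds :data:`VEGETATION`, :data:`SKY` or :data:`OUTSIDE`
    (pixels outside the analyzed circle).
    """

    classes: np.ndarray

    def __post_init__(self) -> None:
        classes = np.asarray(self.classes, dtype=np.int8)
        if classes.ndim != 2:
            raise ValueError("binary map must be 2-D")
        valid = np.isin(classes, (VEGETATION, SKY, OUTSIDE))
        if not valid.all():
            raise ValueError("binary map contains unknown class codes")
        object.__setattr__(self, "classes", classes)

    @property
    def n_vegetation(self) -> int:
        return int((self.classes == VEGETATION).sum())

    @property
    def n_sky(self) -> int:
        return int((self.classes == SKY).sum())

    @property
    def mask(self) -> np.ndarray:
        """Boolean inside-circle mask recovered from the class codes."""
        return self.classes != OUTSIDE


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold algorithm.

    Attributes
    ----------
    method
        Algorithm identifier.
    threshold
        Integer gray value ``t`` in [0, 255]; pixels <= t are vegetation.
    objective
        Optional length-256 trace of the algorithm's objective per candidate
        threshold (NaN where the candidate is inadmissible), for audit plots.
    iterations
        Number of scan steps / smoothing passes / bin widths examined.
    converged
        False when a documented fallback was taken; a warning explains why.
    """

    method: str
    threshold: int
    objective: np.ndarray | None = None
    iterations: int = 0
    converged: bool = True
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0 <= int(self.threshold) <= 255:
            raise ValueError(f"threshold {self.threshold} outside [0, 255]")
        object.__setattr__(self, "threshold", int(self.threshold))


def binarize(image: GrayImage, t: int) -> BinaryMap:
    """Classify pixels: value <= t -> vegetation, value > t -> sky.

    Pixels outside the image mask are labelled :data:`OUTSIDE`.
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold {t} outside [0, 255]")
    classes = np.where(image.values <= t, VEGETATION, SKY).astype(np.int8)
    classes[~image.mask] = OUTSIDE
    return BinaryMap(classes=classes)


def gap_fraction_picture(binary: BinaryMap) -> float:
    """Gap fraction of a binarized photo: sky pixels / analyzed pixels.

    This is the unweighted whole-photo proportion (canopy openness /
    sky-view factor); no zenith-annulus weighting is applied.
    """
    n_sky = binary.n_sky
    n_veg = binary.n_vegetation
    if n_sky + n_veg == 0:
        raise ValueError("binary map has no pixels inside the analyzed area")
    return n_sky / (n_sky + n_veg)


# ---------------------------------------------------------------------------
# histogram-based algorithms
# ---------------------------------------------------------------------------


def _counts(hist: GrayHistogram | np.ndarray) -> np.ndarray:
    if isinstance(hist, GrayHistogram):
        counts = np.asarray(hist.counts, dtype=np.float64)
    else:
        counts = np.asarray(hist, dtype=np.float64)
        if counts.shape != (256,):
            raise ValueError("histogram must have 256 bins")
    if counts.sum() <= 0:
        raise ValueError("histogram is empty")
    return counts


def _require_two_values(counts: np.ndarray) -> np.ndarray:
    nonzero = np.flatnonzero(counts)
    if nonzero.size < 2:
        raise ValueError(
            "histogram has fewer than two distinct gray values; no split exists"
        )
    return nonzero


def _first_argmax(values: np.ndarray, admissible: np.ndarray) -> int:
    """Smallest index of the maximum over admissible candidates."""
    masked = np.where(admissible, values, -np.inf)
    return int(np.argmax(masked))


def threshold_otsu(hist: GrayHistogram | np.ndarray) -> ThresholdResult:
    """Otsu's method: maximize the between-class variance.

    The objective is ``w0*w1*(mu0 - mu1)**2`` where class 0 collects gray
    values <= t; candidates leaving either class empty are inadmissible.
    """
    counts = _counts(hist)
    _require_two_values(counts)
    g = np.arange(256, dtype=np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts) / total
    m0 = np.cumsum(counts * g) / total
    mu_total = m0[-1]
    admissible = (w0 > 0) & (w0 < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mu_total - m0) / (1.0 - w0)
        objective = w0 * (1.0 - w0) * (mu0 - mu1) ** 2
    objective[~admissible] = np.nan
    t = _first_argmax(objective, admissible)
    return ThresholdResult(method="otsu", threshold=t, objective=objective)


def threshold_isodata(hist: GrayHistogram | np.ndarray) -> ThresholdResult:
    """IsoData (Ridler–Calvard): first threshold at or past the class-mean midpoint.

    Scanning t upward from the smallest occupied gray value, the first t with
    ``t >= (mu0(t) + mu1(t)) / 2`` is returned — the fixed point at which the
    threshold splits the distance between the two class means evenly.
    """
    counts = _counts(hist)
    nonzero = _require_two_values(counts)
    g = np.arange(256, dtype=np.float64)
    cw = np.cumsum(counts)
    cm = np.cumsum(counts * g)
    total_w, total_m = cw[-1], cm[-1]
    iterations = 0
    for t in range(int(nonzero[0]), int(nonzero[-1])):
        iterations += 1
        if cw[t] == 0 or cw[t] == total_w:
            continue
        mu0 = cm[t] / cw[t]
        mu1 = (total_m - cm[t]) / (total_w - cw[t])
        if t >= 0.5 * (mu0 + mu1):
            return ThresholdResult(
                method="isodata", threshold=t, iterations=iterations
            )
    # No fixed point before the last occupied value: fall back to the final
    # candidate and flag the failure.
    t = int(nonzero[-1]) - 1
    return ThresholdResult(
        method="isodata",
        threshold=t,
        iterations=iterations,
        converged=False,
        warnings=("no IsoData fixed point below the last occupied gray value",),
    )


def threshold_max_entropy(hist: GrayHistogram | np.ndarray) -> ThresholdResult:
    """Kapur's maximum-entropy threshold.

    Maximizes ``H0(t) + H1(t)``, the Shannon entropies of the two class-
    conditional gray-value distributions; empty-bin terms contribute zero and
    candidates with an empty class are excluded.
    """
    counts = _counts(hist)
    _require_two_values(counts)
    p = counts / counts.sum()
    P0 = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    c = np.cumsum(plogp)
    admissible = (P0 > 0) & (P0 < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h0 = np.log(P0) - c / P0
        h1 = np.log1p(-P0) - (c[-1] - c) / (1.0 - P0)
        objective = h0 + h1
    objective[~admissible] = np.nan
    t = _first_argmax(objective, admissible)
    return ThresholdResult(method="max_entropy", threshold=t, objective=objective)


def threshold_min_error(hist: GrayHistogram | np.ndarray) -> ThresholdResult:
    """Kittler–Illingworth minimum-error threshold, solved by exhaustive scan.

    Models each class as a normal distribution and minimizes
    ``J(t) = 1 + 2*(w0*ln(s0) + w1*ln(s1)) - 2*(w0*ln(w0) + w1*ln(w1))``;
    a candidate is admissible only when both class variances are positive.
    The exhaustive scan avoids the initialization dependence of the original
    iterative scheme.  A solution that leaves one class with less than 1% of
    the pixels is flagged as unstable (``converged=False``) — the known
    failure mode of this criterion on near-unimodal canopy histograms.
    """
    counts = _counts(hist)
    _require_two_values(counts)
    g = np.arange(256, dtype=np.float64)
    total = counts.sum()
    cw = np.cumsum(counts)
    cm = np.cumsum(counts * g)
    cs = np.cumsum(counts * g * g)
    w0 = cw / total
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cm / cw
        mu1 = (cm[-1] - cm) / (cw[-1] - cw)
        var0 = cs / cw - mu0**2
        var1 = (cs[-1] - cs) / (cw[-1] - cw) - mu1**2
    admissible = (cw > 0) & (cw < total) & (var0 > _MIN_VARIANCE) & (var1 > _MIN_VARIANCE)
    if not admissible.any():
        raise ValueError(
            "minimum-error criterion has no admissible threshold "
            "(a class variance vanishes at every split)"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        objective = (
            1.0
            + w0 * np.log(var0)
            + w1 * np.log(var1)
            - 2.0 * (w0 * np.log(w0) + w1 * np.log(w1))
        )
    objective[~admissible] = np.nan
    masked = np.where(admissible, objective, np.inf)
    t = int(np.argmin(masked))
    min_weight = min(w0[t], w1[t])
    warns: tuple[str, ...] = ()
    converged = True
    if min_weight < _MIN_ERROR_WEIGHT_WARN:
        converged = False
        warns = (
            f"minimum-error solution leaves a class with weight "
            f"{min_weight:.4f} < {_MIN_ERROR_WEIGHT_WARN}; histogram is likely unimodal",
        )
        _warnings.warn(warns[0], RuntimeWarning, stacklevel=2)
    return ThresholdResult(
        method="min_error",
        threshold=t,
        objective=objective,
        converged=converged,
        warnings=warns,
    )


def _runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode equal consecutive values -> (value, start, end)."""
    values = np.asarray(values, dtype=np.float64)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [values.size - 1]))
    return values[starts], starts, ends


def _local_maxima_runs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Indices of runs that are local maxima.

    A plateau counts as a single extremum: each run is compared strictly
    against its nearest differing neighbor on each side; boundary runs have
    only one side to beat.
    """
    rv, starts, ends = _runs(values)
    n = rv.size
    left_ok = np.empty(n, dtype=bool)
    right_ok = np.empty(n, dtype=bool)
    left_ok[0] = True
    right_ok[-1] = True
    if n > 1:
        left_ok[1:] = rv[1:] > rv[:-1]
        right_ok[:-1] = rv[:-1] > rv[1:]
    return np.flatnonzero(left_ok & right_ok), starts, ends


def _count_modes(values: np.ndarray) -> int:
    idx, _, _ = _local_maxima_runs(values)
    return int(idx.size)


def _valley_between_modes(values: np.ndarray) -> tuple[int, int]:
    """Gray span (start, end) of the unique minimum run between two modes.

    Assumes ``values`` has exactly two local-maximum runs; with plateaus
    counted once, the stretch between two modes contains exactly one local
    minimum run (any second one would imply a third mode).
    """
    maxima, _, _ = _local_maxima_runs(values)
    lo_run, hi_run = maxima
    rv, rstarts, rends = _runs(values)
    seg = rv[lo_run + 1 : hi_run]
    k = lo_run + 1 + int(np.argmin(seg))
    return int(rstarts[k]), int(rends[k])


def threshold_minimum(hist: GrayHistogram | np.ndarray) -> ThresholdResult:
    """Valley threshold after iterative 3-point moving-average smoothing.

    The histogram is repeatedly smoothed (window of three, reflective
    boundaries, float accumulation) until exactly two modes remain; the
    threshold is the gray value of the unique minimum between them (middle
    of the valley plateau if flat).  Unimodal histograms never split and
    raise :class:`NonConvergenceError`.
    """
    counts = _counts(hist)
    _require_two_values(counts)
    h = counts.astype(np.float64)
    for passes in range(_MINIMUM_MAX_PASSES + 1):
        n_modes = _count_modes(h)
        if n_modes == 2:
            lo, hi = _valley_between_modes(h)
            t = (lo + hi) // 2
            return ThresholdResult(
                method="minimum", threshold=t, iterations=passes
            )
        if n_modes < 2:
            raise NonConvergenceError(
                f"histogram is unimodal after {passes} smoothing passes; "
                "3-point smoothing cannot create a second mode"
            )
        h = uniform_filter1d(h, size=3, mode="reflect")
    raise NonConvergenceError(
        f"histogram still has more than two modes after "
        f"{_MINIMUM_MAX_PASSES} smoothing passes"
    )


def threshold_minimum_histogram(hist: GrayHistogram | np.ndarray) -> ThresholdResult:
    """Valley threshold by progressive re-binning at increasing bin widths.

    For bin width w = 1, 2, 3, ... the counts are re-binned into
    ``[k*w, (k+1)*w - 1]`` starting at gray value 0.  The first width whose
    binned histogram shows exactly two modes yields the threshold: the floor
    of the middle gray value of the unique minimum bin between the modes.
    """
    counts = _counts(hist)
    _require_two_values(counts)
    for width in range(1, _MIN_HISTOGRAM_MAX_WIDTH + 1):
        edges = np.arange(0, 256, width)
        binned = np.add.reduceat(counts, edges)
        if _count_modes(binned) == 2:
            lo_bin, hi_bin = _valley_between_modes(binned)
            gray_lo = lo_bin * width
            gray_hi = min((hi_bin + 1) * width - 1, 255)
            t = (gray_lo + gray_hi) // 2
            return ThresholdResult(
                method="minimum_histogram", threshold=t, iterations=width
            )
    raise NonConvergenceError(
        f"no bin width <= {_MIN_HISTOGRAM_MAX_WIDTH} produces exactly two modes"
    )


# ---------------------------------------------------------------------------
# image-based algorithm
# ---------------------------------------------------------------------------


def threshold_edge_detection(image: GrayImage, stride: int = 1) -> ThresholdResult:
    """Edge-value threshold: maximize contrast across vegetation|sky boundaries.

    For each candidate t the image is (conceptually) binarized and the Edge
    Value is the mean absolute gray difference over all 4-neighbor pixel
    pairs, both inside the mask, that straddle the threshold (one member
    <= t, the other > t).  Candidates inducing no boundary pair are
    inadmissible.  ``stride`` subsamples the pixel grid for very large
    rasters; the default of 1 is the exact computation.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    vals = image.values[::stride, ::stride].astype(np.int64)
    mask = image.mask[::stride, ::stride]
    pairs_lo = []
    pairs_hi = []
    for a, b, m in (
        (vals[:, :-1], vals[:, 1:], mask[:, :-1] & mask[:, 1:]),
        (vals[:-1, :], vals[1:, :], mask[:-1, :] & mask[1:, :]),
    ):
        lo = np.minimum(a, b)[m]
        hi = np.maximum(a, b)[m]
        keep = hi > lo
        pairs_lo.append(lo[keep])
        pairs_hi.append(hi[keep])
    lo = np.concatenate(pairs_lo)
    hi = np.concatenate(pairs_hi)
    if lo.size == 0:
        raise ValueError(
            "image has no contrasting neighbor pairs inside the mask; "
            "edge-detection threshold is undefined"
        )
    diff = (hi - lo).astype(np.float64)
    # A pair (lo, hi) is a boundary pair exactly for thresholds lo <= t < hi;
    # accumulate counts and difference sums with difference arrays.
    cnt = np.zeros(257)
    total = np.zeros(257)
    np.add.at(cnt, lo, 1.0)
    np.add.at(cnt, hi, -1.0)
    np.add.at(total, lo, diff)
    np.add.at(total, hi, -diff)
    cnt = np.cumsum(cnt)[:256]
    total = np.cumsum(total)[:256]
    admissible = cnt > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        objective = total / cnt
    objective[~admissible] = np.nan
    t = _first_argmax(objective, admissible)
    return ThresholdResult(method="edge_detection", threshold=t, objective=objective)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

HISTOGRAM_METHODS = {
    "otsu": threshold_otsu,
    "isodata": threshold_isodata,
    "max_entropy": threshold_max_entropy,
    "min_error": threshold_min_error,
    "minimum": threshold_minimum,
    "minimum_histogram": threshold_minimum_histogram,
}

ALL_METHODS = tuple(HISTOGRAM_METHODS) + ("edge_detection",)


def compute_threshold(image: GrayImage, method: str, stride: int = 1) -> ThresholdResult:
    """Run one named algorithm on an image (histogram built internally)."""
    from .image_io import histogram as _histogram

    name = method.replace("-", "_")
    if name == "edge_detection":
        return threshold_edge_detection(image, stride=stride)
    if name not in HISTOGRAM_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {ALL_METHODS}")
    return HISTOGRAM_METHODS[name](_histogram(image))
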