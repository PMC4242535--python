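"""Stratified accuracy assessment of a binarization against operator labels.

The evaluation protocol: reference pixels are drawn by stratified random
sampling across the gray-value range (by default 16 strata of 16 consecutive
gray values, 24 pixels each, n = 384 per photo), labelled vegetation/sky by
an operator, and compared with the algorithm's classification in a per-
stratum 2x2 confusion matrix.  Because sampling is stratified by gray value
while the algorithm classifies by gray value, the raw cell proportions are
biased for the photo-wide probabilities; they are corrected with the *image
marginal proportions* ``W_k`` — the fraction of each stratum's population
the algorithm assigned to class k.  From the corrected cells come the
percentage correct (PC), the chance-corrected kappa, the reference-based gap
fraction, and the misestimation ratio of the picture-based gap fraction.

Conventions: confusion rows = reference (operator), columns = algorithm;
cell ``n_jk`` has reference class j and algorithm class k.  All overall
estimates are per-stratum values averaged with weights ``N_h / N`` (stratum
population over photo population), with normal-approximation 95% CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .image_io import GrayImage
from .thresholding import OUTSIDE, SKY, VEGETATION, BinaryMap

__all__ = [
    "StratifiedReferenceSample",
    "StratumConfusion",
    "AccuracyReport",
    "stratify_sample",
    "export_label_sheet",
    "load_labels",
    "confusion_by_stratum",
    "percentage_correct_stratum",
    "percentage_correct_overall",
    "kappa_stratum",
    "kappa_overall",
    "gap_fraction_reference",
    "misestimation",
    "assess",
]

logger = logging.getLogger(__name__)

LABEL_VEGETATION = "vegetation"
LABEL_SKY = "sky"
_VALID_LABELS = (LABEL_VEGETATION, LABEL_SKY)

#: z-quantile for the 95% normal-approximation confidence intervals.
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class StratifiedReferenceSample:
    """Reference pixels drawn by stratified random sampling over gray values.

    Attributes
    ----------
    strata
        Ordered inclusive gray-value ranges ``(lo, hi)`` partitioning [0, 255].
    population
        ``N_h`` — number of mask-true pixels of the source image per stratum.
    records
        One row per sampled pixel with columns ``x, y, gray, stratum, label``;
        ``label`` is ``vegetation``/``sky`` or missing before labelling.
    seed
        RNG seed the sample was drawn with (reproducibility).
    """

    strata: tuple[tuple[int, int], ...]
    population: np.ndarray
    records: pd.DataFrame
    seed: int
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        population = np.asarray(self.population, dtype=np.int64)
        if population.shape != (len(self.strata),):
            raise ValueError("population size vector does not match strata")
        records = self.records.reset_index(drop=True)
        required = {"x", "y", "gray", "stratum", "label"}
        if not required.issubset(records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        if records.duplicated(subset=["x", "y"]).any():
            raise ValueError("duplicate pixel coordinates in reference sample")
        for h, (lo, hi) in enumerate(self.strata):
            grays = records.loc[records["stratum"] == h, "gray"]
            if ((grays < lo) | (grays > hi)).any():
                raise ValueError(f"record gray value outside stratum {h} range [{lo},{hi}]")
        counts = self.sample_sizes
        if (counts > population).any():
            raise ValueError("stratum sample size exceeds its population")
        object.__setattr__(self, "population", population)
        object.__setattr__(self, "records", records)

    @property
    def n_strata(self) -> int:
        return len(self.strata)

    @property
    def sample_sizes(self) -> np.ndarray:
        """``n_h`` — sampled pixels per stratum (zeros included)."""
        counts = np.zeros(len(self.strata), dtype=np.int64)
        vc = self.records["stratum"].value_counts()
        counts[vc.index.to_numpy()] = vc.to_numpy()
        return counts

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def N(self) -> int:
        return int(self.population.sum())

    @property
    def is_labeled(self) -> bool:
        return self.records["label"].notna().all() and self.n > 0

    def with_labels(self, labels: Sequence[str]) -> "StratifiedReferenceSample":
        """Return a copy with per-record labels filled in (record order)."""
        labels = list(labels)
        if len(labels) != self.n:
            raise ValueError("one label per record required")
        bad = [lab for lab in labels if lab not in _VALID_LABELS]
        if bad:
            raise ValueError(f"unknown label token(s) {sorted(set(bad))}")
        records = self.records.copy()
        records["label"] = labels
        return StratifiedReferenceSample(
            strata=self.strata,
            population=self.population,
            records=records,
            seed=self.seed,
            warnings=self.warnings,
        )


def _strata_bounds(strata_width: int) -> tuple[tuple[int, int], ...]:
    if strata_width <= 0 or 256 % strata_width != 0:
        raise ValueError(f"strata width {strata_width} must divide 256")
    return tuple(
        (lo, lo + strata_width - 1) for lo in range(0, 256, strata_width)
    )


def stratify_sample(
    image: GrayImage,
    strata_width: int = 16,
    per_stratum: int = 24,
    seed: int = 0,
) -> StratifiedReferenceSample:
    """Draw an unlabeled stratified reference sample from an image.

    Within each gray-value stratum a simple random sample of
    ``min(per_stratum, N_h)`` mask-true pixels is drawn without replacement.
    With the default design (16 strata, 24 pixels each) a fully populated
    image yields 384 reference pixels.  Under-filled strata are recorded as
    warnings.
    """
    if per_stratum < 1:
        raise ValueError("per_stratum must be >= 1")
    strata = _strata_bounds(strata_width)
    rng = np.random.default_rng(seed)
    ys, xs = np.nonzero(image.mask)
    grays = image.values[ys, xs].astype(np.int64)
    stratum_of = grays // strata_width
    rows = []
    population = np.zeros(len(strata), dtype=np.int64)
    warns: list[str] = []
    for h in range(len(strata)):
        idx = np.flatnonzero(stratum_of == h)
        population[h] = idx.size
        take = min(per_stratum, idx.size)
        if take < per_stratum:
            warns.append(
                f"stratum {h} ({strata[h][0]}-{strata[h][1]}) has only "
                f"{idx.size} eligible pixels (< {per_stratum})"
            )
            logger.info(warns[-1])
        if take == 0:
            continue
        chosen = rng.choice(idx, size=take, replace=False)
        for i in chosen:
            rows.append((int(xs[i]), int(ys[i]), int(grays[i]), h))
    records = pd.DataFrame(rows, columns=["x", "y", "gray", "stratum"])
    records["label"] = pd.Series([pd.NA] * len(records), dtype="object")
    return StratifiedReferenceSample(
        strata=strata,
        population=population,
        records=records,
        seed=seed,
        warnings=tuple(warns),
    )


def export_label_sheet(
    sample: StratifiedReferenceSample,
    image: GrayImage,
    out_dir: str | Path,
    chip_radius: int = 10,
    zoom: int = 8,
) -> Path:
    """Write the labelling bundle an operator fills in.

    Produces ``sheet.csv`` (columns x, y, gray, stratum, label — label left
    empty) plus one magnified context chip PNG per record with the reference
    pixel marked in red, so the operator can judge position, blooming and
    reflection effects when labelling.  Chips that extend beyond the image
    border are zero-padded and flagged in the sheet.  Returns the sheet path.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    chips = out_dir / "chips"
    chips.mkdir(parents=True, exist_ok=True)
    sheet = sample.records.copy()
    sheet["label"] = ""
    padded_flags = []
    r = int(chip_radius)
    for i, rec in sample.records.iterrows():
        x, y = int(rec["x"]), int(rec["y"])
        y0, y1 = y - r, y + r + 1
        x0, x1 = x - r, x + r + 1
        padded = y0 < 0 or x0 < 0 or y1 > image.height or x1 > image.width
        chip = np.zeros((2 * r + 1, 2 * r + 1), dtype=np.uint8)
        sy0, sx0 = max(y0, 0), max(x0, 0)
        sy1, sx1 = min(y1, image.height), min(x1, image.width)
        chip[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image.values[sy0:sy1, sx0:sx1]
        rgb = np.repeat(chip[:, :, None], 3, axis=2)
        rgb[r, r] = (255, 0, 0)  # mark the reference pixel
        rgb = np.kron(rgb, np.ones((zoom, zoom, 1), dtype=np.uint8))
        iio.imwrite(chips / f"chip_{i:04d}.png", rgb)
        padded_flags.append(padded)
    sheet["chip_padded"] = padded_flags
    sheet_path = out_dir / "sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    return sheet_path


def load_labels(
    sheet: str | Path | pd.DataFrame, sample: StratifiedReferenceSample
) -> StratifiedReferenceSample:
    """Attach operator labels from a filled-in sheet to a sample.

    Rows are keyed by ``(x, y)`` so the operator may reorder them; every
    record must carry a ``vegetation`` or ``sky`` label.
    """
    if isinstance(sheet, pd.DataFrame):
        table = sheet.copy()
    else:
        table = pd.read_csv(sheet)
    if not {"x", "y", "label"}.issubset(table.columns):
        raise ValueError("label sheet needs columns x, y, label")
    table["label"] = table["label"].astype("object")
    empty = table["label"].isna() | (table["label"].astype(str).str.strip() == "")
    if empty.all():
        raise ValueError("unlabeled records: the sheet has not been filled in")
    if empty.any():
        rows = table.index[empty].tolist()
        raise ValueError(f"unlabeled records at sheet rows {rows}")
    bad = ~table["label"].isin(_VALID_LABELS)
    if bad.any():
        row = int(table.index[bad][0])
        raise ValueError(
            f"unknown label {table.loc[row, 'label']!r} at sheet row {row}; "
            f"expected one of {_VALID_LABELS}"
        )
    if table.duplicated(subset=["x", "y"]).any():
        raise ValueError("duplicate coordinates in label sheet")
    keyed = table.set_index(["x", "y"])["label"]
    sample_keys = list(zip(sample.records["x"], sample.records["y"]))
    missing = [k for k in sample_keys if k not in keyed.index]
    if missing or len(keyed) != len(sample_keys):
        raise ValueError("label sheet coordinates do not match the sample")
    labels = [keyed[k] for k in sample_keys]
    labeled = sample.with_labels(labels)
    for h in range(labeled.n_strata):
        sub = labeled.records[labeled.records["stratum"] == h]
        if len(sub):
            logger.info(
                "stratum %d labels: %d vegetation, %d sky",
                h,
                int((sub["label"] == LABEL_VEGETATION).sum()),
                int((sub["label"] == LABEL_SKY).sum()),
            )
    return labeled


@dataclass(frozen=True)
class StratumConfusion:
    """2x2 confusion cells of one stratum plus its image marginal proportions.

    Cell subscripts: first = reference (operator) class, second = algorithm
    class; e.g. ``n_vs`` counts sampled pixels the operator called vegetation
    but the algorithm called sky.  ``w_v`` and ``w_s`` are the fractions of
    the stratum's *population* (all ``N_h`` pixels, not the sample) the
    algorithm classified vegetation resp. sky.
    """

    h: int
    n_vv: int
    n_vs: int
    n_sv: int
    n_ss: int
    w_v: float
    w_s: float
    N_h: int
    n_h: int

    def __post_init__(self) -> None:
        if self.n_vv + self.n_vs + self.n_sv + self.n_ss != self.n_h:
            raise ValueError("confusion cells do not sum to the stratum sample size")
        if not np.isclose(self.w_v + self.w_s, 1.0):
            raise ValueError("image marginal proportions must sum to 1")


def confusion_by_stratum(
    sample: StratifiedReferenceSample,
    binary: BinaryMap,
    image: GrayImage,
) -> list[StratumConfusion]:
    """Cross-tabulate operator labels against the algorithm's classes.

    Returns one :class:`StratumConfusion` per stratum with a nonzero
    population; ``W`` marginals are computed over the full stratum population
    from ``binary``, never from the sample.
    """
    if not sample.is_labeled:
        raise ValueError("sample must be fully labeled before building confusions")
    if binary.classes.shape != image.values.shape:
        raise ValueError("binary map and image dimensions differ")
    ys, xs = np.nonzero(image.mask)
    grays = image.values[ys, xs].astype(np.int64)
    pop_classes = binary.classes[ys, xs]
    width = sample.strata[0][1] - sample.strata[0][0] + 1
    stratum_of = grays // width
    out: list[StratumConfusion] = []
    n_h = sample.sample_sizes
    for h, (lo, hi) in enumerate(sample.strata):
        N_h = int(sample.population[h])
        if N_h == 0:
            continue
        in_h = stratum_of == h
        n_veg_pop = int((pop_classes[in_h] == VEGETATION).sum())
        w_v = n_veg_pop / N_h
        sub = sample.records[sample.records["stratum"] == h]
        algo = binary.classes[sub["y"].to_numpy(), sub["x"].to_numpy()]
        if (algo == OUTSIDE).any():
            raise ValueError(f"sampled pixel in stratum {h} falls outside the mask")
        ref_veg = (sub["label"] == LABEL_VEGETATION).to_numpy()
        algo_veg = algo == VEGETATION
        out.append(
            StratumConfusion(
                h=h,
                n_vv=int((ref_veg & algo_veg).sum()),
                n_vs=int((ref_veg & ~algo_veg).sum()),
                n_sv=int((~ref_veg & algo_veg).sum()),
                n_ss=int((~ref_veg & ~algo_veg).sum()),
                w_v=w_v,
                w_s=1.0 - w_v,
                N_h=N_h,
                n_h=int(n_h[h]),
            )
        )
    return out


def _corrected_cells(c: StratumConfusion) -> np.ndarray:
    """Bias-corrected cell proportions p_jk = W_k * n_jk / n_.k (0/0 -> 0).

    Rows = reference class (vegetation, sky), columns = algorithm class.
    Scaling each algorithm-class column to its image marginal proportion
    undoes the gray-value stratification's distortion of class prevalences.
    """
    cells = np.array([[c.n_vv, c.n_vs], [c.n_sv, c.n_ss]], dtype=np.float64)
    col_tot = cells.sum(axis=0)
    w = np.array([c.w_v, c.w_s])
    p = np.zeros((2, 2))
    for k in range(2):
        if col_tot[k] > 0:
            p[:, k] = w[k] * cells[:, k] / col_tot[k]
        # col_tot == 0: no sampled pixel of algorithm class k; its cells
        # contribute nothing (exact when W_k == 0, conservative otherwise).
    return p


def percentage_correct_stratum(c: StratumConfusion) -> tuple[float, float]:
    """Bias-corrected percentage correct of one stratum, with its variance.

    ``PC_h = W_V * n_VV/n_.V + W_S * n_SS/n_.S``; the variance is the
    stratified binomial form ``sum_k W_k^2 * q_k (1-q_k) / max(n_.k - 1, 1)``
    with ``q_k = n_kk / n_.k``.
    """
    if c.n_h <= 0:
        raise ValueError("empty stratum sample")
    cells = np.array([[c.n_vv, c.n_vs], [c.n_sv, c.n_ss]], dtype=np.float64)
    col_tot = cells.sum(axis=0)
    w = np.array([c.w_v, c.w_s])
    pc = 0.0
    var = 0.0
    for k in range(2):
        if col_tot[k] == 0:
            continue
        q = cells[k, k] / col_tot[k]
        pc += w[k] * q
        var += w[k] ** 2 * q * (1.0 - q) / max(col_tot[k] - 1.0, 1.0)
    return float(pc), float(var)


def kappa_stratum(c: StratumConfusion) -> tuple[float, float, bool]:
    """Chance-corrected agreement (kappa) of one stratum.

    Built from the bias-corrected cell proportions: observed agreement
    ``p_o`` is the corrected diagonal sum, expected agreement ``p_e`` the
    product-marginal sum.  Returns ``(kappa, variance, degenerate)``; a
    single-class stratum (``p_e = 1``) is degenerate and reported as
    kappa = 0 with zero variance.  The variance is the delta-method
    (Congalton & Green) large-sample form over the corrected proportions,
    divided by the stratum sample size.
    """
    if c.n_h <= 0:
        raise ValueError("empty stratum sample")
    p = _corrected_cells(c)
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if 1.0 - pe < 1e-12:
        return 0.0, 0.0, True
    kappa = (po - pe) / (1.0 - pe)
    theta1, theta2 = po, pe
    theta3 = float(sum(p[i, i] * (row[i] + col[i]) for i in range(2)))
    theta4 = float(
        sum(p[i, j] * (row[j] + col[i]) ** 2 for i in range(2) for j in range(2))
    )
    d = 1.0 - theta2
    var = (
        theta1 * (1.0 - theta1) / d**2
        + 2.0 * (1.0 - theta1) * (2.0 * theta1 * theta2 - theta3) / d**3
        + (1.0 - theta1) ** 2 * (theta4 - 4.0 * theta2**2) / d**4
    ) / c.n_h
    return float(kappa), float(max(var, 0.0)), False


def _weighted_overall(
    estimates: Sequence[float],
    variances: Sequence[float],
    weights: Sequence[float],
) -> tuple[float, float, tuple[float, float]]:
    weights = np.asarray(weights, dtype=np.float64)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError(f"stratum weights sum to {weights.sum()}, expected 1")
    est = np.asarray(estimates, dtype=np.float64)
    var = np.asarray(variances, dtype=np.float64)
    if est.shape != weights.shape or var.shape != weights.shape:
        raise ValueError("per-stratum vectors and weights differ in length")
    overall = float(weights @ est)
    overall_var = float(weights**2 @ var)
    half = _Z95 * np.sqrt(overall_var)
    return overall, overall_var, (overall - half, overall + half)


def percentage_correct_overall(
    per_strata: Sequence[tuple[float, float]], weights: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Population-weighted overall PC with variance and 95% CI."""
    est = [pc for pc, _ in per_strata]
    var = [v for _, v in per_strata]
    return _weighted_overall(est, var, weights)


def kappa_overall(
    per_strata: Sequence[tuple[float, float]], weights: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Population-weighted overall kappa with variance and 95% CI."""
    est = [k for k, _ in per_strata]
    var = [v for _, v in per_strata]
    return _weighted_overall(est, var, weights)


def gap_fraction_reference(sample: StratifiedReferenceSample) -> float:
    """Gap fraction estimated from the operator-labeled reference pixels.

    ``GF_ref = sum_h (N_h / N) * (s_h / n_h)`` with ``s_h`` the sky-labeled
    records of stratum h — the design-unbiased stratified estimator of the
    photo's true sky proportion.  Empty-population strata contribute 0.
    """
    if not sample.is_labeled:
        raise ValueError("sample must be fully labeled")
    n_h = sample.sample_sizes
    N = sample.N
    gf = 0.0
    for h in range(sample.n_strata):
        if sample.population[h] == 0 or n_h[h] == 0:
            continue
        sub = sample.records[sample.records["stratum"] == h]
        s_h = int((sub["label"] == LABEL_SKY).sum())
        gf += (sample.population[h] / N) * (s_h / n_h[h])
    return float(gf)


def misestimation(gf_pic: float, gf_ref: float) -> float:
    """Gap-fraction misestimation ratio ``GF_pic / GF_ref`` (1.0 = unbiased)."""
    if gf_ref <= 0:
        raise ValueError("reference gap fraction is zero; misestimation undefined")
    return gf_pic / gf_ref


@dataclass(frozen=True)
class AccuracyReport:
    """Full accuracy assessment of one binarization against one labeled sample."""

    method: str
    per_stratum: pd.DataFrame
    pc: float
    pc_var: float
    pc_ci: tuple[float, float]
    kappa: float
    kappa_var: float
    kappa_ci: tuple[float, float]
    gf_pic: float
    gf_ref: float
    misestimation: float
    degenerate_strata: tuple[int, ...]

    def to_json_dict(self) -> dict:
        return {
            "method": self.method,
            "pc": self.pc,
            "pc_ci": list(self.pc_ci),
            "kappa": self.kappa,
            "kappa_ci": list(self.kappa_ci),
            "gf_pic": self.gf_pic,
            "gf_ref": self.gf_ref,
            "misestimation": self.misestimation,
            "degenerate_strata": list(self.degenerate_strata),
        }

    def to_csv(self, path: str | Path) -> None:
        rows = self.per_stratum.copy()
        overall = pd.DataFrame(
            [
                {
                    "stratum": "overall",
                    "pc": self.pc,
                    "pc_var": self.pc_var,
                    "kappa": self.kappa,
                    "kappa_var": self.kappa_var,
                }
            ]
        )
        pd.concat([rows, overall], ignore_index=True).to_csv(path, index=False)


def assess(
    image: GrayImage,
    binary: BinaryMap,
    sample: StratifiedReferenceSample,
    method: str = "unknown",
) -> AccuracyReport:
    """Run the whole evaluation protocol for one binarization.

    Builds per-stratum confusions, bias-corrected PC and kappa with their
    weighted overall estimates and 95% CIs, both gap fractions and the
    misestimation ratio.
    """
    from .thresholding import gap_fraction_picture

    confusions = confusion_by_stratum(sample, binary, image)
    weights = np.array([c.N_h for c in confusions], dtype=np.float64)
    weights /= weights.sum()
    pc_parts = [percentage_correct_stratum(c) for c in confusions]
    kappa_parts_full = [kappa_stratum(c) for c in confusions]
    kappa_parts = [(k, v) for k, v, _ in kappa_parts_full]
    degenerate = tuple(
        c.h for c, (_, _, deg) in zip(confusions, kappa_parts_full) if deg
    )
    for h in degenerate:
        logger.info("stratum %d is single-class; kappa reported as 0", h)
    pc, pc_var, pc_ci = percentage_correct_overall(pc_parts, weights)
    kap, kap_var, kap_ci = kappa_overall(kappa_parts, weights)
    gf_pic = gap_fraction_picture(binary)
    gf_ref = gap_fraction_reference(sample)
    per_stratum = pd.DataFrame(
        {
            "stratum": [c.h for c in confusions],
            "gray_lo": [sample.strata[c.h][0] for c in confusions],
            "gray_hi": [sample.strata[c.h][1] for c in confusions],
            "N_h": [c.N_h for c in confusions],
            "n_h": [c.n_h for c in confusions],
            "n_vv": [c.n_vv for c in confusions],
            "n_vs": [c.n_vs for c in confusions],
            "n_sv": [c.n_sv for c in confusions],
            "n_ss": [c.n_ss for c in confusions],
            "w_v": [c.w_v for c in confusions],
            "pc": [p for p, _ in pc_parts],
            "pc_var": [v for _, v in pc_parts],
            "kappa": [k for k, _ in kappa_parts],
            "kappa_var": [v for _, v in kappa_parts],
        }
    )
    return AccuracyReport(
        method=method,
        per_stratum=per_stratum,
        pc=pc,
        pc_var=pc_var,
        pc_ci=pc_ci,
        kappa=kap,
        kappa_var=kap_var,
        kappa_ci=kap_ci,
        gf_pic=gf_pic,
        gf_ref=gf_ref,
        misestimation=misestimation(gf_pic, gf_ref),
        degenerate_strata=degenerate,
    )
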