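"""Synthetic hemispherical-photo scenes with per-pixel ground truth.

Real canopy photos cannot serve as a census oracle because the true class of
every pixel is unknown; this module generates scenes where it is known.  The
generator reproduces the gray-value phenomenology the threshold algorithms
respond to on the blue plane:

* a bimodal gray-value distribution (dark foliage mode, bright sky mode,
  each approximately normal),
* a zenith-to-horizon brightness gradient (sky is brightest overhead),
* mixed pixels along vegetation/sky boundaries whose value is a convex blend
  of the two class distributions,
* exposure handling — ``histogram`` exposure scales the brightest scene
  element to gray value 255 with no clipping, while ``auto`` exposure adds a
  brightness excess and clips at 255, producing the saturated-sky spike of
  overexposed photos,
* blooming, where saturated sky raises the recorded values of nearby
  vegetation pixels without changing what they actually are.

Ground truth is a procedural smoothed random field, not a radiative canopy
model; it reproduces the statistical features above, not leaf optics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter

from .image_io import GrayImage
from .thresholding import OUTSIDE, SKY, VEGETATION, BinaryMap

__all__ = [
    "SceneParams",
    "TruthMap",
    "SyntheticScene",
    "CensusMetrics",
    "generate_truth",
    "render",
    "apply_blooming",
    "generate_scene",
    "census_metrics",
    "label_sample_from_truth",
    "save_scene",
    "load_scene",
]


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters of a synthetic canopy scene.

    Defaults describe a closed-canopy photo on the blue plane: dark foliage
    (mean 40), bright sky (mean 200) well separated from it, a 30-gray-level
    zenith-to-horizon gradient, 5% mixed boundary pixels, and clean
    histogram exposure.  ``exposure="auto"`` with ``clip_excess=60`` instead
    emulates the typical auto-exposed photo whose sky saturates at 255.
    """

    width: int = 512
    height: int = 512
    canopy_cover: float = 0.7
    structure_scale: float = 8.0
    mixed_fraction_target: float = 0.05
    mu_veg: float = 40.0
    sigma_veg: float = 12.0
    mu_sky: float = 200.0
    sigma_sky: float = 18.0
    zenith_gradient: float = 30.0
    exposure: str = "histogram"
    clip_excess: float = 60.0
    blooming_radius: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.canopy_cover <= 1.0:
            raise ValueError("canopy_cover must lie in [0, 1]")
        if self.mu_sky <= self.mu_veg:
            raise ValueError("mu_sky must exceed mu_veg (blue-plane contrast)")
        if self.sigma_veg < 0 or self.sigma_sky < 0:
            raise ValueError("sigmas must be non-negative")
        if not 0.0 <= self.mixed_fraction_target <= 1.0:
            raise ValueError("mixed_fraction_target must lie in [0, 1]")
        if self.exposure not in ("histogram", "auto"):
            raise ValueError("exposure must be 'histogram' or 'auto'")
        if self.width < 2 or self.height < 2:
            raise ValueError("scene must be at least 2x2")
        if self.blooming_radius < 0:
            raise ValueError("blooming_radius must be >= 0")


@dataclass(frozen=True)
class TruthMap:
    """Per-pixel ground truth: vegetation fraction alpha in [0, 1].

    ``alpha == 1`` is pure vegetation, ``alpha == 0`` pure sky, anything in
    between a mixed pixel covering both.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=np.float64)
        if alpha.ndim != 2:
            raise ValueError("truth map must be 2-D")
        if alpha.size and (alpha.min() < 0 or alpha.max() > 1):
            raise ValueError("alpha outside [0, 1]")
        object.__setattr__(self, "alpha", alpha)

    @property
    def is_vegetation(self) -> np.ndarray:
        return self.alpha == 1.0

    @property
    def is_sky(self) -> np.ndarray:
        return self.alpha == 0.0

    @property
    def is_mixed(self) -> np.ndarray:
        return (self.alpha > 0.0) & (self.alpha < 1.0)

    def classes(self, alpha_rule: str = "half") -> np.ndarray:
        """Collapse mixed pixels to the binary truth used for census scoring.

        ``half``: mixed pixels with alpha >= 0.5 count as vegetation.
        ``exclude``: mixed pixels are dropped (returned as :data:`OUTSIDE`).
        """
        if alpha_rule == "half":
            return np.where(self.alpha >= 0.5, VEGETATION, SKY).astype(np.int8)
        if alpha_rule == "exclude":
            cls = np.where(self.alpha >= 0.5, VEGETATION, SKY).astype(np.int8)
            cls[self.is_mixed] = OUTSIDE
            return cls
        raise ValueError("alpha_rule must be 'half' or 'exclude'")


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene together with its ground truth and parameters."""

    truth: TruthMap
    image: GrayImage
    params: SceneParams


def generate_truth(params: SceneParams) -> TruthMap:
    """Procedural ground truth: thresholded smoothed noise plus mixed edges.

    A Gaussian-smoothed white-noise field is thresholded at the quantile
    giving ``canopy_cover`` vegetation; 4-neighbor boundary pixels are then
    converted to mixed pixels with uniform alpha until
    ``mixed_fraction_target`` of all pixels is reached (or the boundary is
    exhausted).  Fully deterministic under ``params.seed``.
    """
    degenerate = params.canopy_cover in (0.0, 1.0)
    if degenerate and params.mixed_fraction_target > 0:
        raise ValueError(
            "a single-class scene (cover 0 or 1) has no boundary to mix; "
            "set mixed_fraction_target=0"
        )
    rng = np.random.default_rng([params.seed, 0])
    shape = (params.height, params.width)
    if degenerate:
        alpha = np.full(shape, 1.0 if params.canopy_cover == 1.0 else 0.0)
        return TruthMap(alpha=alpha)
    field_ = gaussian_filter(
        rng.standard_normal(shape), sigma=params.structure_scale, mode="reflect"
    )
    cut = np.quantile(field_, params.canopy_cover)
    veg = field_ <= cut
    alpha = veg.astype(np.float64)
    if params.mixed_fraction_target > 0:
        boundary = np.zeros(shape, dtype=bool)
        boundary[:, :-1] |= veg[:, :-1] != veg[:, 1:]
        boundary[:, 1:] |= veg[:, :-1] != veg[:, 1:]
        boundary[:-1, :] |= veg[:-1, :] != veg[1:, :]
        boundary[1:, :] |= veg[:-1, :] != veg[1:, :]
        cand = np.flatnonzero(boundary)
        want = round(params.mixed_fraction_target * alpha.size)
        take = min(want, cand.size)
        if take > 0:
            chosen = rng.choice(cand, size=take, replace=False)
            # uniform on the open interval so mixed pixels are never pure
            mix = rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=take)
            alpha.ravel()[chosen] = mix
    return TruthMap(alpha=alpha)


def render(truth: TruthMap, params: SceneParams) -> GrayImage:
    """Render a truth map into an 8-bit gray image.

    Each pixel draws a vegetation value V ~ N(mu_veg, sigma_veg) and a sky
    value S ~ N(mu_sky, sigma_sky) and records ``alpha*V + (1-alpha)*S``; a
    radial brightness gradient peaking at the zenith (image center) is
    added.  ``histogram`` exposure rescales so the brightest pixel lands
    exactly on 255 with no clipped mass; ``auto`` exposure adds
    ``clip_excess`` gray levels before clamping, saturating part of the sky.
    """
    rng = np.random.default_rng([params.seed, 1])
    shape = truth.alpha.shape
    v = rng.normal(params.mu_veg, params.sigma_veg, size=shape)
    s = rng.normal(params.mu_sky, params.sigma_sky, size=shape)
    img = truth.alpha * v + (1.0 - truth.alpha) * s
    if params.zenith_gradient != 0:
        cy = (shape[0] - 1) / 2.0
        cx = (shape[1] - 1) / 2.0
        yy, xx = np.ogrid[0 : shape[0], 0 : shape[1]]
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        d_max = d.max()
        if d_max > 0:
            img = img + params.zenith_gradient * (1.0 - d / d_max)
    if params.exposure == "histogram":
        peak = img.max()
        if peak > 0:
            img = img * (255.0 / peak)
    else:  # auto
        img = img + params.clip_excess
    values = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return GrayImage(values=values)


def apply_blooming(
    image: GrayImage, truth: TruthMap, radius: float
) -> GrayImage:
    """Brighten vegetation near saturated sky (blooming artifact).

    Vegetation and mixed pixels within ``radius`` of a saturated (gray 255)
    pixel are raised toward 255 with a linearly distance-decaying weight
    ``1 - d / (radius + 1)``.  The truth map is untouched: blooming corrupts
    recorded gray values, not what the pixel actually shows — a bloomed
    vegetation pixel is still vegetation in the reference.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return image
    saturated = image.values == 255
    if not saturated.any():
        return image
    dist = distance_transform_edt(~saturated)
    affected = (truth.alpha > 0.0) & (dist > 0) & (dist <= radius)
    if not affected.any():
        return image
    weight = np.clip(1.0 - dist / (radius + 1.0), 0.0, 1.0)
    vals = image.values.astype(np.float64)
    vals[affected] += (255.0 - vals[affected]) * weight[affected]
    values = np.clip(np.rint(vals), 0, 255).astype(np.uint8)
    return GrayImage(values=values, mask=image.mask)


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Full generate -> render -> bloom chain, deterministic under the seed."""
    truth = generate_truth(params)
    image = render(truth, params)
    image = apply_blooming(image, truth, params.blooming_radius)
    return SyntheticScene(truth=truth, image=image, params=params)


@dataclass(frozen=True)
class CensusMetrics:
    """Full-population accuracy of a binarization against ground truth.

    ``gf_truth`` is the census sky proportion of the truth map (the quantity
    a reference sample estimates); ``gf_pic`` the sky proportion of the
    binarization; ``n`` the number of pixels scored.
    """

    pc: float
    kappa: float
    gf_truth: float
    gf_pic: float
    n: int


def census_metrics(
    truth: TruthMap, binary: BinaryMap, alpha_rule: str = "half"
) -> CensusMetrics:
    """Score a binarization against every pixel of the ground truth.

    ``alpha_rule="half"`` assigns mixed pixels to vegetation when their
    vegetation fraction is at least one half; ``"exclude"`` drops mixed
    pixels from the census entirely.  Pixels outside the binary map's mask
    are never scored.
    """
    if truth.alpha.shape != binary.classes.shape:
        raise ValueError("truth and binary map dimensions differ")
    ref = truth.classes(alpha_rule=alpha_rule)
    scored = (ref != OUTSIDE) & (binary.classes != OUTSIDE)
    if not scored.any():
        raise ValueError("no pixels left to score")
    r = ref[scored]
    a = binary.classes[scored]
    n = int(scored.sum())
    pc = float((r == a).mean())
    # census Cohen kappa from the full 2x2 population table
    p_rv = float((r == VEGETATION).mean())
    p_av = float((a == VEGETATION).mean())
    pe = p_rv * p_av + (1.0 - p_rv) * (1.0 - p_av)
    kappa = 0.0 if 1.0 - pe < 1e-12 else (pc - pe) / (1.0 - pe)
    gf_truth = float((r == SKY).mean())
    gf_pic = float((a == SKY).mean())
    return CensusMetrics(pc=pc, kappa=kappa, gf_truth=gf_truth, gf_pic=gf_pic, n=n)


def label_sample_from_truth(sample, truth: TruthMap, alpha_rule: str = "half"):
    """Label a reference sample from ground truth (a perfect operator).

    Stands in for the human operator when evaluating the estimators on
    synthetic scenes; real photos require :func:`hemibin.accuracy.load_labels`.
    """
    from .accuracy import LABEL_SKY, LABEL_VEGETATION

    ref = truth.classes(alpha_rule=alpha_rule)
    xs = sample.records["x"].to_numpy()
    ys = sample.records["y"].to_numpy()
    cls = ref[ys, xs]
    if (cls == OUTSIDE).any():
        raise ValueError(
            "alpha_rule='exclude' dropped a sampled mixed pixel; "
            "use alpha_rule='half' for sampled references"
        )
    labels = [LABEL_VEGETATION if c == VEGETATION else LABEL_SKY for c in cls]
    return sample.with_labels(labels)


def save_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write image.png, truth.png (alpha quantized to 8-bit) and params.json."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / "image.png",
        "truth": out_dir / "truth.png",
        "params": out_dir / "params.json",
    }
    iio.imwrite(paths["image"], scene.image.values)
    truth8 = np.rint(scene.truth.alpha * 255.0).astype(np.uint8)
    iio.imwrite(paths["truth"], truth8)
    paths["params"].write_text(
        json.dumps(
            {"params": asdict(scene.params), "truth_encoding": "alpha*255"},
            indent=2,
        )
        + "\n"
    )
    return paths


def load_scene(out_dir: str | Path) -> SyntheticScene:
    """Reload a scene bundle written by :func:`save_scene` (alpha at 8-bit)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "params.json").read_text())
    params = SceneParams(**meta["params"])
    image = GrayImage(values=np.asarray(iio.imread(out_dir / "image.png")))
    alpha = np.asarray(iio.imread(out_dir / "truth.png")).astype(np.float64) / 255.0
    return SyntheticScene(truth=TruthMap(alpha=alpha), image=image, params=params)
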