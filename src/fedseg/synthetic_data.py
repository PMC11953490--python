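"""Multi-site synthetic binary-segmentation data with controlled heterogeneity.

Each site draws images of a single bright organ-like structure (an ellipse or
an irregular star-convex blob) on a noisy background. Non-IID behaviour across
sites is induced two ways, mirroring what multi-center MRI/CT cohorts exhibit:

* feature shift — per-site foreground intensity and background offset differ,
  so pixel-intensity marginals are measurably different between sites;
* quantity skew — per-site sample counts differ (packaged fixtures follow the
  published six-site prostate counts and eight-site cervical counts).

Images are min-max normalized to [0, 1] per sample before entering the
network; training-split samples may additionally be augmented with small
rotations, horizontal flips and random crops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from ._utils import derive_seed

__all__ = [
    "SiteProfile",
    "Sample",
    "SplitDataset",
    "AugmentConfig",
    "generate_site",
    "normalize_sample",
    "augment",
    "split_dataset",
    "build_fixture",
    "make_site_dataset",
    "save_site_png",
    "save_site_nifti",
    "write_manifest",
    "PROSTATE_SITE_COUNTS",
    "CERVICAL_SITE_COUNTS",
    "TOY4_SITE_COUNTS",
]

# Published per-site sample counts used by the packaged fixtures.
PROSTATE_SITE_COUNTS = (421, 384, 468, 175, 261, 158)
CERVICAL_SITE_COUNTS = (255, 219, 197, 129, 41, 43, 76, 73)
TOY4_SITE_COUNTS = (60, 50, 30, 20)


@dataclass(frozen=True)
class SiteProfile:
    """Generative parameters for one site (pre-normalization intensities)."""

    site_id: int
    n_k: int
    intensity_mean: float
    intensity_shift: float
    noise_sd: float = 0.04
    shape_family: str = "ellipse"
    size_range: tuple[float, float] = (8.0, 16.0)
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0
    # Scanner-like contrast nonlinearity (power law applied to the raw
    # intensities). Unlike a mean offset, it survives per-sample min-max
    # normalization, so sites keep distinct pixel marginals afterwards.
    contrast_gamma: float = 1.0

    def __post_init__(self):
        if self.n_k < 1:
            raise ValueError("n_k must be >= 1")
        if self.shape_family not in ("ellipse", "blob"):
            raise ValueError("shape_family must be 'ellipse' or 'blob'")
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ValueError("degenerate size_range")


@dataclass
class Sample:
    """One image/mask pair; image float, mask in {0, 1}."""

    image: np.ndarray
    mask: np.ndarray


@dataclass
class SplitDataset:
    """Disjoint train/val/test lists of samples for one site."""

    train: list[Sample]
    val: list[Sample]
    test: list[Sample]

    @property
    def n_train(self) -> int:
        return len(self.train)


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation: small rotations, flips, optional crop."""

    rotate_deg: float = 10.0
    flip_prob: float = 0.5
    crop: int | None = None


def _shape_mask(rng: np.random.Generator, profile: SiteProfile) -> np.ndarray:
    h, w = profile.image_size
    lo, hi = profile.size_range
    ry = rng.uniform(lo, hi)
    rx = rng.uniform(lo, hi)
    margin = hi + 1
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    theta = rng.uniform(0, math.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    if profile.shape_family == "ellipse":
        return ((u / rx) ** 2 + (v / ry) ** 2 <= 1.0).astype(np.uint8)
    # star-convex blob: ellipse radius modulated by low-order harmonics
    a1, a2 = rng.uniform(0.05, 0.2, size=2)
    p1, p2 = rng.uniform(0, 2 * math.pi, size=2)
    phi = np.arctan2(v / ry, u / rx)
    radial = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    bound = 1.0 + a1 * np.sin(3 * phi + p1) + a2 * np.sin(5 * phi + p2)
    return (radial <= bound).astype(np.uint8)


def generate_site(profile: SiteProfile) -> list[Sample]:
    """Draw the site's raw (pre-normalization) samples, fully seeded.

    Background pixels are ``intensity_shift`` plus Gaussian noise; foreground
    pixels are ``intensity_mean`` plus Gaussian noise; the mask is the shape
    support and is nonempty by construction.
    """
    rng = np.random.default_rng(profile.seed)
    h, w = profile.image_size
    samples = []
    for _ in range(profile.n_k):
        mask = _shape_mask(rng, profile)
        image = profile.intensity_shift + rng.normal(0.0, profile.noise_sd, (h, w))
        fg = profile.intensity_mean + rng.normal(0.0, profile.noise_sd, (h, w))
        image = np.where(mask > 0, fg, image)
        if profile.contrast_gamma != 1.0:
            image = np.clip(image, 0.0, None) ** profile.contrast_gamma
        samples.append(Sample(image=image.astype(np.float64), mask=mask))
    return samples


def normalize_sample(image: np.ndarray) -> np.ndarray:
    """Per-sample min-max rescaling to [0, 1]; constant images map to zeros."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def augment(sample: Sample, rng: np.random.Generator,
            cfg: AugmentConfig = AugmentConfig()) -> Sample:
    """Random rotation, horizontal flip, optional crop-and-resize-back.

    Image and mask receive identical geometric transforms (bilinear vs nearest
    interpolation); the mask is re-binarized after interpolation.
    """
    image = np.asarray(sample.image, dtype=np.float64)
    mask = np.asarray(sample.mask)
    angle = float(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
    if angle != 0.0:
        image = ndimage.rotate(image, angle, reshape=False, order=1, mode="nearest")
        mask = ndimage.rotate(mask.astype(np.float64), angle, reshape=False,
                              order=0, mode="constant")
    if rng.random() < cfg.flip_prob:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if cfg.crop is not None:
        h, w = image.shape
        c = int(cfg.crop)
        if c > h or c > w:
            raise ValueError(f"crop {c} larger than image {h}x{w}")
        top = int(rng.integers(0, h - c + 1))
        left = int(rng.integers(0, w - c + 1))
        ci = image[top:top + c, left:left + c]
        cm = mask[top:top + c, left:left + c]
        if c != h or c != w:
            from skimage.transform import resize

            image = resize(ci, (h, w), order=1, preserve_range=True,
                           anti_aliasing=False)
            mask = resize(cm.astype(np.float64), (h, w), order=0,
                          preserve_range=True, anti_aliasing=False)
        else:
            image, mask = ci, cm
    return Sample(image=np.ascontiguousarray(image),
                  mask=(np.asarray(mask, dtype=np.float64) > 0.5).astype(np.uint8))


def split_dataset(samples: list[Sample], ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> SplitDataset:
    """Shuffle and split: floor(n * val), floor(n * test), remainder to train."""
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    n_val = int(math.floor(ratios[1] * n))
    n_test = int(math.floor(ratios[2] * n))
    perm = np.random.default_rng(seed).permutation(n)
    val = [samples[i] for i in perm[:n_val]]
    test = [samples[i] for i in perm[n_val:n_val + n_test]]
    train = [samples[i] for i in perm[n_val + n_test:]]
    return SplitDataset(train=train, val=val, test=test)


# Per-site generative parameters spread so that intensity marginals differ
# (feature shift) on top of the count skew.
_SITE_PARAM_CYCLE = [
    # (foreground mean, background offset, noise sd, contrast gamma, family,
    #  shape-size factor)
    (0.82, 0.20, 0.04, 0.55, "ellipse", 1.00),
    (0.60, 0.38, 0.05, 1.60, "blob", 0.80),
    (0.72, 0.28, 0.03, 1.00, "ellipse", 1.25),
    (0.90, 0.12, 0.05, 2.20, "blob", 0.90),
    (0.66, 0.44, 0.04, 0.75, "ellipse", 1.10),
    (0.78, 0.16, 0.06, 1.30, "blob", 0.75),
    (0.58, 0.34, 0.03, 0.90, "ellipse", 1.30),
    (0.86, 0.24, 0.05, 1.80, "blob", 0.95),
]


def build_fixture(name: str, base_seed: int = 0,
                  image_size: tuple[int, int] = (64, 64)) -> list[SiteProfile]:
    """Packaged multi-site fixtures.

    ``prostate_counts``: six sites with the published per-site sample counts;
    ``cervical_counts``: eight sites with the published counts (total 1033);
    ``toy4``: four small sites (60/50/30/20) for desk-scale experiments.
    """
    counts = {
        "prostate_counts": PROSTATE_SITE_COUNTS,
        "cervical_counts": CERVICAL_SITE_COUNTS,
        "toy4": TOY4_SITE_COUNTS,
    }.get(name)
    if counts is None:
        raise ValueError(f"unknown fixture {name!r}")
    h = min(image_size)
    profiles = []
    for k, n_k in enumerate(counts):
        mean, shift, sd, gamma, family, size_factor = _SITE_PARAM_CYCLE[
            k % len(_SITE_PARAM_CYCLE)
        ]
        profiles.append(SiteProfile(
            site_id=k,
            n_k=n_k,
            intensity_mean=mean,
            intensity_shift=shift,
            noise_sd=sd,
            shape_family=family,
            size_range=(h * 0.12 * size_factor, h * 0.25 * size_factor),
            image_size=image_size,
            seed=derive_seed(base_seed, "site", k),
            contrast_gamma=gamma,
        ))
    return profiles


def make_site_dataset(profile: SiteProfile,
                      ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)) -> SplitDataset:
    """Generate, normalize, and split one site's dataset."""
    raw = generate_site(profile)
    normalized = [
        Sample(image=normalize_sample(s.image).astype(np.float32), mask=s.mask)
        for s in raw
    ]
    return split_dataset(normalized, ratios=ratios,
                         seed=derive_seed(profile.seed, "split"))


# -- on-disk dialects --------------------------------------------------------------


def save_site_png(directory, samples: list[Sample]) -> None:
    """Write 8-bit PNG pairs {stem}.png / {stem}_mask.png."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        img8 = np.clip(np.round(normalize_sample(s.image) * 255), 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"sample_{i:04d}.png", img8)
        iio.imwrite(directory / f"sample_{i:04d}_mask.png",
                    (s.mask.astype(np.uint8) * 255))


def save_site_nifti(directory, samples: list[Sample]) -> None:
    """Write single-file NIfTI stacks images.nii.gz / masks.nii.gz."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    images = np.stack([s.image for s in samples], axis=-1).astype(np.float32)
    masks = np.stack([s.mask for s in samples], axis=-1).astype(np.uint8)
    nib.save(nib.Nifti1Image(images, np.eye(4)), str(directory / "images.nii.gz"))
    nib.save(nib.Nifti1Image(masks, np.eye(4)), str(directory / "masks.nii.gz"))


def write_manifest(path, profiles: list[SiteProfile], extra: dict | None = None) -> None:
    """Site manifest: per-site counts and generative parameters, as YAML."""
    doc = {
        "total": int(sum(p.n_k for p in profiles)),
        "sites": [asdict(p) for p in profiles],
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
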