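"""Synthetic chest-phantom generator with ground-truth nodule boxes.

The generator reproduces the *statistical* structure of a NODE21-style
screening corpus — ~23% positive prevalence, ~1.3 annotated nodules per
positive image, a diameter mix dominated by sub-70-px nodules, several
images per patient, and stratified patient-level 70/15/15 splits — not
radiographic realism. Each phantom is a smooth thorax background with
two darker elliptical lung fields, sinusoidal rib bands, additive
Gaussian noise, and radially symmetric intensity bumps for nodules,
each recorded with its tight bounding box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .manifest import BBox, boxes_to_str, read_manifest, write_manifest

# conventional natural-image channel statistics used for standardization
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], np.float32)

NODE21_PREVALENCE = 1134 / 4882  # positive images / all images
NODE21_BOXES_PER_POSITIVE = 1476 / 1134  # mean annotated nodules per positive


@dataclass(frozen=True)
class PhantomParams:
    image_side: int = 224
    n_patients: int = 100
    images_per_patient: tuple[int, int] = (1, 3)  # inclusive uniform range
    prevalence: float = NODE21_PREVALENCE
    second_nodule_prob: float = NODE21_BOXES_PER_POSITIVE - 1.0  # P(a 2nd box)
    # diameter spec in 224-px reference pixels (~80% of boxes below 70 px);
    # samples scale with image_side so smaller phantoms stay placeable
    diameter_log_mean: float = math.log(46.0)
    diameter_log_sd: float = 0.5
    diameter_range: tuple[float, float] = (10.0, 120.0)
    nodule_contrast: float = 0.35
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.image_side < 32:
            raise ValueError("image_side too small")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)  # train/val/test
    stratify_by_label: bool = True
    patient_level: bool = True

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if any(f <= 0 for f in self.fractions):
            raise ValueError("all split fractions must be positive")


SPLIT_NAMES = ("train", "val", "test")


# ---------------------------------------------------------------------
# phantom geometry


def _lung_ellipses(side: int):
    """Two (cy, cx, ry, rx) ellipses standing in for lung fields."""
    return (
        (0.48 * side, 0.30 * side, 0.33 * side, 0.15 * side),
        (0.48 * side, 0.70 * side, 0.33 * side, 0.15 * side),
    )


def lung_mask(side: int) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    m = np.zeros((side, side), bool)
    for cy, cx, ry, rx in _lung_ellipses(side):
        m |= ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return m


def _sample_nodule(side: int, params: PhantomParams, rng: np.random.Generator, max_tries: int = 200):
    """Sample a nodule (cy, cx, diameter) whose tight box sits inside a lung
    ellipse (and therefore inside the image)."""
    scale = side / 224.0
    for _ in range(max_tries):
        d_ref = float(np.clip(math.exp(rng.normal(params.diameter_log_mean, params.diameter_log_sd)), *params.diameter_range))
        d = max(min(d_ref * scale, 0.5 * side), 2.0)
        half = d / 2.0
        cy_e, cx_e, ry, rx = _lung_ellipses(side)[rng.integers(2)]
        if ry - half <= 1 or rx - half <= 1:
            continue
        # uniform in the ellipse shrunk by the box half-side
        u, v = rng.random(), rng.random()
        r = math.sqrt(u)
        theta = 2 * math.pi * v
        cy = cy_e + (ry - half) * r * math.sin(theta)
        cx = cx_e + (rx - half) * r * math.cos(theta)
        w = h = max(int(round(d)), 2)
        x_min = int(round(cx - w / 2.0))
        y_min = int(round(cy - h / 2.0))
        if x_min >= 0 and y_min >= 0 and x_min + w <= side and y_min + h <= side:
            return cy, cx, d, BBox(x_min, y_min, w, h)
    raise RuntimeError("could not place a nodule inside the lung fields")


def sample_nodules(n: int, params: PhantomParams, rng: np.random.Generator):
    """Sample ``n`` nodules; returns (centres, boxes)."""
    specs, boxes = [], []
    for _ in range(n):
        cy, cx, d, box = _sample_nodule(params.image_side, params, rng)
        specs.append((cy, cx, d))
        boxes.append(box)
    return specs, boxes


def render_phantom(params: PhantomParams, rng: np.random.Generator, n_nodules: int = 0):
    """Render one phantom; returns (image in [0,1], list of BBox).

    Deterministic for a given generator state.
    """
    side = params.image_side
    # nodules are drawn first so the box sequence matches manifest sampling
    specs, boxes = sample_nodules(n_nodules, params, rng)
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    img = 0.42 + 0.10 * (yy / side)  # smooth thorax background
    for cy, cx, ry, rx in _lung_ellipses(side):
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        img -= 0.16 * ndimage.gaussian_filter(inside.astype(np.float64), side / 60.0)
    n_ribs = int(rng.integers(6, 9))
    phase = rng.uniform(0, 2 * math.pi)
    img += 0.045 * np.sin(2 * math.pi * n_ribs * yy / side + phase + 0.8 * xx / side)
    for cy, cx, d in specs:
        sigma = d / 4.0  # bump effectively vanishes at the box edge (2 sigma)
        img += params.nodule_contrast * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    img += rng.normal(0.0, params.noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0), boxes


# ---------------------------------------------------------------------
# manifest construction and patient-level stratified splitting


def _assign_splits(df: pd.DataFrame, split: SplitSpec, rng: np.random.Generator) -> pd.Series:
    """Greedy stratified patient-level assignment.

    Patients are grouped by whether they carry any positive image;
    within each stratum, shuffled patients go to whichever partition
    has the largest remaining image deficit for that stratum. This
    keeps per-partition class fractions close to global while never
    splitting a patient.
    """
    if not split.patient_level:
        raise NotImplementedError("only patient-level splitting is supported")
    per_patient = df.groupby("patient_id", sort=True).agg(n=("label", "size"), n_pos=("label", "sum"))
    fr = np.array(split.fractions)
    assignment: dict[str, str] = {}
    filled_tot = np.zeros(3)
    if split.stratify_by_label:
        # positive-carrying patients first, largest positive load first with
        # randomized ties, against positive-image targets
        pos_patients = per_patient[per_patient["n_pos"] > 0]
        targets_pos = fr * pos_patients["n_pos"].sum()
        filled_pos = np.zeros(3)
        order = pos_patients.index.to_numpy()[rng.permutation(len(pos_patients))]
        order = order[np.argsort(-pos_patients.loc[order, "n_pos"].to_numpy(), kind="stable")]
        for pid in order:
            k = int(np.argmax(targets_pos - filled_pos))
            assignment[pid] = SPLIT_NAMES[k]
            filled_pos[k] += per_patient.loc[pid, "n_pos"]
            filled_tot[k] += per_patient.loc[pid, "n"]
        remaining = per_patient[per_patient["n_pos"] == 0]
    else:
        remaining = per_patient
    # pure-negative patients balance the remaining total-image deficit
    targets_tot = fr * per_patient["n"].sum()
    order = remaining.index.to_numpy()[rng.permutation(len(remaining))]
    order = order[np.argsort(-remaining.loc[order, "n"].to_numpy(), kind="stable")]
    for pid in order:
        k = int(np.argmax(targets_tot - filled_tot))
        assignment[pid] = SPLIT_NAMES[k]
        filled_tot[k] += per_patient.loc[pid, "n"]
    return df["patient_id"].map(assignment)


def build_manifest(params: PhantomParams, split: SplitSpec = SplitSpec(), seed: int | None = None) -> pd.DataFrame:
    """Sample patients, labels and boxes (no pixel rendering).

    ``image_path`` values are relative stems; :func:`generate_dataset`
    renders and fills in real paths.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng([seed, 11])
    rows = []
    idx = 0
    for p in range(params.n_patients):
        pid = f"P{p:05d}"
        lo, hi = params.images_per_patient
        for _ in range(int(rng.integers(lo, hi + 1))):
            positive = rng.random() < params.prevalence
            if positive:
                n_boxes = 1 + int(rng.random() < params.second_nodule_prob)
                _, boxes = sample_nodules(n_boxes, params, np.random.default_rng([seed, 13, idx]))
            else:
                boxes = []
            rows.append(
                {
                    "patient_id": pid,
                    "image_path": f"images/{pid}_{idx:05d}.png",
                    "label": int(positive),
                    "boxes": boxes,
                    "render_seed": idx,
                }
            )
            idx += 1
    df = pd.DataFrame(rows)
    df["split"] = _assign_splits(df, split, np.random.default_rng([seed, 17]))
    return df


def generate_dataset(
    params: PhantomParams,
    split: SplitSpec = SplitSpec(),
    out_dir: str | Path = ".",
    seed: int | None = None,
) -> pd.DataFrame:
    """Render the full dataset to ``out_dir`` (PNG images + manifest.csv)."""
    seed = params.seed if seed is None else seed
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    df = build_manifest(params, split, seed)
    for row in df.itertuples():
        rng = np.random.default_rng([seed, 13, row.render_seed])
        n_boxes = len(row.boxes)
        img, boxes = render_phantom(params, rng, n_boxes)
        assert [(b.x_min, b.y_min, b.width, b.height) for b in boxes] == [
            (b.x_min, b.y_min, b.width, b.height) for b in row.boxes
        ]
        Image.fromarray((img * 255).round().astype(np.uint8), mode="L").save(out / row.image_path)
    df = df.drop(columns=["render_seed"])
    write_manifest(df, out / "manifest.csv")
    return read_manifest(out / "manifest.csv")


# ---------------------------------------------------------------------
# preprocessing / augmentation


@dataclass(frozen=True)
class AugmentParams:
    """Magnitudes for the training-only augmentation pipeline."""

    hflip_prob: float = 0.5
    max_rotation_deg: float = 7.0
    max_translation_frac: float = 0.05
    max_intensity_frac: float = 0.10  # brightness and contrast scale


def _resize(image: np.ndarray, side: int) -> np.ndarray:
    if image.shape == (side, side):
        return image.astype(np.float32)
    im = Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8), mode="L")
    return np.asarray(im.resize((side, side), Image.BILINEAR), np.float32) / 255.0


def _standardize(image: np.ndarray) -> np.ndarray:
    """Replicate grayscale to 3 channels and standardize per channel."""
    three = np.repeat(image[None, :, :], 3, axis=0).astype(np.float32)
    return (three - IMAGENET_MEAN[:, None, None]) / IMAGENET_STD[:, None, None]


def preprocess_image(image: np.ndarray, side: int = 224) -> np.ndarray:
    """Deterministic eval-time pipeline: resize, replicate, standardize."""
    return _standardize(_resize(np.asarray(image, np.float64), side))


def augment_training_image(
    image: np.ndarray,
    rng: np.random.Generator,
    split: str = "train",
    side: int = 224,
    params: AugmentParams = AugmentParams(),
) -> np.ndarray:
    """Training-only stochastic pipeline.

    Order: resize, horizontal flip, small-angle rotation, mild
    translation, limited brightness/contrast perturbation, channel
    replication, standardization. Guarded against use on evaluation
    splits, which retain only original images.
    """
    if split != "train":
        raise ValueError("augmentation applies to the training split only; validation and test sets retain original images")
    img = _resize(np.asarray(image, np.float64), side).astype(np.float64)
    if rng.random() < params.hflip_prob:
        img = img[:, ::-1]
    angle = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)
    if angle:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
    shift = rng.uniform(-params.max_translation_frac, params.max_translation_frac, 2) * side
    if np.any(shift):
        img = ndimage.shift(img, shift, order=1, mode="nearest")
    brightness = 1.0 + rng.uniform(-params.max_intensity_frac, params.max_intensity_frac)
    contrast = 1.0 + rng.uniform(-params.max_intensity_frac, params.max_intensity_frac)
    mean = img.mean()
    img = np.clip((img - mean) * contrast + mean * brightness, 0.0, 1.0)
    return _standardize(img.astype(np.float32))


def upsample_minority(
    df: pd.DataFrame,
    factor: float | None = None,
    target_ratio: float | None = None,
) -> pd.DataFrame:
    """Duplicate positive training rows to reduce class imbalance.

    ``factor`` scales the positive count; ``target_ratio`` requests
    positives = ratio * negatives. Duplicates receive independent
    augmentation at load time, so repetition is not literal.
    """
    if (factor is None) == (target_ratio is None):
        raise ValueError("specify exactly one of factor or target_ratio")
    if factor is not None and factor < 1.0:
        raise ValueError("upsampling factor must be >= 1")
    splits = set(df["split"].unique()) if "split" in df else set()
    if splits - {"train"}:
        raise ValueError("minority upsampling applies to the training split only")
    pos = df[df["label"] == 1]
    neg = df[df["label"] == 0]
    if len(pos) == 0:
        raise ValueError("no positive rows to upsample")
    target = int(round(factor * len(pos))) if factor is not None else int(round(target_ratio * len(neg)))
    if target < len(pos):
        raise ValueError("target would shrink the positive class")
    extra = target - len(pos)
    dup = pos.iloc[np.arange(extra) % len(pos)]
    return pd.concat([df, dup], ignore_index=True)


# ---------------------------------------------------------------------
# datasets


class ArrayDataset:
    """In-memory (images, labels) pairs, already model-ready."""

    def __init__(self, images: np.ndarray, labels: np.ndarray):
        assert len(images) == len(labels)
        self.images = np.asarray(images, np.float32)
        self.labels = np.asarray(labels, int)

    def __len__(self):
        return len(self.images)

    def __getitem__(self, i):
        return self.images[i], int(self.labels[i])

    def label(self, i):
        return int(self.labels[i])


class ManifestDataset:
    """Loads manifest rows from disk; augments the training split."""

    def __init__(self, df: pd.DataFrame, root: str | Path, split: str, side: int = 224, augment: bool | None = None, seed: int = 0):
        self.rows = df[df["split"] == split].reset_index(drop=True)
        self.root = Path(root)
        self.split = split
        self.side = side
        self.augment = (split == "train") if augment is None else augment
        self.reseed(seed)

    def reseed(self, seed: int):
        self._rng = np.random.default_rng([seed, 101])

    def __len__(self):
        return len(self.rows)

    def label(self, i):
        return int(self.rows.loc[i, "label"])

    def __getitem__(self, i):
        row = self.rows.loc[i]
        img = np.asarray(Image.open(self.root / row.image_path), np.float64) / 255.0
        if self.augment:
            x = augment_training_image(img, self._rng, split=self.split, side=self.side)
        else:
            x = preprocess_image(img, side=self.side)
        return x, int(row.label)


def make_smoke_set(n: int = 32, side: int = 112, seed: int = 0) -> ArrayDataset:
    """Small, high-contrast, low-noise balanced set for overfitting checks."""
    params = PhantomParams(image_side=side, nodule_contrast=0.6, noise_sd=0.02, seed=seed)
    rng = np.random.default_rng([seed, 23])
    images, labels = [], []
    for i in range(n):
        positive = i % 2 == 1
        img, _ = render_phantom(params, np.random.default_rng([seed, 29, i]), int(positive))
        images.append(preprocess_image(img, side=side))
        labels.append(int(positive))
    _ = rng
    return ArrayDataset(np.stack(images), np.array(labels))
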