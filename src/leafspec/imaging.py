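"""Leaf-image chain: grayscale conversion, Otsu segmentation with
morphological cleanup, background removal, and the 10 foreground
statistics (average gray, per-channel mean/SD/CV) that form the
regressor's input.

Images are 8-bit RGB arrays (H x W x 3) of a single lit leaf on a dark
background, as captured under a characteristic-band light source with
a matching bandpass filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, footprint_rectangle, opening

__all__ = [
    "FeatureVector",
    "SegmentationError",
    "FEATURE_NAMES",
    "to_gray",
    "segment_leaf",
    "remove_background",
    "compute_features",
    "extract_features",
    "extract_features_dir",
]

#: ITU-R BT.601 luminance weights (the common "gray processing" default)
GRAY_WEIGHTS = (0.299, 0.587, 0.114)

FEATURE_NAMES = ["avg_gray",
                 "mean_R", "mean_G", "mean_B",
                 "sd_R", "sd_G", "sd_B",
                 "cv_R", "cv_G", "cv_B"]


class SegmentationError(RuntimeError):
    """Raised when no leaf foreground can be isolated."""


@dataclass
class FeatureVector:
    """The 10 foreground statistics feeding the residue regressor.

    CV is the coefficient of variation sd/mean, reported as 0 (with a
    warning) for a zero-mean channel.  SDs are population form.
    """

    avg_gray: float
    mean_R: float
    mean_G: float
    mean_B: float
    sd_R: float
    sd_G: float
    sd_B: float
    cv_R: float
    cv_G: float
    cv_B: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.size == 0:
        raise ValueError("expected a non-empty H x W x 3 RGB image")
    return img


def to_gray(img: np.ndarray, weights=GRAY_WEIGHTS) -> np.ndarray:
    """Weighted luminance, rounded to 8-bit."""
    img = _check_image(img)
    gray = img.astype(float) @ np.asarray(weights, dtype=float)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def segment_leaf(img: np.ndarray, channel: str = "gray") -> np.ndarray:
    """Boolean leaf mask: Otsu threshold (bright side = leaf), 3x3
    closing then opening, largest connected component.

    `channel` selects the thresholded plane: "gray" (default) or one of
    "R"/"G"/"B".
    """
    img = _check_image(img)
    if channel == "gray":
        plane = to_gray(img)
    elif channel in ("R", "G", "B"):
        plane = img[:, :, "RGB".index(channel)]
    else:
        raise ValueError(f"unknown segmentation channel {channel!r}")

    if np.ptp(plane) == 0:
        raise SegmentationError("uniform image: no foreground/background contrast")
    thr = threshold_otsu(plane)
    mask = plane > thr

    se = footprint_rectangle((3, 3))
    mask = opening(closing(mask, se), se)
    if not mask.any():
        raise SegmentationError("empty foreground after morphological cleanup")

    lab = label(mask, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def remove_background(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every background pixel in all channels; foreground untouched."""
    img = _check_image(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape must match the image frame")
    if not mask.any():
        raise SegmentationError("mask has no foreground pixels")
    out = img.copy()
    out[~mask] = 0
    return out


def compute_features(img: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """The 10 statistics over the foreground pixels only.

    avg_gray is computed on the de-backgrounded gray image over the
    mask; channel SDs are population SDs; CV = sd/mean with a warned
    zero for zero-mean channels.
    """
    img = _check_image(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError("mask shape must match the image frame")
    if not mask.any():
        raise SegmentationError("mask has no foreground pixels")

    fg = remove_background(img, mask)
    avg_gray = float(to_gray(fg)[mask].mean())

    px = img[mask].astype(float)          # (n_fg, 3)
    means = px.mean(axis=0)
    sds = px.std(axis=0)                  # population (ddof=0)
    cvs = np.zeros(3)
    for c in range(3):
        if means[c] > 0:
            cvs[c] = sds[c] / means[c]
        elif sds[c] > 0:
            warnings.warn(f"channel {'RGB'[c]} has zero mean; CV reported as 0")
    return FeatureVector(avg_gray, *means, *sds, *cvs)


def extract_features(img: np.ndarray, channel: str = "gray") -> FeatureVector:
    """Segment + de-background + statistics in one call."""
    mask = segment_leaf(img, channel=channel)
    return compute_features(img, mask)


def extract_features_dir(image_dir, channel: str = "gray",
                         save_masks_to=None) -> pd.DataFrame:
    """Walk a directory of PNG/JPEG images; one feature row per image.

    Images that fail to load or segment are skipped with a warning (the
    `skipped` attribute of the returned frame lists them).  With
    `save_masks_to`, the binary masks are written as PNGs for audit.
    """
    image_dir = Path(image_dir)
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not paths:
        raise FileNotFoundError(f"no PNG/JPEG images under {image_dir}")
    if save_masks_to is not None:
        Path(save_masks_to).mkdir(parents=True, exist_ok=True)

    rows, skipped = [], []
    for p in paths:
        try:
            img = np.asarray(Image.open(p).convert("RGB"))
            mask = segment_leaf(img, channel=channel)
            fv = compute_features(img, mask)
        except (OSError, ValueError, SegmentationError) as exc:
            warnings.warn(f"skipping {p.name}: {exc}")
            skipped.append(p.name)
            continue
        if save_masks_to is not None:
            Image.fromarray(mask.astype(np.uint8) * 255).save(
                Path(save_masks_to) / f"{p.stem}_mask.png")
        rows.append({"sample_id": p.name,
                     **dict(zip(FEATURE_NAMES, fv.to_array()))})
    df = pd.DataFrame(rows)
    df.attrs["skipped"] = skipped
    return df
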