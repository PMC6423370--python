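"""Daily representative-image selection and transmission downsizing.

Each device captures several full-resolution images per day and must pick a
single representative to upload.  The three criteria are file size (rejects
truncated or empty files), mean intensity (rejects black and blown-out
frames), and clarity.  File size and intensity act as hard gates; among the
survivors the sharpest image wins.

Clarity is the variance of a 3x3 discrete Laplacian of the grayscale image
— the standard no-reference sharpness proxy: a defocused image has weak
second derivatives everywhere, so its Laplacian variance collapses.

The representative is downsized from capture resolution (2,592 x 1,944 by
default) to 640 x 480 by exact area-averaged (block-mean) resampling, which
preserves the image mean and handles the non-integer 4.05x scale factor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .models import (
    REPRESENTATIVE_HEIGHT,
    REPRESENTATIVE_WIDTH,
    ImageRecord,
)


class ScoringError(ValueError):
    """The image bytes could not be decoded."""


class AspectRatioError(ValueError):
    """Input and target aspect ratios differ, so block resampling would
    distort the field of view."""


@dataclass(frozen=True)
class SelectionConfig:
    """Gates and target size for representative-image selection.

    ``min_file_size`` rejects truncated uploads; the intensity window
    rejects frames taken in darkness or with a blown-out exposure.  The
    defaults for the window are permissive (40-215 on the 0-255 scale);
    ``min_file_size=0`` disables the size gate, and callers typically set
    it relative to the day's median file size.
    """

    min_file_size: int = 0
    intensity_low: float = 40.0
    intensity_high: float = 215.0
    target_width: int = REPRESENTATIVE_WIDTH
    target_height: int = REPRESENTATIVE_HEIGHT

    def __post_init__(self) -> None:
        if not self.intensity_low < self.intensity_high:
            raise ValueError("intensity_low must be < intensity_high")
        if self.target_width <= 0 or self.target_height <= 0:
            raise ValueError("target dimensions must be positive")


@dataclass(frozen=True)
class ImageScore:
    file_size: int
    mean_intensity: float
    clarity: float


def decode_gray(content: bytes) -> np.ndarray:
    """Decode image bytes to a float64 grayscale array in [0, 255]."""
    try:
        with Image.open(io.BytesIO(content)) as im:
            return np.asarray(im.convert("L"), dtype=np.float64)
    except (UnidentifiedImageError, OSError, ValueError) as exc:
        raise ScoringError(f"cannot decode image: {exc}") from exc


def score_image(content: bytes) -> ImageScore:
    """Score image bytes on the three selection criteria.

    Returns the encoded file size in bytes, the grayscale mean intensity on
    the 0-255 scale, and the clarity (Laplacian variance).  Deterministic;
    raises :class:`ScoringError` on undecodable bytes.
    """
    gray = decode_gray(content)
    lap = ndimage.laplace(gray, mode="nearest")
    return ImageScore(
        file_size=len(content),
        mean_intensity=float(gray.mean()),
        clarity=float(lap.var()),
    )


def select_representative(
    day_images: Sequence[ImageRecord], config: SelectionConfig
) -> Optional[ImageRecord]:
    """Pick the day's representative: gate on file size and mean intensity,
    then take the maximum-clarity survivor, ties broken by earliest capture
    time.  Returns ``None`` when nothing survives the gates."""
    survivors = [
        img
        for img in day_images
        if img.file_size >= config.min_file_size
        and config.intensity_low <= img.mean_intensity <= config.intensity_high
    ]
    if not survivors:
        return None
    return max(survivors, key=lambda img: (img.clarity, -img.capture_time.timestamp()))


def _box_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic matrix of exact pixel-overlap weights
    for 1-D area-averaged downsampling, handling non-integer factors."""
    scale = n_in / n_out
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                w[i, j] = overlap
    return w / scale


def area_resample(arr: np.ndarray, out_height: int, out_width: int) -> np.ndarray:
    """Exact area-average resample of a 2-D array.  Each output pixel is the
    mean of its (possibly fractional) source footprint, so the global mean
    is preserved to floating-point accuracy."""
    wr = _box_weights(arr.shape[0], out_height)
    wc = _box_weights(arr.shape[1], out_width)
    return wr @ arr @ wc.T


def downsample_image(
    content: bytes,
    target_width: int = REPRESENTATIVE_WIDTH,
    target_height: int = REPRESENTATIVE_HEIGHT,
) -> bytes:
    """Downsize an encoded image to the transmission resolution by
    block-mean resampling, returning PNG bytes.

    The input aspect ratio must match the target's (2,592:1,944 = 640:480
    = 4:3); otherwise :class:`AspectRatioError` is raised naming both
    ratios.  An input already at target size is returned byte-unchanged.
    """
    with Image.open(io.BytesIO(content)) as im:
        im.load()
        width, height = im.size
        if width < target_width or height < target_height:
            raise ValueError(
                f"input {width}x{height} smaller than target "
                f"{target_width}x{target_height}"
            )
        if width * target_height != height * target_width:
            raise AspectRatioError(
                f"input aspect {width}:{height} does not match "
                f"target aspect {target_width}:{target_height}"
            )
        if (width, height) == (target_width, target_height):
            return content
        channels = np.asarray(im.convert("RGB"), dtype=np.float64)
        resampled = np.stack(
            [
                area_resample(channels[..., c], target_height, target_width)
                for c in range(channels.shape[-1])
            ],
            axis=-1,
        )
        out = Image.fromarray(
            np.clip(np.rint(resampled), 0, 255).astype(np.uint8), mode="RGB"
        )
    buf = io.BytesIO()
    out.save(buf, format="PNG")
    return buf.getvalue()
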