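"""Hounsfield-window clipping, normalization, size standardization, augmentation.

The preprocessing chain mirrors standard CT practice for stroke CTP slices:
intensities outside the [0, 150] HU window are *replaced with zero* (not
saturated -- the window is a tissue-selection step, so out-of-window voxels
are treated as non-brain), images are mapped to [0, 1] via a bit-depth
scale, standardized to 256x256 by center crop / zero padding, and the
training set may be augmented with small rotations and horizontal flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ContractError, InputError
from .phantom import SliceSample

__all__ = [
    "PreprocessConfig",
    "clip_hounsfield",
    "normalize_intensity",
    "standardize_size",
    "augment",
]


@dataclass
class PreprocessConfig:
    """Windowing and augmentation parameters.

    ``bit_depth`` is the per-channel bit depth B used for normalization: by
    default the clipped HU window [hu_low, hu_high] is first affinely mapped
    onto the 0..2^B-1 integer scale and then divided by 2^B-1, so the window
    lands exactly on [0, 1].  Set ``hu_affine=False`` for data already on a
    bit scale.
    """

    hu_low: float = 0.0
    hu_high: float = 150.0
    target_size: tuple[int, int] = (256, 256)
    bit_depth: int = 8
    hu_affine: bool = True
    augment_rotation_deg: tuple[float, float] = (-20.0, 20.0)
    augment_hflip: bool = True

    def validate(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ConfigurationError("hu_low must be < hu_high")
        if self.bit_depth <= 0:
            raise ConfigurationError("bit_depth must be positive")
        if self.augment_rotation_deg[0] > self.augment_rotation_deg[1]:
            raise ConfigurationError("augment_rotation_deg range is inverted")


def clip_hounsfield(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero out intensities above ``hu_high`` or below ``hu_low``.

    Out-of-window values are replaced with zero rather than clamped: the HU
    window acts as a crude tissue mask, so bone-bright and air-dark pixels
    are removed entirely.  Idempotent.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite values")
    out = image.copy()
    out[(image > cfg.hu_high) | (image < cfg.hu_low)] = 0.0
    return out


def normalize_intensity(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Map a clipped image to [0, 1] by dividing by the bit-depth scale 2^B - 1."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    image = np.asarray(image, dtype=np.float64)
    scale = float(2 ** cfg.bit_depth - 1)
    if cfg.hu_affine:
        image = (image - cfg.hu_low) / (cfg.hu_high - cfg.hu_low) * scale
    return image / scale


def _crop_pad_1d(n: int, target: int) -> tuple[slice, tuple[int, int]]:
    if n >= target:
        start = (n - target) // 2
        return slice(start, start + target), (0, 0)
    before = (target - n) // 2
    return slice(0, n), (before, target - n - before)


def standardize_size(image: np.ndarray, mask: np.ndarray,
                     cfg: PreprocessConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Center-crop or zero-pad ``image`` and ``mask`` to ``target_size``.

    The identical spatial transform is applied to both arrays; padding uses
    the background value 0 and, on odd remainders, the extra row/column goes
    at the bottom/right.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.size == 0:
        raise InputError("empty image")
    if image.shape != mask.shape:
        raise InputError("image and mask shapes differ")
    tr, tc = cfg.target_size
    sr, pr = _crop_pad_1d(image.shape[0], tr)
    sc, pc = _crop_pad_1d(image.shape[1], tc)
    image = np.pad(image[sr, sc], (pr, pc), mode="constant")
    mask = np.pad(mask[sr, sc], (pr, pc), mode="constant")
    return image, mask.astype(np.uint8)


def augment(sample: SliceSample, cfg: PreprocessConfig | None = None,
            rng_seed: int | np.random.Generator = 0) -> SliceSample:
    """Random rotation + horizontal flip, applied identically to image and mask.

    Only legal on training samples; rotation angle is uniform in
    ``augment_rotation_deg``, the image is interpolated bilinearly and the
    mask re-binarized with a 0.5 threshold so it stays exactly binary.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    if sample.split != "train":
        raise ContractError(
            f"augmentation is restricted to the training set (got split={sample.split!r})")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    angle = float(rng.uniform(*cfg.augment_rotation_deg))
    flip = bool(cfg.augment_hflip and rng.random() < 0.5)

    image = sample.image
    mask = sample.mask.astype(np.float64)
    if flip:
        image = image[:, ::-1]
        mask = mask[:, ::-1]
    if angle != 0.0:
        image = ndimage.rotate(image, angle, reshape=False, order=1,
                               mode="constant", cval=0.0)
        mask = ndimage.rotate(mask, angle, reshape=False, order=1,
                              mode="constant", cval=0.0)
    return SliceSample(image=np.ascontiguousarray(image),
                       mask=(mask >= 0.5).astype(np.uint8),
                       patient_id=sample.patient_id,
                       slice_index=sample.slice_index,
                       split=sample.split)
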