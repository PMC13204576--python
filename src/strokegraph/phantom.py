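"""Synthetic CTP-like brain phantoms with ground-truth lesion masks.

Real CT-perfusion cohorts for stroke-core segmentation come as per-patient
stacks of 256x256 axial slices with a handful of slices per patient and
binary lesion annotations.  This module emulates exactly that shape of data:
an elliptical "brain" of textured Hounsfield-like intensity on a zero
background, zero to three irregular lesion blobs per slice offset in
intensity from the surrounding tissue, and per-patient slice counts drawn
from the 2-22 range typical of such acquisitions.  A small fraction of
pixels is forced outside the [0, 150] HU display window so that downstream
window clipping is exercised.

Generation is a pure function of ``(seed, spec)``: the same spec produces
bit-identical cohorts, which the test suite relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InputError

__all__ = ["PhantomSpec", "SliceSample", "generate_cohort", "lesion_fraction"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort.

    Intensities are on a Hounsfield-like scale: brain tissue sits inside the
    [0, 150] window, the background is 0, and lesions are offset from the
    local tissue intensity by ``lesion_contrast`` HU.
    """

    seed: int = 0
    n_patients: int = 10
    slices_per_patient_range: tuple[int, int] = (2, 22)
    image_size: tuple[int, int] = (256, 256)
    lesion_count_range: tuple[int, int] = (0, 3)
    lesion_radius_range: tuple[float, float] = (10.0, 40.0)
    brain_intensity_range: tuple[float, float] = (40.0, 90.0)
    lesion_contrast: float = 35.0
    background_noise_sd: float = 4.0
    out_of_range_fraction: float = 0.002
    # Fraction of the brain area a single slice's lesions may cover at most.
    max_lesion_brain_fraction: float = 0.25

    def validate(self) -> None:
        for name in ("slices_per_patient_range", "lesion_count_range",
                     "lesion_radius_range", "brain_intensity_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} is inverted: ({lo}, {hi})")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.slices_per_patient_range[0] < 1:
            raise ConfigurationError("slices_per_patient_range must start at >= 1")
        if self.lesion_count_range[0] < 0:
            raise ConfigurationError("lesion_count_range must be non-negative")
        if min(self.image_size) < 32:
            raise ConfigurationError("image_size too small for a brain phantom")
        if not (0.0 <= self.out_of_range_fraction < 1.0):
            raise ConfigurationError("out_of_range_fraction must be in [0, 1)")
        lo, hi = self.brain_intensity_range
        if lo < 0 or hi > 150:
            raise ConfigurationError("brain_intensity_range must lie within [0, 150]")


@dataclass
class SliceSample:
    """One axial slice: HU-scale image, binary lesion mask, provenance."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: str
    slice_index: int
    split: str = "train"  # augmentation is only legal on training samples

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise InputError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}")
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise InputError("mask must be binary (values in {0, 1})")
        self.mask = self.mask.astype(np.uint8)


def _ellipse_mask(shape, center, semi_axes, angle):
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _lesion_blob(shape, center, radius, rng):
    """Connected blob with an irregular, sinusoid-perturbed boundary."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = rr - center[0]
    dc = cc - center[1]
    dist = np.hypot(dr, dc)
    theta = np.arctan2(dc, dr)
    boundary = np.full(shape, radius)
    for m in range(2, 6):
        amp = rng.uniform(-0.12, 0.12)
        phase = rng.uniform(0, 2 * np.pi)
        boundary = boundary + radius * amp * np.cos(m * theta + phase)
    return dist <= np.maximum(boundary, 1.0)


def _generate_slice(spec: PhantomSpec, rng: np.random.Generator,
                    brain_center, brain_axes, brain_angle,
                    force_no_lesion: bool):
    rows, cols = spec.image_size
    brain = _ellipse_mask(spec.image_size, brain_center, brain_axes, brain_angle)
    brain_area = int(brain.sum())

    base = rng.uniform(*spec.brain_intensity_range)
    # Smooth low-frequency texture so superpixels see realistic gradients,
    # plus fine acquisition-like noise.
    smooth = gaussian_filter(rng.standard_normal(spec.image_size), sigma=12.0)
    sd = smooth.std()
    smooth = smooth / sd * 6.0 if sd > 0 else smooth
    fine = rng.standard_normal(spec.image_size) * spec.background_noise_sd

    image = np.zeros(spec.image_size, dtype=np.float64)
    image[brain] = base + smooth[brain] + fine[brain]

    mask = np.zeros(spec.image_size, dtype=np.uint8)
    lo, hi = spec.lesion_count_range
    n_lesions = 0 if force_no_lesion else int(rng.integers(lo, hi + 1))
    budget = spec.max_lesion_brain_fraction * brain_area
    for _ in range(n_lesions):
        radius = rng.uniform(*spec.lesion_radius_range)
        # Centre drawn well inside the brain ellipse so blobs stay mostly interior.
        t = rng.uniform(0, 2 * np.pi)
        u = 0.6 * math.sqrt(rng.uniform())
        ca, sa = math.cos(brain_angle), math.sin(brain_angle)
        du = u * brain_axes[0] * math.cos(t)
        dv = u * brain_axes[1] * math.sin(t)
        center = (brain_center[0] + du * ca - dv * sa,
                  brain_center[1] + du * sa + dv * ca)
        blob = _lesion_blob(spec.image_size, center, radius, rng) & brain
        new_mask = mask | blob.astype(np.uint8)
        if new_mask.sum() > budget:
            break
        mask = new_mask
        # Lesion = contrast offset + smooth internal variation.
        variation = gaussian_filter(rng.standard_normal(spec.image_size), sigma=6.0)
        vsd = variation.std()
        if vsd > 0:
            variation = variation / vsd * 4.0
        image[blob] += spec.lesion_contrast + variation[blob]

    # Force a few pixels outside the [0, 150] window (clipping coverage).
    n_out = int(round(spec.out_of_range_fraction * image.size))
    if n_out > 0:
        flat = rng.choice(image.size, size=n_out, replace=False)
        half = n_out // 2
        img_flat = image.reshape(-1)
        img_flat[flat[:half]] = rng.uniform(-80.0, -1.0, size=half)
        img_flat[flat[half:]] = rng.uniform(155.0, 300.0, size=n_out - half)
    return image, mask


def generate_cohort(spec: PhantomSpec) -> list[SliceSample]:
    """Generate a full multi-patient cohort of slices.

    Returns slices for ``spec.n_patients`` patients, each with a slice count
    drawn uniformly from ``slices_per_patient_range``.  The first slice of
    the first patient is always lesion-free so that empty-truth edge cases
    are covered in every cohort.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    samples: list[SliceSample] = []
    lo, hi = spec.slices_per_patient_range
    for p in range(spec.n_patients):
        patient_id = f"P{p:03d}"
        n_slices = int(rng.integers(lo, hi + 1))
        # Brain geometry is fixed per patient (same head across slices).
        center = (rows / 2 + rng.uniform(-8, 8), cols / 2 + rng.uniform(-8, 8))
        axes = (rng.uniform(0.30, 0.37) * rows, rng.uniform(0.25, 0.33) * cols)
        angle = rng.uniform(-0.3, 0.3)
        for s in range(n_slices):
            force_empty = (p == 0 and s == 0)
            image, mask = _generate_slice(spec, rng, center, axes, angle,
                                          force_empty)
            samples.append(SliceSample(image=image, mask=mask,
                                       patient_id=patient_id, slice_index=s))
    return samples


def lesion_fraction(sample: SliceSample) -> float:
    """Fraction of all pixels annotated as lesion."""
    return float(sample.mask.sum()) / sample.mask.size
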