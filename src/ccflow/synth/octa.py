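"""Synthetic OCTA choriocapillaris textures and jittered repeat sets.

The en-face OCTA of a healthy choriocapillaris is a uniform fine meshwork
with no lobular boundaries; it is emulated here as isotropically band-pass
filtered noise thresholded to a target bright-vessel fraction. Repeat
acquisitions differ by small rigid fixation jitter plus speckle-like noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import EuclideanTransform, warp

from .._rng import substream
from ..geometry import FieldGeometry


@dataclass
class OCTARepeatSet:
    """Repeat OCTA acquisitions with recorded ground-truth transforms.

    ``true_transforms`` holds (dx_px, dy_px, theta_deg) applied to each
    repeat (first is always identity); ``signal_strengths`` are device-style
    0-10 quality scores.
    """

    images: list
    true_transforms: list
    noise_sigma: float
    signal_strengths: list


def render_octa(
    geometry: FieldGeometry,
    vessel_density_target: float,
    seed: int,
    sigma_low_px: float = 0.8,
    sigma_high_px: float = 2.6,
    bright_value: int = 220,
    dark_value: int = 15,
) -> np.ndarray:
    """Render a uniform choriocapillaris meshwork texture.

    Seeded Gaussian noise is band-pass filtered (difference of Gaussians,
    isotropic) and thresholded at the quantile that makes the bright-pixel
    fraction match ``vessel_density_target``. No lobular structure is
    imposed — matching the appearance of the averaged en-face slab.
    """
    if not 0.0 < vessel_density_target < 1.0:
        raise ValueError("vessel_density_target must lie in (0, 1)")
    rng = substream(seed, "render_octa")
    noise = rng.standard_normal(geometry.shape)
    band = ndi.gaussian_filter(noise, sigma_low_px) - ndi.gaussian_filter(
        noise, sigma_high_px
    )
    thresh = np.quantile(band, 1.0 - vessel_density_target)
    img = np.where(band > thresh, bright_value, dark_value).astype(np.uint8)
    return img


def make_octa_repeats(
    base: np.ndarray,
    n: int,
    max_shift_px: float,
    max_rot_deg: float,
    noise_sigma: float,
    seed: int,
) -> OCTARepeatSet:
    """Create ``n`` jittered, noisy repeats of a base OCTA image.

    Each repeat after the first is warped by a seeded random rigid
    transform (shift uniform in +-max_shift_px per axis, rotation uniform
    in +-max_rot_deg, about the image centre) and then degraded with i.i.d.
    Gaussian noise. The applied transforms are recorded so registration can
    be validated against ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, "make_octa_repeats")
    images = []
    transforms = []
    strengths = []
    base_f = base.astype(float)
    center = (np.array(base.shape[::-1]) - 1) / 2.0  # (x, y)
    for i in range(n):
        if i == 0:
            dx = dy = theta = 0.0
            warped = base_f.copy()
        else:
            dx = rng.uniform(-max_shift_px, max_shift_px)
            dy = rng.uniform(-max_shift_px, max_shift_px)
            theta = rng.uniform(-max_rot_deg, max_rot_deg)
            # forward transform: rotate about centre then translate
            t1 = EuclideanTransform(translation=-center)
            t2 = EuclideanTransform(rotation=np.deg2rad(theta))
            t3 = EuclideanTransform(translation=center + [dx, dy])
            fwd = t1 + t2 + t3
            warped = warp(
                base_f, fwd.inverse, order=1, mode="constant", cval=float(base_f.mean())
            )
        noisy = warped + rng.normal(0.0, noise_sigma, size=warped.shape)
        images.append(np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8))
        transforms.append((dx, dy, theta))
        strengths.append(int(rng.integers(9, 11)))
    return OCTARepeatSet(
        images=images,
        true_transforms=transforms,
        noise_sigma=noise_sigma,
        signal_strengths=strengths,
    )
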