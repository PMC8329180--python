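"""OCTA choriocapillaris processing: quality gating, averaging, RGB stacks.

Single OCTA acquisitions of the choriocapillaris are speckle-limited;
averaging registered repeat scans (nine in the reference protocol)
suppresses noise by roughly the square root of the repeat count. Scans
are admitted only above a device-style signal-strength score. Retinal
plexus slabs are composed into an RGB overview (R = superficial plexus,
G = deep plexus, B = choriocapillaris). Slab boundaries travel with the
images as metadata — slab extraction itself happens device-side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptySelectionError

#: canonical slab presets, offsets in micrometres relative to the named
#: reference surface (RPE for the choriocapillaris slabs)
CHORIOCAPILLARIS_SLAB_UM = (17.0, 33.0)


@dataclass(frozen=True)
class SlabDefinition:
    """En-face slab bookkeeping: name plus depth boundaries below the RPE.

    ``inner_offset_um`` and ``outer_offset_um`` are signed offsets below
    the retinal pigment epithelium (positive = deeper). The reference
    choriocapillaris slab runs 17-33 um below the RPE; thinner 20-28 um
    and 26-33 um slabs probe its posterior portion.
    """

    name: str
    inner_offset_um: float
    outer_offset_um: float

    def __post_init__(self):
        if self.outer_offset_um <= self.inner_offset_um:
            raise ValueError("outer boundary must be deeper than inner")

    @property
    def thickness_um(self) -> float:
        return self.outer_offset_um - self.inner_offset_um

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "inner_offset_um": self.inner_offset_um,
            "outer_offset_um": self.outer_offset_um,
        }


@dataclass(frozen=True)
class AveragingParams:
    """Frame count and quality gate for repeat averaging."""

    n_frames: int = 9
    min_signal_strength: int = 9

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0 <= self.min_signal_strength <= 10:
            raise ValueError("min_signal_strength must be in 0..10")


def quality_filter(
    images: Sequence[np.ndarray],
    signal_strengths: Sequence[int],
    params: AveragingParams,
):
    """Keep images whose signal strength meets the threshold, in order.

    Returns ``(retained_images, retained_strengths, report)`` where the
    report gives input/retained counts.
    """
    if len(images) != len(signal_strengths):
        raise ValueError("one signal strength per image required")
    keep = [i for i, s in enumerate(signal_strengths) if s >= params.min_signal_strength]
    if not keep:
        raise EmptySelectionError(
            f"no image reaches signal strength {params.min_signal_strength}"
        )
    report = {
        "n_input": len(images),
        "n_retained": len(keep),
        "threshold": params.min_signal_strength,
    }
    return [images[i] for i in keep], [signal_strengths[i] for i in keep], report


def average_frames(
    images: Sequence[np.ndarray],
    params: AveragingParams | None = None,
    output_dtype=np.uint8,
) -> np.ndarray:
    """Per-pixel arithmetic mean of registered repeats.

    Averaged in float64, cast to ``output_dtype`` with round-half-up (or
    returned as float when ``output_dtype`` is None).
    """
    if len(images) == 0:
        raise EmptySelectionError("no images to average")
    shapes = {np.asarray(i).shape for i in images}
    if len(shapes) != 1:
        raise ValueError("images must share a shape")
    mean = np.mean([np.asarray(i, dtype=np.float64) for i in images], axis=0)
    if output_dtype is None:
        return mean
    info = np.iinfo(output_dtype)
    return np.clip(np.floor(mean + 0.5), info.min, info.max).astype(output_dtype)


def compose_rgb(svp: np.ndarray, dcp: np.ndarray, cc: np.ndarray) -> np.ndarray:
    """Stack plexus slabs into an RGB image: R=SVP, G=DCP, B=CC, no blending."""
    svp, dcp, cc = (np.asarray(a) for a in (svp, dcp, cc))
    if not (svp.shape == dcp.shape == cc.shape):
        raise ValueError("slab images must share a shape")
    out = np.empty(svp.shape + (3,), dtype=svp.dtype)
    out[..., 0] = svp
    out[..., 1] = dcp
    out[..., 2] = cc
    return out


def split_rgb(stack: np.ndarray):
    """Inverse of :func:`compose_rgb`: return (svp, dcp, cc) channels."""
    return stack[..., 0].copy(), stack[..., 1].copy(), stack[..., 2].copy()


def mesh_uniformity_stats(
    cc_image: np.ndarray,
    tile_px: int,
    low_freq_cutoff_cpp: float = 0.04,
    low_freq_power_bound: float = 0.25,
) -> dict:
    """Quantify how uniform the choriocapillaris meshwork is.

    Tiles the image, measures the bright-pixel density per tile (bright =
    above the Otsu threshold), and reports the coefficient of variation
    across tiles. Also computes the fraction of (non-DC) spectral power
    below ``low_freq_cutoff_cpp`` cycles/pixel; when that fraction is
    under ``low_freq_power_bound`` the image has no dominant lobule-scale
    structure and ``uniform_mesh`` is flagged true.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(cc_image, dtype=np.float64)
    if img.min() == img.max():
        raise EmptySelectionError("constant image: uniformity is undefined")
    if tile_px < 2 or tile_px > min(img.shape):
        raise ValueError("tile_px must be between 2 and the image size")

    bright = img > threshold_otsu(img)
    ny = img.shape[0] // tile_px
    nx = img.shape[1] // tile_px
    tiles = bright[: ny * tile_px, : nx * tile_px].reshape(ny, tile_px, nx, tile_px)
    densities = tiles.mean(axis=(1, 3))
    mean_d = densities.mean()
    if mean_d == 0:
        raise EmptySelectionError("no bright pixels: uniformity is undefined")
    cv = float(densities.std() / mean_d)

    spectrum = np.abs(np.fft.fftshift(np.fft.fft2(img - img.mean()))) ** 2
    fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0]))
    fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1]))
    fr = np.hypot(*np.meshgrid(fx, fy))
    total = spectrum.sum()
    low = spectrum[(fr > 0) & (fr < low_freq_cutoff_cpp)].sum()
    low_fraction = float(low / total) if total > 0 else 0.0

    return {
        "tile_px": int(tile_px),
        "tile_density_mean": float(mean_d),
        "tile_density_cv": cv,
        "low_freq_power_fraction": low_fraction,
        "uniform_mesh": bool(low_fraction < low_freq_power_bound),
    }
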