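"""Three-step successive-approximation image registration.

Implements the processing chain used to align both the dye-angiography
video frames and the OCTA repeat acquisitions: a rigid estimate for gross
alignment (phase correlation for translation, log-polar correlation for
rotation), an intensity least-squares affine refinement, and a cubic
b-spline free-form deformation fine-tune. Non-overlapping margins caused
by fixation jitter are cropped after stack registration.

Transform convention
--------------------
A :class:`RigidTransform` records the *motion* of the moving image
relative to the fixed one: content is rotated by ``theta_deg`` about the
image centre, then shifted by ``(dx_px, dy_px)``. This is also the ITK
resampling convention (a map from fixed-frame coordinates to moving-frame
coordinates), so ``apply`` uses it directly to pull the moving image back
into the fixed frame. ``make_octa_repeats`` records its ground-truth
jitters in the same convention, making recovered and true transforms
directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import SimpleITK as sitk
from skimage.filters import window as skwindow
from skimage.registration import phase_cross_correlation
from skimage.transform import warp_polar

from .errors import ExcessiveMotionError, NoFeatureError, TooShortError

logger = logging.getLogger(__name__)

_VALID_EPS = 0.999


@dataclass
class RigidTransform:
    """Rigid motion: rotation about the image centre, then translation."""

    dx_px: float
    dy_px: float
    theta_deg: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.dx_px, self.dy_px, self.theta_deg])):
            raise ValueError("rigid parameters must be finite")
        # normalise angle to (-180, 180]
        t = (self.theta_deg + 180.0) % 360.0 - 180.0
        self.theta_deg = 180.0 if t == -180.0 else t

    def to_sitk(self, shape: tuple[int, int]) -> sitk.Euler2DTransform:
        cy, cx = (np.asarray(shape) - 1) / 2.0
        tx = sitk.Euler2DTransform()
        tx.SetCenter((float(cx), float(cy)))
        tx.SetAngle(np.deg2rad(self.theta_deg))
        tx.SetTranslation((float(self.dx_px), float(self.dy_px)))
        return tx

    def apply(self, moving: np.ndarray) -> np.ndarray:
        """Resample ``moving`` into the fixed frame (linear interpolation)."""
        return _resample(moving, self.to_sitk(moving.shape))

    def magnitude(self, shape: tuple[int, int]) -> float:
        """Largest pixel displacement this motion induces on the image."""
        r = 0.5 * float(np.hypot(*shape))
        rot = 2.0 * r * np.sin(np.deg2rad(abs(self.theta_deg)) / 2.0)
        return float(np.hypot(self.dx_px, self.dy_px) + rot)


@dataclass
class TransformChain:
    """Rigid -> affine -> b-spline registration result.

    ``affine`` is the full linear motion (the rigid initialisation folded
    in) as a 2x3 matrix acting on homogeneous pixel (x, y) coordinates
    about the origin; ``deformation`` holds the cubic b-spline control
    grid (ITK coefficient layout) or ``None`` when the non-rigid stage was
    skipped.
    """

    rigid: RigidTransform
    affine: np.ndarray
    deformation: Optional[dict]
    shape: tuple[int, int]
    converged: bool = True
    objective_history: list = field(default_factory=list)
    crop_box: Optional[tuple[int, int, int, int]] = None

    def to_sitk(self) -> sitk.Transform:
        aff = sitk.AffineTransform(2)
        aff.SetMatrix(tuple(self.affine[:, :2].ravel()))
        aff.SetTranslation(tuple(self.affine[:, 2]))
        if self.deformation is None:
            return aff
        btx = _bspline_from_dict(self.deformation)
        total = sitk.CompositeTransform(2)
        total.AddTransform(aff)
        total.AddTransform(btx)  # applied first (fixed -> bspline -> affine)
        return total

    def apply(self, moving: np.ndarray) -> np.ndarray:
        return _resample(moving, self.to_sitk())

    def valid_mask(self, shape: Optional[tuple[int, int]] = None) -> np.ndarray:
        """Pixels of the fixed frame that map inside the moving image."""
        shape = shape or self.shape
        ones = np.ones(shape, dtype=np.float32)
        return _resample(ones, self.to_sitk()) > _VALID_EPS

    def displacement_field(self) -> np.ndarray:
        """Dense (2, ny, nx) displacement (dx, dy) of the motion map."""
        f = sitk.TransformToDisplacementFieldFilter()
        f.SetReferenceImage(sitk.Image(self.shape[1], self.shape[0], sitk.sitkFloat32))
        disp = sitk.GetArrayFromImage(f.Execute(self.to_sitk()))
        return np.moveaxis(disp, -1, 0)

    def to_params(self) -> dict:
        out = {
            "rigid": {
                "dx_px": self.rigid.dx_px,
                "dy_px": self.rigid.dy_px,
                "theta_deg": self.rigid.theta_deg,
            },
            "affine": self.affine.tolist(),
            "converged": bool(self.converged),
            "objective_history": [float(v) for v in self.objective_history],
        }
        if self.deformation is not None:
            out["deformation"] = {
                "fixed_parameters": list(self.deformation["fixed_parameters"]),
                "parameters": list(self.deformation["parameters"]),
            }
        return out


def _resample(moving: np.ndarray, tx: sitk.Transform, default: float = 0.0):
    img = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float32))
    out = sitk.Resample(img, img, tx, sitk.sitkLinear, default, sitk.sitkFloat32)
    return sitk.GetArrayFromImage(out)


def _bspline_from_dict(d: dict) -> sitk.BSplineTransform:
    btx = sitk.BSplineTransform(2, 3)
    btx.SetFixedParameters([float(v) for v in d["fixed_parameters"]])
    btx.SetParameters([float(v) for v in d["parameters"]])
    return btx


def _affine_motion_matrix(tx) -> np.ndarray:
    """2x3 matrix of an sitk linear transform about the origin."""
    a = np.asarray(tx.GetMatrix()).reshape(2, 2)
    c = np.asarray(tx.GetCenter())
    t = np.asarray(tx.GetTranslation())
    offset = c + t - a @ c
    return np.hstack([a, offset[:, None]])


# ---------------------------------------------------------------------------
# rigid estimation


def estimate_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    upsample_factor: int = 20,
    rotation_bins: int = 720,
) -> RigidTransform:
    """Estimate the rigid motion of ``moving`` relative to ``fixed``.

    Translation comes from phase correlation; rotation from phase
    correlation of log-polar resampled Fourier magnitudes (translation
    invariant). If the angular correlation is multi-modal the candidate
    with the higher image correlation wins and the ambiguity is logged.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a shape")
    if fixed.max() == fixed.min() or moving.max() == moving.min():
        raise NoFeatureError("constant image has no registrable features")

    theta_candidates = _estimate_rotation_candidates(fixed, moving, rotation_bins)
    best = None
    for theta in theta_candidates:
        cand = _translation_given_rotation(fixed, moving, theta, upsample_factor)
        score = _alignment_score(fixed, cand.apply(moving))
        if best is None or score > best[0]:
            best = (score, cand)
    if len(theta_candidates) > 1:
        logger.warning(
            "rotation estimate multi-modal (%s deg); keeping best correlation",
            [round(t, 2) for t in theta_candidates],
        )
    return best[1]


def _estimate_rotation_candidates(fixed, moving, rotation_bins) -> list[float]:
    win = skwindow("hann", fixed.shape)
    spec_f = np.abs(np.fft.fftshift(np.fft.fft2(fixed * win)))
    spec_m = np.abs(np.fft.fftshift(np.fft.fft2(moving * win)))
    radius = min(fixed.shape) // 2
    pol_f = warp_polar(spec_f, radius=radius, output_shape=(rotation_bins, radius))
    pol_m = warp_polar(spec_m, radius=radius, output_shape=(rotation_bins, radius))
    # ignore the DC-dominated innermost radii
    pol_f, pol_m = pol_f[:, radius // 8 :], pol_m[:, radius // 8 :]
    shift, error, _ = phase_cross_correlation(
        pol_f, pol_m, upsample_factor=10, normalization=None
    )
    dtheta = 360.0 / rotation_bins
    theta = -float(shift[0]) * dtheta
    # Fourier magnitude is pi-periodic: theta and theta-180 are equivalent
    candidates = [theta]
    alt = theta - 180.0 if theta > 0 else theta + 180.0
    if abs(alt) < 175.0:
        candidates.append(alt)
    # keep magnitudes sane: prefer small rotations first
    candidates.sort(key=abs)
    return candidates[:2]


def _translation_given_rotation(fixed, moving, theta_deg, upsample_factor):
    derot = RigidTransform(0.0, 0.0, theta_deg).apply(moving)
    shift, error, _ = phase_cross_correlation(
        fixed, derot, upsample_factor=upsample_factor, normalization=None
    )
    # phase_cross_correlation returns the shift registering `derot` onto
    # `fixed`; the motion is its negation, expressed before derotation
    t_local = -np.array([shift[1], shift[0]])  # (dx, dy)
    th = np.deg2rad(theta_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    dx, dy = rot @ t_local
    return RigidTransform(float(dx), float(dy), float(theta_deg))


def _alignment_score(fixed, resampled) -> float:
    mask = resampled != 0
    if mask.sum() < 64:
        return -np.inf
    a = fixed[mask] - fixed[mask].mean()
    b = resampled[mask] - resampled[mask].mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float((a * b).sum() / denom) if denom > 0 else -np.inf


# ---------------------------------------------------------------------------
# affine + b-spline refinement


def refine_affine_bspline(
    fixed: np.ndarray,
    moving: np.ndarray,
    init: Optional[RigidTransform] = None,
    control_spacing_px: float = 32.0,
    max_displacement_px: float = 10.0,
    bspline_iterations: int = 100,
    sampling_fraction: float = 0.25,
) -> TransformChain:
    """Least-squares refinement: affine first, then cubic b-spline FFD.

    Both stages minimise the mean squared intensity difference on a
    regular (deterministic) pixel subsample. Each stage keeps its result
    only if the objective did not increase; otherwise the previous
    stage's transform is retained and the chain is flagged unconverged.
    """
    fixed = np.asarray(fixed, dtype=np.float32)
    moving = np.asarray(moving, dtype=np.float32)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a shape")
    if init is None:
        init = RigidTransform(0.0, 0.0, 0.0)

    fixed_s = sitk.GetImageFromArray(fixed)
    moving_s = sitk.GetImageFromArray(moving)

    rigid_tx = init.to_sitk(fixed.shape)
    history = [_masked_ssd(fixed, moving, rigid_tx)]
    converged = True

    # --- affine stage, initialised at the rigid estimate
    aff = sitk.AffineTransform(2)
    aff.SetCenter(rigid_tx.GetCenter())
    aff.SetMatrix(rigid_tx.GetMatrix())
    aff.SetTranslation(rigid_tx.GetTranslation())
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=150, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetMetricSamplingStrategy(reg.REGULAR)
    reg.SetMetricSamplingPercentage(sampling_fraction, 12345)
    reg.SetInitialTransform(aff, inPlace=True)
    try:
        reg.Execute(fixed_s, moving_s)
    except RuntimeError as exc:  # optimizer failure: keep rigid init
        logger.warning("affine stage failed (%s); keeping rigid", exc)
        converged = False
    ssd_aff = _masked_ssd(fixed, moving, aff)
    if ssd_aff > history[-1]:
        aff = sitk.AffineTransform(2)
        aff.SetCenter(rigid_tx.GetCenter())
        aff.SetMatrix(rigid_tx.GetMatrix())
        aff.SetTranslation(rigid_tx.GetTranslation())
        ssd_aff = history[-1]
        converged = False
    history.append(ssd_aff)

    # --- b-spline stage on top of the affine
    ny, nx = fixed.shape
    mesh = [max(1, int(round(nx / control_spacing_px))),
            max(1, int(round(ny / control_spacing_px)))]
    btx = sitk.BSplineTransformInitializer(fixed_s, mesh)
    reg2 = sitk.ImageRegistrationMethod()
    reg2.SetMetricAsMeanSquares()
    reg2.SetInterpolator(sitk.sitkLinear)
    reg2.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-9,
        numberOfIterations=bspline_iterations,
        maximumNumberOfCorrections=7,
    )
    reg2.SetMetricSamplingStrategy(reg2.REGULAR)
    reg2.SetMetricSamplingPercentage(sampling_fraction, 12345)
    reg2.SetMovingInitialTransform(aff)
    reg2.SetInitialTransform(btx, inPlace=True)
    deformation = None
    try:
        reg2.Execute(fixed_s, moving_s)
        params = np.asarray(btx.GetParameters())
        if np.abs(params).max() <= max_displacement_px:
            total = sitk.CompositeTransform(2)
            total.AddTransform(aff)
            total.AddTransform(btx)
            ssd_b = _masked_ssd(fixed, moving, total)
            if ssd_b <= history[-1]:
                deformation = {
                    "fixed_parameters": list(btx.GetFixedParameters()),
                    "parameters": list(btx.GetParameters()),
                    "control_spacing_px": float(control_spacing_px),
                }
                history.append(ssd_b)
            else:
                converged = False
                history.append(history[-1])
        else:
            logger.warning("b-spline displacements exceed bound; discarded")
            converged = False
            history.append(history[-1])
    except RuntimeError as exc:
        logger.warning("b-spline stage failed (%s); keeping affine", exc)
        converged = False
        history.append(history[-1])

    return TransformChain(
        rigid=init,
        affine=_affine_motion_matrix(aff),
        deformation=deformation,
        shape=tuple(fixed.shape),
        converged=converged,
        objective_history=history,
    )


def _masked_ssd(fixed: np.ndarray, moving: np.ndarray, tx: sitk.Transform) -> float:
    """Mean squared intensity difference over validly mapped pixels."""
    res = _resample(moving, tx, default=np.nan)
    ones = _resample(np.ones_like(moving, dtype=np.float32), tx)
    mask = (ones > _VALID_EPS) & np.isfinite(res)
    if mask.sum() < 64:
        return np.inf
    return float(np.mean((fixed[mask] - res[mask]) ** 2))


# ---------------------------------------------------------------------------
# stack registration


def register_stack(
    stack: Sequence[np.ndarray],
    reference_policy: Literal["first", "middle", "previous"] = "first",
    mode: Literal["full", "rigid"] = "full",
    control_spacing_px: float = 32.0,
):
    """Register every frame of a stack into a common reference frame.

    ``reference_policy``:

    - ``first`` / ``middle``: each frame registered directly to that frame
      (default for OCTA repeat sets).
    - ``previous``: rigid motion is estimated frame-to-frame and composed,
      tracking slow drift in long videos; non-rigid refinement (if
      ``mode == 'full'``) still runs against the reference.

    Returns ``(chains, registered, crop_box)`` where ``crop_box`` is the
    ``(row0, col0, height, width)`` rectangle of the reference frame
    covered by every registered frame; the returned stack is cropped to it.
    """
    frames = [np.asarray(f, dtype=np.float32) for f in stack]
    if len(frames) < 2:
        raise TooShortError("need at least 2 frames to register")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError("all frames must share a shape")

    ref_idx = {"first": 0, "middle": len(frames) // 2, "previous": 0}[
        reference_policy
    ]
    reference = frames[ref_idx]

    chains: list[TransformChain] = []
    prev_rigid = RigidTransform(0.0, 0.0, 0.0)
    for i, frame in enumerate(frames):
        if i == ref_idx:
            rigid = RigidTransform(0.0, 0.0, 0.0)
        elif reference_policy == "previous":
            step = estimate_rigid(frames[i - 1], frame)
            rigid = _compose_rigid(prev_rigid, step, frame.shape)
        else:
            rigid = estimate_rigid(reference, frame)
        prev_rigid = rigid

        if mode == "full" and i != ref_idx:
            chain = refine_affine_bspline(
                reference, frame, init=rigid, control_spacing_px=control_spacing_px
            )
        else:
            chain = TransformChain(
                rigid=rigid,
                affine=_affine_motion_matrix(rigid.to_sitk(frame.shape)),
                deformation=None,
                shape=tuple(frame.shape),
            )
        chains.append(chain)

    registered = np.stack([c.apply(f) for c, f in zip(chains, frames)])
    valid = np.logical_and.reduce([c.valid_mask() for c in chains])
    crop = _largest_valid_box(valid)
    if crop is None:
        raise ExcessiveMotionError("registered frames share no common region")
    r0, c0, h, w = crop
    for c in chains:
        c.crop_box = crop
    return chains, registered[:, r0 : r0 + h, c0 : c0 + w], crop


def _compose_rigid(a: RigidTransform, b: RigidTransform, shape) -> RigidTransform:
    """Motion of frame i vs reference: a (i-1 vs ref) composed with b (i vs i-1)."""
    ma = _affine_motion_matrix(a.to_sitk(shape))
    mb = _affine_motion_matrix(b.to_sitk(shape))
    ha = np.vstack([ma, [0, 0, 1]])
    hb = np.vstack([mb, [0, 0, 1]])
    m = ha @ hb  # fixed -> (i-1) -> i
    theta = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
    # translation after rotation about centre
    cy, cx = (np.asarray(shape) - 1) / 2.0
    c = np.array([cx, cy])
    t = m[:2, :2] @ c + m[:2, 2] - c
    return RigidTransform(float(t[0]), float(t[1]), float(theta))


def _largest_valid_box(valid: np.ndarray):
    """Greedy border trim: shave the border line with most invalid pixels."""
    r0, c0 = 0, 0
    r1, c1 = valid.shape
    while r1 > r0 and c1 > c0:
        sub = valid[r0:r1, c0:c1]
        if sub.all():
            return (r0, c0, r1 - r0, c1 - c0)
        bad = [
            (~sub[0]).sum(),
            (~sub[-1]).sum(),
            (~sub[:, 0]).sum(),
            (~sub[:, -1]).sum(),
        ]
        k = int(np.argmax(bad))
        if k == 0:
            r0 += 1
        elif k == 1:
            r1 -= 1
        elif k == 2:
            c0 += 1
        else:
            c1 -= 1
    return None
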