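"""Widefield fluorescence preprocessing.

Fixed stage order: within-session subpixel registration of the blue
channel (transforms reused for violet), across-session affine
registration, brain masking, 7 Hz low-pass filtering, then per-pixel
hemodynamic regression of blue on violet.  The regression residuals are
the corrected stacks consumed by every later stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import affine_transform, fourier_shift
from scipy.signal import butter, filtfilt
from skimage.registration import phase_cross_correlation
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class ImageStack:
    """One channel of a 5-minute widefield trial (frames, height, width)."""

    frames: np.ndarray
    channel: str  # "blue" or "violet"
    fps_per_channel: float
    session_id: str = ""
    mouse_id: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if self.fps_per_channel <= 0:
            raise ValueError("fps_per_channel must be positive")
        if self.channel not in ("blue", "violet", "corrected"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def copy_with(self, frames: np.ndarray, channel: str | None = None) -> "ImageStack":
        return ImageStack(frames, channel or self.channel, self.fps_per_channel,
                          self.session_id, self.mouse_id, self.mask)


@dataclass
class RegistrationTransform:
    """A per-frame translation or per-session affine, logged as JSON."""

    kind: str  # "translation" | "affine"
    parameters: np.ndarray  # (dy, dx) or 2x3 matrix
    reference_image_id: str = ""

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind,
                           "parameters": np.asarray(self.parameters).tolist(),
                           "reference_image_id": self.reference_image_id})


def write_interleaved_tiff(path, blue: ImageStack, violet: ImageStack) -> None:
    """Write a dual-channel stack as interleaved multi-page TIFF.

    Odd pages (1-based) are blue, even pages violet — the first image in
    a stack is always from the blue channel.
    """
    import tifffile

    if blue.n_frames != violet.n_frames:
        raise ValueError("blue and violet frame counts differ")
    inter = np.empty((2 * blue.n_frames, *blue.image_shape), dtype=np.float32)
    inter[0::2] = blue.frames
    inter[1::2] = violet.frames
    tifffile.imwrite(path, inter, metadata={"channels": "blue,violet interleaved"})


def read_interleaved_tiff(path, fps_per_channel: float = 20.0,
                          session_id: str = "", mouse_id: str = "") -> tuple[ImageStack, ImageStack]:
    """Read an interleaved stack, validating the blue-first convention.

    Stacks with an odd page count cannot satisfy blue/violet interleaving
    and are rejected.
    """
    import tifffile

    frames = tifffile.imread(path)
    if frames.ndim != 3 or frames.shape[0] % 2 != 0:
        raise ValueError(f"{path}: not a valid interleaved dual-channel stack")
    blue = ImageStack(frames[0::2], "blue", fps_per_channel, session_id, mouse_id)
    violet = ImageStack(frames[1::2], "violet", fps_per_channel, session_id, mouse_id)
    return blue, violet


def select_representative_image(sessions: list[list[ImageStack]],
                                mouse_reference_index: int = 0) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-session and per-mouse reference images.

    The per-session reference is the first blue frame of the session's
    first stack.  The per-mouse reference is the session reference at
    ``mouse_reference_index`` (a configurable stand-in for the manual
    "clearest and most centered" choice).
    """
    refs = []
    for si, stacks in enumerate(sessions):
        blues = [s for s in stacks if s.channel == "blue"]
        if not blues:
            raise ValueError(f"session {si} has no blue stack")
        refs.append(np.asarray(blues[0].frames[0], float))
    return refs, refs[mouse_reference_index]


def register_within_session(
    blue: ImageStack,
    violet: ImageStack,
    reference: np.ndarray,
    upsample_factor: int = 20,
) -> tuple[ImageStack, ImageStack, list[RegistrationTransform]]:
    """Subpixel translation of every blue frame onto the session reference.

    Shifts are estimated by phase cross-correlation on the blue channel
    only; each violet frame receives its paired blue frame's transform
    verbatim.
    """
    if blue.n_frames != violet.n_frames:
        raise ValueError("blue and violet frame counts differ")
    ref = np.asarray(reference, float)
    out_b = np.empty_like(blue.frames, dtype=np.float32)
    out_v = np.empty_like(violet.frames, dtype=np.float32)
    transforms = []
    for i in range(blue.n_frames):
        shift, _, _ = phase_cross_correlation(ref, blue.frames[i],
                                              upsample_factor=upsample_factor,
                                              normalization=None)
        transforms.append(RegistrationTransform("translation", np.asarray(shift, float)))
        for src, dst in ((blue.frames[i], out_b), (violet.frames[i], out_v)):
            if np.allclose(shift, 0):
                dst[i] = src
            else:
                dst[i] = np.fft.ifftn(fourier_shift(np.fft.fftn(src.astype(float)), shift)).real
    return blue.copy_with(out_b), violet.copy_with(out_v), transforms


def estimate_affine(moving: np.ndarray, reference: np.ndarray) -> RegistrationTransform:
    """Intensity-based affine (MSE metric, multi-resolution) via SimpleITK."""
    import SimpleITK as sitk

    fixed = sitk.GetImageFromArray(np.asarray(reference, np.float32))
    mov = sitk.GetImageFromArray(np.asarray(moving, np.float32))
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-5, numberOfIterations=300,
        relaxationFactor=0.5, gradientMagnitudeTolerance=1e-6)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(
        sitk.CenteredTransformInitializer(fixed, mov, sitk.AffineTransform(2),
                                          sitk.CenteredTransformInitializerFilter.GEOMETRY),
        inPlace=False)
    reg.SetInterpolator(sitk.sitkLinear)
    tx = reg.Execute(fixed, mov)
    if hasattr(tx, "Downcast"):
        tx = tx.Downcast()
    if isinstance(tx, sitk.CompositeTransform):
        tx = tx.GetNthTransform(tx.GetNumberOfTransforms() - 1)
        if hasattr(tx, "Downcast"):
            tx = tx.Downcast()
    tx = sitk.AffineTransform(tx)
    A = np.asarray(tx.GetMatrix(), float).reshape(2, 2)
    c = np.asarray(tx.GetCenter(), float)
    t = np.asarray(tx.GetTranslation(), float)
    # sitk maps fixed -> moving in (x, y); convert to a (row, col) 2x3 matrix
    # usable with scipy.ndimage.affine_transform (output -> input mapping).
    offset = c + t - A @ c
    P = np.array([[0.0, 1.0], [1.0, 0.0]])  # swap (x, y) <-> (row, col)
    A_rc = P @ A @ P
    off_rc = P @ offset
    if abs(np.linalg.det(A_rc)) < 1e-6:
        raise RuntimeError("affine estimation diverged (singular matrix)")
    params = np.column_stack([A_rc, off_rc])
    return RegistrationTransform("affine", params)


def apply_affine(frames: np.ndarray, transform: RegistrationTransform) -> np.ndarray:
    A = transform.parameters[:, :2]
    off = transform.parameters[:, 2]
    out = np.empty_like(frames, dtype=np.float32)
    for i in range(frames.shape[0]):
        out[i] = affine_transform(frames[i].astype(float), A, offset=off, order=1)
    return out


def register_across_sessions(
    session_stacks: list[tuple[ImageStack, ImageStack]],
    session_references: list[np.ndarray],
    mouse_reference: np.ndarray,
) -> tuple[list[tuple[ImageStack, ImageStack]], list[RegistrationTransform]]:
    """One affine per session, estimated on its reference image and applied
    to every frame of both channels."""
    out, transforms = [], []
    for (blue, violet), ref in zip(session_stacks, session_references):
        tx = estimate_affine(ref, mouse_reference)
        transforms.append(tx)
        out.append((blue.copy_with(apply_affine(blue.frames, tx)),
                    violet.copy_with(apply_affine(violet.frames, tx))))
    return out, transforms


def apply_brain_mask(stack: ImageStack, mask: np.ndarray) -> ImageStack:
    """Zero out non-brain pixels and attach the mask for downstream stages."""
    mask = np.asarray(mask, bool)
    if mask.shape != stack.image_shape:
        raise ValueError("mask shape does not match frames")
    if not mask.any():
        raise ValueError("brain mask is empty")
    frames = stack.frames * mask
    out = stack.copy_with(frames)
    out.mask = mask
    return out


def lowpass_filter(data: np.ndarray, fps: float, cutoff: float = 7.0,
                   order: int = 5) -> np.ndarray:
    """Zero-phase 5th-order Butterworth low-pass along the time axis.

    Applied forward and backward (filtfilt), so the effective magnitude
    response is the squared Butterworth response with no phase delay.
    """
    nyq = fps / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    b, a = butter(order, cutoff / nyq, btype="low")
    return filtfilt(b, a, np.asarray(data, float), axis=0)


def lowpass_stack(stack: ImageStack, cutoff: float = 7.0, order: int = 5) -> ImageStack:
    flat = stack.frames.reshape(stack.n_frames, -1)
    filt = lowpass_filter(flat, stack.fps_per_channel, cutoff, order)
    return stack.copy_with(filt.reshape(stack.frames.shape).astype(np.float32))


class HemodynamicCorrector(BaseEstimator, TransformerMixin):
    """Per-pixel regression of the blue channel on the violet channel.

    For every pixel within a 5-minute stack, blue is regressed on violet
    (simple linear regression with intercept); the residuals are the
    hemodynamic-corrected fluorescence.  Zero-variance violet pixels get
    slope 0 (residual = blue minus its mean) and are flagged.

    Attributes
    ----------
    slope_ : (n_pixels,) regression slopes
    intercept_ : (n_pixels,) intercepts
    flagged_ : boolean mask of zero-variance violet pixels
    """

    def fit(self, blue: np.ndarray, violet: np.ndarray) -> "HemodynamicCorrector":
        B = np.asarray(blue, float).reshape(blue.shape[0], -1)
        V = np.asarray(violet, float).reshape(violet.shape[0], -1)
        if B.shape != V.shape:
            raise ValueError("blue and violet shapes differ")
        vm = V.mean(axis=0)
        bm = B.mean(axis=0)
        vc = V - vm
        var_v = (vc**2).sum(axis=0)
        self.flagged_ = var_v <= 1e-12 * max(1.0, float(np.abs(V).max()) ** 2)
        cov = ((B - bm) * vc).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(self.flagged_, 0.0, cov / np.where(var_v == 0, 1.0, var_v))
        self.slope_ = slope
        self.intercept_ = bm - slope * vm
        self._shape = blue.shape[1:]
        return self

    def transform(self, blue: np.ndarray, violet: np.ndarray) -> np.ndarray:
        B = np.asarray(blue, float).reshape(blue.shape[0], -1)
        V = np.asarray(violet, float).reshape(violet.shape[0], -1)
        resid = B - (self.intercept_ + self.slope_ * V)
        return resid.reshape(blue.shape)

    def fit_transform(self, blue, violet):  # noqa: D102 (sklearn signature adapted)
        return self.fit(blue, violet).transform(blue, violet)


def hemodynamic_correction(blue: ImageStack, violet: ImageStack) -> ImageStack:
    """Corrected stack = residuals of per-pixel blue-on-violet regression."""
    if blue.n_frames != violet.n_frames:
        raise ValueError("blue and violet frame counts differ")
    corr = HemodynamicCorrector().fit_transform(blue.frames, violet.frames)
    out = blue.copy_with(corr.astype(np.float32), channel="corrected")
    return out


def preprocess_trial(
    blue: ImageStack,
    violet: ImageStack,
    session_reference: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    cutoff: float = 7.0,
    order: int = 5,
    register: bool = True,
) -> ImageStack:
    """Full single-trial pipeline in the fixed order:
    register -> mask -> low-pass -> hemodynamic regression."""
    if register and session_reference is not None:
        blue, violet, _ = register_within_session(blue, violet, session_reference)
    if mask is not None:
        blue = apply_brain_mask(blue, mask)
        violet = apply_brain_mask(violet, mask)
    blue = lowpass_stack(blue, cutoff, order)
    violet = lowpass_stack(violet, cutoff, order)
    corrected = hemodynamic_correction(blue, violet)
    corrected.mask = mask
    return corrected
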