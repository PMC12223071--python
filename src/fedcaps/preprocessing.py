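"""Preprocessing chain for CT slices.

Stages, in default pipeline order: mutual-information rigid registration
(modality alignment), morphological skull stripping, Perona-Malik anisotropic
diffusion (edge-preserving denoising), and min-max intensity normalization.
An SSIM/PSNR quality gate screens synthetic cross-modality images before they
enter a training pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from skimage.morphology import disk

__all__ = [
    "StructuringElement",
    "RigidTransform",
    "DiffusionParams",
    "erode",
    "dilate",
    "skull_strip",
    "anisotropic_diffusion",
    "minmax_normalize",
    "mutual_information",
    "apply_rigid",
    "register_rigid",
    "quality_gate",
]


@dataclass(frozen=True)
class StructuringElement:
    """Disk-shaped binary footprint used by the morphological operators."""

    radius: int = 2

    @property
    def footprint(self) -> np.ndarray:
        fp = disk(self.radius).astype(bool)
        if not fp.any():
            raise ValueError("empty footprint")
        return fp


@dataclass(frozen=True)
class RigidTransform:
    """Shift (pixels) + rotation (degrees, about the image center)."""

    dy: float = 0.0
    dx: float = 0.0
    theta: float = 0.0

    def __post_init__(self):
        if not all(map(math.isfinite, (self.dy, self.dx, self.theta))):
            raise ValueError("transform parameters must be finite")
        if not -180.0 < self.theta <= 180.0:
            raise ValueError("theta must lie in (-180, 180]")


@dataclass(frozen=True)
class DiffusionParams:
    """Perona-Malik parameters.

    ``kappa`` is the conduction (edge-stop) scale in intensity units;
    gradients well below kappa are smoothed, those above are preserved.
    ``lam`` is the explicit-Euler step; 4-neighbour stability needs
    lam <= 0.25.
    """

    n_iter: int = 10
    kappa: float = 0.1
    lam: float = 0.2
    conduction: str = "exponential"

    def __post_init__(self):
        if not 0.0 < self.lam <= 0.25:
            raise ValueError("lam must be in (0, 0.25] for stability")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.conduction not in ("exponential", "rational"):
            raise ValueError("conduction must be 'exponential' or 'rational'")
        if self.n_iter < 0:
            raise ValueError("n_iter must be >= 0")


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion: pixels where the translated footprint fits inside."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_erosion(mask, structure=se.footprint, border_value=0)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation: pixels where the footprint intersects the set."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_dilation(mask, structure=se.footprint, border_value=0)


def skull_strip(
    image: np.ndarray,
    se: StructuringElement | None = None,
) -> np.ndarray:
    """Brain mask via threshold -> erode -> largest component -> dilate -> fill.

    Erosion detaches the thin bright skull ring from the brain; keeping the
    largest connected component drops the ring; dilation restores the eroded
    margin and hole filling recovers dark interior structures.  A blank image
    yields an empty mask (no error).
    """
    image = np.asarray(image, dtype=float)
    se = se or StructuringElement(radius=2)
    if np.ptp(image) <= 0:
        return np.zeros(image.shape, dtype=bool)
    fg = image > threshold_otsu(image)
    if not fg.any():
        return np.zeros(image.shape, dtype=bool)
    core = erode(fg, se)
    if not core.any():
        return np.zeros(image.shape, dtype=bool)
    labels, n = ndimage.label(core)
    sizes = ndimage.sum_labels(core, labels, index=range(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    mask = dilate(largest, se)
    mask = ndimage.binary_fill_holes(mask)
    # dilation may re-touch stray specks; keep one component
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def _conduction(grad: np.ndarray, kappa: float, kind: str) -> np.ndarray:
    if kind == "exponential":
        return np.exp(-((grad / kappa) ** 2))
    return 1.0 / (1.0 + (grad / kappa) ** 2)


def anisotropic_diffusion(image: np.ndarray, params: DiffusionParams) -> np.ndarray:
    """Perona-Malik diffusion, explicit scheme on 4-neighbourhoods.

    I_{t+1} = I_t + lam * sum_d c(|grad_d I|) * grad_d I over the four axial
    neighbours, with replicate (Neumann) boundaries so the global mean is
    conserved.  ``n_iter=0`` returns the input unchanged.
    """
    out = np.asarray(image, dtype=float).copy()
    for _ in range(params.n_iter):
        padded = np.pad(out, 1, mode="edge")
        d_n = padded[:-2, 1:-1] - out
        d_s = padded[2:, 1:-1] - out
        d_w = padded[1:-1, :-2] - out
        d_e = padded[1:-1, 2:] - out
        flux = sum(
            _conduction(np.abs(d), params.kappa, params.conduction) * d
            for d in (d_n, d_s, d_w, d_e)
        )
        out = out + params.lam * flux
    return out


def minmax_normalize(
    values: np.ndarray,
    new_min: float = 0.0,
    new_max: float = 1.0,
) -> np.ndarray:
    """Affine rescale so the output exactly spans [new_min, new_max].

    v' = (v - min) / (max - min) * (new_max - new_min) + new_min.  Rank order
    is preserved.  Constant input is rejected explicitly.
    """
    values = np.asarray(values, dtype=float)
    lo = values.min()
    hi = values.max()
    if hi <= lo:
        raise ValueError("constant input: min-max normalization undefined")
    return (values - lo) / (hi - lo) * (new_max - new_min) + new_min


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information in bits from the joint intensity histogram.

    MI = H(a) + H(b) - H(a, b) with base-2 logs; equal-width bins over each
    image's own range.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())

    return entropy(pa) + entropy(pb) - entropy(pj.ravel())


def apply_rigid(image: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Resample ``image`` under the transform (bilinear, replicate edges)."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    theta = math.radians(transform.theta)
    ca, sa = math.cos(theta), math.sin(theta)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    # output pixel -> source pixel (inverse map)
    yr = rr - cy - transform.dy
    xr = cc - cx - transform.dx
    src_r = ca * yr + sa * xr + cy
    src_c = -sa * yr + ca * xr + cx
    return ndimage.map_coordinates(
        image, [src_r, src_c], order=1, mode="nearest"
    )


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    max_shift: int = 8,
    angle_range: tuple[float, float] = (-10.0, 10.0),
    bins: int = 32,
    refine_angle: bool = True,
) -> tuple[RigidTransform, np.ndarray, float]:
    """Rigid registration by mutual-information maximization.

    Strategy: exhaustive integer-shift grid at zero rotation, then (optionally)
    a golden-section search over the rotation angle at the best shift, then a
    final half-pixel shift refinement.  Deterministic; returns
    (transform, resampled moving image, MI in bits).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("images must share a shape")
    if max_shift < 0 or angle_range[0] > angle_range[1]:
        raise ValueError("empty search range")

    def score(t: RigidTransform) -> float:
        return mutual_information(apply_rigid(moving, t), fixed, bins=bins)

    best_t = RigidTransform()
    best_s = score(best_t)
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            t = RigidTransform(dy=dy, dx=dx)
            s = score(t)
            if s > best_s:
                best_t, best_s = t, s

    if refine_angle and angle_range[1] > angle_range[0]:
        lo, hi = angle_range
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = score(RigidTransform(best_t.dy, best_t.dx, c))
        fd = score(RigidTransform(best_t.dy, best_t.dx, d))
        for _ in range(20):
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = score(RigidTransform(best_t.dy, best_t.dx, c))
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = score(RigidTransform(best_t.dy, best_t.dx, d))
        theta = (a + b) / 2.0
        cand = RigidTransform(best_t.dy, best_t.dx, theta)
        s = score(cand)
        if s > best_s:
            best_t, best_s = cand, s

    for ddy in (-0.5, 0.0, 0.5):
        for ddx in (-0.5, 0.0, 0.5):
            cand = RigidTransform(best_t.dy + ddy, best_t.dx + ddx, best_t.theta)
            s = score(cand)
            if s > best_s:
                best_t, best_s = cand, s

    return best_t, apply_rigid(moving, best_t), best_s


def quality_gate(
    candidate: np.ndarray,
    reference: np.ndarray,
    ssim_min: float = 0.75,
    psnr_min: float = 22.0,
) -> tuple[bool, float, float]:
    """SSIM/PSNR screen for synthetic images against their reference.

    Both images are assumed on the unit intensity range (peak = 1.0).
    Accept iff SSIM >= ssim_min AND PSNR >= psnr_min.  Identical images get
    PSNR = inf and pass.  A zero-variance reference is rejected as undefined.
    """
    candidate = np.asarray(candidate, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if candidate.shape != reference.shape:
        raise ValueError("images must share a shape")
    if np.ptp(reference) <= 0:
        raise ValueError("reference has zero dynamic range; SSIM undefined")
    ssim = float(
        structural_similarity(reference, candidate, data_range=1.0, gaussian_weights=True)
    )
    if np.array_equal(candidate, reference):
        psnr = float("inf")
    else:
        psnr = float(peak_signal_noise_ratio(reference, candidate, data_range=1.0))
    return (ssim >= ssim_min and psnr >= psnr_min), ssim, psnr
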