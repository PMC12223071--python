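"""Handcrafted and deep feature extraction.

Texture is summarized by gray-level co-occurrence matrices (GLCM) restricted
to a region of interest: intensities inside the ROI are min-max quantized to
``levels`` gray levels and pair counts are accumulated for each spatial
offset (both pixels of a pair must lie in the ROI).  First-order statistics
use population formulas (divide by N, not N-1) and non-excess kurtosis
(Gaussian -> 3).  Deep features are global-average-pooled convolutional maps;
fusion is a weighted concatenation of the deep and handcrafted blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GLCM",
    "FirstOrderStats",
    "FeatureVector",
    "compute_glcm",
    "glcm_contrast",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_correlation",
    "first_order_stats",
    "gap_pool",
    "fuse_features",
    "extract_handcrafted",
    "HANDCRAFTED_NAMES",
]

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0))


@dataclass
class GLCM:
    """Normalized co-occurrence matrix with its quantization metadata."""

    P: np.ndarray                      # levels x levels, sums to 1
    levels: int
    offset: tuple[int, int]
    symmetric: bool = True
    roi_id: str | None = None

    def validate(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.P.shape != (self.levels, self.levels):
            raise ValueError("P shape mismatch")
        if np.any(self.P < 0):
            raise ValueError("P entries must be >= 0")
        if not np.isclose(self.P.sum(), 1.0):
            raise ValueError("P must sum to 1")


@dataclass(frozen=True)
class FirstOrderStats:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    n_pixels: int


@dataclass
class FeatureVector:
    """Named feature values with provenance (handcrafted / deep / fused)."""

    names: list[str]
    values: np.ndarray
    provenance: str = "handcrafted"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def quantize_roi(image: np.ndarray, roi: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantize ROI intensities to integer levels 0..levels-1.

    Pixels outside the ROI are marked -1.  A constant ROI maps to level 0.
    """
    image = np.asarray(image, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    vals = image[roi]
    q = np.full(image.shape, -1, dtype=np.int64)
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        lv = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
        lv = np.clip(lv, 0, levels - 1)
    else:
        lv = np.zeros(image.shape, dtype=np.int64)
    q[roi] = lv[roi]
    return q


def compute_glcm(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    levels: int = 8,
    offset: tuple[int, int] = (0, 1),
    symmetric: bool = True,
) -> GLCM:
    """Co-occurrence matrix for one offset, both pixels restricted to ROI."""
    image = np.asarray(image, dtype=float)
    roi = np.ones(image.shape, dtype=bool) if roi is None else np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    q = quantize_roi(image, roi, levels)
    dr, dc = offset
    H, W = q.shape
    r0 = slice(max(0, -dr), min(H, H - dr))
    c0 = slice(max(0, -dc), min(W, W - dc))
    r1 = slice(max(0, dr), min(H, H + dr))
    c1 = slice(max(0, dc), min(W, W + dc))
    a = q[r0, c0]
    b = q[r1, c1]
    valid = (a >= 0) & (b >= 0)
    if valid.sum() < 1:
        raise ValueError("ROI provides fewer than one pixel pair at this offset")
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    P = counts / counts.sum()
    g = GLCM(P=P, levels=levels, offset=offset, symmetric=symmetric)
    g.validate()
    return g


def glcm_contrast(g: GLCM) -> float:
    """Sum_ij P(i,j) * (i - j)^2 — local intensity variation."""
    i, j = np.indices(g.P.shape)
    return float((g.P * (i - j) ** 2).sum())


def glcm_energy(g: GLCM) -> float:
    """Sum of squared GLCM entries — textural uniformity, in (0, 1]."""
    return float((g.P**2).sum())


def glcm_homogeneity(g: GLCM) -> float:
    """Sum_ij P(i,j) / (1 + |i - j|) — mass near the diagonal, in (0, 1]."""
    i, j = np.indices(g.P.shape)
    return float((g.P / (1.0 + np.abs(i - j))).sum())


def glcm_correlation(g: GLCM) -> float:
    """Standard GLCM correlation sum_ij (i-mu_i)(j-mu_j)P(i,j)/(s_i s_j)."""
    i, j = np.indices(g.P.shape)
    mu_i = float((g.P * i).sum())
    mu_j = float((g.P * j).sum())
    var_i = float((g.P * (i - mu_i) ** 2).sum())
    var_j = float((g.P * (j - mu_j) ** 2).sum())
    if var_i <= 0 or var_j <= 0:
        raise ValueError("zero marginal variance: correlation undefined")
    cov = float((g.P * (i - mu_i) * (j - mu_j)).sum())
    return cov / np.sqrt(var_i * var_j)


def first_order_stats(image: np.ndarray, roi: np.ndarray | None = None) -> FirstOrderStats:
    """Population mean / SD / skewness / non-excess kurtosis over the ROI."""
    image = np.asarray(image, dtype=float)
    roi = np.ones(image.shape, dtype=bool) if roi is None else np.asarray(roi, bool)
    vals = image[roi]
    n = vals.size
    if n < 1:
        raise ValueError("ROI must contain at least one pixel")
    mu = float(vals.mean())
    sd = float(np.sqrt(((vals - mu) ** 2).mean()))
    if n < 2 or sd == 0:
        raise ValueError("SD-normalized moments undefined for constant/singleton ROI")
    z = (vals - mu) / sd
    return FirstOrderStats(
        mean=mu,
        sd=sd,
        skewness=float((z**3).mean()),
        kurtosis=float((z**4).mean()),
        n_pixels=int(n),
    )


def gap_pool(feature_maps: np.ndarray) -> np.ndarray:
    """Global average pooling: per-channel spatial mean of a (C, H, W) stack."""
    feature_maps = np.asarray(feature_maps, dtype=float)
    if feature_maps.ndim != 3 or feature_maps.shape[0] == 0:
        raise ValueError("expected a non-empty (channels, H, W) stack")
    return feature_maps.mean(axis=(1, 2))


def fuse_features(
    deep: np.ndarray | FeatureVector,
    handcrafted: np.ndarray | FeatureVector,
    alpha: float = 1.0,
    beta: float = 1.0,
    mode: str = "concat",
) -> FeatureVector:
    """Fuse deep and handcrafted blocks: [alpha*deep || beta*handcrafted].

    ``mode='sum'`` computes alpha*deep + beta*handcrafted and requires equal
    lengths; concatenation is the default since the two blocks generally have
    different dimensionalities and concatenation preserves both for the
    downstream feature selector.
    """
    if alpha < 0 or beta < 0 or (alpha == 0 and beta == 0):
        raise ValueError("alpha, beta must be >= 0 and not both 0")
    d_names = deep.names if isinstance(deep, FeatureVector) else [
        f"deep_{i}" for i in range(np.size(np.asarray(deep)))
    ]
    h_names = handcrafted.names if isinstance(handcrafted, FeatureVector) else [
        f"hc_{i}" for i in range(np.size(np.asarray(handcrafted)))
    ]
    d = np.asarray(deep.values if isinstance(deep, FeatureVector) else deep, float)
    h = np.asarray(
        handcrafted.values if isinstance(handcrafted, FeatureVector) else handcrafted,
        float,
    )
    if d.size == 0 or h.size == 0:
        raise ValueError("empty feature block")
    if mode == "sum":
        if d.size != h.size:
            raise ValueError("weighted sum requires equal-length blocks")
        return FeatureVector(
            names=[f"fused_{i}" for i in range(d.size)],
            values=alpha * d + beta * h,
            provenance="fused",
        )
    names = [f"deep:{n}" for n in d_names] + [f"hc:{n}" for n in h_names]
    return FeatureVector(
        names=names,
        values=np.concatenate([alpha * d, beta * h]),
        provenance="fused",
    )


HANDCRAFTED_NAMES = [
    "glcm_contrast",
    "glcm_energy",
    "glcm_homogeneity",
    "glcm_correlation",
    "mean",
    "sd",
    "skewness",
    "kurtosis",
]


def extract_handcrafted(
    image: np.ndarray,
    roi: np.ndarray,
    levels: int = 8,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> FeatureVector:
    """GLCM texture (averaged over offsets) + first-order stats for one ROI.

    Degenerate ROIs (constant intensity) yield zero correlation and moments,
    flagged by sd == 0 rather than raising, so that batch extraction over a
    dataset never aborts on a blank region.
    """
    glcm_vals = np.zeros(4)
    n_ok = 0
    for off in offsets:
        try:
            g = compute_glcm(image, roi, levels=levels, offset=off)
        except ValueError:
            continue
        try:
            corr = glcm_correlation(g)
        except ValueError:
            corr = 0.0
        glcm_vals += np.array(
            [glcm_contrast(g), glcm_energy(g), glcm_homogeneity(g), corr]
        )
        n_ok += 1
    if n_ok:
        glcm_vals /= n_ok
    vals = np.asarray(image, dtype=float)[np.asarray(roi, bool)]
    mu = float(vals.mean()) if vals.size else 0.0
    sd = float(np.sqrt(((vals - mu) ** 2).mean())) if vals.size else 0.0
    if sd > 0:
        z = (vals - mu) / sd
        skew, kurt = float((z**3).mean()), float((z**4).mean())
    else:
        skew, kurt = 0.0, 0.0
    return FeatureVector(
        names=list(HANDCRAFTED_NAMES),
        values=np.array(
            [*glcm_vals, mu, sd, skew, kurt]
        ),
        provenance="handcrafted",
    )
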