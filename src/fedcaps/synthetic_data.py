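"""Synthetic CT-like brain phantoms and federated client partitions.

Each phantom is a 2D slice: an elliptical "brain" of intermediate intensity
surrounded by a bright "skull" ring on a dark background, optionally carrying
a bright, irregular tumor blob drawn strictly inside the brain.  Tumor
"types" are geometric presets (size / eccentricity / boundary roughness) that
exist only to drive client heterogeneity; they carry no biological meaning.

A second pseudo-modality channel is produced by a deterministic, strictly
monotone intensity remap followed by a small Gaussian blur — a stand-in for
a learned cross-modality translation that keeps the two domains aligned but
visually distinct.

Coordinates are (row, col), 0-based; masks are boolean arrays.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomSpec",
    "LabeledScan",
    "ClientProfile",
    "TUMOR_TYPE_PRESETS",
    "FEDERATED_TYPE_CYCLE",
    "generate_phantom",
    "generate_dataset",
    "make_pseudo_modality",
    "partition_clients",
    "default_client_profiles",
    "derive_seed",
]

#: (radius_scale, eccentricity, boundary_roughness) per geometric preset.
TUMOR_TYPE_PRESETS: dict[str, tuple[float, float, float]] = {
    "glioma-like": (1.0, 0.35, 0.35),      # larger, irregular boundary
    "meningioma-like": (0.8, 0.15, 0.15),  # rounder, smoother
    "pituitary-like": (0.6, 0.25, 0.20),   # small, central
}


class GeometryError(ValueError):
    """Requested geometry cannot be drawn (e.g. tumor does not fit)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic brain slice."""

    height: int = 64
    width: int = 64
    brain_axes: tuple[float, float] = (24.0, 20.0)   # (row, col) semi-axes
    csf_gap: float = 2.0      # dark rim between brain and skull (CSF-like)
    skull_thickness: float = 3.0
    tumor_present: bool = False
    tumor_type: str = "glioma-like"
    tumor_radius: float = 6.0
    intensity_background: float = 0.05
    intensity_brain: float = 0.45
    intensity_tumor: float = 0.75
    intensity_skull: float = 0.95
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8x8 pixels")
        if not (
            self.intensity_background
            < self.intensity_brain
            < self.intensity_tumor
            < self.intensity_skull
        ):
            raise ValueError(
                "intensity means must satisfy background < brain < tumor < skull"
            )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.tumor_type not in TUMOR_TYPE_PRESETS:
            raise ValueError(f"unknown tumor_type {self.tumor_type!r}")
        if self.tumor_present:
            scale = TUMOR_TYPE_PRESETS[self.tumor_type][0]
            eff = self.tumor_radius * scale
            if eff * 2.0 >= min(self.brain_axes):
                raise GeometryError(
                    f"tumor radius {eff:.1f} too large for brain axes "
                    f"{self.brain_axes}"
                )


@dataclass
class LabeledScan:
    """One image with its ground-truth masks and bookkeeping tags."""

    image: np.ndarray                 # H x W floats in [0, 1]
    brain_mask: np.ndarray            # bool
    tumor_mask: np.ndarray            # bool, subset of brain_mask
    label: str                        # "tumor" | "no-tumor"
    tumor_type: str | None = None
    client_id: str | None = None
    modality: str = "ct"
    scan_id: str = ""
    seed: int = 0

    def validate(self) -> None:
        if self.image.shape != self.brain_mask.shape != self.tumor_mask.shape:
            raise ValueError("image and masks must share one shape")
        if np.any(self.tumor_mask & ~self.brain_mask):
            raise ValueError("tumor_mask must lie inside brain_mask")
        has_tumor = bool(self.tumor_mask.any())
        if has_tumor != (self.label == "tumor"):
            raise ValueError("label inconsistent with tumor_mask")


@dataclass(frozen=True)
class ClientProfile:
    """Sample counts and tumor-type mix requested for one simulated client."""

    client_id: str
    n_ct: int
    n_pseudo: int = 0
    type_mix: dict[str, float] = field(
        default_factory=lambda: {k: 1 / 3 for k in TUMOR_TYPE_PRESETS}
    )
    distribution_kind: str = "iid"

    def validate(self) -> None:
        if self.n_ct < 0 or self.n_pseudo < 0:
            raise ValueError("sample counts must be >= 0")
        total = sum(self.type_mix.values())
        # all-zero mix means the client requests no tumor scans
        if self.type_mix and total != 0.0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_mix must sum to 1, got {total}")


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Per-item seed from a master seed, stable across run order.

    SHA-256 of the master seed plus identifying tokens, truncated below 2^31.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for tok in tokens:
        h.update(b"\x00")
        h.update(str(tok).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float = 0.0,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _rough_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    eccentricity: float,
    roughness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Star-convex blob: radius modulated by a low-order Fourier series."""
    a = radius * (1.0 + eccentricity)
    b = radius * (1.0 - eccentricity)
    angle = rng.uniform(0, np.pi)
    n_harm = 4
    amp = rng.uniform(-roughness, roughness, size=n_harm)
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)

    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    theta = np.arctan2(v / b, u / a)
    mod = np.ones_like(theta)
    for k in range(n_harm):
        mod = mod + amp[k] * np.cos((k + 2) * theta + phase[k])
    mod = np.clip(mod, 0.5, 1.5)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    blob = rho <= mod
    # keep a single connected component (roughness can pinch off slivers)
    labels, n = ndimage.label(blob)
    if n > 1:
        sizes = ndimage.sum_labels(blob, labels, index=range(1, n + 1))
        blob = labels == (1 + int(np.argmax(sizes)))
    return blob


def generate_phantom(spec: PhantomSpec) -> LabeledScan:
    """Draw one phantom deterministically from ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    center = (spec.height / 2.0, spec.width / 2.0)

    brain = _ellipse_mask(shape, center, spec.brain_axes)
    inner_axes = (
        spec.brain_axes[0] + spec.csf_gap,
        spec.brain_axes[1] + spec.csf_gap,
    )
    outer_axes = (
        inner_axes[0] + spec.skull_thickness,
        inner_axes[1] + spec.skull_thickness,
    )
    # the rim between brain and skull stays at background intensity (CSF-like)
    skull = _ellipse_mask(shape, center, outer_axes) & ~_ellipse_mask(
        shape, center, inner_axes
    )

    tumor = np.zeros(shape, dtype=bool)
    tumor_type: str | None = None
    if spec.tumor_present:
        scale, ecc, rough = TUMOR_TYPE_PRESETS[spec.tumor_type]
        radius = spec.tumor_radius * scale
        # center drawn so that even the roughest boundary (1.5x radius at
        # max eccentricity) stays inside the brain ellipse
        margin = radius * (1.0 + ecc) * 1.5
        max_r = (spec.brain_axes[0] - margin) * 0.9
        max_c = (spec.brain_axes[1] - margin) * 0.9
        if max_r <= 0 or max_c <= 0:
            raise GeometryError("tumor_radius too large to fit inside brain")
        t_center = (
            center[0] + rng.uniform(-max_r, max_r) * 0.7,
            center[1] + rng.uniform(-max_c, max_c) * 0.7,
        )
        tumor = _rough_blob(shape, t_center, radius, ecc, rough, rng)
        tumor &= brain
        tumor_type = spec.tumor_type

    image = np.full(shape, spec.intensity_background)
    image[brain] = spec.intensity_brain
    image[skull] = spec.intensity_skull
    image[tumor] = spec.intensity_tumor
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=shape)
    image = np.clip(image, 0.0, 1.0)

    scan = LabeledScan(
        image=image,
        brain_mask=brain,
        tumor_mask=tumor,
        label="tumor" if tumor.any() else "no-tumor",
        tumor_type=tumor_type,
        modality="ct",
        seed=spec.seed,
    )
    scan.validate()
    return scan


def generate_dataset(
    n: int,
    tumor_fraction: float,
    spec_template: PhantomSpec | None = None,
    seed: int = 0,
    type_cycle: Sequence[str] | None = None,
) -> list[LabeledScan]:
    """Generate ``n`` phantoms with exactly ``round(n * tumor_fraction)`` tumors.

    Per-scan seeds are derived by hashing the master seed with the scan index,
    so any subset of the dataset is reproducible independently of generation
    order.  Tumor types cycle through ``type_cycle`` (default: all presets).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    template = spec_template or PhantomSpec()
    types = list(type_cycle or TUMOR_TYPE_PRESETS)
    n_tumor = int(round(n * tumor_fraction))

    scans: list[LabeledScan] = []
    for i in range(n):
        with_tumor = i < n_tumor
        spec = replace(
            template,
            tumor_present=with_tumor,
            tumor_type=types[i % len(types)] if with_tumor else template.tumor_type,
            seed=derive_seed(seed, "phantom", i),
        )
        scan = generate_phantom(spec)
        scan.scan_id = f"scan-{i:05d}"
        scans.append(scan)
    return scans


def make_pseudo_modality(
    scan: LabeledScan,
    remap: Callable[[np.ndarray], np.ndarray] | None = None,
    blur_sigma: float = 0.8,
) -> LabeledScan:
    """Deterministic second-domain channel from a CT scan.

    ``remap`` must be strictly monotone on [0, 1] (checked on a dense grid);
    default is the gamma-like map v -> v**0.5 which brightens soft tissue.
    Masks and labels are untouched.
    """
    if scan.modality != "ct":
        raise ValueError("pseudo-modality is derived from a ct scan")
    if remap is None:
        remap = lambda v: np.sqrt(v)  # noqa: E731
    grid = np.linspace(0.0, 1.0, 257)
    mapped = np.asarray(remap(grid), dtype=float)
    if not np.all(np.diff(mapped) > 0):
        raise ValueError("remap must be strictly monotone increasing on [0,1]")
    image = np.asarray(remap(scan.image), dtype=float)
    if blur_sigma > 0:
        image = ndimage.gaussian_filter(image, blur_sigma, mode="nearest")
    lo, hi = mapped[0], mapped[-1]
    image = np.clip(image, min(lo, hi), max(lo, hi))
    out = LabeledScan(
        image=image,
        brain_mask=scan.brain_mask.copy(),
        tumor_mask=scan.tumor_mask.copy(),
        label=scan.label,
        tumor_type=scan.tumor_type,
        client_id=scan.client_id,
        modality="pseudo-mri",
        scan_id=scan.scan_id + "-pseudo" if scan.scan_id else "",
        seed=scan.seed,
    )
    out.validate()
    return out


#: Tumor-type generation cycle for federated experiments: glioma-weighted
#: (50/25/25) so the glioma-heavy client profiles below are satisfiable.
FEDERATED_TYPE_CYCLE: tuple[str, ...] = (
    "glioma-like",
    "glioma-like",
    "meningioma-like",
    "pituitary-like",
)


def default_client_profiles(total_ct: int = 100) -> list[ClientProfile]:
    """Five heterogeneous hospital profiles (one highly skewed, one IID).

    Mirrors a federated cohort where client 1 is glioma-heavy, client 2 splits
    meningioma/pituitary, client 3 holds only glioma, client 4 is balanced and
    client 5 leans pituitary.  Counts are scaled from ``total_ct`` with 20%
    head-room so the per-type draws stay feasible when the pool is generated
    with :data:`FEDERATED_TYPE_CYCLE`.
    """
    base = max((total_ct * 4 // 5) // 5, 1)
    g, m, p = "glioma-like", "meningioma-like", "pituitary-like"
    return [
        ClientProfile("client-1", base, 0, {g: 0.7, m: 0.3, p: 0.0}, "non-iid"),
        ClientProfile("client-2", base, 0, {g: 0.0, m: 0.5, p: 0.5}, "non-iid"),
        ClientProfile("client-3", base, 0, {g: 1.0, m: 0.0, p: 0.0}, "skewed"),
        ClientProfile("client-4", base, 0, {g: 1 / 3, m: 1 / 3, p: 1 / 3}, "iid"),
        ClientProfile("client-5", base, 0, {g: 0.4, m: 0.0, p: 0.6}, "non-iid"),
    ]


class PartitionShortage(ValueError):
    """Requested per-type counts exceed what the dataset provides."""

    def __init__(self, shortages: dict[str, int]):
        self.shortages = shortages
        super().__init__(f"not enough samples per type: {shortages}")


def _requested_counts(profile: ClientProfile) -> dict[str | None, int]:
    """Largest-remainder rounding of the type mix onto integer counts."""
    n_tumor_slots = profile.n_ct
    mix = {k: v for k, v in profile.type_mix.items() if v > 0}
    if not mix:
        return {None: profile.n_ct}
    raw = {k: v * n_tumor_slots for k, v in mix.items()}
    counts = {k: int(np.floor(r)) for k, r in raw.items()}
    leftover = n_tumor_slots - sum(counts.values())
    order = sorted(mix, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def partition_clients(
    dataset: Sequence[LabeledScan],
    profiles: Sequence[ClientProfile],
    seed: int = 0,
    tumor_fraction_per_client: float | None = None,
) -> dict[str, list[LabeledScan]]:
    """Split a dataset into disjoint per-client subsets honouring type mixes.

    Each profile's ``n_ct`` CT scans are drawn without replacement: tumor scans
    according to ``type_mix`` (within +-1 sample by largest-remainder
    rounding), the remainder from no-tumor scans when
    ``tumor_fraction_per_client`` (default 0.5) reserves a share for them.
    ``n_pseudo`` pseudo-modality scans are synthesised from the client's own
    CT scans, so no extra pool is consumed.

    Raises :class:`PartitionShortage` listing per-type deficits when the
    request is infeasible.
    """
    rng = np.random.default_rng(derive_seed(seed, "partition"))
    tf = 0.5 if tumor_fraction_per_client is None else tumor_fraction_per_client

    pools: dict[str | None, list[int]] = {}
    for idx, scan in enumerate(dataset):
        key = scan.tumor_type if scan.label == "tumor" else None
        pools.setdefault(key, []).append(idx)
    for key in pools:
        pools[key] = list(rng.permutation(pools[key]))

    shortages: dict[str, int] = {}
    demands: list[tuple[ClientProfile, dict[str | None, int]]] = []
    for profile in profiles:
        profile.validate()
        n_tumor = int(round(profile.n_ct * tf))
        n_plain = profile.n_ct - n_tumor
        counts = _requested_counts(
            ClientProfile(
                profile.client_id, n_tumor, profile.n_pseudo,
                profile.type_mix, profile.distribution_kind,
            )
        )
        counts[None] = counts.get(None, 0) + n_plain
        demands.append((profile, counts))
    totals: dict[str | None, int] = {}
    for _, counts in demands:
        for key, c in counts.items():
            totals[key] = totals.get(key, 0) + c
    for key, need in totals.items():
        have = len(pools.get(key, []))
        if need > have:
            shortages[str(key)] = need - have
    if shortages:
        raise PartitionShortage(shortages)

    result: dict[str, list[LabeledScan]] = {}
    for profile, counts in demands:
        picked: list[LabeledScan] = []
        for key, c in counts.items():
            pool = pools.get(key, [])
            take, pools[key] = pool[:c], pool[c:]
            for idx in take:
                scan = dataset[idx]
                scan = LabeledScan(
                    image=scan.image,
                    brain_mask=scan.brain_mask,
                    tumor_mask=scan.tumor_mask,
                    label=scan.label,
                    tumor_type=scan.tumor_type,
                    client_id=profile.client_id,
                    modality=scan.modality,
                    scan_id=scan.scan_id,
                    seed=scan.seed,
                )
                picked.append(scan)
        for j in range(profile.n_pseudo):
            src = picked[j % len(picked)] if picked else None
            if src is None:
                break
            pseudo = make_pseudo_modality(src)
            pseudo.client_id = profile.client_id
            picked.append(pseudo)
        result[profile.client_id] = picked
    return result
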