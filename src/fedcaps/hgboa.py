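"""Hybrid Gorilla-Badger optimization (continuous search + feature selection).

The optimizer hybridizes Gorilla Troops Optimization (GTO) with a Honey
Badger Algorithm (HBA)-style exploitation move.  Each agent, every
iteration, receives

* an exploration proposal — a three-branch rule: uniform re-draw in the
  bounds with probability of the branch gate falling below ``p``; a move
  toward a random member scaled by the decaying amplitude ``C``; or a
  perturbation along the difference to a random member scaled by a random
  sign ``gamma`` in [-1, 1];
* an exploitation proposal — either "follow the silverback"
  (delta * rand * (|x - x_sb| + x) with delta = sin(2.5 - t/T)) when the
  amplitude |C| is at least ``beta``, or the badger-style "fight" move
  x_sb + F * rand * alpha * (x_sb - x) with alpha = 2 exp(-t/T) and flag
  F in {-1, +1};

and each proposal is accepted greedily (kept only if it improves the
agent's fitness).  The best-so-far agent is the *silverback*; its trace is
therefore monotone non-increasing.

For feature selection, agents live in [0, 1]^d; a position is binarized at
0.5 into a feature mask and scored by
``w * (1 - cv_accuracy) + (1 - w) * selected/total``, so the optimizer
trades classification accuracy against subset size.  The feature reduction
rate FRR = 100 * (1 - selected/total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid

__all__ = [
    "SearchSpace",
    "HGBOAParams",
    "Population",
    "delta_schedule",
    "alpha_schedule",
    "follow_silverback",
    "fight_update",
    "explore_update",
    "optimize",
    "select_features",
    "feature_reduction_rate",
    "SelectionResult",
]


@dataclass(frozen=True)
class SearchSpace:
    dim: int
    lb: np.ndarray
    ub: np.ndarray

    @classmethod
    def cube(cls, dim: int, lo: float, hi: float) -> "SearchSpace":
        return cls(dim, np.full(dim, float(lo)), np.full(dim, float(hi)))

    def __post_init__(self):
        object.__setattr__(self, "lb", np.asarray(self.lb, dtype=float))
        object.__setattr__(self, "ub", np.asarray(self.ub, dtype=float))
        if self.lb.shape != (self.dim,) or self.ub.shape != (self.dim,):
            raise ValueError("bounds must have shape (dim,)")
        if not np.all(self.lb < self.ub):
            raise ValueError("require lb < ub elementwise")


@dataclass(frozen=True)
class HGBOAParams:
    """Control parameters.

    ``p`` gates the uniform-reinitialization exploration branch (default
    0.03, the GTO convention); ``beta`` switches the exploitation move:
    follow-the-silverback when |C| >= beta, badger-style fight otherwise.
    ``bounds_mode`` is "clip" or "reflect".
    """

    T: int = 100
    M: int = 30
    p: float = 0.03
    beta: float = 0.8
    seed: int = 0
    bounds_mode: str = "clip"

    def __post_init__(self):
        if self.T < 1 or self.M < 2:
            raise ValueError("require T >= 1 and M >= 2")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.bounds_mode not in ("clip", "reflect"):
            raise ValueError("bounds_mode must be 'clip' or 'reflect'")


@dataclass
class Population:
    positions: np.ndarray              # M x dim
    fitness: np.ndarray                # M
    silverback: np.ndarray
    best_fitness: float
    t: int
    trace: list[float] = field(default_factory=list)


def delta_schedule(t: float, T: float) -> float:
    """delta = sin(2.5 - t/T); rises from sin(2.5) to sin(1.5) over the run."""
    if T <= 0:
        raise ValueError("T must be positive")
    return float(np.sin(2.5 - t / T))


def alpha_schedule(t: float, T: float) -> float:
    """alpha = 2 exp(-t/T); strictly decreasing from 2 to 2/e."""
    if T <= 0:
        raise ValueError("T must be positive")
    return float(2.0 * np.exp(-t / T))


def _apply_bounds(x: np.ndarray, space: SearchSpace, mode: str) -> np.ndarray:
    if mode == "clip":
        return np.clip(x, space.lb, space.ub)
    # reflect once off each bound, then clip any residual excursion
    span = space.ub - space.lb
    y = np.where(x < space.lb, 2 * space.lb - x, x)
    y = np.where(y > space.ub, 2 * space.ub - y, y)
    return np.clip(y, space.lb, space.ub)


def follow_silverback(
    gx: np.ndarray,
    x_sb: np.ndarray,
    t: float,
    T: float,
    rng: np.random.Generator,
    rand1: float | None = None,
) -> np.ndarray:
    """delta * rand1 * (|gx - x_sb| + gx); rand1 drawn once per update."""
    r1 = rng.uniform() if rand1 is None else rand1
    return delta_schedule(t, T) * r1 * (np.abs(gx - x_sb) + gx)


def fight_update(
    gx: np.ndarray,
    x_sb: np.ndarray,
    t: float,
    T: float,
    F: int,
    rng: np.random.Generator,
    rand2: float | None = None,
) -> np.ndarray:
    """x_sb + F * rand2 * alpha * (x_sb - gx) with flag F in {-1, +1}."""
    if F not in (-1, 1):
        raise ValueError("F must be -1 or +1")
    r2 = rng.uniform() if rand2 is None else rand2
    return x_sb + F * r2 * alpha_schedule(t, T) * (x_sb - gx)


def explore_update(
    gx: np.ndarray,
    positions: np.ndarray,
    space: SearchSpace,
    t: float,
    T: float,
    p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Three-branch exploration proposal.

    A single uniform draw ``rand`` selects the branch: rand >= p triggers a
    uniform re-draw in the bounds; otherwise rand >= 0.5 moves toward a
    random member with the decaying amplitude C; otherwise a gamma-signed
    difference move.  (Note the gate direction: small p makes the uniform
    re-draw the dominant exploration move; greedy acceptance in the caller
    keeps only improvements.)
    The amplitude pieces follow the GTO conventions: C = F * (1 - t/T) with
    F = cos(2 r4) + 1, L = C * l with l ~ U[-1, 1], H = Z * gx with
    Z ~ U[-C, C] per dimension.
    """
    M = positions.shape[0]
    if M < 2:
        raise ValueError("population size must be >= 2")
    rand = rng.uniform()
    if rand >= p:
        r1 = rng.uniform(size=space.dim)
        return (space.ub - space.lb) * r1 + space.lb
    r4 = rng.uniform()
    C = (np.cos(2.0 * r4) + 1.0) * (1.0 - t / T)
    l = rng.uniform(-1.0, 1.0)
    L = C * l
    if rand >= 0.5:
        r2 = rng.uniform()
        x_r = positions[rng.integers(M)]
        Z = rng.uniform(-abs(C), abs(C), size=space.dim) if C != 0 else np.zeros(space.dim)
        H = Z * gx
        return (r2 - C) * x_r + L * H
    gx_r = positions[rng.integers(M)]
    r = rng.uniform()
    r3 = rng.uniform()
    gamma = 2.0 * rng.uniform() - 1.0
    diff = gx - gx_r
    return gx - gamma * r * L * (L * diff + r3 * diff)


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    params: HGBOAParams,
) -> Population:
    """Minimize ``objective`` over ``space``; returns the final population.

    Every agent receives an exploration then an exploitation proposal per
    iteration, each accepted greedily, for exactly ``params.T`` iterations.
    Deterministic under ``params.seed``.
    """

    def evaluate(x: np.ndarray) -> float:
        v = float(objective(x))
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite objective value at {x}")
        return v

    rng = np.random.default_rng(params.seed)
    M, T = params.M, params.T
    pos = rng.uniform(space.lb, space.ub, size=(M, space.dim))
    fit = np.array([evaluate(x) for x in pos])
    best_i = int(np.argmin(fit))
    sb, sb_fit = pos[best_i].copy(), float(fit[best_i])
    trace: list[float] = []

    for t in range(T):
        # exploration sweep
        for i in range(M):
            cand = explore_update(pos[i], pos, space, t, T, params.p, rng)
            cand = _apply_bounds(cand, space, params.bounds_mode)
            f = evaluate(cand)
            if f < fit[i]:
                pos[i], fit[i] = cand, f
                if f < sb_fit:
                    sb, sb_fit = cand.copy(), f
        # exploitation sweep
        for i in range(M):
            r4 = rng.uniform()
            C = (np.cos(2.0 * r4) + 1.0) * (1.0 - t / T)
            F = 1 if rng.uniform() < 0.5 else -1
            if abs(C) >= params.beta:
                cand = follow_silverback(pos[i], sb, t, T, rng)
            else:
                cand = fight_update(pos[i], sb, t, T, F, rng)
            cand = _apply_bounds(cand, space, params.bounds_mode)
            f = evaluate(cand)
            if f < fit[i]:
                pos[i], fit[i] = cand, f
                if f < sb_fit:
                    sb, sb_fit = cand.copy(), f
        trace.append(sb_fit)

    return Population(
        positions=pos, fitness=fit, silverback=sb,
        best_fitness=sb_fit, t=T, trace=trace,
    )


def feature_reduction_rate(mask: np.ndarray) -> float:
    """Percent of candidate features discarded: 100 * (1 - selected/total)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return 100.0 * (1.0 - mask.sum() / mask.size)


@dataclass
class SelectionResult:
    mask: np.ndarray
    fitness: float          # internal, minimized
    fitness_score: float    # 1 - fitness, higher is better (reported form)
    frr: float
    cv_accuracy: float
    trace: list[float]


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, n_splits: int, seed: int
) -> float:
    """Nearest-centroid accuracy under stratified cross-validation."""
    Xs = X[:, mask]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(Xs, y):
        clf = NearestCentroid()
        clf.fit(Xs[tr], y[tr])
        accs.append(float((clf.predict(Xs[te]) == y[te]).mean()))
    return float(np.mean(accs))


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    params: HGBOAParams | None = None,
    w: float = 0.9,
    n_splits: int = 3,
    evaluator: Callable[[np.ndarray], float] | None = None,
) -> SelectionResult:
    """Wrapper feature selection: binarized HGBOA positions in [0, 1]^d.

    ``evaluator(mask) -> accuracy`` may replace the default cross-validated
    nearest-centroid classifier.  Fitness (minimized) is
    ``w * (1 - accuracy) + (1 - w) * selected/total``; candidates selecting
    no feature are penalized with fitness 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2D table with >= 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes")
    params = params or HGBOAParams(T=40, M=20)
    d = X.shape[1]

    acc_of = evaluator or (
        lambda mask: _cv_accuracy(X, y, mask, n_splits, params.seed)
    )
    cache: dict[bytes, float] = {}

    def objective(pos: np.ndarray) -> float:
        mask = pos >= 0.5
        if not mask.any():
            return 1.0
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = float(acc_of(mask))
        acc = cache[key]
        return w * (1.0 - acc) + (1.0 - w) * mask.sum() / d

    space = SearchSpace.cube(d, 0.0, 1.0)
    popn = optimize(objective, space, params)
    mask = popn.silverback >= 0.5
    if not mask.any():  # degenerate: fall back to the single best feature
        mask = np.zeros(d, dtype=bool)
        mask[0] = True
    acc = float(acc_of(mask))
    fit = popn.best_fitness
    return SelectionResult(
        mask=mask,
        fitness=fit,
        fitness_score=1.0 - fit,
        frr=feature_reduction_rate(mask),
        cv_accuracy=acc,
        trace=popn.trace,
    )
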