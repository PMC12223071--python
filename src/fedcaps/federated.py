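"""Single-process federated-learning simulation with FedAvg aggregation.

Clients hold disjoint local datasets; each round the server broadcasts the
global flat weight vector, every client trains locally and returns only a
:class:`ClientUpdate` (weights + sample count — never raw data), failures
are injected (independent dropout, additive-noise poisoning), optional
client-level differential-privacy noise is applied (Gaussian mechanism:
clip to an L2 ball, add calibrated noise), and the server aggregates

    w = sum_k (n_k / N) w_k,      N = sum_k n_k,

so clients with more samples weigh more.  Every round's global weights are
digested into the hash-chained ledger, and held-out metrics are recorded.

The aggregator sees only ClientUpdate values; client datasets never cross
that boundary (asserted by an architectural test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .capsules import CapsuleNet, predict, train_classifier
from .ledger import Ledger, append_block, digest_weights
from .synthetic_data import derive_seed

__all__ = [
    "ClientUpdate",
    "DPConfig",
    "FLConfig",
    "RoundRecord",
    "fedavg",
    "local_train",
    "inject_failures",
    "dp_noise",
    "run_simulation",
    "train_centralized",
]


@dataclass
class ClientUpdate:
    client_id: str
    round: int
    n_k: int
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_k < 1:
            raise ValueError("n_k must be >= 1")
        self.weights = np.asarray(self.weights, dtype=np.float64)


@dataclass(frozen=True)
class DPConfig:
    enabled: bool = False
    epsilon: float = 1.0
    delta: float = 1e-5
    clip_norm: float = 10.0

    def __post_init__(self):
        if self.enabled and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0 when DP is enabled")
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be > 0")


@dataclass(frozen=True)
class FLConfig:
    n_clients: int = 5
    rounds: int = 100
    local_epochs: int = 3
    # local Adam state restarts every round, so the feature-path capsule
    # trains with a slightly larger step than the centralized default
    lr: float = 3e-3
    batch_size: int = 16
    dropout_rate: float = 0.10
    noise_rate: float = 0.10
    noise_sigma: float = 0.5           # x weight RMS, poisoning magnitude
    dp: DPConfig = DPConfig()
    seed: int = 0

    def __post_init__(self):
        for name in ("dropout_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class RoundRecord:
    round: int
    participants: list[str]
    dropped: list[str]
    poisoned: list[str]
    global_digest: str
    eval_metrics: dict


def fedavg(updates: Sequence[ClientUpdate]) -> np.ndarray:
    """Sample-count-weighted mean of client weight vectors.

    Contributions are summed in client-id order so the result is invariant
    to the order updates arrive in.
    """
    if not updates:
        raise ValueError("no updates to aggregate")
    length = updates[0].weights.size
    for u in updates:
        if u.weights.size != length:
            raise ValueError("inconsistent weight-vector lengths")
    ordered = sorted(updates, key=lambda u: (u.client_id, u.round))
    N = sum(u.n_k for u in ordered)
    stacked = np.stack([(u.n_k / N) * u.weights for u in ordered])
    return stacked.sum(axis=0)


def local_train(
    client_data: tuple[np.ndarray, np.ndarray],
    global_weights: np.ndarray,
    model_factory: Callable[[], CapsuleNet],
    client_id: str,
    round: int,
    local_epochs: int = 3,
    lr: float = 1e-3,
    batch_size: int = 16,
    seed: int = 0,
) -> ClientUpdate:
    """One client's local update: start from global weights, train, return.

    Only the resulting ClientUpdate crosses back to the aggregator.
    ``local_epochs=0`` returns the global weights unchanged.
    """
    X, y = client_data
    if len(y) == 0:
        raise ValueError("empty client dataset")
    model = model_factory()
    model.set_flat(global_weights)
    if local_epochs > 0:
        model, history = train_classifier(
            X, y, model=model, epochs=local_epochs, lr=lr,
            batch_size=batch_size,
            seed=derive_seed(seed, "local", client_id, round),
        )
        last_loss = history[-1]["loss"]
    else:
        last_loss = None
    return ClientUpdate(
        client_id=client_id,
        round=round,
        n_k=len(y),
        weights=model.get_flat(),
        metadata={"local_epochs": local_epochs, "loss": last_loss},
    )


def inject_failures(
    updates: Sequence[ClientUpdate],
    dropout_rate: float,
    noise_rate: float,
    noise_sigma: float,
    rng: np.random.Generator,
) -> tuple[list[ClientUpdate], dict]:
    """Independent client dropout and additive-noise poisoning.

    Each client is dropped with probability ``dropout_rate``; each survivor
    is poisoned with probability ``noise_rate`` by Gaussian noise with
    standard deviation ``noise_sigma * RMS(weights)``.  Returns the
    surviving (possibly perturbed) updates and an injection log.
    """
    if not 0.0 <= dropout_rate <= 1.0 or not 0.0 <= noise_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    survivors: list[ClientUpdate] = []
    log: dict = {"dropped": [], "poisoned": []}
    for u in updates:
        if rng.uniform() < dropout_rate:
            log["dropped"].append(u.client_id)
            continue
        w = u.weights
        if rng.uniform() < noise_rate:
            rms = float(np.sqrt((w**2).mean())) if w.size else 0.0
            w = w + rng.normal(0.0, noise_sigma * rms, size=w.shape)
            log["poisoned"].append(u.client_id)
            u = ClientUpdate(
                u.client_id, u.round, u.n_k, w,
                {**u.metadata, "poisoned": True},
            )
        survivors.append(u)
    return survivors, log


def dp_noise(
    update: ClientUpdate,
    epsilon: float,
    delta: float,
    clip_norm: float,
    rng: np.random.Generator,
) -> ClientUpdate:
    """Gaussian-mechanism client-level DP: clip L2 norm, add noise.

    sigma = clip_norm * sqrt(2 ln(1.25/delta)) / epsilon per coordinate.
    ``epsilon=inf`` is the configured noiseless mode (clip only).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if clip_norm <= 0:
        raise ValueError("clip_norm must be > 0")
    w = update.weights
    norm = float(np.linalg.norm(w))
    if norm > clip_norm:
        w = w * (clip_norm / norm)
    if np.isfinite(epsilon):
        sigma = clip_norm * np.sqrt(2.0 * np.log(1.25 / delta)) / epsilon
        w = w + rng.normal(0.0, sigma, size=w.shape)
    return ClientUpdate(
        update.client_id, update.round, update.n_k, w,
        {**update.metadata, "dp": True},
    )


def _evaluate_global(
    weights: np.ndarray,
    model_factory: Callable[[], CapsuleNet],
    eval_set: tuple[np.ndarray, np.ndarray],
) -> dict:
    model = model_factory()
    model.set_flat(weights)
    X, y = eval_set
    labels, _ = predict(model, X)
    return {"accuracy": float((labels == np.asarray(y)).mean())}


def run_simulation(
    config: FLConfig,
    client_data: Mapping[str, tuple[np.ndarray, np.ndarray]],
    model_factory: Callable[[], CapsuleNet],
    eval_set: tuple[np.ndarray, np.ndarray],
    ledger: Ledger | None = None,
) -> tuple[list[RoundRecord], np.ndarray, Ledger]:
    """Run the full federated loop; returns (history, final weights, ledger).

    Per round: broadcast -> local_train per client -> inject_failures ->
    optional dp_noise -> fedavg -> ledger append -> held-out evaluation.
    If every client drops out, the round is skipped and the previous global
    weights are retained (no ledger entry for a skipped round).
    Deterministic under ``config.seed``.
    """
    client_ids = sorted(client_data.keys())
    ledger = ledger if ledger is not None else Ledger()
    rng = np.random.default_rng(derive_seed(config.seed, "failures"))
    dp_rng = np.random.default_rng(derive_seed(config.seed, "dp"))
    template = model_factory()
    registry = template.shape_registry()
    global_w = template.get_flat()
    history: list[RoundRecord] = []

    for t in range(config.rounds):
        updates = [
            local_train(
                client_data[cid], global_w, model_factory, cid, t,
                local_epochs=config.local_epochs, lr=config.lr,
                batch_size=config.batch_size, seed=config.seed,
            )
            for cid in client_ids
        ]
        survivors, log = inject_failures(
            updates, config.dropout_rate, config.noise_rate,
            config.noise_sigma, rng,
        )
        if not survivors:
            history.append(
                RoundRecord(
                    round=t, participants=[], dropped=log["dropped"],
                    poisoned=log["poisoned"],
                    global_digest=digest_weights(global_w, registry),
                    eval_metrics={"skipped": True},
                )
            )
            continue
        if config.dp.enabled:
            survivors = [
                dp_noise(
                    u, config.dp.epsilon, config.dp.delta,
                    config.dp.clip_norm, dp_rng,
                )
                for u in survivors
            ]
        global_w = fedavg(survivors)
        digest = digest_weights(global_w, registry)
        append_block(
            ledger, round=t, payload_digest=digest,
            validator_id=ledger.authority_set[t % len(ledger.authority_set)],
        )
        history.append(
            RoundRecord(
                round=t,
                participants=[u.client_id for u in survivors],
                dropped=log["dropped"],
                poisoned=log["poisoned"],
                global_digest=digest,
                eval_metrics=_evaluate_global(global_w, model_factory, eval_set),
            )
        )
    return history, global_w, ledger


def train_centralized(
    data: tuple[np.ndarray, np.ndarray],
    model_factory: Callable[[], CapsuleNet],
    rounds: int,
    local_epochs: int = 3,
    lr: float = 1e-3,
    batch_size: int = 16,
    seed: int = 0,
    client_id: str = "client-1",
) -> np.ndarray:
    """Centralized reference: the same local-update loop on all the data.

    With one client and no failures, FedAvg degenerates to this trajectory
    exactly (identical round digests under the same seed and client id).
    """
    template = model_factory()
    w = template.get_flat()
    for t in range(rounds):
        upd = local_train(
            data, w, model_factory, client_id, t,
            local_epochs=local_epochs, lr=lr, batch_size=batch_size, seed=seed,
        )
        w = upd.weights
    return w
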