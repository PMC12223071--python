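"""Append-only SHA-256 hash chain of per-round model digests.

A desk-scale stand-in for a private proof-of-authority blockchain: a fixed
authority set of validator ids, blocks linked by the previous block's hash,
and O(n) verification that recomputes every hash and link.  There is no
networking or consensus protocol — the PoA essence kept here is that only
authorized validators may append, and any mutation of a recorded block is
detectable.

Canonical weight serialization (what ``digest_weights`` hashes): the UTF-8
shape-registry string ``name:dim1xdim2;...`` followed by the parameter
vector as little-endian IEEE-754 float64 bytes in registry order.  An empty
registry with an empty vector hashes the empty byte string.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Sequence

import numpy as np

__all__ = [
    "LedgerBlock",
    "Ledger",
    "digest_weights",
    "append_block",
    "verify_chain",
    "audit_round",
]

GENESIS_PREV = "0" * 64


def digest_weights(
    weights: np.ndarray,
    registry: Sequence[tuple[str, tuple[int, ...]]] = (),
) -> str:
    """SHA-256 hex digest of the canonical model serialization."""
    weights = np.asarray(weights, dtype="<f8")
    if weights.size and not np.all(np.isfinite(weights)):
        raise ValueError("non-finite weights cannot be digested")
    prefix = "".join(
        f"{name}:{'x'.join(str(int(d)) for d in shape)};" for name, shape in registry
    ).encode("utf-8")
    return hashlib.sha256(prefix + weights.tobytes()).hexdigest()


@dataclass(frozen=True)
class LedgerBlock:
    index: int
    round: int
    prev_hash: str
    payload_digest: str
    validator_id: str
    timestamp: str
    block_hash: str = ""

    def header_bytes(self) -> bytes:
        return "|".join(
            [
                str(self.index),
                str(self.round),
                self.prev_hash,
                self.payload_digest,
                self.validator_id,
                self.timestamp,
            ]
        ).encode("utf-8")

    def compute_hash(self) -> str:
        return hashlib.sha256(self.header_bytes()).hexdigest()


@dataclass
class Ledger:
    """Hash chain with a fixed validator (authority) set.

    ``fixed_clock`` pins timestamps to a constant for byte-reproducible
    chains (golden-file tests); by default blocks carry UTC ISO-8601 times.
    """

    authority_set: tuple[str, ...] = tuple(f"validator-{i}" for i in range(5))
    chain: list[LedgerBlock] = field(default_factory=list)
    fixed_clock: str | None = None

    def _now(self) -> str:
        if self.fixed_clock is not None:
            return self.fixed_clock
        return datetime.now(timezone.utc).isoformat()

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(asdict(b), sort_keys=True) for b in self.chain)

    @classmethod
    def from_jsonl(cls, text: str, authority_set: Sequence[str] | None = None) -> "Ledger":
        blocks = [LedgerBlock(**json.loads(line)) for line in text.splitlines() if line.strip()]
        led = cls(authority_set=tuple(authority_set or cls.authority_set))
        led.chain = blocks
        return led


class UnauthorizedValidator(PermissionError):
    pass


def append_block(
    ledger: Ledger, round: int, payload_digest: str, validator_id: str
) -> LedgerBlock:
    """Append a block; validator must be authorized and rounds monotone."""
    if validator_id not in ledger.authority_set:
        raise UnauthorizedValidator(f"{validator_id!r} not in authority set")
    if ledger.chain and round <= ledger.chain[-1].round:
        raise ValueError(
            f"round {round} not greater than last recorded {ledger.chain[-1].round}"
        )
    prev = ledger.chain[-1].block_hash if ledger.chain else GENESIS_PREV
    draft = LedgerBlock(
        index=len(ledger.chain),
        round=round,
        prev_hash=prev,
        payload_digest=payload_digest,
        validator_id=validator_id,
        timestamp=ledger._now(),
    )
    block = LedgerBlock(**{**asdict(draft), "block_hash": draft.compute_hash()})
    ledger.chain.append(block)
    return block


def verify_chain(ledger: Ledger) -> dict:
    """Recompute every block hash and link; report the first violation.

    Returns {"valid": True} or {"valid": False, "index": i, "reason": ...}.
    Never raises.
    """
    prev = GENESIS_PREV
    for i, block in enumerate(ledger.chain):
        if block.index != i:
            return {"valid": False, "index": i, "reason": "index mismatch"}
        if block.prev_hash != prev:
            return {"valid": False, "index": i, "reason": "broken link"}
        if block.validator_id not in ledger.authority_set:
            return {"valid": False, "index": i, "reason": "unauthorized validator"}
        if block.compute_hash() != block.block_hash:
            return {"valid": False, "index": i, "reason": "block hash mismatch"}
        if i > 0 and block.round <= ledger.chain[i - 1].round:
            return {"valid": False, "index": i, "reason": "non-monotone round"}
        prev = block.block_hash
    return {"valid": True}


def audit_round(
    ledger: Ledger,
    round: int,
    weights: np.ndarray,
    registry: Sequence[tuple[str, tuple[int, ...]]] = (),
) -> bool:
    """Recompute the digest of ``weights`` and compare to the logged one."""
    for block in ledger.chain:
        if block.round == round:
            return digest_weights(weights, registry) == block.payload_digest
    raise KeyError(f"round {round} not recorded in the ledger")
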