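"""Hash-chained append-only transaction ledger.

Every trial transaction (a file moving from one registered party to
another) becomes one block.  A block records the sender, receiver,
timestamp, file attachment and the digest of the previous block; the
SHA-256 digest of a canonical serialization of those fields is the
block's own hash.  Because each block's pre-image embeds its
predecessor's digest, any retroactive edit to a stored block breaks
every digest from that point forward and is detectable by recomputation
(see :mod:`trialchain.audit`).

Canonical pre-image
-------------------
The fields are joined in a fixed order with a ``|`` separator, with the
payload base64-encoded so the serialization is injective::

    index | timestamp | sender_id | receiver_id | file_name | encrypted | b64(payload) | prev_hash

Timestamps are UTC at second precision (``YYYY-MM-DDTHH:MM:SSZ``) and
are supplied by the caller, so chains built from a scripted clock are
bit-reproducible.

Persistence is one JSON-lines file: one block object per line, payload
base64 at rest.  Reading does not verify digests — parse and validate
are deliberately separate so that a corrupted store can still be loaded
and then localized by the audit layer.
"""

from __future__ import annotations

import base64
import binascii
import hashlib
import json
import re
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "Block",
    "Chain",
    "ChainFormatError",
    "ChainStateError",
    "GENESIS_PREV_HASH",
    "append_transaction",
    "compute_block_hash",
    "create_genesis",
    "format_timestamp",
    "read_chain",
    "write_chain",
]

GENESIS_PREV_HASH = "0" * 64
GENESIS_FILE_NAME = "genesis"
REGULATOR_ID = "REGULATOR"

_HEX64 = re.compile(r"^[0-9a-f]{64}$")

_STORE_FIELDS = (
    "index",
    "timestamp",
    "sender",
    "receiver",
    "file_name",
    "encrypted",
    "payload_b64",
    "prev_hash",
    "hash",
)


class ChainFormatError(ValueError):
    """A persisted chain store could not be parsed.

    Carries the 1-based line number of the first bad record.
    """

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class ChainStateError(RuntimeError):
    """Operation applied to a chain in an unusable state (e.g. empty)."""


def format_timestamp(at: datetime) -> str:
    """Render an instant as canonical UTC second-precision ISO-8601."""
    if at.tzinfo is None:
        at = at.replace(tzinfo=timezone.utc)
    return at.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def compute_block_hash(
    index: int,
    timestamp: str,
    sender_id: str,
    receiver_id: str,
    file_name: str,
    encrypted: bool,
    payload: bytes,
    prev_hash: str,
) -> str:
    """SHA-256 digest (lowercase hex) of the canonical block pre-image.

    Pure function: equal inputs always give equal output.
    """
    if not isinstance(payload, (bytes, bytearray)):
        raise TypeError("payload must be a byte sequence")
    if not _HEX64.match(prev_hash):
        raise ValueError(
            "prev_hash must be 64 lowercase hexadecimal characters, "
            f"got {prev_hash!r}"
        )
    pre_image = "|".join(
        (
            str(index),
            timestamp,
            sender_id,
            receiver_id,
            file_name,
            "1" if encrypted else "0",
            base64.b64encode(bytes(payload)).decode("ascii"),
            prev_hash,
        )
    )
    return hashlib.sha256(pre_image.encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class Block:
    """One ledger entry.  Immutable once constructed."""

    index: int
    timestamp: str
    sender_id: str
    receiver_id: str
    file_name: str
    payload: bytes
    encrypted: bool
    prev_hash: str
    block_hash: str

    def recomputed_hash(self) -> str:
        """Digest recomputed from the stored fields (audit primitive)."""
        return compute_block_hash(
            self.index,
            self.timestamp,
            self.sender_id,
            self.receiver_id,
            self.file_name,
            self.encrypted,
            self.payload,
            self.prev_hash,
        )

    def to_store_record(self) -> dict:
        return {
            "index": self.index,
            "timestamp": self.timestamp,
            "sender": self.sender_id,
            "receiver": self.receiver_id,
            "file_name": self.file_name,
            "encrypted": self.encrypted,
            "payload_b64": base64.b64encode(self.payload).decode("ascii"),
            "prev_hash": self.prev_hash,
            "hash": self.block_hash,
        }

    @classmethod
    def from_store_record(cls, record: dict) -> "Block":
        return cls(
            index=record["index"],
            timestamp=record["timestamp"],
            sender_id=record["sender"],
            receiver_id=record["receiver"],
            file_name=record["file_name"],
            payload=base64.b64decode(record["payload_b64"]),
            encrypted=record["encrypted"],
            prev_hash=record["prev_hash"],
            block_hash=record["hash"],
        )


def create_genesis(trial_id: str, created_at: datetime) -> Block:
    """Anchor block of a new trial chain.

    Index 0, all-zero previous hash, regulator as both parties, payload
    carrying the trial identifier.
    """
    if not trial_id:
        raise ValueError("trial_id must be non-empty")
    timestamp = format_timestamp(created_at)
    payload = trial_id.encode("utf-8")
    block_hash = compute_block_hash(
        0, timestamp, REGULATOR_ID, REGULATOR_ID,
        GENESIS_FILE_NAME, False, payload, GENESIS_PREV_HASH,
    )
    return Block(
        index=0,
        timestamp=timestamp,
        sender_id=REGULATOR_ID,
        receiver_id=REGULATOR_ID,
        file_name=GENESIS_FILE_NAME,
        payload=payload,
        encrypted=False,
        prev_hash=GENESIS_PREV_HASH,
        block_hash=block_hash,
    )


class Chain:
    """Append-only ordered sequence of blocks.

    The public API offers no mutation of existing blocks; new blocks are
    added only through :func:`append_transaction` (or internal appends by
    higher layers), and each append persists the chain when a store path
    is attached.
    """

    def __init__(self, blocks: Sequence[Block] = (), store_path: Path | str | None = None):
        self._blocks: list[Block] = list(blocks)
        self.store_path: Path | None = Path(store_path) if store_path is not None else None

    def __len__(self) -> int:
        return len(self._blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self._blocks)

    def __getitem__(self, index: int) -> Block:
        return self._blocks[index]

    @property
    def blocks(self) -> tuple[Block, ...]:
        return tuple(self._blocks)

    @property
    def top(self) -> Block:
        if not self._blocks:
            raise ChainStateError("chain is empty")
        return self._blocks[-1]

    def _append(self, block: Block) -> None:
        # internal: callers are append_transaction / read_chain only
        self._blocks.append(block)

    @classmethod
    def initialize(
        cls,
        trial_id: str,
        created_at: datetime,
        store_path: Path | str | None = None,
    ) -> "Chain":
        """Create a chain holding only the genesis block and persist it."""
        chain = cls([create_genesis(trial_id, created_at)], store_path)
        if chain.store_path is not None:
            write_chain(chain)
        return chain


def append_transaction(
    chain: Chain,
    sender_id: str,
    receiver_id: str,
    file_name: str,
    payload: bytes,
    encrypted: bool,
    at: datetime,
    plaintext: bytes | None = None,
) -> Block:
    """Record one transaction as a new block and persist the chain.

    The version-control layer inspects the upload before the block is
    written: if ``file_name``'s base name already exists on the chain
    with different content, the recorded display name gains an
    incrementing ``(vN)`` suffix.  ``plaintext`` supplies the
    pre-encryption bytes for content fingerprinting when ``payload`` is
    ciphertext; it is never stored.
    """
    if len(chain) == 0:
        raise ChainStateError("cannot append to an empty chain; create genesis first")

    from . import version_control  # deferred: version_control reads Chain

    upload = version_control.classify_upload(
        chain, file_name, plaintext if plaintext is not None else payload
    )
    top = chain.top
    timestamp = format_timestamp(at)
    block_hash = compute_block_hash(
        top.index + 1, timestamp, sender_id, receiver_id,
        upload.display_name, encrypted, payload, top.block_hash,
    )
    block = Block(
        index=top.index + 1,
        timestamp=timestamp,
        sender_id=sender_id,
        receiver_id=receiver_id,
        file_name=upload.display_name,
        payload=bytes(payload),
        encrypted=encrypted,
        prev_hash=top.block_hash,
        block_hash=block_hash,
    )
    chain._append(block)
    if chain.store_path is not None:
        if chain.store_path.exists():
            _append_to_store(chain.store_path, block)
        else:
            write_chain(chain)
    return block


def write_chain(chain: Chain) -> Path:
    """Persist the full chain to its JSON-lines store."""
    if chain.store_path is None:
        raise ValueError("chain has no store_path")
    chain.store_path.parent.mkdir(parents=True, exist_ok=True)
    with open(chain.store_path, "w", encoding="utf-8") as fh:
        for block in chain:
            fh.write(json.dumps(block.to_store_record()) + "\n")
    return chain.store_path


def _append_to_store(store_path: Path, block: Block) -> None:
    with open(store_path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(block.to_store_record()) + "\n")


def read_chain(store_path: Path | str) -> Chain:
    """Load a chain from its JSON-lines store.

    Parsing is intentionally permissive about *content* (a tampered
    payload still loads); it is strict about *structure*, raising
    :class:`ChainFormatError` at the first malformed record.  Integrity
    is checked separately by :func:`trialchain.audit.validate_chain`.
    """
    store_path = Path(store_path)
    blocks: list[Block] = []
    with open(store_path, encoding="utf-8") as fh:
        for line_number, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ChainFormatError(f"invalid JSON record: {exc}", line_number) from exc
            missing = [f for f in _STORE_FIELDS if f not in record]
            if missing:
                raise ChainFormatError(
                    f"record missing fields: {', '.join(missing)}", line_number
                )
            try:
                blocks.append(Block.from_store_record(record))
            except (binascii.Error, ValueError, TypeError) as exc:
                raise ChainFormatError(f"undecodable record: {exc}", line_number) from exc
    return Chain(blocks, store_path)
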