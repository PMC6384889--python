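"""Chain integrity validation and hash-registry audits.

Validation walks the chain chronologically from the genesis block,
recomputing each block's digest from its stored fields and checking the
previous-hash linkage; it stops at the first failure and reports its
index and file name, so a storage-level corruption is localized to the
exact block and file.

A hash registry is the regulator's compact checkpoint: just
``(index, digest)`` pairs, whose size is independent of payload sizes.
Comparing a candidate registry against a trusted one verifies integrity
by string equality alone — the auditor never opens a payload, which is
what makes the audit "zero-knowledge" in the informal sense: confidential
file contents stay closed while their originality is still verifiable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

from .core_ledger import GENESIS_PREV_HASH, Chain, ChainStateError

__all__ = [
    "HashRegistry",
    "InvalidChainError",
    "ValidationReport",
    "candidate_registry",
    "export_hash_registry",
    "read_registry",
    "validate_chain",
    "write_registry",
    "zero_knowledge_audit",
]

FailureKind = Literal["hash-mismatch", "linkage-break"]


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    first_bad_index: int | None = None
    offending_file: str | None = None
    failure_kind: FailureKind | None = None

    def __post_init__(self):
        if self.valid != (self.first_bad_index is None):
            raise ValueError("valid must hold exactly when first_bad_index is None")


class InvalidChainError(RuntimeError):
    """Raised when an operation requiring a valid chain receives a bad one."""

    def __init__(self, report: ValidationReport):
        super().__init__(
            f"chain invalid: {report.failure_kind} at block {report.first_bad_index} "
            f"({report.offending_file})"
        )
        self.report = report


@dataclass(frozen=True)
class HashRegistry:
    """Ordered (index, block_hash) pairs for blocks 0..N."""

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self):
        for position, (index, _) in enumerate(self.entries):
            if index != position:
                raise ValueError("registry indices must be consecutive from 0")

    def __len__(self) -> int:
        return len(self.entries)


def validate_chain(chain: Chain) -> ValidationReport:
    """Chronological hash check; first failure wins.

    For each block the digest is recomputed from the stored fields and
    compared with the stored hash, and the previous-hash link is checked
    against the predecessor.  Blocks after the first bad one are not
    re-reported even though their linkage is transitively broken.
    """
    if len(chain) == 0:
        raise ChainStateError("cannot validate an empty chain")
    prev_hash = GENESIS_PREV_HASH
    for block in chain:
        if block.prev_hash != prev_hash:
            return ValidationReport(False, block.index, block.file_name, "linkage-break")
        if block.recomputed_hash() != block.block_hash:
            return ValidationReport(False, block.index, block.file_name, "hash-mismatch")
        prev_hash = block.block_hash
    return ValidationReport(True)


def export_hash_registry(chain: Chain) -> HashRegistry:
    """Trusted checkpoint of a verified chain.

    Refuses an invalid chain: a checkpoint taken from corrupted storage
    would poison every later audit.
    """
    report = validate_chain(chain)
    if not report.valid:
        raise InvalidChainError(report)
    return HashRegistry(tuple((b.index, b.block_hash) for b in chain))


def candidate_registry(chain: Chain) -> HashRegistry:
    """Registry of a chain *under audit*: digests recomputed from content.

    Unlike :func:`export_hash_registry` this never refuses — the point is
    to fingerprint possibly-corrupted storage so the registries can be
    compared off-line.
    """
    return HashRegistry(tuple((b.index, b.recomputed_hash()) for b in chain))


def zero_knowledge_audit(candidate: HashRegistry, trusted: HashRegistry) -> ValidationReport:
    """Pairwise string comparison of two registries in index order.

    Reports the first mismatching index (a length mismatch fails at the
    first missing/extra index).  No payload is ever read and no hash is
    computed here.
    """
    if len(candidate) == 0 or len(trusted) == 0:
        raise ValueError("registries must be non-empty")
    for (index, cand_hash), (_, trusted_hash) in zip(candidate.entries, trusted.entries):
        if cand_hash != trusted_hash:
            return ValidationReport(False, index, None, "hash-mismatch")
    if len(candidate) != len(trusted):
        return ValidationReport(
            False, min(len(candidate), len(trusted)), None, "linkage-break"
        )
    return ValidationReport(True)


def write_registry(registry: HashRegistry, path: Path | str) -> Path:
    """Write a registry as a two-column CSV (index,hash)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "hash"])
        writer.writerows(registry.entries)
    return path


def read_registry(path: Path | str) -> HashRegistry:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        return HashRegistry(tuple((int(r["index"]), r["hash"]) for r in reader))
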