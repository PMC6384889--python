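"""Content-hash file versioning compatible with an append-only ledger.

Existing ledger entries can never be edited, so corrections arrive as
new transactions.  When an upload reuses a file name already on the
chain, its content is fingerprinted (SHA-256) and compared to every
stored version of that name: identical content is a duplicate of the
existing version, differing content becomes the next version.  Original
documents carry no version number; version N >= 2 is displayed as
``base (vN).ext``.  Old versions are always retained, so the regulator
can see exactly what was changed, by whom, and when.

Fingerprints cover the plaintext supplied at upload time; an upload that
arrives already encrypted with no plaintext available falls back to the
ciphertext bytes, in which case conflict detection across different
passwords is not possible (documented limitation).
"""

from __future__ import annotations

import hashlib
import os
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

if TYPE_CHECKING:
    from .core_ledger import Block, Chain

__all__ = [
    "UploadClass",
    "classify_upload",
    "content_fingerprint",
    "display_name",
    "latest_version",
    "split_versioned_name",
    "version_history",
]

# trailing " (vN)" immediately before the extension, N >= 2
_VERSION_SUFFIX = re.compile(r"^(?P<stem>.*) \(v(?P<n>[0-9]+)\)$")


def content_fingerprint(payload: bytes) -> str:
    """SHA-256 (lowercase hex) of the raw payload bytes."""
    return hashlib.sha256(bytes(payload)).hexdigest()


def split_versioned_name(file_name: str) -> tuple[str, int]:
    """Split a display name into (base_name, version).

    ``"crf.json" -> ("crf.json", 1)``; ``"crf (v2).json" -> ("crf.json", 2)``.
    Matching is case-sensitive and exact.
    """
    stem, ext = os.path.splitext(file_name)
    match = _VERSION_SUFFIX.match(stem)
    if match:
        return match.group("stem") + ext, int(match.group("n"))
    return file_name, 1


def display_name(base_name: str, version: int) -> str:
    """Display name for a version: originals unsuffixed, later ``(vN)``."""
    if version < 1:
        raise ValueError("version numbers start at 1")
    if version == 1:
        return base_name
    stem, ext = os.path.splitext(base_name)
    return f"{stem} (v{version}){ext}"


@dataclass(frozen=True)
class UploadClass:
    """Classification of an upload against the chain's existing versions."""

    kind: Literal["original", "duplicate", "new_version"]
    version: int
    base_name: str

    @property
    def display_name(self) -> str:
        return display_name(self.base_name, self.version)


def _versions_of(chain: "Chain", base_name: str) -> dict[int, "Block"]:
    """First block per version number of ``base_name`` (duplicates skipped)."""
    found: dict[int, "Block"] = {}
    for block in chain:
        if block.index == 0:
            continue
        base, version = split_versioned_name(block.file_name)
        if base == base_name and version not in found:
            found[version] = block
    return found


def classify_upload(chain: "Chain", file_name: str, payload: bytes) -> UploadClass:
    """Decide whether an upload is an original, a duplicate, or a new version.

    Pure function of the chain contents, the file name, and the payload.
    Any explicit ``(vN)`` suffix on the submitted name is stripped first;
    the system, not the uploader, assigns version numbers.
    """
    if not file_name:
        raise ValueError("file_name must be non-empty")
    base_name, _ = split_versioned_name(file_name)
    existing = _versions_of(chain, base_name)
    if not existing:
        return UploadClass("original", 1, base_name)
    fingerprint = content_fingerprint(payload)
    for version in sorted(existing):
        if content_fingerprint(existing[version].payload) == fingerprint:
            return UploadClass("duplicate", version, base_name)
    return UploadClass("new_version", max(existing) + 1, base_name)


def version_history(chain: "Chain", base_name: str) -> list[tuple[int, int, str, str]]:
    """All versions of ``base_name``, ascending.

    Returns ``(version, block_index, uploader, timestamp)`` tuples; empty
    when the name never appeared on the chain.
    """
    base_name, _ = split_versioned_name(base_name)
    found = _versions_of(chain, base_name)
    return [
        (version, block.index, block.sender_id, block.timestamp)
        for version, block in sorted(found.items())
    ]


def latest_version(chain: "Chain", base_name: str) -> "Block":
    """The block holding the highest version of ``base_name``."""
    base_name, _ = split_versioned_name(base_name)
    found = _versions_of(chain, base_name)
    if not found:
        raise KeyError(f"no file named {base_name!r} on the chain")
    return found[max(found)]
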