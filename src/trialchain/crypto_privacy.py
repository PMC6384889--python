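"""Optional password-based payload encryption.

Sensitive attachments can be stored as an unintelligible series of
bytes: a password is stretched with PBKDF2-HMAC-SHA256 (fresh 16-byte
salt, 200,000 iterations by default) and the payload is encrypted with
an authenticated stream construction built from HMAC-SHA256 — a
CTR-style keystream XORed into the plaintext, then an encrypt-then-MAC
tag over the full header and ciphertext.  Wrong passwords and corrupted
blobs fail authentication loudly; decryption never returns silent
garbage.

Block hashes are computed over the stored ciphertext, so auditors can
validate a chain without holding any passwords; content fingerprints
for version control cover the plaintext at upload time (see
:mod:`trialchain.version_control`).

Wire format of a blob (all offsets in bytes)::

    0   4   magic  b"TCB1"
    4   4   KDF iteration count, big-endian
    8   16  KDF salt
    24  16  nonce
    40  32  HMAC-SHA256 tag
    72  ..  ciphertext (same length as plaintext)
"""

from __future__ import annotations

import hashlib
import hmac
import secrets
from dataclasses import dataclass
from random import Random

__all__ = [
    "AuthenticationError",
    "BlobFormatError",
    "DEFAULT_ITERATIONS",
    "EncryptedBlob",
    "decrypt_payload",
    "derive_key",
    "encrypt_payload",
]

MAGIC = b"TCB1"
DEFAULT_ITERATIONS = 200_000
MIN_ITERATIONS = 10_000
SALT_LEN = 16
NONCE_LEN = 16
TAG_LEN = 32
KEY_LEN = 32
_HEADER_LEN = 4 + 4 + SALT_LEN + NONCE_LEN + TAG_LEN


class AuthenticationError(ValueError):
    """Wrong password or tampered ciphertext: the MAC did not verify."""


class BlobFormatError(ValueError):
    """The byte sequence is not a well-formed encrypted blob."""


def derive_key(password: str, salt: bytes, iterations: int = DEFAULT_ITERATIONS) -> bytes:
    """Stretch a password into a 32-byte key with PBKDF2-HMAC-SHA256.

    Deterministic in (password, salt, iterations).  The iteration floor
    guards against accidentally cheap derivations.
    """
    if not password:
        raise ValueError("password must be non-empty")
    if len(salt) < SALT_LEN:
        raise ValueError(f"salt must be at least {SALT_LEN} bytes")
    if iterations < MIN_ITERATIONS:
        raise ValueError(f"iterations must be at least {MIN_ITERATIONS}")
    return hashlib.pbkdf2_hmac("sha256", password.encode("utf-8"), salt, iterations, KEY_LEN)


@dataclass(frozen=True)
class EncryptedBlob:
    kdf_salt: bytes
    kdf_iterations: int
    nonce: bytes
    auth_tag: bytes
    ciphertext: bytes

    def to_bytes(self) -> bytes:
        return (
            MAGIC
            + self.kdf_iterations.to_bytes(4, "big")
            + self.kdf_salt
            + self.nonce
            + self.auth_tag
            + self.ciphertext
        )

    @classmethod
    def from_bytes(cls, raw: bytes) -> "EncryptedBlob":
        if len(raw) < _HEADER_LEN or raw[:4] != MAGIC:
            raise BlobFormatError("not an encrypted blob (bad magic or truncated header)")
        iterations = int.from_bytes(raw[4:8], "big")
        salt = raw[8 : 8 + SALT_LEN]
        nonce = raw[8 + SALT_LEN : 8 + SALT_LEN + NONCE_LEN]
        tag = raw[8 + SALT_LEN + NONCE_LEN : _HEADER_LEN]
        return cls(salt, iterations, nonce, tag, raw[_HEADER_LEN:])


def _subkeys(master: bytes) -> tuple[bytes, bytes]:
    enc_key = hmac.new(master, b"trialchain/enc", hashlib.sha256).digest()
    mac_key = hmac.new(master, b"trialchain/mac", hashlib.sha256).digest()
    return enc_key, mac_key


def _keystream_xor(enc_key: bytes, nonce: bytes, data: bytes) -> bytes:
    out = bytearray(len(data))
    offset = 0
    counter = 0
    while offset < len(data):
        ks = hmac.new(enc_key, nonce + counter.to_bytes(8, "big"), hashlib.sha256).digest()
        chunk = data[offset : offset + len(ks)]
        for i, byte in enumerate(chunk):
            out[offset + i] = byte ^ ks[i]
        offset += len(chunk)
        counter += 1
    return bytes(out)


def _tag(mac_key: bytes, iterations: int, salt: bytes, nonce: bytes, ciphertext: bytes) -> bytes:
    mac = hmac.new(mac_key, digestmod=hashlib.sha256)
    mac.update(MAGIC)
    mac.update(iterations.to_bytes(4, "big"))
    mac.update(salt)
    mac.update(nonce)
    mac.update(ciphertext)
    return mac.digest()


def encrypt_payload(
    payload: bytes,
    password: str,
    iterations: int = DEFAULT_ITERATIONS,
    rng: Random | None = None,
) -> EncryptedBlob:
    """Encrypt with a fresh salt and nonce; randomized by design.

    ``rng`` substitutes a seeded generator for the OS entropy source so
    scripted simulations can reproduce chains byte-for-byte; leave it
    None for real use.
    """
    if rng is None:
        salt = secrets.token_bytes(SALT_LEN)
        nonce = secrets.token_bytes(NONCE_LEN)
    else:
        salt = rng.randbytes(SALT_LEN)
        nonce = rng.randbytes(NONCE_LEN)
    master = derive_key(password, salt, iterations)
    enc_key, mac_key = _subkeys(master)
    ciphertext = _keystream_xor(enc_key, nonce, bytes(payload))
    tag = _tag(mac_key, iterations, salt, nonce, ciphertext)
    return EncryptedBlob(salt, iterations, nonce, tag, ciphertext)


def decrypt_payload(blob: EncryptedBlob | bytes, password: str) -> bytes:
    """Invert :func:`encrypt_payload`; authenticate before decrypting."""
    if isinstance(blob, (bytes, bytearray)):
        blob = EncryptedBlob.from_bytes(bytes(blob))
    master = derive_key(password, blob.kdf_salt, blob.kdf_iterations)
    enc_key, mac_key = _subkeys(master)
    expected = _tag(mac_key, blob.kdf_iterations, blob.kdf_salt, blob.nonce, blob.ciphertext)
    if not hmac.compare_digest(expected, blob.auth_tag):
        raise AuthenticationError("authentication failed: wrong password or corrupted data")
    return _keystream_xor(enc_key, blob.nonce, blob.ciphertext)
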