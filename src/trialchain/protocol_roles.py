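"""The trial network: participants, roles, routes, codes, and unblinding.

A private trial chain is instantiated by the regulator, who registers
every participating party and is the only party with full read access
to everything since the chain's instantiation.  Transactions are
authorized against a role-edge policy describing who may send what to
whom: the sponsor sends the blinded treatment distribution to the
investigator, completed CRFs flow from the investigator to the CRO,
cleaned data and analysis scripts from the CRO back to the sponsor, and
the sponsor's final package goes to the regulator.  An IVRS issues one
verification code per subject (handed by the patient to the
investigator at each visit, legitimizing the CRF) and posts
password-encrypted decoding keys — the arm-label mapping used for
unblinding — to the chain.

Patients appear in the registry for code custody but never send blocks
themselves; their interaction with the ledger is mediated entirely by
the verification codes.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from random import Random

from . import crypto_privacy, version_control
from .core_ledger import Block, Chain, append_transaction

__all__ = [
    "AuthorizationError",
    "Authorization",
    "DEFAULT_POLICY",
    "DECODING_KEYS_FILE",
    "Participant",
    "ParticipantRegistry",
    "Role",
    "TransactionPolicy",
    "VerificationCode",
    "authorize_transaction",
    "generate_verification_codes",
    "post_decoding_keys",
    "unblind",
]

DECODING_KEYS_FILE = "decodingKeys.json"
CODE_LENGTH = 8
_CODE_ALPHABET = string.ascii_uppercase + string.digits


class Role(str, Enum):
    REGULATOR = "REGULATOR"
    SPONSOR = "SPONSOR"
    CRO = "CRO"
    INVESTIGATOR = "INVESTIGATOR"
    IVRS = "IVRS"
    DSMB = "DSMB"
    EXTERNAL_SOURCE = "EXTERNAL_SOURCE"
    PATIENT = "PATIENT"


@dataclass(frozen=True)
class Participant:
    participant_id: str
    role: Role
    display_name: str = ""


class AuthorizationError(PermissionError):
    pass


@dataclass(frozen=True)
class Authorization:
    allowed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.allowed


# Routes of the idealized trial network. The chain store itself is held
# by the regulator, so "posts to the chain" routes terminate there.
DEFAULT_POLICY_EDGES: frozenset[tuple[Role, Role]] = frozenset(
    {
        (Role.SPONSOR, Role.INVESTIGATOR),   # blinded treatment distribution
        (Role.INVESTIGATOR, Role.CRO),       # completed CRFs
        (Role.CRO, Role.SPONSOR),            # cleaned data + analysis scripts
        (Role.SPONSOR, Role.REGULATOR),      # protocol, final data package
        (Role.IVRS, Role.INVESTIGATOR),      # subject verification codes
        (Role.IVRS, Role.REGULATOR),         # encrypted decoding keys on-chain
        (Role.EXTERNAL_SOURCE, Role.SPONSOR),  # outside data collection
    }
)


@dataclass(frozen=True)
class TransactionPolicy:
    allowed_edges: frozenset[tuple[Role, Role]] = DEFAULT_POLICY_EDGES

    def permits(self, sender_role: Role, receiver_role: Role) -> bool:
        return (sender_role, receiver_role) in self.allowed_edges

    @classmethod
    def from_config(cls, config: dict) -> "TransactionPolicy":
        """Build from ``{"allowed_edges": [["SPONSOR", "REGULATOR"], ...]}``."""
        edges = frozenset(
            (Role(sender), Role(receiver)) for sender, receiver in config["allowed_edges"]
        )
        return cls(edges)

    def to_config(self) -> dict:
        return {
            "allowed_edges": sorted(
                [sender.value, receiver.value] for sender, receiver in self.allowed_edges
            )
        }


@dataclass
class ParticipantRegistry:
    """Roster of registered parties; exactly one regulator per trial."""

    participants: dict[str, Participant] = field(default_factory=dict)

    @classmethod
    def bootstrap(cls, regulator: Participant) -> "ParticipantRegistry":
        if regulator.role is not Role.REGULATOR:
            raise ValueError("bootstrap participant must hold the REGULATOR role")
        return cls({regulator.participant_id: regulator})

    def get(self, participant_id: str) -> Participant:
        try:
            return self.participants[participant_id]
        except KeyError:
            raise KeyError(f"participant {participant_id!r} is not registered") from None

    def __contains__(self, participant_id: str) -> bool:
        return participant_id in self.participants


def register_participant(
    registry: ParticipantRegistry,
    acting_party: Participant,
    new_participant: Participant,
) -> ParticipantRegistry:
    """Regulator-only roster addition; duplicate ids are rejected."""
    if acting_party.role is not Role.REGULATOR:
        raise AuthorizationError(
            f"only the regulator may register participants (caller role: {acting_party.role.value})"
        )
    if new_participant.participant_id in registry:
        raise ValueError(f"participant id {new_participant.participant_id!r} already registered")
    if new_participant.role is Role.REGULATOR and any(
        p.role is Role.REGULATOR for p in registry.participants.values()
    ):
        raise ValueError("a trial has exactly one regulator")
    registry.participants[new_participant.participant_id] = new_participant
    return registry


def authorize_transaction(
    policy: TransactionPolicy, sender: Participant, receiver: Participant
) -> Authorization:
    if policy.permits(sender.role, receiver.role):
        return Authorization(True)
    return Authorization(
        False,
        f"no route {sender.role.value} -> {receiver.role.value} in the trial policy",
    )


@dataclass(frozen=True)
class VerificationCode:
    subject_id: str
    code: str


def generate_verification_codes(subject_ids: list[str], seed: int) -> list[VerificationCode]:
    """One unique 8-character alphanumeric code per subject.

    Deterministic for a fixed seed; collisions (vanishingly rare at this
    code length) are re-drawn so codes are pairwise distinct.
    """
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject ids must be distinct")
    rng = Random(seed)
    seen: set[str] = set()
    codes = []
    for subject_id in subject_ids:
        while True:
            code = "".join(rng.choice(_CODE_ALPHABET) for _ in range(CODE_LENGTH))
            if code not in seen:
                break
        seen.add(code)
        codes.append(VerificationCode(subject_id, code))
    return codes


def post_decoding_keys(
    chain: Chain,
    ivrs: Participant,
    mapping: dict[str, str],
    password: str,
    at: datetime,
    rng: Random | None = None,
) -> Block:
    """Encrypt the arm mapping and append it as an IVRS block.

    The plaintext mapping never touches the chain: it is serialized,
    encrypted under the IVRS password, and stored as ciphertext until
    unblinding.
    """
    if ivrs.role is not Role.IVRS:
        raise AuthorizationError("decoding keys may only be posted by the IVRS")
    plaintext = json.dumps(mapping, sort_keys=True).encode("utf-8")
    blob = crypto_privacy.encrypt_payload(plaintext, password, rng=rng)
    return append_transaction(
        chain,
        sender_id=ivrs.participant_id,
        receiver_id="REGULATOR",
        file_name=DECODING_KEYS_FILE,
        payload=blob.to_bytes(),
        encrypted=True,
        at=at,
        plaintext=plaintext,
    )


def unblind(chain: Chain, password: str) -> dict[str, str]:
    """Decrypt the latest on-chain decoding keys and return the arm mapping."""
    block = version_control.latest_version(chain, DECODING_KEYS_FILE)
    plaintext = crypto_privacy.decrypt_payload(block.payload, password)
    return json.loads(plaintext.decode("utf-8"))
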