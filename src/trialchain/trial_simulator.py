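"""Scripted replay of a four-arm allergen-immunotherapy trial.

The fixture generator emulates the chronology of a completed phase II
omalizumab trial run through the ledger: protocol upload, verification
code issuance and encrypted decoding keys, the blinded treatment
distribution, per-visit CRFs from the investigator, the CRO's cleaned
data and analysis-script placeholder, and the sponsor's final package
to the regulator.  Two subjects carry real printed values — subject
73491's day-0 labs (WBC 5.9, eosinophils 4.6%, platelets 223) and the
adverse-event lists for subjects 73491 and 73511; every other subject,
visit, and demographic is synthesized from seeded draws inside the
physiological ranges declared in ``SYNTHETIC_LAB_RANGES`` and carries
no authority beyond being plausible.

Both hostile scenarios are reproducible here: *user-mediated*
tampering, where a logged-in sponsor re-uploads CRFs with the adverse
events stripped (caught by version control, not by hashing — the
append path never breaks a digest), and *storage-level* corruption,
where bytes of a stored record are mutated behind the API's back
(caught by hash validation, localized to the block and file).

A scenario replayed with the same seed produces a byte-identical chain
store: the clock is scripted (trial day d maps to t0 + d days) and all
randomness, including the encryption of the decoding keys, flows from
the scenario seed.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from random import Random

from . import crf_adverse_events, protocol_roles, version_control
from .core_ledger import Block, Chain, append_transaction, read_chain
from .crf_adverse_events import CRF, Demographics, LabPanel, serialize_crf
from .protocol_roles import (
    DEFAULT_POLICY_EDGES,
    Participant,
    ParticipantRegistry,
    Role,
    TransactionPolicy,
    authorize_transaction,
    generate_verification_codes,
    post_decoding_keys,
    register_participant,
)

__all__ = [
    "DEFAULT_SEED",
    "ScriptedTransaction",
    "ScriptError",
    "TrialScenario",
    "default_roster",
    "generate_trial_fixture",
    "replay",
    "simulate_storage_corruption",
    "simulate_user_tamper",
]

DEFAULT_SEED = 20190222
TRIAL_ID = "NCT00078195"
TRIAL_START = datetime(2019, 2, 22, 9, 0, 0, tzinfo=timezone.utc)
IVRS_PASSWORD = "ivrs-decoding-key-passphrase"

# Printed worked-example values carried by the default fixture.
SUBJECT_73491 = "73491"
SUBJECT_73511 = "73511"
DAY0_LABS_73491 = {"wbc": 5.9, "eosinophil_pct": 4.6, "platelets": 223.0}
ADVERSE_EVENTS_73491 = (
    "muscle strain",
    "injection site swelling",
    "sinus headaches",
    "nasal congestion",
)
ADVERSE_EVENTS_73511 = (
    "chest tightness",
    "injection site reactions",
    "sinus congestion",
    "decreased blood pressure",
    "lower respiratory tract infection",
)

# Synthetic draw windows for labs the source never printed. These are
# broad adult reference intervals, not trial data.
SYNTHETIC_LAB_RANGES: dict[str, tuple[float, float]] = {
    "wbc": (4.0, 11.0),            # 10^3 cells/uL
    "eosinophil_pct": (0.5, 6.0),  # %
    "platelets": (150.0, 400.0),   # 10^3 cells/uL
    "monocytes": (0.2, 0.8),       # 10^3 cells/uL
    "neutrophils": (1.8, 7.5),     # 10^3 cells/uL
    "basophils": (0.0, 0.2),       # 10^3 cells/uL
    "lymphocytes": (1.0, 4.0),     # 10^3 cells/uL
    "rbc": (4.0, 5.9),             # 10^6 cells/uL
    "hemoglobin": (12.0, 17.5),    # g/dL
    "free_ige": (10.0, 300.0),     # assay units
    "free_igg": (100.0, 1500.0),   # assay units
}
SYNTHETIC_RACES = ("White", "Black or African American", "Asian", "Other")
SYNTHETIC_GENDERS = ("Female", "Male")


@dataclass(frozen=True)
class ScriptedTransaction:
    sender_id: str
    receiver_id: str
    action: str
    file_name: str
    day: int
    payload_b64: str = ""
    encrypt_password: str = ""

    @property
    def payload(self) -> bytes:
        return base64.b64decode(self.payload_b64)


@dataclass
class TrialScenario:
    trial_id: str
    subjects: list[tuple[str, str]]  # (subject_id, blinded arm code)
    event_script: list[ScriptedTransaction]
    seed: int
    codes: dict[str, str] = field(default_factory=dict)  # subject -> verification code


class ScriptError(RuntimeError):
    """A scripted transaction violated the trial policy; names the step."""


def default_roster() -> tuple[ParticipantRegistry, TransactionPolicy]:
    """Standard single-site roster: one party per network role."""
    regulator = Participant("REGULATOR", Role.REGULATOR, "Trial Regulator")
    registry = ParticipantRegistry.bootstrap(regulator)
    for pid, role, name in (
        ("SPONSOR", Role.SPONSOR, "Trial Sponsor"),
        ("CRO", Role.CRO, "Clinical Research Organization"),
        ("INVESTIGATOR_x", Role.INVESTIGATOR, "Site Investigator"),
        ("IVRS", Role.IVRS, "IVRS Provider"),
        ("DSMB", Role.DSMB, "Data Safety Management Board"),
        ("EXTERNAL", Role.EXTERNAL_SOURCE, "External Data Source"),
    ):
        register_participant(registry, regulator, Participant(pid, role, name))
    return registry, TransactionPolicy(DEFAULT_POLICY_EDGES)


def _synthetic_subject_ids(n: int, rng: Random) -> list[str]:
    ids = [SUBJECT_73491, SUBJECT_73511]
    while len(ids) < n:
        candidate = str(rng.randint(70000, 79999))
        if candidate not in ids:
            ids.append(candidate)
    return ids[:n]


def _synthetic_crf(
    subject_id: str,
    arm_code: str,
    day: int,
    code: str,
    rng: Random,
    fixed_labs: dict[str, float] | None = None,
    adverse_events: tuple[str, ...] = (),
) -> CRF:
    labs = {
        name: round(rng.uniform(lo, hi), 1)
        for name, (lo, hi) in SYNTHETIC_LAB_RANGES.items()
    }
    if fixed_labs:
        labs.update(fixed_labs)
    demographics = Demographics(
        race=rng.choice(SYNTHETIC_RACES),
        gender=rng.choice(SYNTHETIC_GENDERS),
        age=float(rng.randint(18, 65)),
    )
    return CRF(
        subject_id=subject_id,
        visit_day=day,
        arm_code=arm_code,
        demographics=demographics,
        labs=LabPanel(**labs),
        adverse_events=list(adverse_events),
        verification_code=code,
    )


def generate_trial_fixture(
    n_subjects: int = 4, n_arms: int = 4, seed: int = DEFAULT_SEED
) -> TrialScenario:
    """Build the scripted trial scenario.

    Arms are assigned round-robin so they stay balanced; the default
    (4, 4) gives one subject per arm.  All payloads are fixed at
    generation time, so :func:`replay` is a pure function of the
    scenario.
    """
    if n_arms < 1 or n_subjects < n_arms:
        raise ValueError("need n_subjects >= n_arms >= 1")
    rng = Random(seed)
    subject_ids = _synthetic_subject_ids(n_subjects, rng)
    arm_codes = [f"ARM_{chr(ord('A') + i)}" for i in range(n_arms)]
    subjects = [(sid, arm_codes[i % n_arms]) for i, sid in enumerate(subject_ids)]

    codes = generate_verification_codes(subject_ids, seed=rng.randrange(2**31))
    code_by_subject = {c.subject_id: c.code for c in codes}

    script: list[ScriptedTransaction] = []

    def step(sender, receiver, action, file_name, day, payload: bytes, password=""):
        script.append(
            ScriptedTransaction(
                sender, receiver, action, file_name, day,
                base64.b64encode(payload).decode("ascii"), password,
            )
        )

    protocol_text = (
        f"Study protocol for trial {TRIAL_ID}: randomized evaluation of allergen "
        f"immunotherapy co-administered with omalizumab across {n_arms} treatment arms.\n"
    )
    step("SPONSOR", "REGULATOR", "protocol_upload", "studyProtocol.txt", 0,
         protocol_text.encode())

    codes_csv = "subject_id,code\n" + "".join(
        f"{c.subject_id},{c.code}\n" for c in codes
    )
    step("IVRS", "INVESTIGATOR_x", "verification_codes", "verificationCodes.csv", 0,
         codes_csv.encode())

    arm_mapping = {arm: f"treatment plan {arm[-1]}" for arm in arm_codes}
    step("IVRS", "REGULATOR", "decoding_keys", protocol_roles.DECODING_KEYS_FILE, 0,
         json.dumps(arm_mapping, sort_keys=True).encode(), password=IVRS_PASSWORD)

    distribution_csv = "subject_id,arm_code\n" + "".join(
        f"{sid},{arm}\n" for sid, arm in subjects
    )
    step("SPONSOR", "INVESTIGATOR_x", "treatment_distribution",
         "treatmentDistribution.csv", 1, distribution_csv.encode())

    for subject_id, arm in subjects:
        fixed = DAY0_LABS_73491 if subject_id == SUBJECT_73491 else None
        events: tuple[str, ...] = ()
        if subject_id == SUBJECT_73491:
            events = ADVERSE_EVENTS_73491
        elif subject_id == SUBJECT_73511:
            events = ADVERSE_EVENTS_73511
        crf = _synthetic_crf(
            subject_id, arm, 0, code_by_subject[subject_id], rng,
            fixed_labs=fixed, adverse_events=events,
        )
        step("INVESTIGATOR_x", "CRO", "crf_upload",
             f"crf_{subject_id}_day0.json", 2, serialize_crf(crf))

    cleaned_csv = "subject_id,arm_code,visit_day,complete\n" + "".join(
        f"{sid},{arm},0,yes\n" for sid, arm in subjects
    )
    step("CRO", "SPONSOR", "cleaned_data", "cleanedData.csv", 30, cleaned_csv.encode())
    placeholder = (
        "# Placeholder analysis script: stands in for the trial's real\n"
        "# statistical pipeline, which is not distributed here.\n"
        "print('summary statistics placeholder')\n"
    )
    step("CRO", "SPONSOR", "analysis_scripts", "analysisScripts.py", 30,
         placeholder.encode())

    final_package = json.dumps(
        {
            "trial_id": TRIAL_ID,
            "n_subjects": n_subjects,
            "n_arms": n_arms,
            "conclusion": "final data package for regulatory review",
        },
        sort_keys=True,
    ).encode()
    step("SPONSOR", "REGULATOR", "final_package", "finalPackage.json", 60, final_package)

    return TrialScenario(TRIAL_ID, subjects, script, seed, code_by_subject)


def _day_to_instant(day: int, ordinal: int) -> datetime:
    # one minute between same-day transactions keeps timestamps distinct
    return TRIAL_START + timedelta(days=day, minutes=ordinal)


def replay(scenario: TrialScenario, store_path: Path | str | None = None) -> Chain:
    """Execute the scripted transactions onto a fresh chain.

    Every step is authorized against the trial policy before it is
    appended; a policy violation aborts naming the offending step.  The
    resulting chain always passes validation.
    """
    registry, policy = default_roster()
    chain = Chain.initialize(scenario.trial_id, TRIAL_START, store_path)
    crypto_rng = Random(scenario.seed ^ 0x5EED)
    for ordinal, tx in enumerate(scenario.event_script, start=1):
        sender = registry.get(tx.sender_id)
        receiver = registry.get(tx.receiver_id)
        decision = authorize_transaction(policy, sender, receiver)
        if not decision:
            raise ScriptError(f"step {ordinal} ({tx.action}): {decision.reason}")
        at = _day_to_instant(tx.day, ordinal)
        if tx.encrypt_password:
            post_decoding_keys(
                chain, sender, json.loads(tx.payload.decode()),
                tx.encrypt_password, at, rng=crypto_rng,
            )
        else:
            append_transaction(
                chain, tx.sender_id, tx.receiver_id, tx.file_name,
                tx.payload, False, at,
            )
    return chain


def simulate_user_tamper(
    chain: Chain,
    actor: Participant,
    target_subject_ids: list[str],
    day: int = 45,
) -> Chain:
    """Legitimate-channel tampering: re-upload CRFs with events erased.

    For each target subject the latest on-chain CRF is copied, its
    adverse-event list emptied, and the copy appended under the same
    base file name by ``actor`` — so version control stamps it ``(v2)``
    (or higher) and records exactly who changed what, and when.  The
    originals are untouched and the chain still validates: tampering
    through the append path never breaks a hash.
    """
    for ordinal, subject_id in enumerate(target_subject_ids, start=1):
        block = _latest_crf_block(chain, subject_id)
        if block is None:
            raise KeyError(f"no on-chain CRF for subject {subject_id!r}")
        crf = crf_adverse_events.parse_crf(block.payload)
        tampered = crf.model_copy(update={"adverse_events": []})
        base_name, _ = version_control.split_versioned_name(block.file_name)
        append_transaction(
            chain,
            actor.participant_id,
            "REGULATOR",
            base_name,
            serialize_crf(tampered),
            False,
            _day_to_instant(day, ordinal),
        )
    return chain


def _latest_crf_block(chain: Chain, subject_id: str) -> Block | None:
    best: Block | None = None
    best_version = 0
    for block in chain:
        if block.index == 0 or block.encrypted:
            continue
        if not crf_adverse_events.is_crf_payload(block.payload):
            continue
        crf = crf_adverse_events.parse_crf(block.payload)
        if crf.subject_id != subject_id:
            continue
        _, version = version_control.split_versioned_name(block.file_name)
        if best is None or version >= best_version:
            best, best_version = block, version
    return best


@dataclass(frozen=True)
class ByteFlip:
    """Mutation spec: XOR one payload byte of the stored record."""

    offset: int = 0
    xor_mask: int = 0x01


def simulate_storage_corruption(
    store_path: Path | str,
    block_selector: int | str,
    mutation: ByteFlip = ByteFlip(),
) -> Path:
    """Mutate a stored record directly, bypassing the append-only API.

    ``block_selector`` is a block index or a file base name (the latest
    version of that name).  The payload byte at ``mutation.offset`` is
    XORed with ``mutation.xor_mask`` and the record rewritten with its
    original hash fields intact — exactly what a storage-level fault or
    attack looks like.  The genesis block is refused: it anchors every
    audit.
    """
    store_path = Path(store_path)
    chain = read_chain(store_path)
    if isinstance(block_selector, int):
        matches = [b for b in chain if b.index == block_selector]
        if not matches:
            raise KeyError(f"no block with index {block_selector}")
        target = matches[0]
    else:
        target = version_control.latest_version(chain, block_selector)
    if target.index == 0:
        raise ValueError("refusing to corrupt the genesis block (audit anchor)")
    if not target.payload:
        raise ValueError(f"block {target.index} has an empty payload")

    mutated = bytearray(target.payload)
    offset = mutation.offset % len(mutated)
    mutated[offset] ^= mutation.xor_mask
    if bytes(mutated) == target.payload:
        raise ValueError("mutation is a no-op (xor_mask 0)")

    lines = store_path.read_text(encoding="utf-8").splitlines()
    for i, line in enumerate(lines):
        record = json.loads(line)
        if record["index"] == target.index:
            record["payload_b64"] = base64.b64encode(bytes(mutated)).decode("ascii")
            lines[i] = json.dumps(record)
            break
    store_path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return store_path
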