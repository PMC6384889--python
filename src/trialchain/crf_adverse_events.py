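"""Case report forms and the automated adverse-event feed.

The canonical CRF is a JSON document: one subject-visit with
demographics, an immunological lab panel (cell concentrations, free IgE
and IgG, hemoglobin, platelets), a free-text adverse-event list, and the
subject's verification code.  A flat CSV dialect (one row per visit,
events ``;``-separated) is accepted for scanned paper workflows.  CRF
blocks on the chain are recognized by the ``document_type`` field inside
the payload, never by file-name convention.

The adverse-event feed scans every CRF-bearing block — all versions,
since superseded versions remain on the append-only chain — and emits
one notice per event per CRF version, each traceable to its source
block.  This gives the regulator and DSMB each subject's reactions at
the soonest possible time, bypassing the slower CRF → CRO → sponsor →
DSMB relay.  Notices from old versions persist when a file is
re-uploaded: a later version with the events stripped out contributes
nothing new but erases nothing either.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import crypto_privacy, version_control
from .core_ledger import Chain
from .protocol_roles import VerificationCode

__all__ = [
    "CRF",
    "AdverseEventNotice",
    "CodeCheck",
    "CRFValidationError",
    "Demographics",
    "FeedResult",
    "FeedWarning",
    "LabPanel",
    "crfs_from_csv",
    "extract_adverse_events",
    "is_crf_payload",
    "normalize_event_text",
    "parse_crf",
    "serialize_crf",
    "validate_verification_code",
]

CRF_DOCUMENT_TYPE = "crf"


class CRFValidationError(ValueError):
    """Payload is not a valid CRF document; lists the offending fields."""

    def __init__(self, fields: list[str], message: str):
        super().__init__(message)
        self.fields = fields


class Demographics(BaseModel):
    model_config = ConfigDict(extra="forbid")
    race: Optional[str] = None
    gender: Optional[str] = None
    age: Optional[float] = Field(default=None, ge=0)


class LabPanel(BaseModel):
    """Per-visit laboratory measurements; every field optional.

    Units: cell concentrations in 10^3 cells/uL (RBC 10^6 cells/uL),
    eosinophils as a percentage, hemoglobin in g/dL, free IgE/IgG as
    assay concentrations.
    """

    model_config = ConfigDict(extra="forbid")
    wbc: Optional[float] = Field(default=None, ge=0)
    eosinophil_pct: Optional[float] = Field(default=None, ge=0)
    platelets: Optional[float] = Field(default=None, ge=0)
    monocytes: Optional[float] = Field(default=None, ge=0)
    neutrophils: Optional[float] = Field(default=None, ge=0)
    basophils: Optional[float] = Field(default=None, ge=0)
    lymphocytes: Optional[float] = Field(default=None, ge=0)
    rbc: Optional[float] = Field(default=None, ge=0)
    hemoglobin: Optional[float] = Field(default=None, ge=0)
    free_ige: Optional[float] = Field(default=None, ge=0)
    free_igg: Optional[float] = Field(default=None, ge=0)


class CRF(BaseModel):
    """One subject-visit case report form."""

    model_config = ConfigDict(extra="forbid")
    subject_id: str
    visit_day: int = Field(ge=0)
    arm_code: str = ""
    demographics: Demographics = Field(default_factory=Demographics)
    labs: LabPanel = Field(default_factory=LabPanel)
    adverse_events: list[str] = Field(default_factory=list)
    verification_code: str = ""
    extras: dict = Field(default_factory=dict)

    @field_validator("subject_id")
    @classmethod
    def _non_empty_subject(cls, value: str) -> str:
        if not value:
            raise ValueError("subject_id must be non-empty")
        return value


_KNOWN_FIELDS = set(CRF.model_fields) - {"extras"} | {"document_type"}


def parse_crf(payload: bytes) -> CRF:
    """Parse a canonical JSON CRF (or a single-row CSV document).

    Unknown top-level fields are preserved in ``extras``; missing or
    invalid required fields raise :class:`CRFValidationError` naming
    them.
    """
    text = bytes(payload).decode("utf-8", errors="replace").strip()
    if text.startswith("{"):
        try:
            document = json.loads(text)
        except json.JSONDecodeError as exc:
            raise CRFValidationError(["<document>"], f"invalid JSON: {exc}") from exc
        return _crf_from_mapping(document)
    crfs = crfs_from_csv(text)
    if len(crfs) != 1:
        raise CRFValidationError(
            ["<document>"], f"expected one CSV visit row, found {len(crfs)}"
        )
    return crfs[0]


def _crf_from_mapping(document: dict) -> CRF:
    extras = dict(document.get("extras", {}))
    fields = {}
    for key, value in document.items():
        if key in ("extras", "document_type"):
            continue
        if key in _KNOWN_FIELDS:
            fields[key] = value
        else:
            extras[key] = value
    try:
        return CRF(**fields, extras=extras)
    except ValidationError as exc:
        bad = [".".join(str(p) for p in err["loc"]) or "<document>" for err in exc.errors()]
        raise CRFValidationError(bad, f"invalid CRF fields: {', '.join(bad)}") from exc


def serialize_crf(crf: CRF) -> bytes:
    """Canonical JSON bytes; ``serialize -> parse`` is the identity."""
    document = {"document_type": CRF_DOCUMENT_TYPE, **crf.model_dump(exclude_none=True)}
    return json.dumps(document, sort_keys=True).encode("utf-8")


_CSV_LAB_COLUMNS = tuple(LabPanel.model_fields)
_CSV_DEMO_COLUMNS = tuple(Demographics.model_fields)


def crfs_from_csv(text: str) -> list[CRF]:
    """Ingest the flat CSV dialect: one visit per row.

    Columns ``subject_id, visit_day, arm_code, verification_code``, the
    demographic and lab column names, and ``adverse_events`` with events
    separated by ``;``.  Unrecognized columns land in ``extras``.
    """
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or "subject_id" not in reader.fieldnames:
        raise CRFValidationError(["subject_id"], "CSV header must include subject_id")
    crfs = []
    for row in reader:
        document: dict = {"labs": {}, "demographics": {}}
        for column, raw in row.items():
            if raw is None or raw == "":
                continue
            if column in _CSV_LAB_COLUMNS:
                document["labs"][column] = float(raw)
            elif column == "age":
                document["demographics"]["age"] = float(raw)
            elif column in _CSV_DEMO_COLUMNS:
                document["demographics"][column] = raw
            elif column == "adverse_events":
                document["adverse_events"] = [
                    e.strip() for e in raw.split(";") if e.strip()
                ]
            elif column == "visit_day":
                document["visit_day"] = int(raw)
            else:
                document[column] = raw
        crfs.append(_crf_from_mapping(document))
    return crfs


@dataclass(frozen=True)
class CodeCheck:
    valid: bool
    reason: str = ""


def validate_verification_code(crf: CRF, issued: list[VerificationCode]) -> CodeCheck:
    """A CRF is legitimate iff it carries its subject's issued code."""
    if not crf.verification_code:
        return CodeCheck(False, "missing: no verification code on the CRF")
    by_subject = {c.subject_id: c.code for c in issued}
    expected = by_subject.get(crf.subject_id)
    if expected is None:
        return CodeCheck(False, f"unknown subject: no code issued for {crf.subject_id!r}")
    if crf.verification_code != expected:
        return CodeCheck(False, "mismatch: code does not match the one issued to this subject")
    return CodeCheck(True)


@dataclass(frozen=True)
class AdverseEventNotice:
    subject_id: str
    event_text: str
    source_block_index: int
    crf_version: int
    timestamp: str


@dataclass(frozen=True)
class FeedWarning:
    block_index: int
    file_name: str
    reason: str


@dataclass(frozen=True)
class FeedResult:
    """Ordered adverse-event notices plus unreadable-block warnings."""

    notices: tuple[AdverseEventNotice, ...]
    warnings: tuple[FeedWarning, ...] = ()

    def __iter__(self):
        return iter(self.notices)

    def __len__(self) -> int:
        return len(self.notices)


def normalize_event_text(event: str) -> str:
    """Case-insensitive, whitespace-normalized form used for dedup in reports."""
    return " ".join(event.lower().split())


def extract_adverse_events(
    chain: Chain, passwords: dict[str, str] | None = None
) -> FeedResult:
    """Auto-populate the adverse-event feed from on-chain CRFs.

    Every CRF-bearing block contributes one notice per listed event,
    ordered by block index; superseded CRF versions keep their notices,
    labeled with the version they came from.  Encrypted blocks are
    decrypted with ``passwords[file_base_name]`` when provided;
    otherwise they are reported as unreadable rather than silently
    skipped.  Unparseable CRF payloads likewise become warnings and the
    scan continues.
    """
    passwords = passwords or {}
    notices: list[AdverseEventNotice] = []
    warnings: list[FeedWarning] = []
    for block in chain:
        if block.index == 0:
            continue
        base_name, crf_version = version_control.split_versioned_name(block.file_name)
        payload = block.payload
        if block.encrypted:
            password = passwords.get(base_name)
            if password is None:
                warnings.append(
                    FeedWarning(block.index, block.file_name, "encrypted: no password provided")
                )
                continue
            try:
                payload = crypto_privacy.decrypt_payload(payload, password)
            except (crypto_privacy.AuthenticationError, crypto_privacy.BlobFormatError) as exc:
                warnings.append(FeedWarning(block.index, block.file_name, str(exc)))
                continue
        if not is_crf_payload(payload):
            continue
        try:
            crf = parse_crf(payload)
        except CRFValidationError as exc:
            warnings.append(FeedWarning(block.index, block.file_name, str(exc)))
            continue
        for event in crf.adverse_events:
            notices.append(
                AdverseEventNotice(
                    subject_id=crf.subject_id,
                    event_text=event,
                    source_block_index=block.index,
                    crf_version=crf_version,
                    timestamp=block.timestamp,
                )
            )
    return FeedResult(tuple(notices), tuple(warnings))


def is_crf_payload(payload: bytes) -> bool:
    text = bytes(payload).decode("utf-8", errors="replace").lstrip()
    if not text.startswith("{"):
        return False
    try:
        document = json.loads(text)
    except json.JSONDecodeError:
        return False
    return isinstance(document, dict) and document.get("document_type") == CRF_DOCUMENT_TYPE
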