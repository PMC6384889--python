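# Methods

## Ledger model

Each trial transaction — one file moving from one registered party to
another — is one block; there is no batching. A block holds an index,
a UTC timestamp, sender and receiver identifiers, the recorded file
name, the payload, an encryption flag, the previous block's digest, and
its own digest. The digest is SHA-256 over a canonical pre-image: the
UTF-8 encoding of the fields joined in fixed order with a `|`
separator, with the payload base64-encoded:

```
index | timestamp | sender | receiver | file_name | encrypted(0/1) | b64(payload) | prev_hash
```

"Concatenate and hash" admits ambiguous serializations (`"ab"+"c"` vs
`"a"+"bc"`); the separator plus base64 makes the pre-image injective, so
equal digests imply equal field tuples for all practical purposes. The
genesis block has index 0, an all-zero previous hash, the regulator as
both parties, and the trial identifier as payload. Timestamps are
second-precision ISO-8601 (`YYYY-MM-DDTHH:MM:SSZ`) and injected by the
caller, never read from the wall clock inside the library, so scripted
replays are bit-reproducible. Digests are rendered as 64 lowercase hex
characters.

Persistence is one JSON-lines file, one block per line, payload base64
at rest, fields `index, timestamp, sender, receiver, file_name,
encrypted, payload_b64, prev_hash, hash`. Reading is deliberately
split from validating: a store whose payload was edited on disk still
parses, and the corruption is then localized by the audit layer. A
structurally broken store (bad JSON, missing fields) raises a format
error naming the first bad line. Because the bookkeeping per block is
fixed-length, store size is linear in total payload bytes plus block
count; the acceptance suite fits this regression over chains of
10–1000 blocks.

## Version control

Ledger entries are never mutated; corrections arrive as new
transactions. At append time the upload's content fingerprint
(SHA-256 of the payload bytes) is compared against every stored version
sharing the same base name (the submitted name with any trailing
` (vN)` stripped before the extension; matching is exact and
case-sensitive). Three outcomes:

- *original* — base name unseen; recorded unsuffixed (version 1);
- *duplicate(N)* — content identical to an existing version N; the
  transaction is still recorded (append-only history) under the
  existing display name, with no version bump, since only differing
  re-uploads constitute new versions;
- *new_version(N)* — content differs from all stored versions;
  N = 1 + highest existing version, displayed as `base (vN).ext`.

Version numbers the uploader writes into the submitted file name are
stripped and ignored: the system assigns versions. Per base name the
versions are therefore exactly 1..K with no gaps. Fingerprints cover
the plaintext supplied at upload time; an upload arriving already
encrypted with no plaintext falls back to ciphertext bytes, in which
case re-encryptions of identical content under fresh salts will not be
detected as duplicates — a documented limitation, accepted so that
auditing never requires keys (see below). Conflict scope is per base
name with content compared by fingerprint; a global content-identity
check across differing names was considered and rejected as producing
surprising cross-file version couplings.

## Audit

Validation walks blocks in index order, checks the previous-hash link
against the predecessor, recomputes each digest from the stored fields,
and stops at the first failure, reporting its index, file name, and
failure kind (`linkage-break` vs `hash-mismatch`). First-failure
semantics are intentional: downstream blocks are transitively broken
and re-reporting them adds noise, not information.

Registry audits compare `(index, hash)` pairs by string equality only.
Two constructors exist with different trust contracts:

- `export_hash_registry` — the regulator's trusted checkpoint; refuses
  an invalid chain, because checkpointing corrupted storage would poison
  later audits;
- `candidate_registry` — fingerprints a chain *under audit* by
  recomputing each block's digest from its stored fields; never
  refuses.

For tampering of any hashed field (payload, timestamp, parties, file
name, previous-hash link) the registry comparison and full validation
agree on verdict and failure index; the one exception is an edit that
rewrites only the stored bookkeeping `hash` column itself, which only
full validation can flag. Registry comparison performs zero hash
computations, and registry size is independent of payload sizes, so an
auditor can verify a multi-gigabyte chain from a few kilobytes of
digests without reading any confidential content.

## Encryption

Payload encryption is password-based and authenticated, built on
primitives from the Python standard library:

- **KDF**: PBKDF2-HMAC-SHA256, 16-byte random salt, 200,000 iterations
  by default (floor 10,000), 32-byte master key.
- **Cipher**: CTR-style keystream, block *i* =
  `HMAC-SHA256(enc_key, nonce ‖ i)`, XORed into the plaintext; 16-byte
  random nonce per encryption.
- **Authentication**: encrypt-then-MAC; `HMAC-SHA256(mac_key, header ‖
  ciphertext)` with constant-time comparison. `enc_key` and `mac_key`
  are derived from the master key by HMAC with distinct labels.

A wrong password or any bit-flip in the blob fails authentication with
an explicit error; decryption never returns garbage. Encryption is
randomized (fresh salt and nonce), so equal plaintexts yield unequal
blobs; for reproducible simulations a seeded generator can be injected
in place of the OS entropy source. The wire format is
`magic ‖ iterations(4B BE) ‖ salt(16) ‖ nonce(16) ‖ tag(32) ‖ ciphertext`.

Block hashes cover the stored ciphertext, not the plaintext. The
alternative (hashing plaintext) would let auditors confirm content
identity but would make validation impossible without every password;
since the audit trail is the system's core guarantee, ciphertext
hashing was chosen. Passwords are never written to the chain or logs.

## Protocol and roles

The participant roster is bootstrapped with the single regulator, who
alone registers further parties. The default transaction policy is the
edge list

```
SPONSOR→INVESTIGATOR, INVESTIGATOR→CRO, CRO→SPONSOR, SPONSOR→REGULATOR,
IVRS→INVESTIGATOR, IVRS→REGULATOR, EXTERNAL_SOURCE→SPONSOR
```

and is configurable (JSON edge list) since real networks differ.
Patients are registry entries for code custody but never block
senders. Verification codes are 8-character uppercase alphanumerics
from a seeded PRNG with collision re-draw — one per subject, reused
across that subject's visits. Decoding keys (the blinded arm-label
mapping) go on-chain only as an encrypted blob posted by the IVRS;
unblinding decrypts the latest version with the IVRS password.

## CRFs and the adverse-event feed

The canonical CRF is a flat JSON document (`document_type: "crf"`):
subject id, visit day, blinded arm code, demographics (race, gender,
age), an optional per-visit lab panel (WBC, eosinophil %, platelets,
monocytes, neutrophils, basophils, lymphocytes — 10³ cells/µL except
eosinophils in %; RBC in 10⁶ cells/µL; hemoglobin g/dL; free IgE and
IgG assay concentrations, all non-negative), a free-text adverse-event
list, and the verification code. Unknown fields are preserved in an
`extras` map rather than rejected. A CSV dialect (one visit per row,
events `;`-separated) supports scanned paper workflows. CRF blocks are
recognized by the `document_type` field, not by file-name convention.

The feed emits one notice per event per CRF version in block order;
notices carry the source block index and version, and superseded
versions keep their notices. Encrypted blocks with no supplied
password, and unparseable CRF payloads, become explicit warnings —
never silent skips. Event texts are free text; reports deduplicate
case-insensitively after whitespace normalization, with no clinical
coding (MedDRA/CTCAE out of scope).

## The simulator

`generate_trial_fixture(n_subjects=4, n_arms=4, seed)` scripts the
trial chronology — protocol upload, verification codes and encrypted
decoding keys, blinded treatment distribution CSV, one day-0 CRF per
subject, CRO cleaned data plus an analysis-script placeholder, and the
sponsor's final package. The default embeds the published worked
values (subject 73491's day-0 WBC 5.9, eosinophils 4.6 %, platelets
223; the adverse-event lists for subjects 73491 and 73511); every
other lab, demographic, and subject id is drawn from the seeded ranges
in `SYNTHETIC_LAB_RANGES` — broad adult reference intervals, labeled
synthetic, with no data authority. Arms are assigned round-robin, so
subject counts stay balanced. The scripted clock maps trial day *d* to
`t0 + d` days (one minute between same-day steps), and the decoding-key
encryption draws from a generator seeded by the scenario, so a replay
is byte-identical per seed.

The two attack scenarios are first-class operations:
`simulate_user_tamper` re-uploads targeted CRFs with events emptied
through the authorized append path (caught by versioning, chain still
validates), and `simulate_storage_corruption` flips a payload byte in
the stored record directly, leaving the recorded hashes untouched
(caught and localized by validation; the genesis block is refused as
the audit anchor).

## What the simulations do and do not show

Passing tests demonstrate the mechanics — tamper evidence, fault
localization, version attribution, feed completeness — on synthetic,
scripted data at small scale (4 subjects, one visit each, ~12 blocks;
property sweeps up to 1000 blocks). They say nothing about data that
is falsified at the point of origin before entering the chain, about
multi-machine replicated storage, about real authentication of
parties, or about clinical interpretation of the lab values and events.
The statistical-analysis block is an explicit placeholder. The
"zero-knowledge" audit is the informal hash-only sense, not a formal
zero-knowledge cryptographic protocol.

## Numerical and edge-case choices

- Hash text is lowercase hex; a malformed `prev_hash` is rejected
  before hashing.
- Empty payloads are legal everywhere (fingerprint = SHA-256 of the
  empty string); the storage-corruption operation refuses an empty
  payload since there is no byte to flip.
- Validation of an empty chain is a state error, not a report.
- Registry comparison of empty registries is rejected; a length
  mismatch fails at the first missing index.
- Code generation re-draws on collision, so uniqueness holds at any
  tested scale; at 8 alphanumeric characters the birthday bound makes
  re-draws negligible.
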