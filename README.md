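# trialchain

An append-only, tamper-evident ledger for clinical trial data
management, with content-hash version control, hash-registry audits,
password-based payload encryption, a role-based transaction protocol,
and automated adverse-event extraction from case report forms (CRFs).

## The problem

A clinical trial moves confidential documents among many parties —
sponsor, investigator site, CRO, IVRS provider, safety board, regulator
— and regulators have limited means to trace data back to its source or
to notice retroactive edits. `trialchain` records every exchange as one
block of a SHA-256 hash chain held by the regulator, so the full
transaction history is immutable, timestamped, and auditable.

Two distinct attack channels are covered:

- **Storage-level corruption** (bytes changed behind the API's back) is
  caught by hash validation. Block *i* stores
  `hash_i = SHA-256(index | timestamp | sender | receiver | file | enc | b64(payload) | hash_{i-1})`,
  so any edit to a stored block changes its recomputed digest and every
  digest after it; chronological re-validation localizes the fault to
  the exact block and file. Because digests are fixed-length, an audit
  needs only the `(index, hash)` registry — integrity is verified by
  string comparison without ever opening a payload.
- **User-level tampering** (a legitimate party re-uploading a doctored
  file) cannot break any hash, because it arrives through the append
  path. It is exposed instead by version control: each upload's content
  is fingerprinted (SHA-256) and compared against existing versions of
  the same base name; differing content is stamped with an incrementing
  `(vN)` suffix, originals keep no suffix, and nothing is ever
  overwritten — so who changed what, and when, is on the record.

Adverse events are parsed directly from every on-chain CRF version and
fed to the regulator and DSMB, so a later "cleaned" version that drops
events adds nothing and erases nothing.

## Worked example

Replay the packaged four-subject, four-arm trial scenario (two subjects
carry the published worked values: subject 73491's day-0 labs — WBC
5.9 ×10³ cells/µL, eosinophils 4.6 %, platelets 223 ×10³ cells/µL — and
the adverse-event lists for subjects 73491 and 73511):

```console
$ trialchain simulate --seed 7 --out demo.jsonl
replayed 11 transactions -> 12 blocks at demo.jsonl

$ trialchain ledger --store demo.jsonl | head -6
   0  2019-02-22T09:00:00Z       REGULATOR -> REGULATOR       genesis
   1  2019-02-22T09:01:00Z         SPONSOR -> REGULATOR       studyProtocol.txt
   2  2019-02-22T09:02:00Z            IVRS -> INVESTIGATOR_x  verificationCodes.csv
   3  2019-02-22T09:03:00Z            IVRS -> REGULATOR       decodingKeys.json  [encrypted]
   4  2019-02-23T09:04:00Z         SPONSOR -> INVESTIGATOR_x  treatmentDistribution.csv
   5  2019-02-24T09:05:00Z  INVESTIGATOR_x -> CRO             crf_73491_day0.json
```

A sponsor quietly re-uploads subject 73491's CRF with the adverse
events deleted — the system stamps it `(v2)` and names the editor:

```console
$ trialchain tamper --store demo.jsonl --mode user --subject 73491
$ trialchain versions --store demo.jsonl --file crf_73491_day0.json
v1  block    5  2019-02-24T09:05:00Z  INVESTIGATOR_x  crf_73491_day0.json
v2  block   12  2019-04-08T09:01:00Z         SPONSOR  crf_73491_day0 (v2).json
```

A storage-level byte flip in the treatment distribution is localized by
validation:

```console
$ trialchain tamper --store demo.jsonl --mode storage --file treatmentDistribution.csv
$ trialchain validate --store demo.jsonl
INVALID: hash-mismatch at block 4 — treatmentDistribution.csv
```

And the adverse-event feed keeps every version-1 notice while the
tampered version 2 contributes none:

```console
$ trialchain ae-feed --store demo.jsonl | head -5
adverse-event feed (regulator): 9 notices
  subject 73491  v1  block 5  muscle strain
  subject 73491  v1  block 5  injection site swelling
  subject 73491  v1  block 5  sinus headaches
  subject 73491  v1  block 5  nasal congestion
```

The same flows are available as a library — see
`trialchain.core_ledger`, `version_control`, `audit`,
`crypto_privacy`, `protocol_roles`, `crf_adverse_events`, and
`trial_simulator`; `docs/methods.md` documents the design.

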