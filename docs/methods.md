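# Methods

## The synchronization model

`elnbridge` synchronizes tree-structured entries (dicts, lists, scalars —
the in-memory image of each platform's JSON representation) between exactly
two registered platforms, A and B, where A is the first-registered platform.
One *sync model* binds one input mask per platform at a recorded mask
version, a per-side sync-key dot-path, and an ordered list of field
mappings.  A run proceeds as: list entries on both sides (the delegates
already apply the collection scope and the update-time cutoff policy), flag
per entry every mapping whose current value differs from the last-sync
snapshot, pair entries by equal sync-key values, plan creations for
unmatched entries, resolve a direction per pair, and transfer values
through the mappings' transfer operators.  `plan_sync` computes all of this
without side effects; `apply_plan` performs the writes.

Assumptions worth stating explicitly:

* **Run-at-a-time semantics.**  No external edits occur during a single
  run; concurrent edits are modelled as happening *between* runs.  This
  matches a batch/cron execution model and is what the mock platforms'
  scripted edit rounds emulate.
* **Change detection is value-based, not timestamp-based.**  The sync state
  stores, per pair and mapping, the value last written on each side; a
  field counts as changed iff its current value differs from that snapshot
  (appearing/disappearing fields count as changes).  Timestamps decide only
  *conflicts*, so skew between platform clocks cannot fabricate or mask
  changes.  Deleting the state file forces a full cold-start re-sync.
* **Last-write-wins, whole-entry.**  If both sides of a pair changed, the
  entry with the later `updated_at` sources *all* mapped fields — there is
  no field-level merge, even when the two sides changed disjoint fields.
  This is a deliberate, literal reading of the conflict rule; a merge would
  silently interleave two users' edits.  An exact timestamp tie is broken
  deterministically in favor of side A and logged as a conflict tie.
* **The engine never deletes.**  Pairs recorded in the state but no longer
  listed by either platform are logged as orphaned state; nothing is
  removed on any platform, and unmapped fields are never written
  (write payloads are built by setting only mapped paths on the target's
  current payload).

## Parameters that matter

| parameter | where | default | meaning |
|---|---|---|---|
| `scope` | platform config | absent | collection restricting which entries take part (only the Chemotion-like platform has collections; the Herbie-like one has no comparable feature, so its scope stays absent) |
| `existing_policy` | platform config | `all` | `all`, or `updated_after(t)`: only entries last updated at or after `t` (UTC) are listed |
| `allow_create` | platform config | `false` | whether unmatched partner entries may be created on this platform |
| `mask_version` | sync model side | — | checked against the platform's reported version at plan time; a mismatch aborts the run, since syncing against a changed schema corrupts entries |
| `interval`, `max_runs` | autosync | 60 s / required | in-process scheduler; a warning is logged when no manual run preceded autosync |

All timestamps are stored timezone-aware and compared in UTC; payload
date-time *fields* are plain strings validated against each mask's declared
strptime pattern and converted between conventions by `datefmt` transfer
operators.

## The transfer-operator DSL

Operators are finite expression trees over a single input value: `id`,
`cast`, `datefmt`, `remap` (finite dictionary, optional default; a missing
entry is a domain error), `add/sub/mul/div` with a constant, `concat`,
`split`, `ifeq`, and `pipe` for composition.  Evaluation is pure and
deterministic; the DSL is intentionally not Turing-complete — no loops, no
state, no access to the payload beyond the given value — because list
iteration is handled structurally by array mappings.  Operators are
single-input: combining several source fields into one target field is out
of scope.  `serialize_operator`/`parse_operator` are exact inverses on the
tree, and the serialized text is canonical (a fixed point of
parse-then-serialize).  A domain error (unmatched date pattern, failed
cast, missing remap entry) skips that one mapping for that one entry,
logged; other mappings proceed.

## Numerical and structural choices

* **Dot-paths**: purely numeric segments are 0-based list indices; reads
  are total (missing nodes yield a distinct absent marker, never an
  exception); writes have value semantics (the input tree is never
  mutated), create missing intermediate maps, and refuse to index through
  scalars.
* **Absent source values** skip the mapping rather than writing nulls —
  destructive nulling of the target is worse than staleness.
* **Pairing** canonicalizes key values to stripped text.  A key value
  duplicated on one side makes all its entries — *and* the clean
  counterpart entry on the other side — ambiguous: they are excluded from
  pairing and from creation and logged, because a guessed pairing or a
  duplicate creation is data corruption.
* **Array mappings** pair elements by index and truncate or extend the
  target list to the source length; the source order is authoritative.  No
  element-identity mechanism is assumed.
* **Creation** populates mapped fields plus the target sync key.  If the
  target mask declares required fields not covered by mappings, the
  creation fails and is logged (`create-failed`) — the engine cannot invent
  values.
* **Per-entry atomicity**: a write failure on one pair is logged and does
  not roll back other pairs; snapshots are updated only for pairs actually
  written.
* **1:1 model shape**: a sync model maps one mask to one mask; exactly two
  platforms per configuration (side A = first registered, which is also the
  tie-break winner).
* **Unknown config keys are errors**, not ignored: a silently misread key
  in a sync engine corrupts data on both platforms.

## What the mock platforms emulate — and what they do not

The bundled mocks reproduce the structural features the engine cares about:
per-mask field schemas (integer, text, choice-from-list, date-time with a
pattern, list-of-record), collections and token auth on the Chemotion-like
side, deterministic entry ids, and update timestamps driven by an
injectable manual clock so conflict resolution is exactly reproducible.
The REST delegate plus the bundled WSGI app serve the same store over
HTTP+JSON, and both delegate kinds pass one shared contract test suite.

They do **not** emulate: realistic chemistry content or molecule handling,
pagination, rate limits, partial API failures mid-request, cross-entry
links (link synchronization is a non-goal), attachments/files, deletions
(the contract cannot report them), or multi-user concurrent editing within
a run.  Passing tests therefore demonstrate the synchronization logic —
pairing, diffing, conflict resolution, transfer, gating — under faithful
structural conditions, not robustness against every failure mode of a live
ELN deployment.

## The scenario generator

`generate_random_scenario(seed, …)` populates both mocks with
schema-conformant random entries.  Defaults — 8 entries per side, 30 % key
overlap, 30 % edit rate per round — represent a small working set with a
meaningful mix of paired, one-sided and edited entries; creation is
interleaved in random order with a 30 s clock tick so either side may hold
the later timestamp of a pair.  Optional knobs inject duplicate sync keys
and out-of-scope entries.  The same seed reproduces the platforms and the
edit script byte-for-byte (scenarios serialize to JSON for regression use).
The engine-wide property checks run 100 scenarios at 5 entries per side
with overlaps cycling through {0, ¼, ½, ¾, 1} and a 0.4 edit rate — small
enough to keep the whole suite interactive, large enough that every
pairing/conflict/creation branch is exercised many times per batch.

## Known limitations

* Whole-entry overwrite means a conflict loser's edits to *unchanged-by-
  winner* fields are lost by design; the loser is logged (`conflict-loser`)
  so the history is auditable.
* Array element pairing by index misattributes changes when a list is
  reordered on one side.
* The dry run reports one representative object per direction (matching
  the interactive test dialog it replaces), not the full plan; the full
  plan is available programmatically via `plan_sync`.
* The REST delegate is a skeleton for the contract, not a hardened client
  (no retries, no pagination).
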