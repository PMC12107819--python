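"""The synchronization delegator: collect, diff, pair, create, transfer, log.

One run of the engine for a sync model proceeds in six steps:

1/3. read all entries of the paired mask from each platform, one after the
     other (delegates already apply collection scope and timeframe policy);
2/4. for each entry, flag every mapping whose current value differs from the
     value snapshotted at the last synchronization of that pair (with no
     snapshot — a cold start — every mapped field counts as changed);
5.   match entry pairs by equal sync-key values; unmatched entries become
     planned creations on the other platform when its settings allow it;
6.   transfer values through the mappings' transfer operators into the
     target entries, then persist fresh snapshots.

Conflict rule (last-write-wins): when both sides of a pair changed, the
entry with the later ``updated_at`` is the source for *all* mapped fields —
no field-level merge.  A timestamp tie is broken deterministically in favor
of side A (the first-registered platform) and logged as a conflict tie.

``plan_sync`` is side-effect-free; ``apply_plan`` performs the writes and
updates the state pair-wise (a failure on one pair does not roll back
others).  ``simulate`` is the dry-run test mode: one direction, one
representative object, zero delegate writes.  The engine never deletes
entries; pairs that vanish from a platform are logged as orphaned state.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Callable, Optional, Union

from .datamodel import (
    ChangeRecord,
    Entry,
    Mapping,
    PairState,
    SyncModel,
    SyncState,
    validate_sync_model,
)
from .delegates import DelegateError, PlatformDelegate, SchemaViolation
from .operators import OperatorDomainError, evaluate_operator, parse_operator
from .paths import ABSENT, get_path, set_path

__all__ = [
    "EngineError",
    "SkipRecord",
    "PlannedPairSync",
    "PlannedCreation",
    "SyncPlan",
    "PairingResult",
    "ProcessLog",
    "RunSummary",
    "canonical_key",
    "mapped_values",
    "changed_mappings",
    "collect_changes",
    "pair_entries",
    "resolve_direction",
    "apply_mapping_direction",
    "plan_sync",
    "apply_plan",
    "run_sync",
    "simulate",
    "run_autosync",
]


class EngineError(RuntimeError):
    """A run-level failure: unvalidated model, unreachable delegate, ..."""


# --------------------------------------------------------------------------
# plan data


@dataclass
class SkipRecord:
    reason: str  # no-change | missing-key | ambiguous-key | conflict-loser |
    #              create-disallowed | create-failed | orphaned-state
    entry_ref: str
    pair_key: Optional[str] = None
    detail: str = ""

    def to_dict(self) -> dict:
        return {
            "reason": self.reason,
            "entry_ref": self.entry_ref,
            "pair_key": self.pair_key,
            "detail": self.detail,
        }


@dataclass
class PlannedPairSync:
    pair_key: str
    direction: str  # a_to_b | b_to_a
    source_entry: Entry
    target_entry: Entry
    new_target_payload: dict
    records: list[ChangeRecord]
    conflict_tie: bool = False


@dataclass
class PlannedCreation:
    direction: str  # side holding the source -> side where the entry is created
    pair_key: str
    source_entry: Entry
    target_mask: str
    payload: dict
    record: ChangeRecord


@dataclass
class SyncPlan:
    run_id: str
    model_name: str
    planned_at: datetime
    pair_syncs: list[PlannedPairSync] = field(default_factory=list)
    creations: list[PlannedCreation] = field(default_factory=list)
    skips: list[SkipRecord] = field(default_factory=list)

    def planned_updates(self) -> list[ChangeRecord]:
        return [r for ps in self.pair_syncs for r in ps.records if r.action == "update"]

    def is_empty(self) -> bool:
        return not self.creations and not any(
            r.action == "update" for ps in self.pair_syncs for r in ps.records
        )


@dataclass
class PairingResult:
    pairs: list[tuple[Entry, Entry, str]]
    unmatched_a: list[tuple[Entry, str]]
    unmatched_b: list[tuple[Entry, str]]
    missing_key_a: list[Entry] = field(default_factory=list)
    missing_key_b: list[Entry] = field(default_factory=list)
    ambiguous_a: list[Entry] = field(default_factory=list)
    ambiguous_b: list[Entry] = field(default_factory=list)


# --------------------------------------------------------------------------
# process log


@dataclass
class RunSummary:
    run_id: str
    model_name: str
    started: datetime
    finished: datetime
    updates: int
    creates: int
    skips: int
    errors: int
    status: str  # ok | failed

    def to_dict(self) -> dict:
        return {
            "type": "run",
            "run_id": self.run_id,
            "model": self.model_name,
            "started": self.started.isoformat(),
            "finished": self.finished.isoformat(),
            "updates": self.updates,
            "creates": self.creates,
            "skips": self.skips,
            "errors": self.errors,
            "status": self.status,
        }


class ProcessLog:
    """Append-only run history, serialized as JSON lines (one object per line)."""

    def __init__(self, path: Optional[Union[str, Path]] = None):
        self.path = Path(path) if path else None
        self.lines: list[dict] = []
        if self.path and self.path.exists():
            for raw in self.path.read_text().splitlines():
                if raw.strip():
                    self.lines.append(json.loads(raw))

    def append(self, obj: dict) -> None:
        self.lines.append(obj)
        if self.path:
            with self.path.open("a") as fh:
                fh.write(json.dumps(obj, default=str) + "\n")

    def runs(self) -> list[dict]:
        return [l for l in self.lines if l.get("type") == "run"]

    def changes(self, run_id: Optional[str] = None) -> list[dict]:
        out = [l for l in self.lines if l.get("type") == "change"]
        if run_id is not None:
            out = [l for l in out if l.get("run_id") == run_id]
        return out

    def has_runs(self) -> bool:
        return bool(self.runs())

    def next_run_id(self) -> str:
        return f"run-{len(self.runs()) + 1:04d}"


# --------------------------------------------------------------------------
# building blocks


def canonical_key(value: Any) -> Optional[str]:
    """Canonical text form of a sync-key value; None when unusable for pairing."""
    if value is ABSENT or value is None:
        return None
    text = str(value).strip()
    return text or None


def mapped_values(model: SyncModel, payload: dict, side: str) -> dict[str, Any]:
    """Current values at every top-level mapping key on one side; absent keys omitted."""
    out: dict[str, Any] = {}
    for m in model.mappings:
        value = get_path(payload, model.key_for(m, side))
        if value is not ABSENT:
            out[m.identifier] = value
    return out


def changed_mappings(
    model: SyncModel, payload: dict, side: str, pair_state: Optional[PairState]
) -> set[str]:
    """Mapping identifiers whose current value differs from the last-sync snapshot.

    With no snapshot (cold start) every mapping is flagged.  A mapping also
    counts as changed when the field appeared or disappeared since the
    snapshot was taken.
    """
    if pair_state is None:
        return {m.identifier for m in model.mappings}
    snapshot = pair_state.snapshot(side)
    current = mapped_values(model, payload, side)
    changed = set()
    for m in model.mappings:
        mid = m.identifier
        if (mid in current) != (mid in snapshot) or current.get(mid) != snapshot.get(mid):
            changed.add(mid)
    return changed


def collect_changes(
    delegate: PlatformDelegate,
    model: SyncModel,
    side: str,
    state: SyncState,
) -> list[tuple[Entry, set[str]]]:
    """Read all entries of the model's mask on one side and flag changed mappings.

    Entries are returned in the delegate's deterministic order (by entry
    id).  Entries whose payload is not a mapping are skipped here and
    surface in the run log.
    """
    side_cfg = model.side(side)
    try:
        entries = delegate.list_entries(side_cfg.mask_name)
    except DelegateError as exc:
        raise EngineError(
            f"cannot list {side_cfg.mask_name!r} entries on side {side.upper()}: {exc}"
        ) from exc
    out = []
    for entry in entries:
        key = canonical_key(get_path(entry.payload, side_cfg.sync_key))
        pair_state = state.get_pair(model.name, key) if key else None
        out.append((entry, changed_mappings(model, entry.payload, side, pair_state)))
    return out


def pair_entries(
    entries_a: list[Entry], entries_b: list[Entry], model: SyncModel
) -> PairingResult:
    """Match entry pairs by equal (canonicalized) sync-key values.

    Entries without a usable key value and entries sharing a duplicated key
    value on one side are excluded from pairing — a wrong pairing would
    corrupt both platforms, so the engine never guesses.
    """

    def index(entries: list[Entry], sync_key: str):
        by_key: dict[str, list[Entry]] = {}
        keyless: list[Entry] = []
        for e in entries:
            key = canonical_key(get_path(e.payload, sync_key))
            if key is None:
                keyless.append(e)
            else:
                by_key.setdefault(key, []).append(e)
        unique = {k: v[0] for k, v in by_key.items() if len(v) == 1}
        duplicated = [e for v in by_key.values() if len(v) > 1 for e in v]
        dup_keys = {k for k, v in by_key.items() if len(v) > 1}
        return unique, keyless, duplicated, dup_keys

    unique_a, keyless_a, ambiguous_a, dup_keys_a = index(entries_a, model.side_a.sync_key)
    unique_b, keyless_b, ambiguous_b, dup_keys_b = index(entries_b, model.side_b.sync_key)

    # a key duplicated on either side is ambiguous for both: its clean
    # counterpart must neither pair nor seed a creation
    for key in sorted(set(unique_a) & dup_keys_b):
        ambiguous_a.append(unique_a.pop(key))
    for key in sorted(set(unique_b) & dup_keys_a):
        ambiguous_b.append(unique_b.pop(key))

    pairs = [
        (unique_a[k], unique_b[k], k) for k in sorted(set(unique_a) & set(unique_b))
    ]
    unmatched_a = [(unique_a[k], k) for k in sorted(set(unique_a) - set(unique_b))]
    unmatched_b = [(unique_b[k], k) for k in sorted(set(unique_b) - set(unique_a))]
    return PairingResult(
        pairs=pairs,
        unmatched_a=unmatched_a,
        unmatched_b=unmatched_b,
        missing_key_a=keyless_a,
        missing_key_b=keyless_b,
        ambiguous_a=ambiguous_a,
        ambiguous_b=ambiguous_b,
    )


def resolve_direction(
    entry_a: Entry, entry_b: Entry, changed_a: bool, changed_b: bool
) -> tuple[Optional[str], bool]:
    """Choose the transfer direction for a pair (last-write-wins).

    Returns ``(direction, is_tie)``: ``(None, False)`` when neither side
    changed; the changed side when only one did; with both changed, the side
    with the later ``updated_at`` sources *all* mapped fields, and an exact
    timestamp tie deterministically favors side A (logged as conflict-tie).
    """
    if not changed_a and not changed_b:
        return None, False
    if changed_a and not changed_b:
        return "a_to_b", False
    if changed_b and not changed_a:
        return "b_to_a", False
    if entry_a.updated_at > entry_b.updated_at:
        return "a_to_b", False
    if entry_b.updated_at > entry_a.updated_at:
        return "b_to_a", False
    return "a_to_b", True


def _transfer_atomic(
    mapping: Mapping,
    mapping_label: str,
    source_tree: Any,
    target_tree: Any,
    src_key: str,
    dst_key: str,
    direction: str,
    pair_key: str,
    now: datetime,
) -> tuple[Any, list[ChangeRecord]]:
    value = get_path(source_tree, src_key)
    records: list[ChangeRecord] = []
    if value is ABSENT:
        records.append(
            ChangeRecord(
                direction=direction,
                pair_key_value=pair_key,
                mapping_id=mapping_label,
                action="skip",
                reason="missing-source",
                timestamp=now,
            )
        )
        return target_tree, records
    op_text = mapping.operator_for(direction)
    if op_text:
        try:
            value = evaluate_operator(parse_operator(op_text), value)
        except OperatorDomainError as exc:
            records.append(
                ChangeRecord(
                    direction=direction,
                    pair_key_value=pair_key,
                    mapping_id=mapping_label,
                    action="skip",
                    reason=f"operator-error: {exc}",
                    timestamp=now,
                )
            )
            return target_tree, records
    existing = get_path(target_tree, dst_key)
    if existing is not ABSENT and existing == value:
        return target_tree, records
    new_tree = set_path(target_tree if target_tree is not ABSENT else {}, dst_key, value)
    records.append(
        ChangeRecord(
            direction=direction,
            pair_key_value=pair_key,
            mapping_id=mapping_label,
            old=None if existing is ABSENT else existing,
            new=value,
            action="update",
            timestamp=now,
        )
    )
    return new_tree, records


def apply_mapping_direction(
    mapping: Mapping,
    source_payload: Any,
    target_payload: Any,
    direction: str,
    pair_key: str = "",
    now: Optional[datetime] = None,
    _label: Optional[str] = None,
) -> tuple[Any, list[ChangeRecord]]:
    """Transfer one mapping from source to target payload (value semantics).

    Atomic mappings read the source key, push the value through the
    direction's transfer operator and write the target key, emitting an
    update record only when the written value differs from what the target
    already holds.  Array mappings pair elements by index, apply each
    submapping element-wise and truncate or extend the target list to the
    source list's length.  An operator domain error or an absent source
    value skips just this mapping; others proceed.
    """
    now = now or datetime.now(timezone.utc)
    label = _label or mapping.identifier
    src_key = mapping.key_a if direction == "a_to_b" else mapping.key_b
    dst_key = mapping.key_b if direction == "a_to_b" else mapping.key_a

    if mapping.data_type == "atomic":
        return _transfer_atomic(
            mapping, label, source_payload, target_payload, src_key, dst_key,
            direction, pair_key, now,
        )

    source_list = get_path(source_payload, src_key)
    if source_list is ABSENT:
        return target_payload, [
            ChangeRecord(
                direction=direction, pair_key_value=pair_key, mapping_id=label,
                action="skip", reason="missing-source", timestamp=now,
            )
        ]
    if not isinstance(source_list, list):
        return target_payload, [
            ChangeRecord(
                direction=direction, pair_key_value=pair_key, mapping_id=label,
                action="skip", reason="source-not-a-list", timestamp=now,
            )
        ]
    existing = get_path(target_payload, dst_key)
    existing_list = existing if isinstance(existing, list) else []
    records: list[ChangeRecord] = []
    new_list: list[Any] = []
    for i, element in enumerate(source_list):
        target_element = existing_list[i] if i < len(existing_list) else {}
        for sub in mapping.submappings:
            target_element, sub_records = apply_mapping_direction(
                sub, element, target_element, direction,
                pair_key=pair_key, now=now, _label=f"{label}[{i}].{sub.identifier}",
            )
            records.extend(sub_records)
        new_list.append(target_element)
    if new_list == existing_list and existing is not ABSENT:
        return target_payload, records
    new_tree = set_path(target_payload, dst_key, new_list)
    if not any(r.action == "update" for r in records):
        # pure truncation/extension or first materialization of the list
        records.append(
            ChangeRecord(
                direction=direction, pair_key_value=pair_key, mapping_id=label,
                old=None if existing is ABSENT else existing, new=new_list,
                action="update", timestamp=now,
            )
        )
    return new_tree, records


# --------------------------------------------------------------------------
# planning


def _build_target_payload(
    model: SyncModel, source_entry: Entry, target_payload: dict, direction: str,
    pair_key: str, now: datetime,
) -> tuple[dict, list[ChangeRecord]]:
    records: list[ChangeRecord] = []
    payload = target_payload
    for mapping in model.mappings:
        payload, recs = apply_mapping_direction(
            mapping, source_entry.payload, payload, direction, pair_key=pair_key, now=now
        )
        records.extend(recs)
    return payload, records


def plan_sync(
    model: SyncModel,
    delegate_a: PlatformDelegate,
    delegate_b: PlatformDelegate,
    state: SyncState,
    now: Optional[datetime] = None,
    run_id: str = "dry-run",
) -> SyncPlan:
    """Compute the full change plan for one sync model without writing anything."""
    now = now or datetime.now(timezone.utc)
    findings = validate_sync_model(model, delegate_a.list_types(), delegate_b.list_types())
    errors = [f for f in findings if f.level == "error"]
    if errors:
        raise EngineError(
            f"sync model {model.name!r} failed validation: "
            + "; ".join(f.message for f in errors)
        )

    collected_a = collect_changes(delegate_a, model, "a", state)
    collected_b = collect_changes(delegate_b, model, "b", state)
    changed_by_id_a = {e.entry_id: ch for e, ch in collected_a}
    changed_by_id_b = {e.entry_id: ch for e, ch in collected_b}

    pairing = pair_entries([e for e, _ in collected_a], [e for e, _ in collected_b], model)
    plan = SyncPlan(run_id=run_id, model_name=model.name, planned_at=now)

    for entry in pairing.missing_key_a + pairing.missing_key_b:
        plan.skips.append(
            SkipRecord("missing-key", f"{entry.platform_id}/{entry.mask_name}/{entry.entry_id}")
        )
    for entry in pairing.ambiguous_a + pairing.ambiguous_b:
        plan.skips.append(
            SkipRecord(
                "ambiguous-key",
                f"{entry.platform_id}/{entry.mask_name}/{entry.entry_id}",
                detail="duplicate sync-key value on one side; excluded from pairing",
            )
        )

    # unmatched entries: plan a creation on the opposite platform when allowed
    for source_side, unmatched, target_delegate in (
        ("a", pairing.unmatched_a, delegate_b),
        ("b", pairing.unmatched_b, delegate_a),
    ):
        direction = "a_to_b" if source_side == "a" else "b_to_a"
        target_side = "b" if source_side == "a" else "a"
        target_mask = model.side(target_side).mask_name
        for entry, key in unmatched:
            ref = f"{entry.platform_id}/{entry.mask_name}/{entry.entry_id}"
            if not target_delegate.config.allow_create:
                plan.skips.append(SkipRecord("create-disallowed", ref, pair_key=key))
                continue
            payload, _ = _build_target_payload(model, entry, {}, direction, key, now)
            # the created entry must carry the sync key so the pair forms
            key_path = model.side(target_side).sync_key
            source_key_value = get_path(entry.payload, model.side(source_side).sync_key)
            payload = set_path(payload, key_path, source_key_value)
            descriptor = next(
                (d for d in target_delegate.list_types() if d.mask_name == target_mask), None
            )
            problems = descriptor.validate_payload(payload) if descriptor else []
            if problems:
                plan.skips.append(
                    SkipRecord(
                        "create-failed", ref, pair_key=key,
                        detail="required mask fields not covered by mappings: "
                        + "; ".join(problems),
                    )
                )
                continue
            plan.creations.append(
                PlannedCreation(
                    direction=direction,
                    pair_key=key,
                    source_entry=entry,
                    target_mask=target_mask,
                    payload=payload,
                    record=ChangeRecord(
                        direction=direction,
                        pair_key_value=key,
                        mapping_id="<entry>",
                        new=target_mask,
                        action="create_entry",
                        timestamp=now,
                    ),
                )
            )

    # paired entries: resolve direction, build the target payload
    for entry_a, entry_b, key in pairing.pairs:
        changed_a = changed_by_id_a.get(entry_a.entry_id, set())
        changed_b = changed_by_id_b.get(entry_b.entry_id, set())
        direction, tie = resolve_direction(entry_a, entry_b, bool(changed_a), bool(changed_b))
        ref = f"pair:{key}"
        if direction is None:
            plan.skips.append(SkipRecord("no-change", ref, pair_key=key))
            continue
        if changed_a and changed_b:
            loser = "b_to_a" if direction == "a_to_b" else "a_to_b"
            plan.skips.append(
                SkipRecord(
                    "conflict-loser", ref, pair_key=key,
                    detail=f"both sides changed; {loser} changes overwritten"
                    + (" (timestamp tie, side A wins)" if tie else ""),
                )
            )
        source, target = (entry_a, entry_b) if direction == "a_to_b" else (entry_b, entry_a)
        new_payload, records = _build_target_payload(
            model, source, target.payload, direction, key, now
        )
        if not any(r.action == "update" for r in records):
            plan.skips.append(SkipRecord("no-change", ref, pair_key=key))
            skips_only = [r for r in records if r.action == "skip"]
            if skips_only:
                # keep operator/missing-source skips visible in the log
                plan.pair_syncs.append(
                    PlannedPairSync(key, direction, source, target, target.payload,
                                    skips_only, tie)
                )
            continue
        plan.pair_syncs.append(
            PlannedPairSync(key, direction, source, target, new_payload, records, tie)
        )

    # pairs known from previous runs but absent now: orphaned, never deleted
    seen_keys = {key for _, _, key in pairing.pairs}
    seen_keys |= {key for _, key in pairing.unmatched_a}
    seen_keys |= {key for _, key in pairing.unmatched_b}
    for key in sorted(state.known_keys(model.name) - seen_keys):
        plan.skips.append(
            SkipRecord(
                "orphaned-state", f"pair:{key}", pair_key=key,
                detail="pair present in sync state but no longer listed by the platforms",
            )
        )
    return plan


# --------------------------------------------------------------------------
# application


def apply_plan(
    plan: SyncPlan,
    model: SyncModel,
    delegate_a: PlatformDelegate,
    delegate_b: PlatformDelegate,
    state: SyncState,
    log: Optional[ProcessLog] = None,
    now: Optional[datetime] = None,
) -> tuple[SyncState, list[ChangeRecord]]:
    """Execute a plan: create missing entries, transfer values, snapshot state.

    Returns the new state (the input state is not modified) and the applied
    change records.  Failures are per-entry: a write error on one pair is
    logged and the remaining pairs still proceed; snapshots are updated only
    for successfully written pairs.
    """
    now = now or plan.planned_at
    log = log or ProcessLog()
    new_state = state.model_copy(deep=True)
    applied: list[ChangeRecord] = []
    errors = 0
    started = now

    def log_change(record: ChangeRecord) -> None:
        entry = {"type": "change", "run_id": plan.run_id}
        entry.update(json.loads(record.model_dump_json()))
        log.append(entry)

    delegate_for = {"a": delegate_a, "b": delegate_b}

    for creation in plan.creations:
        target_side = "b" if creation.direction == "a_to_b" else "a"
        source_side = "a" if creation.direction == "a_to_b" else "b"
        target_delegate = delegate_for[target_side]
        try:
            created = target_delegate.create_entry(creation.target_mask, creation.payload)
        except (DelegateError, SchemaViolation) as exc:
            errors += 1
            log.append(
                {
                    "type": "error", "run_id": plan.run_id, "pair_key": creation.pair_key,
                    "message": f"creation failed: {exc}",
                }
            )
            continue
        applied.append(creation.record)
        log_change(creation.record)
        snapshots = {
            source_side: mapped_values(model, creation.source_entry.payload, source_side),
            target_side: mapped_values(model, created.payload, target_side),
        }
        new_state.set_pair(
            model.name,
            creation.pair_key,
            PairState(
                last_sync_time=now, snapshot_a=snapshots["a"], snapshot_b=snapshots["b"]
            ),
        )

    for pair_sync in plan.pair_syncs:
        updates = [r for r in pair_sync.records if r.action == "update"]
        for record in pair_sync.records:
            if record.action == "skip":
                log_change(record)
        if not updates:
            continue
        target_side = "b" if pair_sync.direction == "a_to_b" else "a"
        source_side = "a" if pair_sync.direction == "a_to_b" else "b"
        target_delegate = delegate_for[target_side]
        try:
            written = target_delegate.write_entry(
                pair_sync.target_entry.mask_name,
                pair_sync.target_entry.entry_id,
                pair_sync.new_target_payload,
            )
        except (DelegateError, SchemaViolation) as exc:
            errors += 1
            log.append(
                {
                    "type": "error", "run_id": plan.run_id, "pair_key": pair_sync.pair_key,
                    "message": f"write failed: {exc}",
                }
            )
            continue
        for record in updates:
            applied.append(record)
            log_change(record)
        snapshots = {
            source_side: mapped_values(model, pair_sync.source_entry.payload, source_side),
            target_side: mapped_values(model, written.payload, target_side),
        }
        new_state.set_pair(
            model.name,
            pair_sync.pair_key,
            PairState(
                last_sync_time=now, snapshot_a=snapshots["a"], snapshot_b=snapshots["b"]
            ),
        )

    creates = sum(1 for r in applied if r.action == "create_entry")
    updates_n = sum(1 for r in applied if r.action == "update")
    summary = RunSummary(
        run_id=plan.run_id,
        model_name=plan.model_name,
        started=started,
        finished=now,
        updates=updates_n,
        creates=creates,
        skips=len(plan.skips),
        errors=errors,
        status="ok" if errors == 0 else "failed",
    )
    for skip in plan.skips:
        log.append({"type": "skip", "run_id": plan.run_id, **skip.to_dict()})
    log.append(summary.to_dict())
    return new_state, applied


def run_sync(
    model: SyncModel,
    delegate_a: PlatformDelegate,
    delegate_b: PlatformDelegate,
    state: SyncState,
    log: Optional[ProcessLog] = None,
    now: Optional[datetime] = None,
    run_id: Optional[str] = None,
) -> tuple[SyncState, SyncPlan, list[ChangeRecord]]:
    """Plan and apply one synchronization run for one sync model."""
    log = log or ProcessLog()
    run_id = run_id or log.next_run_id()
    plan = plan_sync(model, delegate_a, delegate_b, state, now=now, run_id=run_id)
    new_state, applied = apply_plan(plan, model, delegate_a, delegate_b, state, log, now=now)
    return new_state, plan, applied


# --------------------------------------------------------------------------
# dry-run test mode


@dataclass
class SimulationSummary:
    """Per-mapping old/new values a real run would apply, for one object and direction."""

    direction: str
    pair_key: Optional[str]
    changes: list[dict]  # {mapping_id, old, new, action}

    def is_empty(self) -> bool:
        return not self.changes


def simulate(
    model: SyncModel,
    delegate_a: PlatformDelegate,
    delegate_b: PlatformDelegate,
    state: SyncState,
    direction: str,
    object_key: Optional[str] = None,
) -> SimulationSummary:
    """Simulated synchronization of one direction; no delegate write occurs.

    The two directions are independent tests.  The summary reports the
    changes of one representative object only (the requested ``object_key``
    or the first object with planned changes) and equals the subset of a
    real plan restricted to that direction and object.
    """
    if direction not in ("a_to_b", "b_to_a"):
        raise ValueError(f"direction must be 'a_to_b' or 'b_to_a', got {direction!r}")
    plan = plan_sync(model, delegate_a, delegate_b, state, run_id="simulate")
    candidates: dict[str, list[dict]] = {}
    for creation in plan.creations:
        if creation.direction == direction:
            candidates.setdefault(creation.pair_key, []).append(
                {
                    "mapping_id": "<entry>",
                    "old": None,
                    "new": creation.target_mask,
                    "action": "create_entry",
                }
            )
    for pair_sync in plan.pair_syncs:
        if pair_sync.direction == direction:
            rows = [
                {"mapping_id": r.mapping_id, "old": r.old, "new": r.new, "action": r.action}
                for r in pair_sync.records
                if r.action == "update"
            ]
            if rows:
                candidates.setdefault(pair_sync.pair_key, []).extend(rows)
    if object_key is not None:
        return SimulationSummary(direction, object_key, candidates.get(object_key, []))
    if not candidates:
        return SimulationSummary(direction, None, [])
    first = sorted(candidates)[0]
    return SimulationSummary(direction, first, candidates[first])


# --------------------------------------------------------------------------
# autosync


def run_autosync(
    models: list[SyncModel],
    delegate_a: PlatformDelegate,
    delegate_b: PlatformDelegate,
    state: SyncState,
    interval: float,
    max_runs: int,
    log: Optional[ProcessLog] = None,
    sleep: Callable[[float], None] = time.sleep,
    on_tick: Optional[Callable[[int], None]] = None,
) -> tuple[SyncState, ProcessLog]:
    """Periodically scheduled synchronization: plan+apply every *interval* seconds.

    A failing run is logged and does not stop the schedule.  If no prior
    (manual) run is recorded in the log, a warning line is appended first —
    the process history should be watched once before automating it.
    """
    log = log or ProcessLog()
    if not log.has_runs():
        log.append(
            {
                "type": "warning",
                "message": "autosync started without a prior manual run; "
                "start one sync manually to monitor the process first",
            }
        )
    for tick in range(max_runs):
        if on_tick:
            on_tick(tick)
        for model in models:
            try:
                state, _, _ = run_sync(model, delegate_a, delegate_b, state, log=log)
            except (EngineError, DelegateError) as exc:
                log.append(
                    {
                        "type": "run",
                        "run_id": log.next_run_id(),
                        "model": model.name,
                        "started": None,
                        "finished": None,
                        "updates": 0,
                        "creates": 0,
                        "skips": 0,
                        "errors": 1,
                        "status": "failed",
                        "message": str(exc),
                    }
                )
        if tick < max_runs - 1 and interval > 0:
            sleep(interval)
    return state, log
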