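"""Sync engine: change detection, pairing, conflict resolution, plan/apply."""

import itertools
import random
from datetime import datetime, timezone

import pytest

from elnbridge.datamodel import Entry, Mapping, SyncState
from elnbridge.engine import (
    EngineError,
    ProcessLog,
    apply_mapping_direction,
    canonical_key,
    collect_changes,
    mapped_values,
    pair_entries,
    plan_sync,
    resolve_direction,
    run_autosync,
    run_sync,
    simulate,
)
from elnbridge.fixtures import Scenario, build_membrane_case, generate_random_scenario
from elnbridge.operators import evaluate_operator, parse_operator
from elnbridge.paths import ABSENT, get_path

from conftest import sync_all

T0 = datetime(2024, 3, 1, 10, 0, tzinfo=timezone.utc)


def entry(platform: str, key_path: str, key: str, updated=T0, **fields) -> Entry:
    payload: dict = {}
    from elnbridge.paths import set_path

    payload = set_path(payload, key_path, key)
    for path, value in fields.items():
        payload = set_path(payload, path.replace("__", "."), value)
    return Entry(
        platform_id=platform,
        mask_name="reaction",
        mask_version="1",
        entry_id=f"{platform}-{key}",
        updated_at=updated,
        payload=payload,
    )


def clone(scenario: Scenario) -> Scenario:
    return Scenario.from_dict(scenario.to_dict())


# -- change detection -------------------------------------------------------

def test_unchanged_entry_yields_empty_changed_set(membrane):
    state, _ = sync_all(membrane)
    delegate_a, _ = membrane.delegates()
    model = membrane.config.sync_models[0]
    collected = collect_changes(delegate_a, model, "a", state)
    assert all(changed == set() for _, changed in collected)


def test_cold_start_flags_all_mapped_fields(membrane):
    delegate_a, _ = membrane.delegates()
    model = membrane.config.sync_models[0]
    collected = collect_changes(delegate_a, model, "a", SyncState())
    assert collected  # at least the fixture reaction
    for _, changed in collected:
        assert changed == {m.identifier for m in model.mappings}


@pytest.mark.parametrize("seed", range(10))
def test_injected_edits_flagged_exactly_matching_brute_force_diff(seed):
    scenario = generate_random_scenario(seed, n_entries=6, overlap=1.0, edit_rate=0.5)
    state, _ = sync_all(scenario)
    delegate_a, delegate_b = scenario.delegates()
    model = scenario.config.sync_models[0]
    pre = {}
    for delegate, mask in ((delegate_a, "reaction"), (delegate_b, "post-modification")):
        for e in delegate.list_entries(mask):
            pre[e.entry_id] = e.payload
    edits = scenario.apply_round(0)

    for side, delegate in (("a", delegate_a), ("b", delegate_b)):
        collected = collect_changes(delegate, model, side, state)
        sync_key = model.side(side).sync_key
        for e, changed in collected:
            key = canonical_key(get_path(e.payload, sync_key))
            pair_state = state.get_pair(model.name, key)
            # brute force: compare each mapped value against the snapshot
            expected = set()
            snapshot = pair_state.snapshot(side) if pair_state else None
            for m in model.mappings:
                current = get_path(e.payload, model.key_for(m, side))
                if snapshot is None:
                    expected.add(m.identifier)
                    continue
                in_snap = m.identifier in snapshot
                if (current is not ABSENT) != in_snap or (
                    in_snap and snapshot[m.identifier] != current
                ):
                    expected.add(m.identifier)
            assert changed == expected
    # and the flagged entries are exactly those whose stored value really moved
    effective = {
        ed.entry_id for ed in edits if get_path(pre[ed.entry_id], ed.path) != ed.value
    }
    flagged = set()
    for side, delegate in (("a", delegate_a), ("b", delegate_b)):
        for e, changed in collect_changes(delegate, model, side, state):
            if changed:
                flagged.add(e.entry_id)
    assert flagged == effective


# -- pairing ----------------------------------------------------------------

def test_documented_sync_key_pairing(demo_model):
    a = entry("chem", "properties.name", "PM-07")
    b = entry("herbie", "values.reaction_name", "PM-07")
    result = pair_entries([a], [b], demo_model)
    assert [(p[0].entry_id, p[1].entry_id, p[2]) for p in result.pairs] == [
        ("chem-PM-07", "herbie-PM-07", "PM-07")
    ]
    assert pair_entries([], [], demo_model).pairs == []


def test_missing_and_duplicate_keys_excluded(demo_model):
    a1 = entry("chem", "properties.name", "dup")
    a2 = Entry(**{**a1.model_dump(), "entry_id": "chem-dup2"})
    a3 = entry("chem", "properties.other", "x")  # no sync-key value
    b = entry("herbie", "values.reaction_name", "dup")
    result = pair_entries([a1, a2, a3], [b], demo_model)
    assert result.pairs == []
    assert {e.entry_id for e in result.ambiguous_a} == {"chem-dup", "chem-dup2"}
    assert [e.entry_id for e in result.missing_key_a] == ["chem-x"]
    # the clean counterpart of an ambiguous key must not seed a creation
    assert result.unmatched_b == []
    assert [e.entry_id for e in result.ambiguous_b] == ["herbie-dup"]


@pytest.mark.parametrize("seed", range(20))
def test_pairing_equals_quadratic_brute_force(seed, demo_model):
    rng = random.Random(seed)
    keys = [f"K{i}" for i in range(12)]
    entries_a = [
        entry("chem", "properties.name", rng.choice(keys) if rng.random() < 0.7 else f"onlyA{i}")
        for i in range(20)
    ]
    entries_b = [
        entry("herbie", "values.reaction_name", rng.choice(keys) if rng.random() < 0.7 else f"onlyB{i}")
        for i in range(20)
    ]
    # entry ids must be unique per side for this test
    for i, e in enumerate(entries_a):
        object.__setattr__(e, "entry_id", f"a{i}")
    for i, e in enumerate(entries_b):
        object.__setattr__(e, "entry_id", f"b{i}")

    result = pair_entries(entries_a, entries_b, demo_model)

    # quadratic oracle over all pairs, on unique keys only
    def keyof(e, path):
        v = get_path(e.payload, path)
        return None if v is ABSENT else str(v).strip() or None

    keys_a = [keyof(e, "properties.name") for e in entries_a]
    keys_b = [keyof(e, "values.reaction_name") for e in entries_b]
    unique_a = {k for k in keys_a if k and keys_a.count(k) == 1}
    unique_b = {k for k in keys_b if k and keys_b.count(k) == 1}
    expected_pairs = set()
    for ea, ka in zip(entries_a, keys_a):
        for eb, kb in zip(entries_b, keys_b):
            if ka and ka == kb and ka in unique_a and kb in unique_b:
                expected_pairs.add((ea.entry_id, eb.entry_id, ka))
    assert {(a.entry_id, b.entry_id, k) for a, b, k in result.pairs} == expected_pairs
    # every entry lands in exactly one bucket
    for e, k in zip(entries_a, keys_a):
        buckets = [
            any(p[0].entry_id == e.entry_id for p in result.pairs),
            any(x.entry_id == e.entry_id for x, _ in result.unmatched_a),
            e in result.missing_key_a,
            e in result.ambiguous_a,
        ]
        assert sum(buckets) == 1


# -- conflict resolution ----------------------------------------------------

def truth_table_oracle(changed_a, changed_b, t_a, t_b):
    if not changed_a and not changed_b:
        return (None, False)
    if changed_a and not changed_b:
        return ("a_to_b", False)
    if changed_b and not changed_a:
        return ("b_to_a", False)
    if t_a > t_b:
        return ("a_to_b", False)
    if t_b > t_a:
        return ("b_to_a", False)
    return ("a_to_b", True)  # deterministic tie-break: side A wins


def test_later_update_wins_all_fields():
    a = entry("chem", "properties.name", "k", updated=datetime(2024, 3, 1, 10, 0, tzinfo=timezone.utc))
    b = entry("herbie", "values.reaction_name", "k", updated=datetime(2024, 3, 1, 10, 5, tzinfo=timezone.utc))
    assert resolve_direction(a, b, True, True) == ("b_to_a", False)
    assert resolve_direction(a, b, True, False) == ("a_to_b", False)
    assert resolve_direction(a, b, False, False) == (None, False)


def test_conflict_truth_table_500_random_cases():
    rng = random.Random(42)
    times = [datetime(2024, 3, 1, 10, m, tzinfo=timezone.utc) for m in range(3)]
    cases = list(itertools.product([False, True], [False, True], times, times))
    cases += [
        (rng.random() < 0.5, rng.random() < 0.5, rng.choice(times), rng.choice(times))
        for _ in range(500 - len(cases))
    ]
    for changed_a, changed_b, t_a, t_b in cases:
        a = entry("chem", "properties.name", "k", updated=t_a)
        b = entry("herbie", "values.reaction_name", "k", updated=t_b)
        assert resolve_direction(a, b, changed_a, changed_b) == truth_table_oracle(
            changed_a, changed_b, t_a, t_b
        )


# -- mapping application ----------------------------------------------------

def test_atomic_identity_transfer(demo_model):
    mapping = demo_model.mappings[0]  # Reaction Name
    target, records = apply_mapping_direction(
        mapping, {"properties": {"name": "PM-07"}}, {}, "a_to_b", pair_key="PM-07"
    )
    assert target == {"values": {"reaction_name": "PM-07"}}
    assert [r.action for r in records] == ["update"]


def test_absent_source_skips_and_leaves_target_untouched(demo_model):
    mapping = demo_model.mappings[1]  # Weight
    target_before = {"values": {"weight": 7}}
    target, records = apply_mapping_direction(mapping, {}, target_before, "a_to_b", pair_key="k")
    assert target == target_before
    assert [r.action for r in records] == ["skip"]
    assert records[0].reason == "missing-source"


def test_operator_domain_error_skips_only_that_mapping(demo_model):
    status = demo_model.mappings[3]  # Status (remap)
    target, records = apply_mapping_direction(
        status, {"properties": {"status": "not-in-vocabulary"}}, {}, "a_to_b", pair_key="k"
    )
    assert target == {}
    assert records[0].action == "skip"
    assert "operator-error" in records[0].reason


def test_array_mapping_against_hand_unrolled_oracle():
    mapping = Mapping(
        identifier="arr",
        data_type="array",
        key_a="properties.components",
        key_b="values.components",
        submappings=[
            Mapping(identifier="n", key_a="name", key_b="component"),
            Mapping(identifier="m", key_a="amount_mg", key_b="amount"),
        ],
    )
    source = {
        "properties": {
            "components": [
                {"name": "PAN", "amount_mg": 250},
                {"name": "EDA", "amount_mg": 480},
                {"name": "H2O", "amount_mg": 10},
            ]
        }
    }
    target, records = apply_mapping_direction(mapping, source, {}, "a_to_b", pair_key="k")
    # hand-unrolled: 3 elements x 2 submappings = 6 element-level writes
    assert target == {
        "values": {
            "components": [
                {"component": "PAN", "amount": 250},
                {"component": "EDA", "amount": 480},
                {"component": "H2O", "amount": 10},
            ]
        }
    }
    updates = [r for r in records if r.action == "update"]
    assert len(updates) == 6
    assert {r.mapping_id for r in updates} == {
        "arr[0].n", "arr[0].m", "arr[1].n", "arr[1].m", "arr[2].n", "arr[2].m"
    }


def test_array_truncates_to_source_length():
    mapping = Mapping(
        identifier="arr",
        data_type="array",
        key_a="a",
        key_b="b",
        submappings=[Mapping(identifier="v", key_a="x", key_b="x")],
    )
    target, records = apply_mapping_direction(
        mapping, {"a": [{"x": 1}]}, {"b": [{"x": 1}, {"x": 2}, {"x": 3}]}, "a_to_b", pair_key="k"
    )
    assert target == {"b": [{"x": 1}]}
    assert any(r.action == "update" for r in records)


# -- plan / apply -----------------------------------------------------------

def test_membrane_creation_planned_only_when_allowed(membrane):
    model = membrane.config.model("Membrane products")
    delegate_a, delegate_b = membrane.delegates()
    plan = plan_sync(model, delegate_a, delegate_b, SyncState())
    assert len(plan.creations) == 1
    creation = plan.creations[0]
    assert creation.direction == "b_to_a"
    assert creation.target_mask == "sample"
    assert creation.pair_key == "PAN$20/013-PAN-EDA-01;"

    denied = clone(membrane)
    denied.config.platforms[0].allow_create = False
    delegate_a, delegate_b = denied.delegates()
    plan = plan_sync(model, delegate_a, delegate_b, SyncState())
    assert plan.creations == []
    assert [s.reason for s in plan.skips if s.pair_key == creation.pair_key] == [
        "create-disallowed"
    ]


def test_apply_then_replan_is_empty(membrane):
    state, _ = sync_all(membrane)
    delegate_a, delegate_b = membrane.delegates()
    for model in membrane.config.sync_models:
        plan = plan_sync(model, delegate_a, delegate_b, state)
        assert plan.is_empty()
        assert plan.creations == []


def test_plan_is_side_effect_free(membrane):
    delegate_a, delegate_b = membrane.delegates()
    before = (membrane.platform_a.content_hash(), membrane.platform_b.content_hash())
    for model in membrane.config.sync_models:
        plan_sync(model, delegate_a, delegate_b, SyncState())
    assert (membrane.platform_a.content_hash(), membrane.platform_b.content_hash()) == before


def test_version_mismatch_aborts_run(membrane):
    model = membrane.config.sync_models[0]
    bad = model.model_copy(
        update={"side_a": model.side_a.model_copy(update={"mask_version": "2"})}
    )
    delegate_a, delegate_b = membrane.delegates()
    with pytest.raises(EngineError, match="version"):
        plan_sync(bad, delegate_a, delegate_b, SyncState())


def test_snapshots_equal_platform_values_after_run(membrane):
    state, _ = sync_all(membrane)
    delegate_a, delegate_b = membrane.delegates()
    for model in membrane.config.sync_models:
        for key, pair_state in state.pairs.get(model.name, {}).items():
            ea = next(
                e
                for e in delegate_a.list_entries(model.side_a.mask_name)
                if canonical_key(get_path(e.payload, model.side_a.sync_key)) == key
            )
            eb = next(
                e
                for e in delegate_b.list_entries(model.side_b.mask_name)
                if canonical_key(get_path(e.payload, model.side_b.sync_key)) == key
            )
            assert pair_state.snapshot_a == mapped_values(model, ea.payload, "a")
            assert pair_state.snapshot_b == mapped_values(model, eb.payload, "b")


def test_orphaned_pairs_logged_never_deleted(membrane):
    state, _ = sync_all(membrane)
    # entries fall out of both listings via a narrower timeframe policy
    model = membrane.config.model("Membrane products")
    membrane.clock.tick(3600)
    from elnbridge.delegates import InMemoryDelegate

    from elnbridge.datamodel import ExistingPolicy

    policy = ExistingPolicy(mode="updated_after", updated_after=membrane.clock.now())
    cfg_a = membrane.config.platforms[0].model_copy(update={"existing_policy": policy})
    cfg_b = membrane.config.platforms[1].model_copy(update={"existing_policy": policy})
    delegate_a = InMemoryDelegate(cfg_a, membrane.platform_a)
    delegate_b = InMemoryDelegate(cfg_b, membrane.platform_b)
    plan = plan_sync(model, delegate_a, delegate_b, state)
    assert "orphaned-state" in {s.reason for s in plan.skips}
    assert membrane.platform_b.find_by_key("product", "values.product_name", "PAN$20/013-PAN-EDA-01;")


# -- dry run ----------------------------------------------------------------

def test_simulate_two_directions_no_mutation(membrane):
    delegate_a, delegate_b = membrane.delegates()
    model = membrane.config.sync_models[0]
    before = (membrane.platform_a.content_hash(), membrane.platform_b.content_hash())
    ab = simulate(model, delegate_a, delegate_b, SyncState(), "a_to_b")
    ba = simulate(model, delegate_a, delegate_b, SyncState(), "b_to_a")
    assert (membrane.platform_a.content_hash(), membrane.platform_b.content_hash()) == before
    assert not ab.is_empty()  # cold start, Chemotion updated last: A -> B
    assert ba.is_empty()
    with pytest.raises(ValueError):
        simulate(model, delegate_a, delegate_b, SyncState(), "sideways")


def test_simulate_on_synchronized_state_is_empty(membrane):
    state, _ = sync_all(membrane)
    delegate_a, delegate_b = membrane.delegates()
    model = membrane.config.sync_models[0]
    assert simulate(model, delegate_a, delegate_b, state, "a_to_b").is_empty()
    assert simulate(model, delegate_a, delegate_b, state, "b_to_a").is_empty()


@pytest.mark.parametrize("seed", range(10))
def test_simulation_equals_real_run_change_set(seed):
    scenario = generate_random_scenario(seed, n_entries=5, overlap=1.0, edit_rate=0.6)
    state, _ = sync_all(scenario)
    scenario.apply_round(0)
    model = scenario.config.sync_models[0]

    sim_copy = clone(scenario)
    delegate_a, delegate_b = sim_copy.delegates()
    summaries = {
        d: simulate(model, delegate_a, delegate_b, state, d) for d in ("a_to_b", "b_to_a")
    }

    real = clone(scenario)
    delegate_a, delegate_b = real.delegates()
    _, _, applied = run_sync(model, delegate_a, delegate_b, state)
    for direction, summary in summaries.items():
        if summary.pair_key is None:
            continue
        real_subset = sorted(
            (r.mapping_id, r.old, r.new)
            for r in applied
            if r.direction == direction
            and r.pair_key_value == summary.pair_key
            and r.action == "update"
        )
        sim_subset = sorted((c["mapping_id"], c["old"], c["new"]) for c in summary.changes)
        assert sim_subset == real_subset


# -- autosync ---------------------------------------------------------------

def test_autosync_loop_applies_edits_on_the_right_tick(membrane):
    state, _ = sync_all(membrane)  # manual run first
    delegate_a, delegate_b = membrane.delegates()
    log = ProcessLog()
    naps = []

    def on_tick(tick):
        if tick == 1:
            membrane.apply_round(0)

    state, log = run_autosync(
        [membrane.config.sync_models[0]],
        delegate_a,
        delegate_b,
        state,
        interval=0.0,
        max_runs=3,
        log=log,
        sleep=naps.append,
        on_tick=on_tick,
    )
    runs = log.runs()
    assert len(runs) == 3
    assert [r["updates"] for r in runs] == [0, 3, 0]
    assert all(r["status"] == "ok" for r in runs)


def test_autosync_survives_a_failing_tick(membrane):
    state, _ = sync_all(membrane)
    delegate_a, delegate_b = membrane.delegates()
    model = membrane.config.sync_models[0]

    class FlakyDelegate:
        def __init__(self, inner):
            self.inner = inner
            self.calls = 0

        def __getattr__(self, item):
            return getattr(self.inner, item)

        def list_entries(self, *args, **kwargs):
            self.calls += 1
            if self.calls == 2:  # outage during the second tick
                from elnbridge.delegates import DelegateError

                raise DelegateError("simulated outage")
            return self.inner.list_entries(*args, **kwargs)

    flaky = FlakyDelegate(delegate_a)
    state, log = run_autosync(
        [model], flaky, delegate_b, state, interval=0.0, max_runs=3, log=ProcessLog()
    )
    statuses = [r["status"] for r in log.runs()]
    assert statuses.count("failed") == 1
    assert statuses[-1] == "ok"


def test_autosync_warns_without_prior_manual_run(membrane):
    delegate_a, delegate_b = membrane.delegates()
    _, log = run_autosync(
        [membrane.config.sync_models[0]],
        delegate_a,
        delegate_b,
        SyncState(),
        interval=0.0,
        max_runs=1,
        log=ProcessLog(),
    )
    assert any(l.get("type") == "warning" for l in log.lines)
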