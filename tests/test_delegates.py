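"""Mock platform behavior and the delegate contract (in-memory and REST)."""

import threading
from datetime import datetime, timedelta, timezone
from wsgiref.simple_server import WSGIServer, make_server

import pytest

from elnbridge.datamodel import PlatformConfig
from elnbridge.delegates import (
    AuthError,
    InMemoryDelegate,
    ManualClock,
    MockPlatform,
    RestDelegate,
    SchemaViolation,
    UnknownEntryError,
    UnknownMaskError,
    UnknownScopeError,
    make_wsgi_app,
)
from elnbridge.fixtures import (
    MEMBRANE_NAME,
    build_chemotion_platform,
    build_herbie_platform,
    generate_random_scenario,
)

EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


def chem_config(**overrides) -> PlatformConfig:
    base = dict(
        platform_id="chem",
        display_name="Chemotion",
        endpoint="mock:empty-chemotion",
        credential="chem-token",
        scope="membranes",
        allow_create=True,
    )
    base.update(overrides)
    return PlatformConfig(**base)


# -- mask listings ----------------------------------------------------------

def test_mock_platforms_report_their_masks():
    assert [m.mask_name for m in build_chemotion_platform().list_types()] == ["reaction", "sample"]
    assert [m.mask_name for m in build_herbie_platform().list_types()] == [
        "post-modification",
        "product",
    ]
    empty = MockPlatform("empty", masks=[])
    assert empty.list_types() == []


# -- listing scope and timeframe --------------------------------------------

def test_scope_and_since_filtering_matches_brute_force():
    platform = build_chemotion_platform(ManualClock())
    for i in range(5):
        platform.clock.tick(60)
        platform.create_entry(
            "reaction", {"properties": {"name": f"in-{i}"}}, collection="membranes"
        )
    for i in range(3):
        platform.clock.tick(60)
        platform.create_entry(
            "reaction", {"properties": {"name": f"out-{i}"}}, collection="archive"
        )
    scoped = platform.list_entries("reaction", scope="membranes")
    assert len(scoped) == 5

    everything = platform.list_entries("reaction", since=EPOCH)
    assert len(everything) == 8
    cutoff = everything[3].updated_at
    since = platform.list_entries("reaction", since=cutoff)
    brute = [e for e in everything if e.updated_at >= cutoff]
    assert [e.entry_id for e in since] == [e.entry_id for e in brute]

    late = platform.clock.now() + timedelta(days=1)
    assert platform.list_entries("reaction", since=late) == []

    with pytest.raises(UnknownMaskError):
        platform.list_entries("nope")
    with pytest.raises(UnknownScopeError):
        platform.list_entries("reaction", scope="nope")


def test_delegate_applies_configured_policy():
    platform = build_chemotion_platform(ManualClock())
    early = platform.create_entry("reaction", {"properties": {"name": "early"}}, collection="membranes")
    platform.clock.tick(3600)
    cutoff = platform.clock.now()
    platform.clock.tick(3600)
    late = platform.create_entry("reaction", {"properties": {"name": "late"}}, collection="membranes")
    delegate = InMemoryDelegate(
        chem_config(existing_policy={"updated_after": cutoff.isoformat()}), platform
    )
    listed = delegate.list_entries("reaction")
    assert [e.entry_id for e in listed] == [late.entry_id]
    # writing bumps updated_at, pulling an old entry back into the timeframe
    platform.set_field("reaction", early.entry_id, "properties.name", "early-edited")
    assert len(delegate.list_entries("reaction")) == 2


# -- read / write / create --------------------------------------------------

def test_create_membrane_sample_retrievable_by_key():
    platform = build_chemotion_platform()
    platform.create_entry(
        "sample", {"properties": {"name": MEMBRANE_NAME}}, collection="membranes"
    )
    found = platform.find_by_key("sample", "properties.name", MEMBRANE_NAME)
    assert found is not None
    assert found.payload["properties"]["name"] == MEMBRANE_NAME


def test_write_then_read_and_timestamp_monotonicity():
    platform = build_chemotion_platform(ManualClock())
    entry = platform.create_entry("reaction", {"properties": {"name": "r1"}}, collection="membranes")
    t0 = entry.updated_at
    platform.clock.tick(60)
    platform.write_entry("reaction", entry.entry_id, {"properties": {"name": "r1", "weight_mg": 9}})
    back = platform.read_entry("reaction", entry.entry_id)
    assert back.payload["properties"]["weight_mg"] == 9
    assert back.updated_at > t0
    with pytest.raises(UnknownEntryError):
        platform.read_entry("reaction", "reaction-9999")


@pytest.mark.parametrize(
    "path,value",
    [
        ("properties.weight_mg", "abc"),  # text into integer field
        ("properties.status", "no-such-status"),  # outside the choice list
        ("properties.performed_at", "March 1st"),  # unparseable date-time
        ("properties.components", "not-a-list"),
    ],
)
def test_schema_violations_rejected(path, value):
    platform = build_chemotion_platform()
    payload = {"properties": {"name": "r1"}}
    keys = path.split(".")
    payload[keys[0]][keys[1]] = value
    with pytest.raises(SchemaViolation):
        platform.create_entry("reaction", payload, collection="membranes")


def test_required_field_enforced():
    platform = build_chemotion_platform()
    with pytest.raises(SchemaViolation, match="required"):
        platform.create_entry("sample", {"properties": {"description": "no name"}})


# -- determinism ------------------------------------------------------------

def test_same_seed_builds_identical_platforms():
    a = generate_random_scenario(seed=7)
    b = generate_random_scenario(seed=7)
    assert a.platform_a.to_dict() == b.platform_a.to_dict()
    assert a.platform_b.to_dict() == b.platform_b.to_dict()
    restored = MockPlatform.from_dict(a.platform_a.to_dict())
    assert restored.to_dict() == a.platform_a.to_dict()


def test_credential_checked():
    platform = build_chemotion_platform(token="right-token")
    with pytest.raises(AuthError):
        InMemoryDelegate(chem_config(credential="wrong"), platform)


# -- the same contract suite over both delegate kinds ------------------------


@pytest.fixture(params=["memory", "rest"])
def bound_delegate(request):
    platform = build_chemotion_platform(ManualClock(), token="chem-token")
    platform.create_entry("reaction", {"properties": {"name": "seeded"}}, collection="membranes")
    platform.create_entry("reaction", {"properties": {"name": "outside"}}, collection="archive")
    if request.param == "memory":
        yield InMemoryDelegate(chem_config(), platform), platform
        return
    server = make_server("127.0.0.1", 0, make_wsgi_app(platform), WSGIServer)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    config = chem_config(endpoint=f"http://127.0.0.1:{server.server_port}")
    try:
        yield RestDelegate(config), platform
    finally:
        server.shutdown()
        thread.join(timeout=5)


def test_contract(bound_delegate):
    """In-memory and REST delegates satisfy the identical contract."""
    delegate, platform = bound_delegate
    assert [m.mask_name for m in delegate.list_types()] == ["reaction", "sample"]
    assert [m.mask_version for m in delegate.list_types()] == ["1", "1"]

    listed = delegate.list_entries("reaction")
    assert [e.entry_id for e in listed] == ["reaction-0001"]  # scope applied

    entry = delegate.read_entry("reaction", "reaction-0001")
    assert entry.payload["properties"]["name"] == "seeded"

    new_payload = {"properties": {"name": "seeded", "weight_mg": 11}}
    written = delegate.write_entry("reaction", "reaction-0001", new_payload)
    assert written.payload == new_payload
    assert delegate.read_entry("reaction", "reaction-0001").payload == new_payload

    created = delegate.create_entry("reaction", {"properties": {"name": "fresh"}})
    assert created.entry_id.startswith("reaction-")
    assert platform.entry_collection("reaction", created.entry_id) == "membranes"

    with pytest.raises(UnknownMaskError):
        delegate.list_entries("no-such-mask")
    with pytest.raises(UnknownEntryError):
        delegate.read_entry("reaction", "reaction-9999")
    with pytest.raises(SchemaViolation):
        delegate.write_entry(
            "reaction", "reaction-0001", {"properties": {"name": "x", "weight_mg": "NaN"}}
        )


def test_rest_rejects_bad_credential():
    platform = build_chemotion_platform(token="chem-token")
    server = make_server("127.0.0.1", 0, make_wsgi_app(platform), WSGIServer)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    try:
        delegate = RestDelegate(
            chem_config(credential="wrong", endpoint=f"http://127.0.0.1:{server.server_port}")
        )
        with pytest.raises(AuthError):
            delegate.list_types()
    finally:
        server.shutdown()
        thread.join(timeout=5)
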