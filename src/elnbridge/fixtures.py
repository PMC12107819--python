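"""Deterministic mock-platform content and test scenarios.

Two mock ELN personalities are built here: a Chemotion-style chemistry ELN
(payload fields under ``properties.*``, entries organized in collections,
masks ``reaction`` and ``sample``) and a Herbie-style materials-science ELN
(fields under ``values.*``, masks ``post-modification`` and ``product``).
On top of them sit:

* :func:`build_demo_sync_model` — the reference sync model for
  ``reaction`` ↔ ``post-modification`` with exactly ten mappings, from
  *Reaction Name* down to *Time*, including a date-time transfer operator,
  a choice-label remap and an element-wise array mapping;
* :func:`build_membrane_case` — the membrane post-modification scenario: a
  membrane ``product`` "PAN$20/013-PAN-EDA-01;" documented on the
  Herbie-like platform that the bridge must create as a Chemotion-like
  ``sample``, plus a filled-in ``reaction`` whose weight, reaction
  conditions and status are edited in a scripted second round;
* :func:`generate_random_scenario` — seeded random platform contents with a
  configurable key overlap and edit rate, for property-based engine tests.

Only the membrane/product name, the field kinds and the sync-key paths of
the worked example are fixed by its source systems; all other concrete
field values, labels and timestamps in these fixtures are synthetic
constants chosen for the tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Any, Callable, Optional

from .datamodel import (
    BridgeConfig,
    Mapping,
    PlatformConfig,
    SyncModel,
    SyncModelSide,
)
from .paths import get_path
from .delegates import (
    FieldSpec,
    InMemoryDelegate,
    ManualClock,
    MaskDescriptor,
    MockPlatform,
)

__all__ = [
    "MEMBRANE_NAME",
    "chemotion_masks",
    "herbie_masks",
    "build_chemotion_platform",
    "build_herbie_platform",
    "build_demo_sync_model",
    "build_product_sync_model",
    "build_membrane_config",
    "Edit",
    "Scenario",
    "build_membrane_case",
    "generate_random_scenario",
    "resolve_mock_endpoint",
    "MOCK_FIXTURES",
]

MEMBRANE_NAME = "PAN$20/013-PAN-EDA-01;"

# status vocabularies differ between the two platforms; the demo sync model
# translates between them with a choice remap
CHEM_STATUS = ("planned", "running", "done", "failed")
HERBIE_STATUS = ("Planned", "In Progress", "Successful", "Not Successful")
CHEM_DATE_FMT = "%Y-%m-%d %H:%M"
HERBIE_DATE_FMT = "%d.%m.%Y %H:%M"


# --------------------------------------------------------------------------
# mask schemas


def chemotion_masks() -> list[MaskDescriptor]:
    reaction = MaskDescriptor(
        mask_name="reaction",
        mask_version="1",
        fields=(
            FieldSpec("properties.name", "text", required=True),
            FieldSpec("properties.weight_mg", "integer"),
            FieldSpec("properties.conditions", "text"),
            FieldSpec("properties.status", "choice", options=CHEM_STATUS),
            FieldSpec("properties.temperature_c", "number"),
            FieldSpec("properties.solvent", "text"),
            FieldSpec("properties.yield_percent", "number"),
            FieldSpec("properties.performed_at", "datetime", format=CHEM_DATE_FMT),
            FieldSpec(
                "properties.components",
                "list",
                item_fields=(
                    FieldSpec("name", "text"),
                    FieldSpec("amount_mg", "integer"),
                ),
            ),
            FieldSpec("properties.duration", "text"),
        ),
    )
    sample = MaskDescriptor(
        mask_name="sample",
        mask_version="1",
        fields=(
            FieldSpec("properties.name", "text", required=True),
            FieldSpec("properties.description", "text"),
            FieldSpec("properties.weight_mg", "integer"),
        ),
    )
    return [reaction, sample]


def herbie_masks() -> list[MaskDescriptor]:
    post_modification = MaskDescriptor(
        mask_name="post-modification",
        mask_version="1",
        fields=(
            FieldSpec("values.reaction_name", "text", required=True),
            FieldSpec("values.weight", "integer"),
            FieldSpec("values.conditions", "text"),
            FieldSpec("values.status", "choice", options=HERBIE_STATUS),
            FieldSpec("values.temperature", "number"),
            FieldSpec("values.solvent", "text"),
            FieldSpec("values.yield_percent", "number"),
            FieldSpec("values.performed_on", "datetime", format=HERBIE_DATE_FMT),
            FieldSpec(
                "values.components",
                "list",
                item_fields=(
                    FieldSpec("component", "text"),
                    FieldSpec("amount", "integer"),
                ),
            ),
            FieldSpec("values.time", "text"),
        ),
    )
    product = MaskDescriptor(
        mask_name="product",
        mask_version="1",
        fields=(
            FieldSpec("values.product_name", "text", required=True),
            FieldSpec("values.description", "text"),
            FieldSpec("values.mass_mg", "integer"),
        ),
    )
    return [post_modification, product]


def build_chemotion_platform(
    clock: Optional[ManualClock] = None, token: Optional[str] = None
) -> MockPlatform:
    return MockPlatform(
        name="chemotion-mock",
        masks=chemotion_masks(),
        clock=clock,
        collections=("membranes", "archive"),
        token=token,
    )


def build_herbie_platform(
    clock: Optional[ManualClock] = None, token: Optional[str] = None
) -> MockPlatform:
    return MockPlatform(
        name="herbie-mock", masks=herbie_masks(), clock=clock, token=token
    )


# --------------------------------------------------------------------------
# sync models

_STATUS_AB = dict(zip(CHEM_STATUS, HERBIE_STATUS))
_STATUS_BA = dict(zip(HERBIE_STATUS, CHEM_STATUS))


def _remap_text(table: dict) -> str:
    body = ", ".join(f'"{k}": "{v}"' for k, v in table.items())
    return "remap({" + body + "})"


def build_demo_sync_model() -> SyncModel:
    """The reference ``reaction`` ↔ ``post-modification`` model: ten mappings."""
    mappings = [
        Mapping(identifier="Reaction Name", key_a="properties.name", key_b="values.reaction_name"),
        Mapping(identifier="Weight", key_a="properties.weight_mg", key_b="values.weight"),
        Mapping(identifier="Conditions", key_a="properties.conditions", key_b="values.conditions"),
        Mapping(
            identifier="Status",
            key_a="properties.status",
            key_b="values.status",
            operator_ab=_remap_text(_STATUS_AB),
            operator_ba=_remap_text(_STATUS_BA),
        ),
        Mapping(identifier="Temperature", key_a="properties.temperature_c", key_b="values.temperature"),
        Mapping(identifier="Solvent", key_a="properties.solvent", key_b="values.solvent"),
        Mapping(identifier="Yield", key_a="properties.yield_percent", key_b="values.yield_percent"),
        Mapping(
            identifier="Performed",
            key_a="properties.performed_at",
            key_b="values.performed_on",
            operator_ab=f'datefmt("{CHEM_DATE_FMT}", "{HERBIE_DATE_FMT}")',
            operator_ba=f'datefmt("{HERBIE_DATE_FMT}", "{CHEM_DATE_FMT}")',
        ),
        Mapping(
            identifier="Components",
            data_type="array",
            key_a="properties.components",
            key_b="values.components",
            submappings=[
                Mapping(identifier="Component Name", key_a="name", key_b="component"),
                Mapping(identifier="Component Amount", key_a="amount_mg", key_b="amount"),
            ],
        ),
        Mapping(identifier="Time", key_a="properties.duration", key_b="values.time"),
    ]
    return SyncModel(
        name="Post-modification of membranes",
        side_a=SyncModelSide(mask_name="reaction", mask_version="1", sync_key="properties.name"),
        side_b=SyncModelSide(
            mask_name="post-modification", mask_version="1", sync_key="values.reaction_name"
        ),
        mappings=mappings,
    )


def build_product_sync_model() -> SyncModel:
    """``sample`` ↔ ``product``: carries fabricated membranes into the chemistry ELN."""
    return SyncModel(
        name="Membrane products",
        side_a=SyncModelSide(mask_name="sample", mask_version="1", sync_key="properties.name"),
        side_b=SyncModelSide(mask_name="product", mask_version="1", sync_key="values.product_name"),
        mappings=[
            Mapping(identifier="Product Name", key_a="properties.name", key_b="values.product_name"),
            Mapping(
                identifier="Product Description",
                key_a="properties.description",
                key_b="values.description",
            ),
            Mapping(identifier="Product Weight", key_a="properties.weight_mg", key_b="values.mass_mg"),
        ],
    )


def build_membrane_config(
    endpoint_a: str = "mock:membrane-chemotion",
    endpoint_b: str = "mock:membrane-herbie",
    allow_create_a: bool = True,
    allow_create_b: bool = True,
    state_path: Optional[str] = None,
    log_path: Optional[str] = None,
) -> BridgeConfig:
    return BridgeConfig(
        platforms=[
            PlatformConfig(
                platform_id="chemotion",
                display_name="Chemotion (mock)",
                endpoint=endpoint_a,
                credential="chem-token",
                scope="membranes",
                allow_create=allow_create_a,
            ),
            PlatformConfig(
                platform_id="herbie",
                display_name="Herbie (mock)",
                endpoint=endpoint_b,
                credential="herbie-token",
                allow_create=allow_create_b,
            ),
        ],
        sync_models=[build_demo_sync_model(), build_product_sync_model()],
        state_path=state_path,
        log_path=log_path,
    )


# --------------------------------------------------------------------------
# scenarios


@dataclass
class Edit:
    platform_id: str
    mask_name: str
    entry_id: str
    path: str
    value: Any

    def to_dict(self) -> dict:
        return {
            "platform_id": self.platform_id,
            "mask_name": self.mask_name,
            "entry_id": self.entry_id,
            "path": self.path,
            "value": self.value,
        }


@dataclass
class Scenario:
    """A reproducible test setup: two populated mocks, a config, an edit script."""

    seed: int
    clock: ManualClock
    platform_a: MockPlatform
    platform_b: MockPlatform
    config: BridgeConfig
    edit_rounds: list[list[Edit]] = field(default_factory=list)

    def delegates(self) -> tuple[InMemoryDelegate, InMemoryDelegate]:
        return (
            InMemoryDelegate(self.config.platform_a, self.platform_a),
            InMemoryDelegate(self.config.platform_b, self.platform_b),
        )

    def apply_round(self, index: int, tick_seconds: float = 60.0) -> list[Edit]:
        """Replay one round of scripted user edits (the clock advances first)."""
        edits = self.edit_rounds[index]
        self.clock.tick(tick_seconds)
        by_platform = {
            self.platform_a.name: self.platform_a,
            self.platform_b.name: self.platform_b,
        }
        for edit in edits:
            by_platform[edit.platform_id].set_field(
                edit.mask_name, edit.entry_id, edit.path, edit.value
            )
        return edits

    def to_dict(self) -> dict:
        import json

        return {
            "seed": self.seed,
            "platform_a": self.platform_a.to_dict(),
            "platform_b": self.platform_b.to_dict(),
            "config": json.loads(self.config.model_dump_json(exclude_none=True)),
            "edit_rounds": [[e.to_dict() for e in round_] for round_ in self.edit_rounds],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        platform_a = MockPlatform.from_dict(data["platform_a"])
        platform_b = MockPlatform.from_dict(data["platform_b"])
        # both platforms share one clock so edit rounds stay ordered
        clock = platform_a.clock
        platform_b.clock = clock
        return cls(
            seed=data["seed"],
            clock=clock,
            platform_a=platform_a,
            platform_b=platform_b,
            config=BridgeConfig.model_validate(data["config"]),
            edit_rounds=[
                [Edit(**e) for e in round_] for round_ in data.get("edit_rounds", [])
            ],
        )


def build_membrane_case() -> Scenario:
    """The membrane post-modification use case.

    Before the first sync the Herbie-like platform documents the fabricated
    membrane (a ``product`` named ``PAN$20/013-PAN-EDA-01;``) and an empty
    ``post-modification`` shell for it; the Chemotion-like platform holds
    the filled-in ``reaction`` (collection ``membranes``) with the membrane
    weight (integer), the reaction conditions (free text) and the reaction
    status (choice from a list).  The scripted second round edits exactly
    those three reaction parameters.
    """
    clock = ManualClock(datetime(2024, 3, 1, 9, 0, tzinfo=timezone.utc))
    chem = build_chemotion_platform(clock, token="chem-token")
    herbie = build_herbie_platform(clock, token="herbie-token")

    reaction_name = "PM-PAN-EDA-01"

    herbie.create_entry(
        "product",
        {
            "values": {
                "product_name": MEMBRANE_NAME,
                "description": "flat-sheet polyacrylonitrile membrane, EDA batch 01 (synthetic fixture)",
                "mass_mg": 1250,
            }
        },
    )
    clock.tick(60)
    herbie.create_entry(
        "post-modification",
        {"values": {"reaction_name": reaction_name}},
    )
    clock.tick(60)
    chem.create_entry(
        "reaction",
        {
            "properties": {
                "name": reaction_name,
                "weight_mg": 250,
                "conditions": "EDA in water, reflux 2 h (synthetic fixture)",
                "status": "running",
                "temperature_c": 80.0,
                "solvent": "water",
                "yield_percent": 0.0,
                "performed_at": "2024-03-01 08:00",
                "components": [
                    {"name": "PAN membrane", "amount_mg": 250},
                    {"name": "ethylenediamine", "amount_mg": 480},
                ],
                "duration": "2 h",
            }
        },
        collection="membranes",
    )

    reaction = chem.find_by_key("reaction", "properties.name", reaction_name)
    assert reaction is not None
    edits = [
        Edit("chemotion-mock", "reaction", reaction.entry_id, "properties.weight_mg", 275),
        Edit(
            "chemotion-mock",
            "reaction",
            reaction.entry_id,
            "properties.conditions",
            "EDA in water, reflux 3 h, then washed (synthetic fixture)",
        ),
        Edit("chemotion-mock", "reaction", reaction.entry_id, "properties.status", "done"),
    ]
    return Scenario(
        seed=0,
        clock=clock,
        platform_a=chem,
        platform_b=herbie,
        config=build_membrane_config(),
        edit_rounds=[edits],
    )


# --------------------------------------------------------------------------
# randomized scenarios

_SOLVENTS = ("water", "ethanol", "DMF", "THF", "toluene")
_CONDITION_WORDS = ("reflux", "stirred", "under argon", "cooled", "sonicated", "dark")
_COMPONENT_NAMES = ("PAN membrane", "EDA", "NaOH", "buffer", "crosslinker")


def _random_datetime(rng: random.Random, fmt: str) -> str:
    base = datetime(2024, 1, 1, tzinfo=timezone.utc)
    minutes = rng.randrange(0, 200 * 24 * 60)
    return (base + timedelta(minutes=minutes)).strftime(fmt)


def _reaction_payload(rng: random.Random, name: str) -> dict:
    return {
        "properties": {
            "name": name,
            "weight_mg": rng.randrange(50, 500),
            "conditions": " ".join(rng.sample(_CONDITION_WORDS, 2)),
            "status": rng.choice(CHEM_STATUS),
            "temperature_c": float(rng.randrange(20, 120)),
            "solvent": rng.choice(_SOLVENTS),
            "yield_percent": round(rng.uniform(0, 100), 1),
            "performed_at": _random_datetime(rng, CHEM_DATE_FMT),
            "components": [
                {"name": rng.choice(_COMPONENT_NAMES), "amount_mg": rng.randrange(1, 1000)}
                for _ in range(rng.randrange(0, 3))
            ],
            "duration": f"{rng.randrange(1, 48)} h",
        }
    }


def _postmod_payload(rng: random.Random, name: str) -> dict:
    return {
        "values": {
            "reaction_name": name,
            "weight": rng.randrange(50, 500),
            "conditions": " ".join(rng.sample(_CONDITION_WORDS, 2)),
            "status": rng.choice(HERBIE_STATUS),
            "temperature": float(rng.randrange(20, 120)),
            "solvent": rng.choice(_SOLVENTS),
            "yield_percent": round(rng.uniform(0, 100), 1),
            "performed_on": _random_datetime(rng, HERBIE_DATE_FMT),
            "components": [
                {"component": rng.choice(_COMPONENT_NAMES), "amount": rng.randrange(1, 1000)}
                for _ in range(rng.randrange(0, 3))
            ],
            "time": f"{rng.randrange(1, 48)} h",
        }
    }


# editable atomic fields per side: (path, value factory)
def _editable_fields(rng: random.Random):
    return {
        "a": [
            ("properties.weight_mg", lambda: rng.randrange(50, 500)),
            ("properties.conditions", lambda: " ".join(rng.sample(_CONDITION_WORDS, 3))),
            ("properties.status", lambda: rng.choice(CHEM_STATUS)),
            ("properties.temperature_c", lambda: float(rng.randrange(20, 120))),
            ("properties.solvent", lambda: rng.choice(_SOLVENTS)),
            ("properties.duration", lambda: f"{rng.randrange(1, 48)} h"),
        ],
        "b": [
            ("values.weight", lambda: rng.randrange(50, 500)),
            ("values.conditions", lambda: " ".join(rng.sample(_CONDITION_WORDS, 3))),
            ("values.status", lambda: rng.choice(HERBIE_STATUS)),
            ("values.temperature", lambda: float(rng.randrange(20, 120))),
            ("values.solvent", lambda: rng.choice(_SOLVENTS)),
            ("values.time", lambda: f"{rng.randrange(1, 48)} h"),
        ],
    }


def generate_random_scenario(
    seed: int,
    n_entries: int = 8,
    overlap: float = 0.3,
    edit_rate: float = 0.3,
    duplicate_keys: bool = False,
    out_of_scope: int = 0,
    allow_create_a: bool = True,
    allow_create_b: bool = True,
    n_edit_rounds: int = 1,
) -> Scenario:
    """Seeded random contents for both mocks plus a scripted edit sequence.

    ``n_entries`` reactions / post-modifications are created per side; an
    ``overlap`` fraction of them share sync-key values (and therefore pair),
    the rest are unique per side.  Each edit round touches each entry's
    mapped atomic fields with probability ``edit_rate``.  ``out_of_scope``
    extra reactions go into a collection outside the configured scope;
    ``duplicate_keys`` injects a duplicated sync-key value on side A.
    """
    if not 0 <= overlap <= 1 or not 0 <= edit_rate <= 1:
        raise ValueError("overlap and edit_rate must lie in [0, 1]")
    if n_entries < 0 or out_of_scope < 0 or n_edit_rounds < 0:
        raise ValueError("counts must be non-negative")
    rng = random.Random(seed)
    clock = ManualClock(datetime(2024, 3, 1, 9, 0, tzinfo=timezone.utc))
    chem = build_chemotion_platform(clock)
    herbie = build_herbie_platform(clock)

    n_shared = round(overlap * n_entries)
    keys_shared = [f"RX-{seed % 1000:03d}-{i:03d}" for i in range(n_shared)]
    keys_a = keys_shared + [f"RXA-{seed % 1000:03d}-{i:03d}" for i in range(n_entries - n_shared)]
    keys_b = keys_shared + [f"RXB-{seed % 1000:03d}-{i:03d}" for i in range(n_entries - n_shared)]

    # interleave creations in random order so either side may hold the
    # later updated_at of a pair
    jobs: list[tuple[str, str]] = [("a", k) for k in keys_a] + [("b", k) for k in keys_b]
    rng.shuffle(jobs)
    created: dict[tuple[str, str], str] = {}
    for side, key in jobs:
        clock.tick(30)
        if side == "a":
            entry = chem.create_entry("reaction", _reaction_payload(rng, key), collection="membranes")
        else:
            entry = herbie.create_entry("post-modification", _postmod_payload(rng, key))
        created[(side, key)] = entry.entry_id

    if duplicate_keys and keys_a:
        clock.tick(30)
        dup = chem.create_entry(
            "reaction", _reaction_payload(rng, keys_a[0]), collection="membranes"
        )
        created[("a", keys_a[0] + "#dup")] = dup.entry_id

    for i in range(out_of_scope):
        clock.tick(30)
        chem.create_entry(
            "reaction",
            _reaction_payload(rng, f"OUT-{seed % 1000:03d}-{i:03d}"),
            collection="archive",
        )

    fields = _editable_fields(rng)
    edit_rounds: list[list[Edit]] = []
    for _ in range(n_edit_rounds):
        edits: list[Edit] = []
        for (side, key), entry_id in sorted(created.items()):
            if rng.random() >= edit_rate:
                continue
            platform = chem if side == "a" else herbie
            mask = "reaction" if side == "a" else "post-modification"
            path, make_value = rng.choice(fields[side])
            current = platform.read_entry(mask, entry_id).payload
            old = get_path(current, path)
            value = make_value()
            for _attempt in range(10):
                if value != old:
                    break
                value = make_value()
            if value == old:
                continue
            edits.append(Edit(platform.name, mask, entry_id, path, value))
        edit_rounds.append(edits)

    config = BridgeConfig(
        platforms=[
            PlatformConfig(
                platform_id="chemotion",
                display_name="Chemotion (mock)",
                endpoint="mock:empty-chemotion",
                credential="chem-token",
                scope="membranes",
                allow_create=allow_create_a,
            ),
            PlatformConfig(
                platform_id="herbie",
                display_name="Herbie (mock)",
                endpoint="mock:empty-herbie",
                credential="herbie-token",
                allow_create=allow_create_b,
            ),
        ],
        sync_models=[build_demo_sync_model()],
    )
    return Scenario(
        seed=seed,
        clock=clock,
        platform_a=chem,
        platform_b=herbie,
        config=config,
        edit_rounds=edit_rounds,
    )


# --------------------------------------------------------------------------
# mock endpoint registry (used by the CLI to run the full demo offline)

MOCK_FIXTURES: dict[str, Callable[[], MockPlatform]] = {
    "membrane-chemotion": lambda: build_membrane_case().platform_a,
    "membrane-herbie": lambda: build_membrane_case().platform_b,
    "empty-chemotion": lambda: build_chemotion_platform(),
    "empty-herbie": lambda: build_herbie_platform(),
}


def resolve_mock_endpoint(endpoint: str) -> tuple[MockPlatform, Optional[str]]:
    """Resolve a ``mock:<fixture>[@<store.json>]`` endpoint.

    With an ``@path`` suffix the platform is loaded from that JSON store if
    it exists (and the caller should save it back after mutating), so
    consecutive CLI invocations see a persistent mock platform.
    """
    if not endpoint.startswith("mock:"):
        raise ValueError(f"not a mock endpoint: {endpoint!r}")
    spec = endpoint[len("mock:") :]
    store: Optional[str] = None
    if "@" in spec:
        spec, store = spec.split("@", 1)
    if spec not in MOCK_FIXTURES:
        raise ValueError(
            f"unknown mock fixture {spec!r}; available: {sorted(MOCK_FIXTURES)}"
        )
    if store:
        from pathlib import Path
        import json

        path = Path(store)
        if path.exists():
            return MockPlatform.from_dict(json.loads(path.read_text())), store
    return MOCK_FIXTURES[spec](), store
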