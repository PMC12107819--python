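import random

import pytest

from elnbridge.datamodel import (
    BridgeConfig,
    Mapping,
    PlatformConfig,
    SyncModel,
    SyncModelSide,
    SyncState,
)
from elnbridge.engine import ProcessLog, run_sync
from elnbridge.fixtures import build_membrane_case, build_demo_sync_model


@pytest.fixture
def membrane():
    return build_membrane_case()


@pytest.fixture
def demo_model():
    return build_demo_sync_model()


def sync_all(scenario, state=None, log=None):
    """Run every sync model of a scenario once; returns (state, applied records)."""
    state = state if state is not None else SyncState()
    log = log or ProcessLog()
    delegate_a, delegate_b = scenario.delegates()
    applied = []
    for model in scenario.config.sync_models:
        state, _, records = run_sync(model, delegate_a, delegate_b, state, log=log)
        applied.extend(records)
    return state, applied


def random_config(rng: random.Random) -> BridgeConfig:
    """A structurally valid random configuration, for round-trip checks."""

    def mapping(i: int, depth: int = 0) -> Mapping:
        if depth < 1 and rng.random() < 0.25:
            return Mapping(
                identifier=f"map-{i}",
                data_type="array",
                key_a=f"properties.list{i}",
                key_b=f"values.list{i}",
                submappings=[mapping(100 * (i + 1) + j, depth + 1) for j in range(rng.randint(1, 3))],
            )
        op = rng.choice(
            [None, "id", 'cast("str")', 'remap({"x": "y"}, null)', "pipe(add(1), mul(2))"]
        )
        return Mapping(
            identifier=f"map-{i}",
            key_a=f"properties.f{i}",
            key_b=f"values.f{i}",
            operator_ab=op,
            operator_ba=rng.choice([None, "id"]),
        )

    models = []
    for m in range(rng.randint(0, 3)):
        models.append(
            SyncModel(
                name=f"model-{m}",
                side_a=SyncModelSide(
                    mask_name=rng.choice(["reaction", "sample"]),
                    mask_version=str(rng.randint(1, 3)),
                    sync_key="properties.name",
                ),
                side_b=SyncModelSide(
                    mask_name=rng.choice(["post-modification", "product"]),
                    mask_version=str(rng.randint(1, 3)),
                    sync_key="values.reaction_name",
                ),
                mappings=[mapping(i) for i in range(rng.randint(0, 5))],
            )
        )
    policy = rng.choice(["all", {"updated_after": "2024-01-01T00:00:00+00:00"}])
    return BridgeConfig(
        platforms=[
            PlatformConfig(
                platform_id="chem",
                display_name="Chemotion",
                endpoint="mock:empty-chemotion",
                credential=f"tok-{rng.randint(0, 999)}",
                scope=rng.choice([None, "membranes"]),
                existing_policy=policy,
                allow_create=rng.random() < 0.5,
            ),
            PlatformConfig(
                platform_id="herbie",
                display_name="Herbie",
                endpoint="mock:empty-herbie",
                credential="tok-b",
                allow_create=rng.random() < 0.5,
            ),
        ],
        sync_models=models,
    )
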