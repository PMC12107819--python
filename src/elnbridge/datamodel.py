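"""Configuration and state objects consumed by every other module.

A bridge configuration registers exactly two ELN platforms and any number of
*sync models*.  A sync model pairs one input mask (entry type) per platform,
names the per-side *sync key* paths whose equal values identify an entry
pair, and lists the field-to-field *mappings* with optional transfer
operators.  Side A of every sync model is the first-registered platform,
side B the second.

Configurations are declarative YAML or JSON documents; unknown keys are
rejected rather than ignored, because a silently misread key in a sync
engine corrupts data on both platforms.  The engine's only mutable persisted
artifact is the :class:`SyncState`: per synchronized pair, the snapshot of
the last value written on each side for every mapping.  Change detection
compares current values against these snapshots instead of trusting
platform timestamps alone, so it is robust to clock skew between platforms.
All timestamps are stored timezone-aware and compared in UTC.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .operators import OperatorSyntaxError, parse_operator
from .paths import DotPath, MalformedPathError

__all__ = [
    "ConfigError",
    "StateStoreError",
    "ExistingPolicy",
    "PlatformConfig",
    "Mapping",
    "SyncModelSide",
    "SyncModel",
    "BridgeConfig",
    "Entry",
    "PairState",
    "SyncState",
    "ChangeRecord",
    "Finding",
    "load_config",
    "parse_config",
    "save_config",
    "validate_sync_model",
    "persist_state",
    "load_state",
]


class ConfigError(ValueError):
    """A configuration document failed to parse or validate."""


class StateStoreError(RuntimeError):
    """The persisted sync state could not be read or written."""


def _utc(dt: datetime) -> datetime:
    if dt.tzinfo is None:
        raise ValueError(f"timestamp {dt.isoformat()} is naive; timezone required")
    return dt.astimezone(timezone.utc)


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ExistingPolicy(_Model):
    """Which existing entries take part: all, or only those updated after a cutoff."""

    mode: Literal["all", "updated_after"] = "all"
    updated_after: Optional[datetime] = None

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        if isinstance(data, str):
            if data != "all":
                raise ValueError(f"existing_policy string must be 'all', got {data!r}")
            return {"mode": "all"}
        if isinstance(data, dict) and set(data) == {"updated_after"}:
            return {"mode": "updated_after", "updated_after": data["updated_after"]}
        return data

    @model_validator(mode="after")
    def _check(self) -> "ExistingPolicy":
        if self.mode == "updated_after":
            if self.updated_after is None:
                raise ValueError("existing_policy 'updated_after' requires a timestamp")
            object.__setattr__(self, "updated_after", _utc(self.updated_after))
        elif self.updated_after is not None:
            raise ValueError("existing_policy 'all' takes no timestamp")
        return self

    def cutoff(self) -> Optional[datetime]:
        return self.updated_after if self.mode == "updated_after" else None


class PlatformConfig(_Model):
    """One registered ELN endpoint plus its synchronization policy."""

    platform_id: str = Field(pattern=r"^[A-Za-z0-9_-]+$")
    display_name: str
    endpoint: str
    credential: str
    scope: Optional[str] = None
    existing_policy: ExistingPolicy = Field(default_factory=ExistingPolicy)
    allow_create: bool = False


def _check_dot_path(text: str, what: str) -> str:
    try:
        DotPath.parse(text)
    except MalformedPathError as exc:
        raise ValueError(f"{what}: {exc}") from exc
    return text


class Mapping(_Model):
    """One field-to-field correspondence between the two platforms.

    ``atomic`` mappings transfer a single value, optionally through a
    per-direction transfer operator; ``array`` mappings carry no operators
    and instead apply their submappings to each element of the source list.
    """

    identifier: str = Field(min_length=1)
    data_type: Literal["atomic", "array"] = "atomic"
    key_a: str
    key_b: str
    operator_ab: Optional[str] = None
    operator_ba: Optional[str] = None
    submappings: list["Mapping"] = Field(default_factory=list)

    @field_validator("key_a", "key_b")
    @classmethod
    def _paths(cls, v: str) -> str:
        return _check_dot_path(v, "mapping key")

    @field_validator("operator_ab", "operator_ba")
    @classmethod
    def _operators(cls, v: Optional[str]) -> Optional[str]:
        if v is not None:
            try:
                parse_operator(v)
            except OperatorSyntaxError as exc:
                raise ValueError(f"invalid transfer operator {v!r}: {exc}") from exc
        return v

    @model_validator(mode="after")
    def _structure(self) -> "Mapping":
        if self.data_type == "atomic":
            if self.submappings:
                raise ValueError(
                    f"atomic mapping {self.identifier!r} must not have submappings"
                )
        else:
            if not self.submappings:
                raise ValueError(
                    f"array mapping {self.identifier!r} needs at least one submapping"
                )
            if self.operator_ab or self.operator_ba:
                raise ValueError(
                    f"array mapping {self.identifier!r} must not carry transfer operators"
                )
        return self

    def operator_for(self, direction: str) -> Optional[str]:
        return self.operator_ab if direction == "a_to_b" else self.operator_ba


class SyncModelSide(_Model):
    mask_name: str = Field(min_length=1)
    mask_version: str
    sync_key: str

    @field_validator("mask_version", mode="before")
    @classmethod
    def _version(cls, v: Any) -> str:
        return str(v)

    @field_validator("sync_key")
    @classmethod
    def _key(cls, v: str) -> str:
        return _check_dot_path(v, "sync key")


class SyncModel(_Model):
    """Pairing of one input mask per platform plus the ordered field mappings."""

    name: str = Field(min_length=1)
    side_a: SyncModelSide
    side_b: SyncModelSide
    mappings: list[Mapping] = Field(default_factory=list)

    @model_validator(mode="after")
    def _unique_identifiers(self) -> "SyncModel":
        seen: set[str] = set()

        def walk(maps: list[Mapping]) -> None:
            for m in maps:
                if m.identifier in seen:
                    raise ValueError(
                        f"duplicate mapping identifier {m.identifier!r} in sync model {self.name!r}"
                    )
                seen.add(m.identifier)
                walk(m.submappings)

        walk(self.mappings)
        return self

    def side(self, which: str) -> SyncModelSide:
        return self.side_a if which == "a" else self.side_b

    def key_for(self, mapping: Mapping, which: str) -> str:
        return mapping.key_a if which == "a" else mapping.key_b


class BridgeConfig(_Model):
    """The full declarative configuration: two platforms plus the sync models."""

    platforms: list[PlatformConfig]
    sync_models: list[SyncModel] = Field(default_factory=list)
    state_path: Optional[str] = None
    log_path: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "BridgeConfig":
        if len(self.platforms) != 2:
            raise ValueError(
                f"a bridge configuration registers exactly two platforms, got {len(self.platforms)}"
            )
        ids = [p.platform_id for p in self.platforms]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate platform_id in {ids}")
        names = [m.name for m in self.sync_models]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate sync model names in {names}")
        return self

    @property
    def platform_a(self) -> PlatformConfig:
        return self.platforms[0]

    @property
    def platform_b(self) -> PlatformConfig:
        return self.platforms[1]

    def platform(self, which: str) -> PlatformConfig:
        return self.platform_a if which == "a" else self.platform_b

    def model(self, name: str) -> SyncModel:
        for m in self.sync_models:
            if m.name == name:
                return m
        raise KeyError(f"no sync model named {name!r}")


# --------------------------------------------------------------------------
# run-time records


class Entry(_Model):
    """One record held by a platform, with its tree-structured payload."""

    model_config = ConfigDict(extra="forbid")

    platform_id: str
    mask_name: str
    mask_version: str
    entry_id: str
    updated_at: datetime
    payload: dict[str, Any] = Field(default_factory=dict)

    @field_validator("mask_version", mode="before")
    @classmethod
    def _version(cls, v: Any) -> str:
        return str(v)

    @field_validator("updated_at")
    @classmethod
    def _aware(cls, v: datetime) -> datetime:
        return _utc(v)


class ChangeRecord(_Model):
    """One field-level delta detected or applied during a run."""

    direction: Literal["a_to_b", "b_to_a"]
    pair_key_value: str
    mapping_id: str
    old: Any = None
    new: Any = None
    action: Literal["update", "create_entry", "skip"]
    reason: Optional[str] = None
    timestamp: datetime

    @field_validator("timestamp")
    @classmethod
    def _aware(cls, v: datetime) -> datetime:
        return _utc(v)

    @model_validator(mode="after")
    def _delta(self) -> "ChangeRecord":
        if self.action == "update" and self.old == self.new:
            raise ValueError("update record requires old != new")
        return self


class PairState(_Model):
    last_sync_time: datetime
    snapshot_a: dict[str, Any] = Field(default_factory=dict)
    snapshot_b: dict[str, Any] = Field(default_factory=dict)

    @field_validator("last_sync_time")
    @classmethod
    def _aware(cls, v: datetime) -> datetime:
        return _utc(v)

    def snapshot(self, which: str) -> dict[str, Any]:
        return self.snapshot_a if which == "a" else self.snapshot_b


class SyncState(_Model):
    """Snapshots of the last-synchronized mapped values, per model and pair key."""

    pairs: dict[str, dict[str, PairState]] = Field(default_factory=dict)

    def get_pair(self, model_name: str, pair_key: str) -> Optional[PairState]:
        return self.pairs.get(model_name, {}).get(pair_key)

    def set_pair(self, model_name: str, pair_key: str, state: PairState) -> None:
        self.pairs.setdefault(model_name, {})[pair_key] = state

    def known_keys(self, model_name: str) -> set[str]:
        return set(self.pairs.get(model_name, {}))


class Finding(_Model):
    """One validator result; validation returns findings instead of raising."""

    level: Literal["error", "warning"]
    code: str
    message: str

    def __str__(self) -> str:
        return f"{self.level.upper()} [{self.code}] {self.message}"


# --------------------------------------------------------------------------
# config I/O


def _format_validation_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<document>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def parse_config(text: str, source: str = "<string>") -> BridgeConfig:
    """Parse a YAML or JSON configuration document (JSON is a YAML subset)."""
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigError(f"{source}: parse error{where}: {exc}") from exc
    if raw is None:
        raise ConfigError(f"{source}: empty configuration document")
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    try:
        return BridgeConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{source}: {_format_validation_error(exc)}") from exc


def load_config(path: Union[str, Path]) -> BridgeConfig:
    """Load and validate a configuration file (``.yaml``/``.yml``/``.json``)."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    return parse_config(text, source=str(path))


def _config_dict(config: BridgeConfig) -> dict:
    return json.loads(config.model_dump_json(exclude_none=True))


def save_config(config: BridgeConfig, path: Union[str, Path], fmt: Optional[str] = None) -> None:
    """Serialize *config* so that :func:`load_config` reparses an equal object graph."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    data = _config_dict(config)
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# --------------------------------------------------------------------------
# sync-model validation against platform mask descriptors


def validate_sync_model(model: SyncModel, types_a: list, types_b: list) -> list[Finding]:
    """Check a sync model against the mask descriptors reported by both platforms.

    Returns findings instead of raising: an ``error`` for a mask missing on a
    platform or recorded with a different version (synchronizing against the
    wrong schema version corrupts entries after a platform update), and a
    ``warning`` for a mapping or sync-key path absent from the mask schema.
    """
    findings: list[Finding] = []
    for which, side, types in (("A", model.side_a, types_a), ("B", model.side_b, types_b)):
        by_name = {d.mask_name: d for d in types}
        desc = by_name.get(side.mask_name)
        if desc is None:
            findings.append(
                Finding(
                    level="error",
                    code="missing-mask",
                    message=f"platform {which} does not provide mask {side.mask_name!r}",
                )
            )
            continue
        if str(desc.mask_version) != side.mask_version:
            findings.append(
                Finding(
                    level="error",
                    code="version-mismatch",
                    message=(
                        f"mask {side.mask_name!r} on platform {which}: model expects "
                        f"version {side.mask_version}, platform reports {desc.mask_version}"
                    ),
                )
            )
        if not desc.has_path(side.sync_key):
            findings.append(
                Finding(
                    level="warning",
                    code="missing-path",
                    message=(
                        f"sync key {side.sync_key!r} not found in mask "
                        f"{side.mask_name!r} on platform {which}"
                    ),
                )
            )

        def warn(mapping: Mapping, key: str) -> None:
            findings.append(
                Finding(
                    level="warning",
                    code="missing-path",
                    message=(
                        f"mapping {mapping.identifier!r}: path {key!r} not found in "
                        f"mask {side.mask_name!r} on platform {which}"
                    ),
                )
            )

        for m in model.mappings:
            key = m.key_a if which == "A" else m.key_b
            if not desc.has_path(key):
                warn(m, key)
            elif m.data_type == "array":
                for sub in m.submappings:
                    subkey = sub.key_a if which == "A" else sub.key_b
                    if not desc.item_has_path(key, subkey):
                        warn(sub, f"{key}[].{subkey}")
    return findings


# --------------------------------------------------------------------------
# state persistence


def persist_state(state: SyncState, store: Union[str, Path]) -> None:
    """Write *state* as a single JSON document; atomic via a temp file."""
    path = Path(store)
    try:
        tmp = path.with_suffix(path.suffix + ".tmp")
        tmp.write_text(state.model_dump_json(indent=2))
        tmp.replace(path)
    except OSError as exc:
        raise StateStoreError(f"cannot write state store {path}: {exc}") from exc


def load_state(store: Union[str, Path]) -> SyncState:
    """Read a previously persisted state; a corrupt document is an explicit error."""
    path = Path(store)
    try:
        text = path.read_text()
    except OSError as exc:
        raise StateStoreError(f"cannot read state store {path}: {exc}") from exc
    try:
        data = json.loads(text)
        return SyncState.model_validate(data)
    except (json.JSONDecodeError, ValidationError) as exc:
        raise StateStoreError(f"state store {path} is corrupted: {exc}") from exc
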