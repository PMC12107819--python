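"""Platform API translators: the per-ELN adapters the sync engine talks to.

Every participating platform is represented by a *delegate* implementing one
fixed contract — list the available input masks, list entries of a mask
(honoring the configured collection scope and update-time cutoff), and read,
write or create individual entries.  The engine itself never speaks a
platform API; all communication goes through a delegate.

Two delegates ship with the package:

``InMemoryDelegate``
    wraps a :class:`MockPlatform`, an in-process store emulating either a
    Chemotion-style ELN (payload fields under ``properties.*``, entries
    organized in collections) or a Herbie-style ELN (fields under
    ``values.*``, no collections).  Mocks use an injectable
    :class:`ManualClock` so update timestamps — and hence last-write-wins
    conflict resolution — are fully deterministic in tests.

``RestDelegate``
    a generic HTTP+JSON skeleton (bearer-token auth) for platforms exposing
    the contract over REST; :func:`make_wsgi_app` serves a ``MockPlatform``
    through the same endpoints so the two delegates can be verified against
    an identical contract test suite.  Pagination is not modelled; a real
    platform adapter would add a page-size parameter to the listing calls.
"""

from __future__ import annotations

import itertools
import json
import urllib.error
import urllib.parse
import urllib.request
from abc import ABC, abstractmethod
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Any, Callable, Iterable, Optional

from .datamodel import Entry, PlatformConfig
from .paths import ABSENT, get_path, set_path

__all__ = [
    "DelegateError",
    "UnknownMaskError",
    "UnknownEntryError",
    "UnknownScopeError",
    "SchemaViolation",
    "AuthError",
    "FieldSpec",
    "MaskDescriptor",
    "ManualClock",
    "MockPlatform",
    "PlatformDelegate",
    "InMemoryDelegate",
    "RestDelegate",
    "make_wsgi_app",
]


class DelegateError(RuntimeError):
    """Base class for delegate/platform failures."""


class UnknownMaskError(DelegateError):
    pass


class UnknownEntryError(DelegateError):
    pass


class UnknownScopeError(DelegateError):
    pass


class SchemaViolation(DelegateError):
    """A payload value conflicts with the mask's declared field schema."""


class AuthError(DelegateError):
    pass


# --------------------------------------------------------------------------
# mask schemas

_FIELD_TYPES = ("integer", "number", "text", "choice", "datetime", "list")


@dataclass(frozen=True)
class FieldSpec:
    """One declared field of an input mask.

    ``path`` is the dot-path inside the entry payload.  ``choice`` fields
    carry their allowed ``options``; ``datetime`` fields the strptime
    ``format`` their string values must match; ``list`` fields declare the
    per-element schema in ``item_fields`` (paths relative to the element).
    """

    path: str
    type: str = "text"
    required: bool = False
    options: tuple[str, ...] = ()
    format: Optional[str] = None
    item_fields: tuple["FieldSpec", ...] = ()

    def __post_init__(self) -> None:
        if self.type not in _FIELD_TYPES:
            raise ValueError(f"unknown field type {self.type!r}")
        if self.type == "choice" and not self.options:
            raise ValueError(f"choice field {self.path!r} needs options")
        if self.type == "datetime" and not self.format:
            raise ValueError(f"datetime field {self.path!r} needs a format")
        if self.type == "list" and not self.item_fields:
            raise ValueError(f"list field {self.path!r} needs item_fields")

    def check(self, value: Any, where: str) -> list[str]:
        problems: list[str] = []
        if value is None:
            return problems
        if self.type == "integer":
            if isinstance(value, bool) or not isinstance(value, int):
                problems.append(f"{where}: expected integer, got {value!r}")
        elif self.type == "number":
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                problems.append(f"{where}: expected number, got {value!r}")
        elif self.type == "text":
            if not isinstance(value, str):
                problems.append(f"{where}: expected text, got {value!r}")
        elif self.type == "choice":
            if value not in self.options:
                problems.append(
                    f"{where}: {value!r} not in declared choices {list(self.options)}"
                )
        elif self.type == "datetime":
            if not isinstance(value, str):
                problems.append(f"{where}: expected date-time text, got {value!r}")
            else:
                try:
                    datetime.strptime(value, self.format or "")
                except ValueError:
                    problems.append(
                        f"{where}: {value!r} does not match pattern {self.format!r}"
                    )
        elif self.type == "list":
            if not isinstance(value, list):
                problems.append(f"{where}: expected list, got {value!r}")
            else:
                for i, element in enumerate(value):
                    for sub in self.item_fields:
                        sub_value = get_path(element, sub.path)
                        if sub_value is ABSENT:
                            if sub.required:
                                problems.append(f"{where}[{i}].{sub.path}: required field missing")
                            continue
                        problems.extend(sub.check(sub_value, f"{where}[{i}].{sub.path}"))
        return problems

    def to_dict(self) -> dict:
        out: dict[str, Any] = {"path": self.path, "type": self.type}
        if self.required:
            out["required"] = True
        if self.options:
            out["options"] = list(self.options)
        if self.format:
            out["format"] = self.format
        if self.item_fields:
            out["item_fields"] = [f.to_dict() for f in self.item_fields]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "FieldSpec":
        return cls(
            path=data["path"],
            type=data.get("type", "text"),
            required=data.get("required", False),
            options=tuple(data.get("options", ())),
            format=data.get("format"),
            item_fields=tuple(cls.from_dict(f) for f in data.get("item_fields", ())),
        )


@dataclass(frozen=True)
class MaskDescriptor:
    """Schema of one input mask (entry type) as reported by a platform."""

    mask_name: str
    mask_version: str
    fields: tuple[FieldSpec, ...] = ()

    def field_at(self, path: str) -> Optional[FieldSpec]:
        for f in self.fields:
            if f.path == path:
                return f
        return None

    def has_path(self, path: str) -> bool:
        return self.field_at(path) is not None

    def item_has_path(self, list_path: str, subpath: str) -> bool:
        f = self.field_at(list_path)
        if f is None or f.type != "list":
            return False
        return any(sub.path == subpath for sub in f.item_fields)

    def declared_paths(self) -> list[str]:
        out = []
        for f in self.fields:
            out.append(f.path)
            for sub in f.item_fields:
                out.append(f"{f.path}[].{sub.path}")
        return out

    def validate_payload(self, payload: dict) -> list[str]:
        problems: list[str] = []
        for f in self.fields:
            value = get_path(payload, f.path)
            if value is ABSENT:
                if f.required:
                    problems.append(f"{f.path}: required field missing")
                continue
            problems.extend(f.check(value, f.path))
        return problems

    def to_dict(self) -> dict:
        return {
            "mask_name": self.mask_name,
            "mask_version": self.mask_version,
            "fields": [f.to_dict() for f in self.fields],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MaskDescriptor":
        return cls(
            mask_name=data["mask_name"],
            mask_version=str(data["mask_version"]),
            fields=tuple(FieldSpec.from_dict(f) for f in data.get("fields", ())),
        )


# --------------------------------------------------------------------------
# deterministic clock


class ManualClock:
    """An injectable clock: time advances only when told to."""

    def __init__(self, start: Optional[datetime] = None):
        self._now = start or datetime(2024, 3, 1, 9, 0, tzinfo=timezone.utc)
        if self._now.tzinfo is None:
            raise ValueError("clock start must be timezone-aware")

    def now(self) -> datetime:
        return self._now

    def tick(self, seconds: float = 60.0) -> datetime:
        self._now = self._now + timedelta(seconds=seconds)
        return self._now

    def set(self, when: datetime) -> None:
        if when.tzinfo is None:
            raise ValueError("clock time must be timezone-aware")
        self._now = when.astimezone(timezone.utc)


# --------------------------------------------------------------------------
# in-memory mock platform


@dataclass
class _StoredEntry:
    entry_id: str
    payload: dict
    updated_at: datetime
    collection: Optional[str] = None


class MockPlatform:
    """An in-process mock ELN holding masks, collections and entries.

    Deterministic: entry ids are assigned from a per-mask counter, and all
    timestamps come from the injected clock, so two instances built by the
    same fixture script hold identical serialized contents.
    """

    def __init__(
        self,
        name: str,
        masks: Iterable[MaskDescriptor],
        clock: Optional[ManualClock] = None,
        collections: Iterable[str] = (),
        token: Optional[str] = None,
    ):
        self.name = name
        self.clock = clock or ManualClock()
        self.masks: dict[str, MaskDescriptor] = {m.mask_name: m for m in masks}
        self.collections: set[str] = set(collections)
        self.token = token
        self._entries: dict[str, dict[str, _StoredEntry]] = {m: {} for m in self.masks}
        self._counters: dict[str, itertools.count] = {m: itertools.count(1) for m in self.masks}

    # -- contract operations ------------------------------------------------

    def list_types(self) -> list[MaskDescriptor]:
        return sorted(self.masks.values(), key=lambda m: m.mask_name)

    def _mask(self, mask_name: str) -> MaskDescriptor:
        try:
            return self.masks[mask_name]
        except KeyError:
            raise UnknownMaskError(
                f"platform {self.name!r} has no mask {mask_name!r}"
            ) from None

    def list_entries(
        self,
        mask_name: str,
        scope: Optional[str] = None,
        since: Optional[datetime] = None,
    ) -> list[Entry]:
        self._mask(mask_name)
        if scope is not None and scope not in self.collections:
            raise UnknownScopeError(f"platform {self.name!r} has no collection {scope!r}")
        out = []
        for stored in self._entries[mask_name].values():
            if scope is not None and stored.collection != scope:
                continue
            if since is not None and stored.updated_at < since:
                continue
            out.append(self._to_entry(mask_name, stored))
        return sorted(out, key=lambda e: e.entry_id)

    def read_entry(self, mask_name: str, entry_id: str) -> Entry:
        stored = self._entries[self._mask(mask_name).mask_name].get(entry_id)
        if stored is None:
            raise UnknownEntryError(f"no entry {entry_id!r} of mask {mask_name!r}")
        return self._to_entry(mask_name, stored)

    def write_entry(self, mask_name: str, entry_id: str, payload: dict) -> Entry:
        mask = self._mask(mask_name)
        stored = self._entries[mask_name].get(entry_id)
        if stored is None:
            raise UnknownEntryError(f"no entry {entry_id!r} of mask {mask_name!r}")
        problems = mask.validate_payload(payload)
        if problems:
            raise SchemaViolation(
                f"write to {mask_name}/{entry_id} violates schema: " + "; ".join(problems)
            )
        stored.payload = _deep_copy(payload)
        stored.updated_at = self.clock.now()
        return self._to_entry(mask_name, stored)

    def create_entry(
        self, mask_name: str, payload: dict, collection: Optional[str] = None
    ) -> Entry:
        mask = self._mask(mask_name)
        if collection is not None and collection not in self.collections:
            raise UnknownScopeError(f"platform {self.name!r} has no collection {collection!r}")
        problems = mask.validate_payload(payload)
        if problems:
            raise SchemaViolation(
                f"create of {mask_name} violates schema: " + "; ".join(problems)
            )
        entry_id = f"{mask_name}-{next(self._counters[mask_name]):04d}"
        stored = _StoredEntry(
            entry_id=entry_id,
            payload=_deep_copy(payload),
            updated_at=self.clock.now(),
            collection=collection,
        )
        self._entries[mask_name][entry_id] = stored
        return self._to_entry(mask_name, stored)

    # -- fixture helpers ----------------------------------------------------

    def set_field(self, mask_name: str, entry_id: str, path: str, value: Any) -> Entry:
        """Edit one field in place (bumps updated_at), as a user edit would."""
        current = self.read_entry(mask_name, entry_id)
        return self.write_entry(mask_name, entry_id, set_path(current.payload, path, value))

    def find_by_key(self, mask_name: str, key_path: str, key_value: Any) -> Optional[Entry]:
        for entry in self.list_entries(mask_name):
            if get_path(entry.payload, key_path) == key_value:
                return entry
        return None

    def _to_entry(self, mask_name: str, stored: _StoredEntry) -> Entry:
        mask = self.masks[mask_name]
        return Entry(
            platform_id=self.name,
            mask_name=mask_name,
            mask_version=mask.mask_version,
            entry_id=stored.entry_id,
            updated_at=stored.updated_at,
            payload=_deep_copy(stored.payload),
        )

    def entry_collection(self, mask_name: str, entry_id: str) -> Optional[str]:
        return self._entries[mask_name][entry_id].collection

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "now": self.clock.now().isoformat(),
            "token": self.token,
            "collections": sorted(self.collections),
            "masks": [m.to_dict() for m in self.list_types()],
            "entries": {
                mask: [
                    {
                        "entry_id": s.entry_id,
                        "payload": s.payload,
                        "updated_at": s.updated_at.isoformat(),
                        "collection": s.collection,
                    }
                    for s in sorted(stored.values(), key=lambda s: s.entry_id)
                ]
                for mask, stored in sorted(self._entries.items())
            },
            "counters": {mask: self._peek_counter(mask) for mask in sorted(self.masks)},
        }

    def _peek_counter(self, mask: str) -> int:
        nxt = next(self._counters[mask])
        self._counters[mask] = itertools.count(nxt)  # restore
        return nxt

    @classmethod
    def from_dict(cls, data: dict) -> "MockPlatform":
        clock = ManualClock(datetime.fromisoformat(data["now"]))
        platform = cls(
            name=data["name"],
            masks=[MaskDescriptor.from_dict(m) for m in data["masks"]],
            clock=clock,
            collections=data.get("collections", ()),
            token=data.get("token"),
        )
        for mask, entries in data.get("entries", {}).items():
            for e in entries:
                platform._entries[mask][e["entry_id"]] = _StoredEntry(
                    entry_id=e["entry_id"],
                    payload=e["payload"],
                    updated_at=datetime.fromisoformat(e["updated_at"]),
                    collection=e.get("collection"),
                )
        for mask, nxt in data.get("counters", {}).items():
            platform._counters[mask] = itertools.count(nxt)
        return platform

    def content_hash(self) -> str:
        """Stable digest of the entire platform content; used to prove dry runs write nothing."""
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _deep_copy(tree: Any) -> Any:
    if isinstance(tree, dict):
        return {k: _deep_copy(v) for k, v in tree.items()}
    if isinstance(tree, list):
        return [_deep_copy(v) for v in tree]
    return tree


# --------------------------------------------------------------------------
# delegate contract


class PlatformDelegate(ABC):
    """The platform API translator contract bound to one registered platform.

    ``list_entries`` already applies the platform's configured scope
    (collection) and existing-entry policy (update-time cutoff), so the
    engine never sees out-of-scope entries.
    """

    def __init__(self, config: PlatformConfig):
        self.config = config

    @abstractmethod
    def list_types(self) -> list[MaskDescriptor]: ...

    @abstractmethod
    def list_entries(self, mask_name: str, since: Optional[datetime] = None) -> list[Entry]: ...

    @abstractmethod
    def read_entry(self, mask_name: str, entry_id: str) -> Entry: ...

    @abstractmethod
    def write_entry(self, mask_name: str, entry_id: str, payload: dict) -> Entry: ...

    @abstractmethod
    def create_entry(self, mask_name: str, payload: dict) -> Entry: ...

    def effective_since(self, since: Optional[datetime]) -> Optional[datetime]:
        cutoff = self.config.existing_policy.cutoff()
        if since is None:
            return cutoff
        if cutoff is None:
            return since
        return max(since, cutoff)


class InMemoryDelegate(PlatformDelegate):
    """Delegate over a :class:`MockPlatform` living in the same process."""

    def __init__(self, config: PlatformConfig, platform: MockPlatform):
        super().__init__(config)
        self.platform = platform
        if platform.token is not None and platform.token != config.credential:
            raise AuthError(
                f"credential rejected by platform {platform.name!r}"
            )

    def list_types(self) -> list[MaskDescriptor]:
        return self.platform.list_types()

    def list_entries(self, mask_name: str, since: Optional[datetime] = None) -> list[Entry]:
        return self.platform.list_entries(
            mask_name, scope=self.config.scope, since=self.effective_since(since)
        )

    def read_entry(self, mask_name: str, entry_id: str) -> Entry:
        return self.platform.read_entry(mask_name, entry_id)

    def write_entry(self, mask_name: str, entry_id: str, payload: dict) -> Entry:
        return self.platform.write_entry(mask_name, entry_id, payload)

    def create_entry(self, mask_name: str, payload: dict) -> Entry:
        return self.platform.create_entry(mask_name, payload, collection=self.config.scope)


# --------------------------------------------------------------------------
# generic REST delegate + WSGI mock server


def _entry_to_json(entry: Entry) -> dict:
    return {
        "platform_id": entry.platform_id,
        "mask_name": entry.mask_name,
        "mask_version": entry.mask_version,
        "entry_id": entry.entry_id,
        "updated_at": entry.updated_at.isoformat(),
        "payload": entry.payload,
    }


def _entry_from_json(data: dict) -> Entry:
    return Entry.model_validate(data)


class RestDelegate(PlatformDelegate):
    """Delegate for a platform exposing the contract over HTTP+JSON.

    Endpoints: ``GET /types``, ``GET /entries/{mask}``, ``GET|PUT
    /entries/{mask}/{id}``, ``POST /entries/{mask}``; authentication by
    ``Authorization: Bearer <credential>``.
    """

    def __init__(self, config: PlatformConfig, timeout: float = 10.0):
        super().__init__(config)
        self.base = config.endpoint.rstrip("/")
        self.timeout = timeout

    def _request(self, method: str, path: str, query: Optional[dict] = None, body: Any = None):
        url = self.base + path
        if query:
            url += "?" + urllib.parse.urlencode({k: v for k, v in query.items() if v is not None})
        data = json.dumps(body).encode() if body is not None else None
        req = urllib.request.Request(url, data=data, method=method)
        req.add_header("Authorization", f"Bearer {self.config.credential}")
        if data is not None:
            req.add_header("Content-Type", "application/json")
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return json.loads(resp.read().decode() or "null")
        except urllib.error.HTTPError as exc:
            detail = exc.read().decode(errors="replace")
            try:
                detail = json.loads(detail).get("error", detail)
            except (json.JSONDecodeError, AttributeError):
                pass
            if exc.code == 401:
                raise AuthError(detail) from exc
            if exc.code == 404:
                if isinstance(detail, str) and detail.startswith("mask:"):
                    raise UnknownMaskError(detail[len("mask:") :].strip()) from exc
                raise UnknownEntryError(detail) from exc
            if exc.code == 422:
                raise SchemaViolation(detail) from exc
            if exc.code == 400 and "collection" in detail:
                raise UnknownScopeError(detail) from exc
            raise DelegateError(f"HTTP {exc.code}: {detail}") from exc
        except urllib.error.URLError as exc:
            raise DelegateError(f"cannot reach {url}: {exc.reason}") from exc

    def list_types(self) -> list[MaskDescriptor]:
        return [MaskDescriptor.from_dict(m) for m in self._request("GET", "/types")]

    def list_entries(self, mask_name: str, since: Optional[datetime] = None) -> list[Entry]:
        effective = self.effective_since(since)
        data = self._request(
            "GET",
            f"/entries/{urllib.parse.quote(mask_name, safe='')}",
            query={
                "scope": self.config.scope,
                "since": effective.isoformat() if effective else None,
            },
        )
        return [_entry_from_json(e) for e in data]

    def read_entry(self, mask_name: str, entry_id: str) -> Entry:
        data = self._request(
            "GET",
            f"/entries/{urllib.parse.quote(mask_name, safe='')}/{urllib.parse.quote(entry_id, safe='')}",
        )
        return _entry_from_json(data)

    def write_entry(self, mask_name: str, entry_id: str, payload: dict) -> Entry:
        data = self._request(
            "PUT",
            f"/entries/{urllib.parse.quote(mask_name, safe='')}/{urllib.parse.quote(entry_id, safe='')}",
            body={"payload": payload},
        )
        return _entry_from_json(data)

    def create_entry(self, mask_name: str, payload: dict) -> Entry:
        data = self._request(
            "POST",
            f"/entries/{urllib.parse.quote(mask_name, safe='')}",
            body={"payload": payload, "collection": self.config.scope},
        )
        return _entry_from_json(data)


def make_wsgi_app(platform: MockPlatform, token: Optional[str] = None) -> Callable:
    """Serve *platform* through the REST contract endpoints (WSGI callable)."""
    expected = token if token is not None else platform.token

    def respond(start_response, status: str, body: Any):
        blob = json.dumps(body).encode()
        start_response(status, [("Content-Type", "application/json")])
        return [blob]

    def app(environ, start_response):
        auth = environ.get("HTTP_AUTHORIZATION", "")
        if expected is not None and auth != f"Bearer {expected}":
            return respond(start_response, "401 Unauthorized", {"error": "bad credential"})
        method = environ["REQUEST_METHOD"]
        parts = [p for p in environ.get("PATH_INFO", "").split("/") if p]
        query = urllib.parse.parse_qs(environ.get("QUERY_STRING", ""))
        try:
            if parts == ["types"] and method == "GET":
                return respond(
                    start_response, "200 OK", [m.to_dict() for m in platform.list_types()]
                )
            if len(parts) >= 2 and parts[0] == "entries":
                mask = urllib.parse.unquote(parts[1])
                if len(parts) == 2 and method == "GET":
                    scope = query.get("scope", [None])[0]
                    since_raw = query.get("since", [None])[0]
                    since = datetime.fromisoformat(since_raw) if since_raw else None
                    entries = platform.list_entries(mask, scope=scope, since=since)
                    return respond(
                        start_response, "200 OK", [_entry_to_json(e) for e in entries]
                    )
                if len(parts) == 2 and method == "POST":
                    body = _read_body(environ)
                    entry = platform.create_entry(
                        mask, body.get("payload", {}), collection=body.get("collection")
                    )
                    return respond(start_response, "200 OK", _entry_to_json(entry))
                if len(parts) == 3:
                    entry_id = urllib.parse.unquote(parts[2])
                    if method == "GET":
                        entry = platform.read_entry(mask, entry_id)
                        return respond(start_response, "200 OK", _entry_to_json(entry))
                    if method == "PUT":
                        body = _read_body(environ)
                        entry = platform.write_entry(mask, entry_id, body.get("payload", {}))
                        return respond(start_response, "200 OK", _entry_to_json(entry))
            return respond(start_response, "404 Not Found", {"error": "no such route"})
        except UnknownMaskError as exc:
            return respond(start_response, "404 Not Found", {"error": f"mask: {exc}"})
        except UnknownEntryError as exc:
            return respond(start_response, "404 Not Found", {"error": str(exc)})
        except UnknownScopeError as exc:
            return respond(start_response, "400 Bad Request", {"error": f"collection: {exc}"})
        except SchemaViolation as exc:
            return respond(start_response, "422 Unprocessable Entity", {"error": str(exc)})

    def _read_body(environ) -> dict:
        length = int(environ.get("CONTENT_LENGTH") or 0)
        raw = environ["wsgi.input"].read(length) if length else b"{}"
        return json.loads(raw.decode() or "{}")

    return app
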