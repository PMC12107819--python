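"""Dot-path navigation inside tree-structured entry payloads.

Entry payloads are trees of dicts (string keys), lists and scalars — the
in-memory image of each platform's JSON representation of an entry.  Fields
are addressed by *dot-paths* such as ``properties.name`` or
``values.components.0.amount``: a purely numeric segment is a 0-based list
index, anything else is a map key.

``get_path`` never raises on missing nodes; it returns the :data:`ABSENT`
sentinel so callers can distinguish "field not present" from a stored
``None``.  ``set_path`` has value semantics: it returns a new tree sharing
unmodified branches with the input, which is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterator, Union

__all__ = [
    "ABSENT",
    "DotPath",
    "MalformedPathError",
    "PathTypeError",
    "get_path",
    "set_path",
]

Segment = Union[str, int]


class _Absent:
    """Singleton marker distinguishing a missing node from a stored None."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "<absent>"

    def __bool__(self) -> bool:
        return False


ABSENT = _Absent()


class MalformedPathError(ValueError):
    """Raised when dot-path text cannot be parsed into segments."""


class PathTypeError(TypeError):
    """Raised when a write would index through an incompatible node type."""


@dataclass(frozen=True)
class DotPath:
    """A parsed navigational path: map keys and 0-based list indices."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise MalformedPathError("a dot-path needs at least one segment")
        for seg in self.segments:
            if isinstance(seg, int):
                if seg < 0:
                    raise MalformedPathError(f"negative list index {seg!r}")
            elif isinstance(seg, str):
                if not seg:
                    raise MalformedPathError("empty path segment")
            else:  # pragma: no cover - defensive
                raise MalformedPathError(f"bad segment type {type(seg).__name__}")

    @classmethod
    def parse(cls, text: str) -> "DotPath":
        if not isinstance(text, str) or not text or text != text.strip():
            raise MalformedPathError(f"malformed dot-path {text!r}")
        segments: list[Segment] = []
        for raw in text.split("."):
            if raw == "":
                raise MalformedPathError(f"empty segment in dot-path {text!r}")
            segments.append(int(raw) if raw.isdigit() else raw)
        return cls(tuple(segments))

    def __str__(self) -> str:
        return ".".join(str(s) for s in self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)


def _as_path(path: Union[str, DotPath]) -> DotPath:
    return path if isinstance(path, DotPath) else DotPath.parse(path)


def get_path(payload: Any, path: Union[str, DotPath]) -> Any:
    """Return the node addressed by *path*, or :data:`ABSENT`.

    Missing intermediate nodes, out-of-range indices and type mismatches
    (e.g. a string segment into a list) all yield ``ABSENT`` — reads are
    total over any tree.
    """
    node = payload
    for seg in _as_path(path):
        if isinstance(seg, int):
            if isinstance(node, list) and 0 <= seg < len(node):
                node = node[seg]
            else:
                return ABSENT
        else:
            if isinstance(node, dict) and seg in node:
                node = node[seg]
            else:
                return ABSENT
    return node


def set_path(payload: Any, path: Union[str, DotPath], value: Any) -> Any:
    """Return a new tree equal to *payload* with *path* set to *value*.

    Missing intermediate map nodes are created; a missing node under an
    integer segment becomes a list padded with ``None`` up to the index.
    Indexing through an existing scalar raises :class:`PathTypeError`.
    The input tree is not modified.
    """
    segments = _as_path(path).segments
    return _set(payload, segments, value, prefix=())


def _set(node: Any, segments: tuple[Segment, ...], value: Any, prefix: tuple[Segment, ...]) -> Any:
    if not segments:
        return value
    seg, rest = segments[0], segments[1:]
    where = ".".join(str(s) for s in prefix) or "<root>"
    if isinstance(seg, int):
        if node is None or node is ABSENT:
            node = []
        if not isinstance(node, list):
            raise PathTypeError(
                f"cannot index {type(node).__name__} node at {where!r} with list index {seg}"
            )
        new_list = list(node)
        while len(new_list) <= seg:
            new_list.append(None)
        new_list[seg] = _set(new_list[seg], rest, value, prefix + (seg,))
        return new_list
    else:
        if node is None or node is ABSENT:
            node = {}
        if not isinstance(node, dict):
            raise PathTypeError(
                f"cannot descend into {type(node).__name__} node at {where!r} with key {seg!r}"
            )
        new_map = dict(node)
        new_map[seg] = _set(new_map.get(seg, ABSENT), rest, value, prefix + (seg,))
        return new_map
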