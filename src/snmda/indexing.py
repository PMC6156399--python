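"""Ordered, bijective name <-> position maps for diseases and miRNAs.

Every matrix in the pipeline carries one (or two) of these so that rows
and columns are always addressable by entity name, never by bare integer.
Identifiers are opaque strings; no database-specific validation is done.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator


class EntityIndex:
    """Immutable ordered index over a set of unique entity names."""

    __slots__ = ("names", "position")

    def __init__(self, names: Iterable[str]) -> None:
        names = tuple(str(n) for n in names)
        if len(set(names)) != len(names):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))
            raise ValueError(f"duplicate entity name: {dup!r}")
        self.names: tuple[str, ...] = names
        self.position: dict[str, int] = {n: i for i, n in enumerate(names)}

    @classmethod
    def sorted(cls, names: Iterable[str]) -> "EntityIndex":
        """Build an index with lexicographically sorted names (deterministic)."""
        return cls(sorted(set(str(n) for n in names)))

    def index(self, name: str) -> int:
        try:
            return self.position[name]
        except KeyError:
            raise KeyError(f"unknown entity: {name!r}") from None

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.position

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def __getitem__(self, i: int) -> str:
        return self.names[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EntityIndex):
            return NotImplemented
        return self.names == other.names

    def __hash__(self) -> int:
        return hash(self.names)

    def __repr__(self) -> str:
        preview = ", ".join(self.names[:3])
        suffix = ", ..." if len(self.names) > 3 else ""
        return f"EntityIndex([{preview}{suffix}], n={len(self.names)})"
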