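"""Cut-set value type shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CutSet:
    """An (ordered-insensitive) set of reaction deletions.

    ``is_mcs``/``is_cmcs`` record the status assigned by enumeration and the
    desired-behaviour filter; ``None`` means "not determined".
    """

    reactions: frozenset
    is_mcs: bool | None = None
    is_cmcs: bool | None = None

    def __post_init__(self):
        object.__setattr__(self, "reactions", frozenset(self.reactions))

    @property
    def size(self) -> int:
        return len(self.reactions)

    def sorted(self) -> tuple:
        return tuple(sorted(self.reactions))

    def __iter__(self):
        return iter(self.reactions)

    def __contains__(self, rid) -> bool:
        return rid in self.reactions

    def __le__(self, other) -> bool:
        return self.reactions <= other.reactions

    def __repr__(self) -> str:
        flags = ""
        if self.is_cmcs:
            flags = ", cMCS"
        elif self.is_mcs:
            flags = ", MCS"
        return f"CutSet({{{', '.join(self.sorted())}}}{flags})"


def sort_cutsets(cutsets) -> list:
    """Canonical order: by size, then lexicographic by member ids."""
    return sorted(cutsets, key=lambda c: (c.size, c.sorted()))
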