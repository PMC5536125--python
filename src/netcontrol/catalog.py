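"""Protein-complex catalog: named, possibly overlapping protein sets."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ComplexCatalog:
    complexes: dict[str, set[str]]
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name, members in self.complexes.items():
            if not members:
                raise ValueError(f"complex {name!r} is empty")

    def membership(self) -> set[str]:
        """Union of all complex member sets."""
        out: set[str] = set()
        for members in self.complexes.values():
            out |= members
        return out

    def complexes_of(self, node_id: str) -> list[str]:
        return sorted(n for n, m in self.complexes.items() if node_id in m)

    def __len__(self) -> int:
        return len(self.complexes)
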