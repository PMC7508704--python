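"""In-memory containers for RNA chains with heavy-atom coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .secondary_structure import BasePair, SecondaryStructure


@dataclass(eq=False)
class AtomRecord:
    """One heavy atom: PDB-style name, element symbol and position in Å."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass(eq=False)
class ResidueRecord:
    """One nucleotide: deposited name, mapped parent base, atoms, 1-based index."""

    original_name: str
    parent_base: Optional[str]
    atoms: list[AtomRecord]
    index: int

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    def coords(self, names: Optional[Iterable[str]] = None) -> np.ndarray:
        if names is None:
            return np.array([a.position for a in self.atoms])
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                raise KeyError(f"residue {self.index} ({self.original_name}) has no atom {n!r}")
            out.append(a.position)
        return np.array(out)

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            self.original_name,
            self.parent_base,
            [AtomRecord(a.name, a.element, a.position.copy()) for a in self.atoms],
            self.index,
        )


@dataclass(eq=False)
class RnaChain:
    """An ordered 5'->3' run of residues extracted from one structure."""

    source_id: str
    chain_id: str
    residues: list[ResidueRecord]
    removed_crossing_pairs: frozenset = frozenset()
    secondary_structure: Optional["SecondaryStructure"] = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.parent_base or "N" for r in self.residues)

    def residue(self, index: int) -> ResidueRecord:
        """1-based access; assumes indices are contiguous after sanitation."""
        res = self.residues[index - 1]
        if res.index != index:
            raise KeyError(f"chain {self.chain_id}: residue indices not contiguous at {index}")
        return res

    def reindex(self) -> None:
        for k, res in enumerate(self.residues, start=1):
            res.index = k

    def copy(self) -> "RnaChain":
        return RnaChain(
            self.source_id,
            self.chain_id,
            [r.copy() for r in self.residues],
            self.removed_crossing_pairs,
            self.secondary_structure,
        )
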