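"""Secondary-structure representation.

A secondary structure is a set of canonical base pairs on a sequence of
``length`` nucleotides.  Indices are 0-based internally; every file format
and user-facing report uses 1-based coordinates (the converters in
:mod:`shapefold.io` are the only crossing point).

Structures are pseudoknot-free: pairs are properly nested, each nucleotide
participates in at most one pair, and every hairpin loop encloses at least
``min_hairpin`` unpaired nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

DEFAULT_MIN_HAIRPIN = 3


class StructureError(ValueError):
    """Raised when a pair set violates the secondary-structure invariants."""


@dataclass(frozen=True)
class SecondaryStructure:
    """One conformation: an immutable set of base pairs.

    Parameters
    ----------
    length : int
        Number of nucleotides.
    pairs : frozenset of (int, int)
        0-based index pairs with ``i < j``.
    """

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(tuple(p) for p in self.pairs))

    @classmethod
    def from_pairs(cls, length: int, pairs: Iterable[tuple[int, int]],
                   min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> "SecondaryStructure":
        """Build and validate a structure from an iterable of 0-based pairs."""
        s = cls(length, frozenset((min(i, j), max(i, j)) for i, j in pairs))
        s.validate(min_hairpin=min_hairpin)
        return s

    def validate(self, min_hairpin: int = DEFAULT_MIN_HAIRPIN) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise StructureError(f"pair ({i}, {j}) out of range for length {self.length}")
            if j - i <= min_hairpin:
                raise StructureError(
                    f"pair ({i}, {j}) encloses {j - i - 1} nt, fewer than min_hairpin={min_hairpin}")
            for k in (i, j):
                if k in seen:
                    raise StructureError(f"nucleotide {k} appears in more than one pair")
                seen.add(k)
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i, j = plist[a]
            for b in range(a + 1, len(plist)):
                k, l = plist[b]
                if k > j:
                    break
                if i < k <= j < l:
                    raise StructureError(f"pseudoknot: pairs ({i},{j}) and ({k},{l}) cross")

    def partner(self) -> np.ndarray:
        """Partner index per position, -1 where unpaired."""
        p = np.full(self.length, -1, dtype=np.int64)
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return p

    def pair_indicator(self, pair_index: dict[tuple[int, int], int], n_pairs: int) -> np.ndarray:
        """Binary indicator vector over a fixed enumeration of candidate pairs."""
        v = np.zeros(n_pairs, dtype=np.float64)
        for p in self.pairs:
            if p in pair_index:
                v[pair_index[p]] = 1.0
        return v

    def to_dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        stack: list[int] = []
        pairs = set()
        for idx, c in enumerate(db):
            if c == "(":
                stack.append(idx)
            elif c == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {idx + 1}")
                pairs.add((stack.pop(), idx))
            elif c != ".":
                raise StructureError(f"invalid dot-bracket character {c!r} at position {idx + 1}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
        return cls(len(db), frozenset(pairs))

    def children_map(self) -> dict[tuple[int, int] | None, list[tuple[int, int]]]:
        """Loop-decomposition tree: for each pair (and the exterior loop, keyed
        by ``None``) the list of directly nested pairs, in 5'→3' order."""
        tree: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
        stack: list[tuple[int, int]] = []
        for p in sorted(self.pairs):
            while stack and p[0] > stack[-1][1]:
                stack.pop()
            parent = stack[-1] if stack else None
            tree.setdefault(parent, []).append(p)
            tree.setdefault(p, [])
            stack.append(p)
        return tree

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)
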