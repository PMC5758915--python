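"""Nearest-neighbor thermodynamic model.

A deliberately compact free-energy model for RNA secondary structure:
sequence-dependent base-pair stack increments, logarithmic size penalties
for hairpin and internal/bulge loops, and a linear multibranch-loop term
(offset + per-branch + per-unpaired).  Dangling ends and coaxial stacking
are omitted (extension points).  All values live in an editable flat
parameter file; a default set ships with the package.

Free energies are in kcal/mol throughout.  The per-nucleotide
pseudo-free-energy restraint enters here: when a bonus vector is supplied,
each base-pair stack additionally contributes the bonus of each of its four
nucleotide positions, once per stack occurrence — so nucleotides interior
to a helix receive their bonus twice (two stacks) and helix-end nucleotides
once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .structure import SecondaryStructure, StructureError

GAS_CONSTANT = 1.9872042586e-3  # kcal/(mol·K)

WC_WOBBLE_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")


class ParameterError(ValueError):
    """Raised when a thermodynamic parameter file is incomplete or malformed."""


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the folding calculation.

    Attributes
    ----------
    R : float
        Gas constant, kcal/(mol·K).
    T : float
        Absolute temperature in kelvin.  Default 310.15 K (37 °C).
    """

    T: float = 310.15
    R: float = GAS_CONSTANT

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")

    @property
    def kT(self) -> float:
        """Thermal energy R·T, kcal/mol."""
        return self.R * self.T


@dataclass(frozen=True)
class NearestNeighborParams:
    """Free-energy parameter set for the simplified nearest-neighbor model."""

    stack_energies: dict[tuple[str, str], float]
    hairpin_base: float
    hairpin_log_coeff: float
    internal_base: float
    internal_log_coeff: float
    multibranch_offset: float
    multibranch_per_branch: float
    multibranch_per_unpaired: float
    allowed_pairs: frozenset = frozenset(WC_WOBBLE_PAIRS)
    min_hairpin: int = 3

    def __post_init__(self):
        if self.min_hairpin < 3:
            raise ParameterError(f"min_hairpin must be >= 3, got {self.min_hairpin}")
        for key, value in self.stack_energies.items():
            outer, inner = key
            if outer not in self.allowed_pairs or inner not in self.allowed_pairs:
                raise ParameterError(f"stack key {key} uses a disallowed pair")
            if not math.isfinite(value):
                raise ParameterError(f"stack energy for {key} is not finite")

    def hairpin_penalty(self, size: int) -> float:
        """Hairpin-loop closure penalty for ``size`` unpaired nucleotides."""
        n = max(size, self.min_hairpin)
        return self.hairpin_base + self.hairpin_log_coeff * math.log(n / self.min_hairpin)

    def internal_bulge_penalty(self, size: int) -> float:
        """Internal/bulge-loop penalty for ``size`` total unpaired nucleotides."""
        return self.internal_base + self.internal_log_coeff * math.log(max(size, 1))

    def multibranch_penalty(self, n_branches: int, n_unpaired: int) -> float:
        """Linear multibranch-loop term; ``n_branches`` counts the closing helix."""
        return (self.multibranch_offset
                + self.multibranch_per_branch * n_branches
                + self.multibranch_per_unpaired * n_unpaired)

    def pair_allowed(self, a: str, b: str) -> bool:
        return a + b in self.allowed_pairs


_SECTIONS = ("stacks", "hairpin", "internal", "multibranch", "general")


def _parse_param_text(text: str, origin: str) -> NearestNeighborParams:
    sections: dict[str, list[tuple[str, ...]]] = {}
    current: str | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip().lower()
            if current not in _SECTIONS:
                raise ParameterError(f"{origin}:{lineno}: unknown section [{current}]")
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ParameterError(f"{origin}:{lineno}: entry before any section header")
        sections[current].append(tuple(line.split()))

    for required in ("stacks", "hairpin", "internal", "multibranch"):
        if required not in sections:
            raise ParameterError(f"{origin}: missing [{required}] table")

    def scalar_table(name: str, keys: dict[str, float | int]) -> dict[str, float]:
        out = dict(keys)
        for entry in sections.get(name, ()):
            if len(entry) != 2:
                raise ParameterError(f"{origin}: [{name}] entry {' '.join(entry)!r} "
                                     "is not 'key value'")
            key, val = entry
            if key not in out:
                raise ParameterError(f"{origin}: [{name}] has unknown key {key!r}")
            try:
                out[key] = float(val)
            except ValueError:
                raise ParameterError(f"{origin}: [{name}] {key} value {val!r} is not numeric")
        missing = [k for k, v in out.items() if v is None]
        if missing:
            raise ParameterError(f"{origin}: [{name}] missing keys {missing}")
        return out

    general = scalar_table("general", {"min_hairpin": 3.0})
    min_hairpin = int(general["min_hairpin"])
    allowed = frozenset(WC_WOBBLE_PAIRS)

    stacks: dict[tuple[str, str], float] = {}
    for entry in sections["stacks"]:
        if len(entry) != 3:
            raise ParameterError(f"{origin}: [stacks] entry {' '.join(entry)!r} "
                                 "is not 'outer inner value'")
        outer, inner, val = entry[0].upper(), entry[1].upper(), entry[2]
        if outer not in allowed or inner not in allowed:
            raise ParameterError(f"{origin}: [stacks] unknown pair key {outer} {inner}")
        try:
            stacks[(outer, inner)] = float(val)
        except ValueError:
            raise ParameterError(f"{origin}: [stacks] value {val!r} for {outer}/{inner} "
                                 "is not numeric")
    missing = [k for k in ((o, i) for o in WC_WOBBLE_PAIRS for i in WC_WOBBLE_PAIRS)
               if k not in stacks]
    if missing:
        raise ParameterError(f"{origin}: [stacks] missing {len(missing)} entries, "
                             f"first {missing[0]}")

    hp = scalar_table("hairpin", {"base": None, "log_coeff": None})
    il = scalar_table("internal", {"base": None, "log_coeff": None})
    mb = scalar_table("multibranch", {"offset": None, "per_branch": None,
                                      "per_unpaired": None})
    return NearestNeighborParams(
        stack_energies=stacks,
        hairpin_base=hp["base"], hairpin_log_coeff=hp["log_coeff"],
        internal_base=il["base"], internal_log_coeff=il["log_coeff"],
        multibranch_offset=mb["offset"], multibranch_per_branch=mb["per_branch"],
        multibranch_per_unpaired=mb["per_unpaired"],
        allowed_pairs=allowed, min_hairpin=min_hairpin,
    )


def load_params(source: str | Path = "default") -> NearestNeighborParams:
    """Load a nearest-neighbor parameter set.

    ``source`` is either the name of a shipped set (``"default"``) or a path
    to a flat parameter file (sections ``[stacks]``, ``[hairpin]``,
    ``[internal]``, ``[multibranch]``, optional ``[general]``).
    """
    if source == "default":
        text = resources.files("shapefold.data").joinpath("default_params.txt").read_text()
        return _parse_param_text(text, "default")
    path = Path(source)
    if not path.exists():
        raise ParameterError(f"parameter file {path} does not exist")
    return _parse_param_text(path.read_text(), str(path))


def validate_structure(seq: str, s: SecondaryStructure,
                       params: NearestNeighborParams) -> None:
    """Check a structure against a sequence under the model's constraints."""
    if len(seq) != s.length:
        raise StructureError(f"structure length {s.length} != sequence length {len(seq)}")
    s.validate(min_hairpin=params.min_hairpin)
    for i, j in s.pairs:
        if not params.pair_allowed(seq[i], seq[j]):
            raise StructureError(f"pair ({i + 1}, {j + 1}) {seq[i]}-{seq[j]} is not canonical")


def stack_occurrences(s: SecondaryStructure) -> list[tuple[int, int]]:
    """Outer pairs (i, j) such that (i+1, j-1) is also paired — one entry per
    base-pair stack."""
    return [(i, j) for i, j in s.pairs if (i + 1, j - 1) in s.pairs]


def stack_counts(s: SecondaryStructure) -> np.ndarray:
    """Number of stacks containing each nucleotide (0, 1 or 2)."""
    counts = np.zeros(s.length, dtype=np.int64)
    for i, j in stack_occurrences(s):
        for k in (i, i + 1, j - 1, j):
            counts[k] += 1
    return counts


def structure_energy(seq: str, s: SecondaryStructure, params: NearestNeighborParams,
                     bonus: np.ndarray | None = None) -> float:
    """Loop-decomposition free energy of one structure, kcal/mol.

    The energy is the sum over loops: stack increments for stacked pairs,
    size penalties for hairpin and internal/bulge loops, and the linear
    multibranch term.  The exterior loop contributes zero.  With ``bonus``
    supplied, each stack adds the bonuses of its four positions.
    """
    validate_structure(seq, s, params)
    if bonus is not None and len(bonus) != s.length:
        raise ValueError(f"bonus length {len(bonus)} != sequence length {s.length}")

    tree = s.children_map()
    energy = 0.0
    for parent, children in tree.items():
        if parent is None:
            continue  # exterior loop: no penalty
        i, j = parent
        if not children:
            energy += params.hairpin_penalty(j - i - 1)
        elif len(children) == 1:
            k, l = children[0]
            if k == i + 1 and l == j - 1:
                energy += params.stack_energies[(seq[i] + seq[j], seq[k] + seq[l])]
            else:
                energy += params.internal_bulge_penalty((k - i - 1) + (j - l - 1))
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            energy += params.multibranch_penalty(len(children) + 1, unpaired)

    if bonus is not None:
        b = np.asarray(bonus, dtype=np.float64)
        for i, j in stack_occurrences(s):
            energy += b[i] + b[i + 1] + b[j - 1] + b[j]
    return float(energy)
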