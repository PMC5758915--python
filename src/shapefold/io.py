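"""Readers and writers for the standard plain-text formats.

FASTA (sequence in), two-column SHAPE reactivity files (1-based index,
normalized reactivity, sentinel <= -500 for missing data), CT files and
dot-bracket strings (structures in/out).  Everything on disk is 1-based;
the in-memory representation is 0-based, and these functions are the only
crossing point between the two conventions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .partition import clean_sequence
from .reactivity import MISSING, ReactivityProfile
from .structure import SecondaryStructure

MISSING_THRESHOLD = -500.0


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending location."""


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA file.

    Returns ``(description, sequence)`` with the sequence uppercased and
    T mapped to U.  Multi-record files are rejected with guidance.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise FormatError(f"{path}: {len(records)} records found; supply one "
                          "sequence per file (split the file and run each "
                          "sequence separately)")
    rec = records[0]
    try:
        seq = clean_sequence(str(rec.seq))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not seq:
        raise FormatError(f"{path}: empty sequence")
    return rec.description, seq


def read_shape(path: str | Path, length: int) -> ReactivityProfile:
    """Read a two-column SHAPE file (1-based index, reactivity).

    Indices absent from the file, and entries at or below the -500
    sentinel threshold, are flagged missing.
    """
    values = np.full(length, MISSING)
    mask = np.ones(length, dtype=bool)
    seen: set[int] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'index reactivity', "
                              f"got {raw!r}")
        try:
            idx = int(fields[0])
            val = float(fields[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric entry in {raw!r}")
        if not (1 <= idx <= length):
            raise FormatError(f"{path}:{lineno}: index {idx} out of range "
                              f"1..{length}")
        if idx in seen:
            raise FormatError(f"{path}:{lineno}: duplicate index {idx}")
        seen.add(idx)
        if val <= MISSING_THRESHOLD:
            continue
        values[idx - 1] = val
        mask[idx - 1] = False
    return ReactivityProfile(values, mask)


def write_shape(path: str | Path, profile: ReactivityProfile) -> None:
    lines = []
    for i, (v, m) in enumerate(zip(profile.values, profile.missing_mask), start=1):
        lines.append(f"{i}\t{MISSING if m else v:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path: str | Path) -> tuple[str, SecondaryStructure]:
    """Read a CT file (header line, then 6 columns, 1-based, 0 = unpaired)."""
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}:1: CT header must start with the count")
    if len(lines) - 1 < n:
        raise FormatError(f"{path}: header promises {n} rows, found {len(lines) - 1}")
    bases = []
    partner = np.zeros(n + 1, dtype=np.int64)
    for row in range(1, n + 1):
        fields = lines[row].split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{row + 1}: expected 6 CT columns")
        idx = int(fields[0])
        if idx != row:
            raise FormatError(f"{path}:{row + 1}: index {idx} out of order")
        bases.append(fields[1])
        partner[idx] = int(fields[4])
    pairs = set()
    for i in range(1, n + 1):
        j = partner[i]
        if j == 0:
            continue
        if not (1 <= j <= n) or partner[j] != i:
            raise FormatError(f"{path}: inconsistent pairing: {i} pairs {j} "
                              f"but {j} pairs {partner[j] if 1 <= j <= n else '?'}")
        if i < j:
            pairs.add((i - 1, j - 1))
    seq = clean_sequence("".join(bases))
    return seq, SecondaryStructure(n, frozenset(pairs))


def write_ct(path: str | Path, seq: str, s: SecondaryStructure,
             title: str = "") -> None:
    if len(seq) != s.length:
        raise ValueError("sequence and structure lengths differ")
    partner = s.partner()
    lines = [f"{s.length}\t{title}"]
    for i in range(s.length):
        nxt = i + 2 if i + 1 < s.length else 0
        lines.append(f"{i + 1}\t{seq[i]}\t{i}\t{nxt}\t{partner[i] + 1}\t{i + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dotbracket(path: str | Path) -> tuple[str | None, SecondaryStructure]:
    """Read a dot-bracket file: optional '>' header, optional sequence line,
    then the dot-bracket string."""
    lines = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if not lines:
        raise FormatError(f"{path}: no dot-bracket line found")
    seq = None
    db = lines[-1]
    if len(lines) >= 2:
        seq = clean_sequence(lines[-2])
    try:
        s = SecondaryStructure.from_dotbracket(db)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if seq is not None and len(seq) != s.length:
        raise FormatError(f"{path}: sequence and dot-bracket lengths differ")
    return seq, s


def write_dotbracket(path: str | Path, seq: str, s: SecondaryStructure,
                     name: str = "structure") -> None:
    Path(path).write_text(f">{name}\n{seq}\n{s.to_dotbracket()}\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: dict, files: list[str | Path],
                   extras: dict | None = None) -> None:
    """Machine-readable run manifest: resolved configuration, every output
    file with its checksum, and any extra run records (seeds, timings)."""
    manifest = {
        "config": config,
        "files": [{"path": str(Path(f).name), "sha256": file_checksum(f)}
                  for f in files],
    }
    if extras:
        manifest.update(extras)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
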