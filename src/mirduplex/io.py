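"""Readers and writers for the formats the tool touches.

FASTA is handled through Biopython.  The Vienna combined dialect is a FASTA
variant with one structure line after each sequence line, optionally followed
by the energy in parentheses, e.g.::

    >hsa-mir-21
    UAGCUUAUCAGACUGAUGUUGA...
    ..(((((.((((...))))))))).. (-24.30)
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError
from .structures import HairpinRecord

_ENERGY_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file (wrapped or unwrapped)."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], wrap: int = 60) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_vienna(path) -> list[HairpinRecord]:
    """Read the Vienna combined dialect: header, sequence, structure lines."""
    out: list[HairpinRecord] = []
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise InputError(f"{path}: expected a '>' header at line {i + 1}")
        rid = lines[i][1:].split()[0]
        if i + 2 >= len(lines) + 1 or i + 1 >= len(lines):
            raise InputError(f"{path}: truncated record {rid}")
        seq = lines[i + 1].strip()
        structure = None
        energy = None
        consumed = 2
        if i + 2 < len(lines) and not lines[i + 2].startswith(">"):
            raw = lines[i + 2].strip()
            m = _ENERGY_RE.search(raw)
            if m:
                energy = float(m.group(1))
                raw = raw[: m.start()].strip()
            structure = raw
            consumed = 3
        out.append(HairpinRecord(rid, seq, structure, energy=energy))
        i += consumed
    if not out:
        raise InputError(f"no records in {path}")
    return out


def write_vienna(path, records: Sequence[HairpinRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")
            if r.structure is not None:
                line = r.structure
                if r.energy is not None:
                    line += f" ({r.energy:.2f})"
                fh.write(line + "\n")


def read_hairpins(path) -> list[HairpinRecord]:
    """Auto-detect plain FASTA vs the Vienna combined dialect."""
    text = Path(path).read_text()
    body_lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith(">")]
    # a structure line's first token is all dots/brackets (energy may follow)
    has_structure = any(set(ln.split()[0]) <= set("().") for ln in body_lines)
    if has_structure:
        return read_vienna(path)
    return [HairpinRecord(rid, seq) for rid, seq in read_fasta(path)]
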