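"""Codon encoding and standard genetic code tables.

Codons are encoded as integers in 0..63 (base-4 over A,C,G,T); -1 marks a
codon that is not a gapless ACGT triplet. Amino acids are one-letter codes
with '*' for stop.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

INVALID = -1

#: codon index -> codon string, index 0..63
CODON_STRINGS = tuple(
    b1 + b2 + b3 for b1 in BASES for b2 in BASES for b3 in BASES
)

_table = CodonTable.unambiguous_dna_by_id[1]

#: codon index -> one-letter amino acid ('*' for stop)
AA = np.array(
    [
        "*" if c in _table.stop_codons else _table.forward_table[c]
        for c in CODON_STRINGS
    ],
    dtype="U1",
)

STOP = frozenset(
    i for i, c in enumerate(CODON_STRINGS) if c in _table.stop_codons
)


def encode_codon(codon: str) -> int:
    """Encode a 3-letter codon string; gaps, Ns etc. give INVALID."""
    if len(codon) != 3:
        return INVALID
    idx = 0
    for ch in codon.upper():
        b = _BASE_INDEX.get(ch)
        if b is None:
            return INVALID
        idx = idx * 4 + b
    return idx


def decode_codon(idx: int) -> str:
    if idx < 0:
        return "---"
    return CODON_STRINGS[idx]


def codon_aa(idx: int) -> str:
    """Amino acid of an encoded codon; '' for invalid."""
    if idx < 0:
        return ""
    return str(AA[idx])


def base_at(idx: int, pos: int) -> int:
    """Base index (0..3) at codon position pos (0..2)."""
    return (idx // (4 ** (2 - pos))) % 4


def with_base(idx: int, pos: int, base: int) -> int:
    """Encoded codon with position pos replaced by base index."""
    shift = 4 ** (2 - pos)
    old = (idx // shift) % 4
    return idx + (base - old) * shift


def _degeneracy_tables():
    """Per (codon, position) degeneracy class.

    0 = other, 1 = non-degenerate (each of the four bases yields a
    distinct amino acid), 2 = fourfold-degenerate (no base change alters
    the amino acid). Stop codons are 'other' at every position, and a
    position one of whose variants is a stop is not non-degenerate (a
    stop is not an amino acid).
    """
    cls = np.zeros((64, 3), dtype=np.int8)
    for idx in range(64):
        if idx in STOP:
            continue
        for pos in range(3):
            aas = {AA[with_base(idx, pos, b)] for b in range(4)}
            if len(aas) == 4 and "*" not in aas:
                cls[idx, pos] = 1
            elif len(aas) == 1:
                cls[idx, pos] = 2
    return cls


#: DEGENERACY[codon, pos] in {0 other, 1 non-degenerate, 2 fourfold}
DEGENERACY = _degeneracy_tables()

#: BASE_AT[codon, pos] = base index at that position
BASE_AT = np.array(
    [[(i // 16) % 4, (i // 4) % 4, i % 4] for i in range(64)], dtype=np.int8
)
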