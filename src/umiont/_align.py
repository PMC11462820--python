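"""Shared edit-distance alignment helpers built on edlib.

All pileup-style operations in the package anchor a query sequence onto the
single-unit reference and express it as one row of base codes over reference
positions.  Codes: 0..3 = A,C,G,T, 4 = deletion (reference base absent from
the query), 255 = reference position not covered by the alignment.
Insertions (query bases absent from the reference) are returned separately,
keyed by the reference junction after which they occur.
"""

from __future__ import annotations

import re

import edlib
import numpy as np

A, C, G, T, DEL = 0, 1, 2, 3, 4
UNCOVERED = 255

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = "ACGT-"

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_ENC_TABLE = np.full(256, UNCOVERED, dtype=np.uint8)
for _b, _c in _BASE_TO_CODE.items():
    _ENC_TABLE[ord(_b)] = _c
    _ENC_TABLE[ord(_b.lower())] = _c


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A,C,G,T -> 0..3; anything else 255)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[c] for c in codes)


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Levenshtein distance with unit costs; -1 if a cap ``k`` is exceeded."""
    if a == b:
        return 0
    return edlib.align(a, b, mode="NW", k=k)["editDistance"]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def project_onto_reference(seq: str, reference: str):
    """Anchor ``seq`` onto ``reference`` (reference global, seq infix-free).

    The reference is aligned end-to-end while flanking bases of ``seq``
    (adapters, UMIs) are ignored, which suits full-length amplicon reads and
    consensus sequences.  Returns ``(row, insertions, n_edits)`` where ``row``
    is a uint8 array of length ``len(reference)`` (codes as module docstring)
    and ``insertions`` maps a 0-based reference junction ``j`` (insertion
    between reference positions j-1 and j) to the inserted string.
    """
    res = edlib.align(reference, seq, mode="HW", task="path")
    start = res["locations"][0][0]
    row = np.full(len(reference), UNCOVERED, dtype=np.uint8)
    insertions: dict[int, str] = {}
    seq_codes = encode(seq)
    r = 0  # reference cursor
    q = start  # seq cursor
    for n, op in parse_cigar(res["cigar"]):
        if op in "=XM":
            row[r : r + n] = seq_codes[q : q + n]
            r += n
            q += n
        elif op == "I":  # consumes query (= reference) only: deletion in seq
            row[r : r + n] = DEL
            r += n
        else:  # "D": consumes target (= seq) only: insertion relative to ref
            insertions[r] = seq[q : q + n]
            q += n
    return row, insertions, res["editDistance"]
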