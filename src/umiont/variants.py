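"""Variant-level calling on pileups of consensus sequences (or raw reads,
the UMI-free comparison mode) and benchmarking against a truth set.

The variant level of an allele is the fraction of sequences carrying it at
a position.  On a VNTR, a variant private to one of K repeat units sits at
level ~1/K, so the caller thresholds on level rather than on a genotype
model; the default floor of 0.85% sits below the 1.25% single-unit level of
an 80-unit locus while staying above residual background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import UNCOVERED, encode, project_onto_reference
from .seqio import VariantRow

_CODE_TO_BASE = "ACGT"
DEFAULT_MIN_LEVEL = 0.0085


@dataclass
class PileupColumn:
    position: int  # 1-based
    counts: dict[str, int]  # allele -> count ('A','C','G','T','-', '+SEQ')
    depth: int


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    tn: int

    @staticmethod
    def _ratio(num: int, denom: int) -> float | None:
        return num / denom if denom > 0 else None

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def f1(self) -> float | None:
        p, s = self.precision, self.sensitivity
        if p is None or s is None or p + s == 0:
            return None
        return 2 * p * s / (p + s)

    def as_frame(self) -> pd.DataFrame:
        rows = [("TP", self.tp), ("FP", self.fp), ("FN", self.fn), ("TN", self.tn)]
        for name in ("sensitivity", "specificity", "precision", "f1"):
            v = getattr(self, name)
            rows.append((name, float("nan") if v is None else round(v, 6)))
        return pd.DataFrame(rows, columns=["metric", "value"])


def alignment_matrix(sequences: list[str], reference: str):
    """Project sequences onto the reference: (n, L) uint8 base-code matrix
    plus per-sequence insertion dicts."""
    rows = np.empty((len(sequences), len(reference)), dtype=np.uint8)
    all_ins = []
    for i, seq in enumerate(sequences):
        row, ins, _ = project_onto_reference(seq, reference)
        rows[i] = row
        all_ins.append(ins)
    return rows, all_ins


def pileup(
    sequences: list[str],
    reference: str,
    matrix: np.ndarray | None = None,
    insertions: list[dict[int, str]] | None = None,
) -> list[PileupColumn]:
    """Per-position allele counts over aligned sequences.

    ``sequences`` may be consensus sequences (UMI mode) or raw reads
    (UMI-free mode); a precomputed :func:`alignment_matrix` can be passed to
    avoid re-aligning.
    """
    if not sequences and matrix is None:
        raise ValueError("empty input")
    if matrix is None:
        matrix, insertions = alignment_matrix(sequences, reference)
    L = matrix.shape[1]
    cols: list[PileupColumn] = []
    per_code = [(matrix == v).sum(axis=0) for v in range(5)]
    ins_at: dict[int, dict[str, int]] = {}
    if insertions:
        for ins in insertions:
            for junction, seq in ins.items():
                ins_at.setdefault(junction, {}).setdefault("+" + seq, 0)
                ins_at[junction]["+" + seq] += 1
    for pos in range(L):
        counts = {}
        for v in range(4):
            c = int(per_code[v][pos])
            if c:
                counts[_CODE_TO_BASE[v]] = c
        d = int(per_code[4][pos])
        if d:
            counts["-"] = d
        for tok, c in ins_at.get(pos, {}).items():
            counts[tok] = c
        depth = int(matrix.shape[0] - (matrix[:, pos] == UNCOVERED).sum())
        cols.append(PileupColumn(pos + 1, counts, depth))
    return cols


def call_variants(
    columns: list[PileupColumn],
    reference: str,
    min_level: float = DEFAULT_MIN_LEVEL,
    call_indels: bool = False,
) -> list[VariantRow]:
    """Emit every non-reference allele whose level strictly exceeds
    ``min_level``; multiple alternate alleles per position are allowed.
    Indel alleles are skipped unless ``call_indels``."""
    ref_codes = encode(reference)
    out: list[VariantRow] = []
    for col in columns:
        if col.depth == 0:
            continue
        ref_base = _CODE_TO_BASE[ref_codes[col.position - 1]]
        for allele, count in sorted(col.counts.items()):
            if allele == ref_base:
                continue
            if (allele == "-" or allele.startswith("+")) and not call_indels:
                continue
            level = count / col.depth
            if level > min_level:
                out.append(
                    VariantRow(col.position, ref_base, allele, level, count, col.depth)
                )
    return out


def benchmark(
    calls: list[VariantRow],
    truth: pd.DataFrame,
    assayable_positions: list[int],
) -> BenchmarkResult:
    """Compare calls with a truth table over the assayable positions.

    ``truth`` needs columns position/alt.  A call is a true positive iff its
    (position, alt) pair appears in the truth; true negatives are counted
    per assayable position carrying neither a truth variant nor a call.
    """
    if not assayable_positions:
        raise ValueError("assayable position set must be non-empty")
    assayable = set(assayable_positions)
    truth_pairs = {
        (int(r.position), str(r.alt)) for r in truth.itertuples() if int(r.position) in assayable
    }
    call_pairs = {(v.position, v.alt) for v in calls if v.position in assayable}
    tp = len(call_pairs & truth_pairs)
    fp = len(call_pairs - truth_pairs)
    fn = len(truth_pairs - call_pairs)
    neg_positions = assayable - {p for p, _ in truth_pairs} - {p for p, _ in call_pairs}
    return BenchmarkResult(tp=tp, fp=fp, fn=fn, tn=len(neg_positions))
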