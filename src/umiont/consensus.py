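"""Per-cluster consensus building and consensus-quality metrics.

The consensus engine is a reference-anchored majority vote: every read of a
UMI cluster is projected onto the single-unit reference, and each reference
position takes the majority base among covering reads (a deletion wins only
as a majority; ties fall back to the reference base, biasing toward the
reference exactly when the data are uninformative).  An insertion is emitted
only when the identical inserted sequence occurs at the same reference
junction in more than half of the cluster's reads.

Residual quality is summarized dataset-wide as
``error_rate = n_differences / (n_sequences * length_sequences)`` with
``Q = -10 * log10(error_rate)``; a perfect consensus set is reported as the
lower bound ``-10*log10(1/total_bases)`` and flagged as such.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._align import DEL, UNCOVERED, encode, parse_cigar, project_onto_reference
from .cluster import UmiCluster
from .readprep import UmiRead

_CODE_TO_BASE = "ACGT"

SYSTEMATIC_CLASSES = frozenset({"C>A", "G>T"})


@dataclass
class ConsensusSequence:
    """Polished per-molecule sequence with per-reference-position support."""

    cluster_id: int
    sequence: str
    support: np.ndarray  # winning-allele fraction per reference position
    cluster_size: int
    umi_key: str


@dataclass
class QcMetrics:
    n_differences: int
    n_sequences: int
    length_sequences: float  # mean truth length, bases
    error_rate: float
    dataset_q: float
    is_lower_bound: bool = False
    consensus_q: list[float] = field(default_factory=list)

    @property
    def total_bases(self) -> int:
        return int(round(self.n_sequences * self.length_sequences))


@dataclass
class ErrorProfile:
    substitutions: dict[str, int]  # "X>Y" -> count over the 12 classes
    insertions: int
    deletions: int
    flagged_classes: frozenset[str] = SYSTEMATIC_CLASSES

    @property
    def total(self) -> int:
        return sum(self.substitutions.values()) + self.insertions + self.deletions

    @property
    def flagged_count(self) -> int:
        return sum(self.substitutions.get(c, 0) for c in self.flagged_classes)


def build_consensus(
    reads: list[UmiRead] | list[str],
    reference: str,
    min_cluster_reads: int = 20,
    cluster_id: int = 0,
    umi_key: str = "",
) -> ConsensusSequence | None:
    """Majority consensus of one cluster's strand-normalized reads.

    Returns ``None`` for clusters below ``min_cluster_reads`` or with no
    alignable read.
    """
    seqs = [r.record.sequence if isinstance(r, UmiRead) else r for r in reads]
    if umi_key == "" and reads and isinstance(reads[0], UmiRead):
        umi_key = Counter(r.umi_key for r in reads).most_common(1)[0][0]
    if len(seqs) < min_cluster_reads:
        return None
    L = len(reference)
    ref_codes = encode(reference)
    counts = np.zeros((L, 5), dtype=np.int32)
    ins_counter: Counter[tuple[int, str]] = Counter()
    n_used = 0
    for seq in seqs:
        try:
            row, insertions, _ = project_onto_reference(seq, reference)
        except (IndexError, TypeError):  # pragma: no cover - unalignable read
            continue
        covered = row != UNCOVERED
        np.add.at(counts, (np.flatnonzero(covered), row[covered].astype(np.intp)), 1)
        for junction, inserted in insertions.items():
            ins_counter[(junction, inserted)] += 1
        n_used += 1
    if n_used == 0:
        return None

    depth = counts.sum(axis=1)
    best = counts.max(axis=1)
    winner = counts.argmax(axis=1)
    ref_count = counts[np.arange(L), ref_codes.astype(np.intp)]
    winner = np.where(ref_count == best, ref_codes, winner)  # ties -> reference
    winner = np.where(depth == 0, ref_codes, winner)
    support = np.where(depth > 0, best / np.maximum(depth, 1), 1.0)

    majority_ins: dict[int, str] = {}
    for (junction, inserted), c in ins_counter.items():
        if c * 2 > n_used:  # strictly more than half of the reads
            prev = majority_ins.get(junction)
            if prev is None or ins_counter[(junction, prev)] < c:
                majority_ins[junction] = inserted

    parts: list[str] = []
    for pos in range(L):
        if pos in majority_ins:
            parts.append(majority_ins[pos])
        code = winner[pos]
        if code != DEL:
            parts.append(_CODE_TO_BASE[code])
    if L in majority_ins:
        parts.append(majority_ins[L])
    return ConsensusSequence(cluster_id, "".join(parts), support, len(seqs), umi_key)


def build_all_consensus(
    clusters: list[UmiCluster],
    umi_reads: list[UmiRead],
    reference: str,
    min_cluster_reads: int = 20,
):
    """Consensus for every sufficiently large cluster.

    Returns ``(consensus_list, n_rejected)``; ``clusters`` member indices
    refer to ``umi_reads``.
    """
    out: list[ConsensusSequence] = []
    rejected = 0
    for cl in clusters:
        members = [umi_reads[i] for i in cl.members]
        cons = build_consensus(
            members, reference, min_cluster_reads, cluster_id=cl.cluster_id
        )
        if cons is None:
            rejected += 1
        else:
            out.append(cons)
    return out, rejected


# ---------------------------------------------------------------------------
# quality metrics


def _edits(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW")["editDistance"]


def consensus_q(consensus: str, truth: str) -> tuple[float, bool]:
    """Per-sequence Phred: -10*log10(edits/length).

    A perfect sequence is capped at -10*log10(1/(2*length)) and flagged as a
    lower bound.
    """
    n = len(truth)
    edits = _edits(consensus, truth)
    if edits == 0:
        return float(-10 * np.log10(1 / (2 * n))), True
    return float(-10 * np.log10(edits / n)), False


def dataset_q_from_counts(n_differences: int, total_bases: int) -> tuple[float, bool]:
    """The dataset Q-score formula on raw counts; perfect sets are reported
    as the lower bound -10*log10(1/total_bases), flagged."""
    if total_bases <= 0:
        raise ValueError("total_bases must be positive")
    if n_differences == 0:
        return float(-10 * np.log10(1 / total_bases)), True
    return float(-10 * np.log10(n_differences / total_bases)), False


def dataset_q(consensus_set: list[str], truths: list[str]) -> QcMetrics:
    """Dataset Q-score of a consensus set against its paired truths."""
    if not consensus_set:
        raise ValueError("empty consensus set")
    if len(consensus_set) != len(truths):
        raise ValueError("each consensus needs a paired truth")
    diffs = [_edits(c, t) for c, t in zip(consensus_set, truths)]
    n_diff = int(sum(diffs))
    total = sum(len(t) for t in truths)
    q, bound = dataset_q_from_counts(n_diff, total)
    per_seq = [consensus_q(c, t)[0] for c, t in zip(consensus_set, truths)]
    return QcMetrics(
        n_differences=n_diff,
        n_sequences=len(consensus_set),
        length_sequences=total / len(consensus_set),
        error_rate=n_diff / total if n_diff else 1 / total,
        dataset_q=q,
        is_lower_bound=bound,
        consensus_q=per_seq,
    )


def _left_align(ops: list[tuple[str, int, int, int]], truth: str, cons: str):
    """Shift indel ops left over equal bases so homopolymer indels are
    classified at their leftmost placement."""
    out = []
    for kind, t0, c0, n in ops:
        if kind == "del":
            while t0 > 0 and truth[t0 - 1] == truth[t0 + n - 1]:
                t0 -= 1
        elif kind == "ins":
            while c0 > 0 and cons[c0 - 1] == cons[c0 + n - 1]:
                c0 -= 1
        out.append((kind, t0, c0, n))
    return out


def _classify_pair(truth: str, cons: str, subs: Counter, counts: dict):
    res = edlib.align(truth, cons, mode="NW", task="path")
    t = c = 0
    ops = []
    for n, op in parse_cigar(res["cigar"]):
        if op in "=M":
            t += n
            c += n
        elif op == "X":
            for i in range(n):
                subs[f"{truth[t + i]}>{cons[c + i]}"] += 1
            t += n
            c += n
        elif op == "I":  # truth base absent from consensus: deletion
            ops.append(("del", t, c, n))
            t += n
        else:  # "D": consensus extra bases: insertion
            ops.append(("ins", t, c, n))
            c += n
    for kind, _, _, n in _left_align(ops, truth, cons):
        counts[kind] += n


def error_profile(
    consensus_set: list[str],
    truths: list[str],
    flagged_classes: frozenset[str] = SYSTEMATIC_CLASSES,
) -> ErrorProfile:
    """Classify every truth/consensus difference into the 12 substitution
    classes (truth>consensus), insertions and deletions."""
    subs: Counter[str] = Counter()
    counts = {"ins": 0, "del": 0}
    for cons, truth in zip(consensus_set, truths):
        _classify_pair(truth, cons, subs, counts)
    return ErrorProfile(dict(subs), counts["ins"], counts["del"], flagged_classes)


def dataset_q_excluding(
    flagged_classes: frozenset[str],
    consensus_set: list[str],
    truths: list[str],
) -> QcMetrics:
    """Dataset Q-score with flagged substitution classes removed from the
    difference count (chemistry-systematic error filtering)."""
    bad = set(flagged_classes) - {f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b}
    if bad:
        raise ValueError(f"unknown substitution classes: {sorted(bad)}")
    profile = error_profile(consensus_set, truths, frozenset(flagged_classes))
    total = sum(len(t) for t in truths)
    n_diff = profile.total - profile.flagged_count
    q, bound = dataset_q_from_counts(n_diff, total)
    return QcMetrics(
        n_differences=n_diff,
        n_sequences=len(consensus_set),
        length_sequences=total / len(consensus_set),
        error_rate=n_diff / total if n_diff else 1 / total,
        dataset_q=q,
        is_lower_bound=bound,
    )
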