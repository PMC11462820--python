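"""Read preparation: quality/length filtering, alignment to the unit
reference, chimera removal by alignment overlap, and terminal UMI-pair
extraction."""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from ._align import parse_cigar, reverse_complement
from .design import UmiDesign
from .seqio import FastqRecord
from .simulate import LSP_FWD, LSP_REV, UVP_FWD, UVP_REV


@dataclass
class AlignmentSummary:
    """Best semi-global alignment of a read onto the unit reference.

    ``overlap_fraction`` is the fraction of reference positions aligned to
    read bases (deletion gaps excluded), the quantity thresholded by the
    chimera filter.
    """

    read_id: str
    orientation: str  # '+' or '-'
    ref_start: int  # 1-based inclusive
    ref_end: int
    edit_distance: int
    overlap_fraction: float
    unalignable: bool = False


@dataclass
class UmiRead:
    """A read that passed preparation: strand-normalized record, its
    alignment, and the extracted terminal UMI pair (reference orientation)."""

    record: FastqRecord  # strand-normalized to + orientation
    alignment: AlignmentSummary
    umi_start: str
    umi_end: str

    @property
    def umi_key(self) -> str:
        return self.umi_start + self.umi_end


def filter_reads(
    reads,
    min_length: int = 1000,
    min_mean_q: float = 9.0,
):
    """Keep reads strictly longer than ``min_length`` with mean per-base
    quality strictly above ``min_mean_q``.

    Mean quality is computed in error-probability space,
    -10*log10(mean per-base error probability).  Returns
    ``(kept, tally)`` with rejection counts by reason.
    """
    kept = []
    tally = {"short": 0, "low_quality": 0, "passed": 0}
    for rec in reads:
        if len(rec) <= min_length:
            tally["short"] += 1
        elif rec.mean_error_quality <= min_mean_q:
            tally["low_quality"] += 1
        else:
            tally["passed"] += 1
            kept.append(rec)
    return kept, tally


def _overlap_stats(read_seq: str, reference: str):
    """HW alignment (read global, reference local); returns
    (edit_distance, ref_start0, ref_end0_incl, aligned_ref_bases)."""
    res = edlib.align(read_seq, reference, mode="HW", task="path")
    start, end = res["locations"][0]
    aligned = 0
    for n, op in parse_cigar(res["cigar"]):
        if op in "=XM":
            aligned += n
    return res["editDistance"], start, end, aligned


def align_to_reference(
    record: FastqRecord, reference: str, min_overlap_flag: float = 0.5
) -> AlignmentSummary:
    """Best semi-global alignment over both orientations.

    Ties are broken toward the + strand.  Reads whose alignment covers less
    than half the reference are flagged unalignable.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    fwd = _overlap_stats(record.sequence, reference)
    rev = _overlap_stats(reverse_complement(record.sequence), reference)
    if rev[0] < fwd[0]:
        orient, (dist, start, end, aligned) = "-", rev
    else:
        orient, (dist, start, end, aligned) = "+", fwd
    frac = aligned / len(reference)
    return AlignmentSummary(
        read_id=record.id,
        orientation=orient,
        ref_start=start + 1,
        ref_end=end + 1,
        edit_distance=dist,
        overlap_fraction=frac,
        unalignable=frac < min_overlap_flag,
    )


def overlap_filter(umi_reads: list[UmiRead], min_overlap: float = 0.95) -> list[UmiRead]:
    """Keep reads whose alignment covers strictly more than ``min_overlap``
    of the reference; removes chimeric amplicons."""
    return [r for r in umi_reads if r.alignment.overlap_fraction > min_overlap]


def _find_anchor(segment: str, anchor: str, max_edits: int):
    """Locate ``anchor`` within ``segment`` allowing ``max_edits``; returns
    (start, end_exclusive) in segment coordinates or None."""
    res = edlib.align(anchor, segment, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1:
        return None
    start, end = res["locations"][0]
    return start, end + 1


def extract_umi_pair(
    record: FastqRecord,
    design: UmiDesign,
    anchor_uvp: tuple[str, str] = (UVP_FWD, UVP_REV),
    anchor_lsp: tuple[str, str] = (LSP_FWD, LSP_REV),
    max_anchor_edits: int = 3,
    window: int = 200,
):
    """Extract the terminal UMI pair from a strand-normalized read.

    The 5' UMI lies between the UVP and LSP anchors within ``window`` bases
    of the read start; the 3' UMI between the reverse-complemented LSP'/UVP'
    anchors at the read end.  Both are returned in reference orientation.
    Returns ``(umi_start, umi_end)`` or ``None`` if an anchor is missing or
    the enclosed segment length is implausible for the design.
    """
    seq = record.sequence
    head = seq[:window]
    uvp = _find_anchor(head, anchor_uvp[0], max_anchor_edits)
    if uvp is None:
        return None
    lsp = _find_anchor(head[uvp[1] :], anchor_lsp[0], max_anchor_edits)
    if lsp is None:
        return None
    umi_start = head[uvp[1] : uvp[1] + lsp[0]]

    tail = seq[-window:]
    offset = len(seq) - len(tail)
    lsp_rc = _find_anchor(tail, reverse_complement(anchor_lsp[1]), max_anchor_edits)
    if lsp_rc is None:
        return None
    uvp_rc = _find_anchor(tail[lsp_rc[1] :], reverse_complement(anchor_uvp[1]), max_anchor_edits)
    if uvp_rc is None:
        return None
    umi_end = tail[lsp_rc[1] : lsp_rc[1] + uvp_rc[0]]

    tol = max(4, design.length // 4)
    if abs(len(umi_start) - design.length) > tol or abs(len(umi_end) - design.length) > tol:
        return None
    return umi_start, umi_end


def prepare_reads(
    reads,
    reference: str,
    design: UmiDesign,
    min_length: int = 1000,
    min_mean_q: float = 9.0,
    min_overlap: float = 0.95,
    max_anchor_edits: int = 3,
):
    """Run the full preparation stage: filter, align, overlap-filter, extract.

    Returns ``(umi_reads, tally)``; the tally counts rejections per stage.
    """
    kept, tally = filter_reads(reads, min_length, min_mean_q)
    tally.update({"unalignable": 0, "low_overlap": 0, "no_umi": 0, "prepared": 0})
    out: list[UmiRead] = []
    for rec in kept:
        summ = align_to_reference(rec, reference)
        if summ.unalignable:
            tally["unalignable"] += 1
            continue
        if summ.overlap_fraction <= min_overlap:
            tally["low_overlap"] += 1
            continue
        if summ.orientation == "-":
            rec = FastqRecord(rec.id, reverse_complement(rec.sequence), rec.qualities[::-1])
        pair = extract_umi_pair(rec, design, max_anchor_edits=max_anchor_edits)
        if pair is None:
            tally["no_umi"] += 1
            continue
        tally["prepared"] += 1
        out.append(UmiRead(rec, summ, pair[0], pair[1]))
    return out, tally


def umi_table(umi_reads: list[UmiRead]) -> pd.DataFrame:
    """Tabular view of prepared reads (the clustering stage's input)."""
    return pd.DataFrame(
        {
            "read_id": [r.record.id for r in umi_reads],
            "umi_start": [r.umi_start for r in umi_reads],
            "umi_end": [r.umi_end for r in umi_reads],
            "orientation": [r.alignment.orientation for r in umi_reads],
            "overlap_fraction": [round(r.alignment.overlap_fraction, 4) for r in umi_reads],
            "edit_distance": [r.alignment.edit_distance for r in umi_reads],
        }
    )
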