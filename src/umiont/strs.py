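"""Extraction of the intra-unit dinucleotide short tandem repeat from
consensus sequences.

Because upstream indels shift coordinates, the repeat is located by aligning
short flanking anchors taken from the reference around the configured
interval, not by fixed positions.  Complete dinucleotide units are counted
5'->3'; units deviating from the motif at one base (e.g. ``GA`` or ``AA``
in a ``CA`` run) are counted and flagged with their unit index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import pandas as pd


@dataclass
class StrRecord:
    consensus_id: str
    sequence: str  # the enclosed STR segment ('' when invalid)
    repeat_count: int
    degeneration: list[tuple[int, str]] = field(default_factory=list)  # (unit index 1-based, observed)
    valid: bool = True


def _locate(segment: str, anchor: str, max_edits: int):
    res = edlib.align(anchor, segment, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] == -1:
        return None
    start, end = res["locations"][0]
    return start, end + 1


def extract_str(
    consensus: str,
    reference: str,
    str_interval: tuple[int, int],
    motif: str = "CA",
    flank_length: int = 15,
    max_flank_edits: int = 2,
    consensus_id: str = "",
) -> StrRecord:
    """Extract the repeat between the two reference flanks of
    ``str_interval`` (1-based inclusive reference coordinates).

    Returns a record with ``valid=False`` (and empty sequence) when either
    flank cannot be located within ``max_flank_edits``.
    """
    start, end = str_interval
    if not (1 <= start <= end <= len(reference)):
        raise ValueError("str_interval outside the reference")
    left = reference[max(0, start - 1 - flank_length) : start - 1]
    right = reference[end : end + flank_length]
    if len(left) < flank_length or len(right) < flank_length:
        raise ValueError("reference too short to provide full flanks")

    loc_l = _locate(consensus, left, max_flank_edits)
    if loc_l is None:
        return StrRecord(consensus_id, "", 0, [], valid=False)
    rest_off = loc_l[1]
    loc_r = _locate(consensus[rest_off:], right, max_flank_edits)
    if loc_r is None:
        return StrRecord(consensus_id, "", 0, [], valid=False)
    segment = consensus[rest_off : rest_off + loc_r[0]]

    m = len(motif)
    n_units = len(segment) // m  # trailing incomplete unit not counted
    flags: list[tuple[int, str]] = []
    for i in range(n_units):
        unit = segment[i * m : (i + 1) * m]
        if unit != motif:
            flags.append((i + 1, unit))
    return StrRecord(consensus_id, segment, n_units, flags, valid=True)


def extract_strs(
    consensus_sequences: dict[str, str],
    reference: str,
    str_interval: tuple[int, int],
    motif: str = "CA",
    **kwargs,
) -> list[StrRecord]:
    return [
        extract_str(seq, reference, str_interval, motif, consensus_id=cid, **kwargs)
        for cid, seq in consensus_sequences.items()
    ]


def str_summary(records_per_sample: dict[str, list[StrRecord]]) -> pd.DataFrame:
    """Per-sample STR summary plus a cohort roll-up row.

    Invalid records are excluded from all denominators and reported in
    their own column.
    """
    rows = []
    all_valid: list[StrRecord] = []
    for sample, records in records_per_sample.items():
        valid = [r for r in records if r.valid]
        all_valid.extend(valid)
        rows.append(_summarize(sample, valid, len(records) - len(valid)))
    n_invalid_total = sum(
        1 for recs in records_per_sample.values() for r in recs if not r.valid
    )
    rows.append(_summarize("cohort", all_valid, n_invalid_total))
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "n_records",
            "n_invalid",
            "n_unique_strs",
            "min_repeats",
            "max_repeats",
            "median_repeats",
            "fraction_degenerate",
        ],
    )


def _summarize(sample: str, valid: list[StrRecord], n_invalid: int):
    if not valid:
        return (sample, 0, n_invalid, 0, None, None, None, None)
    lengths = sorted(r.repeat_count for r in valid)
    unique = len({r.sequence for r in valid})
    frac_degen = sum(1 for r in valid if r.degeneration) / len(valid)
    mid = len(lengths) // 2
    median = (
        lengths[mid] if len(lengths) % 2 else (lengths[mid - 1] + lengths[mid]) / 2
    )
    return (
        sample,
        len(valid),
        n_invalid,
        unique,
        lengths[0],
        lengths[-1],
        median,
        round(frac_degen, 4),
    )
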