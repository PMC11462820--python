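"""Per-repeat haplotype extraction and coverage-corrected VNTR copy number.

Each consensus sequence (one template repeat unit) is reduced to its allele
string over the panel of called variant positions.  Copy number estimation
then proceeds in three stages:

1. unique haplotypes -- tally identical allele strings;
2. noise filtering -- merge rare strings (below ``n_sequences * 0.0085``)
   into their nearest neighbour within edit distance 1, then drop strings
   rarer than a binomial minimal-occurrence threshold;
3. coverage correction -- divide each retained haplotype's count by the
   median count and round, so truly identical repeat units (expansions)
   contribute their full multiplicity.  The summed copies are the estimated
   repeat number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._align import edit_distance
from .seqio import VariantRow
from .variants import alignment_matrix

_CODE_TO_SYM = "ACGT-"
DEFAULT_FLOOR = 0.0085


@dataclass
class Haplotype:
    alleles: str  # string over the ordered panel ('-' = deletion)
    raw_count: int
    filtered_count: int = 0
    copies: int = 0


@dataclass
class CopyNumberEstimate:
    haplotypes: list[Haplotype]
    n_sequences: int
    min_occurrence: int  # binomial threshold k actually applied

    @property
    def unique_count(self) -> int:
        """Stage-1 estimate: number of unique haplotypes."""
        return len([h for h in self.haplotypes if h.raw_count > 0])

    @property
    def filtered_count(self) -> int:
        """Stage-2 estimate: haplotypes surviving noise filtering."""
        return len([h for h in self.haplotypes if h.filtered_count > 0])

    @property
    def total_copies(self) -> int:
        """Stage-3 estimate: the coverage-corrected repeat number."""
        return sum(h.copies for h in self.haplotypes)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(h.alleles, h.raw_count, h.filtered_count, h.copies) for h in self.haplotypes],
            columns=["haplotype", "raw_count", "filtered_count", "copies"],
        )


def panel_from_calls(calls_per_sample: list[list[VariantRow]]) -> list[int]:
    """Cohort panel: sorted union of positions called in any sample."""
    positions = {v.position for calls in calls_per_sample for v in calls}
    return sorted(positions)


def extract_haplotypes(
    consensus_sequences: list[str],
    reference: str,
    panel_positions: list[int],
    sample_calls: list[VariantRow],
    min_level: float = DEFAULT_FLOOR,
    matrix: np.ndarray | None = None,
) -> dict[str, int]:
    """Tally allele strings over the panel across consensus sequences.

    At panel positions where this sample's variant level is below
    ``min_level`` (including positions called only in other samples), every
    sequence contributes the sample-major allele, so sub-noise positions
    cannot split haplotypes.  A deletion spanning a panel position is
    recorded as ``-``.
    """
    if not panel_positions:
        raise ValueError("panel must be non-empty")
    if matrix is None:
        matrix, _ = alignment_matrix(consensus_sequences, reference)
    cols = np.asarray(panel_positions, dtype=np.intp) - 1
    sub = matrix[:, cols].copy()

    called_here = {
        v.position for v in sample_calls if v.level >= min_level
    }
    for j, pos in enumerate(panel_positions):
        column = sub[:, j]
        valid = column <= 4
        if not valid.any():
            continue
        major = np.bincount(column[valid], minlength=5).argmax()
        if pos not in called_here:
            # below-noise position: only the major allele enters haplotypes
            sub[:, j] = major
        else:
            sub[~valid, j] = major  # uncovered -> major, do not invent alleles
    strings = ["".join(_CODE_TO_SYM[c] for c in row) for row in sub]
    counts: dict[str, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    return counts


def noise_filter(
    counts: dict[str, int],
    n_sequences: int,
    floor: float = DEFAULT_FLOOR,
    max_edit: int = 1,
) -> dict[str, int]:
    """Merge sub-threshold haplotypes into their nearest neighbour.

    Every haplotype with count below ``n_sequences * floor`` is merged into
    the haplotype at the smallest edit distance, provided that distance is
    at most ``max_edit`` (ties: higher-count target, then lexicographic);
    low-count haplotypes are processed in ascending count order, and a
    haplotype with no eligible target is kept unmerged.  Total observations
    are conserved.
    """
    threshold = n_sequences * floor
    merged = dict(counts)
    low = sorted(
        (h for h in merged if merged[h] < threshold), key=lambda h: (merged[h], h)
    )
    for h in low:
        if h not in merged:
            continue
        best_target, best_d = None, None
        for other, c in merged.items():
            if other == h:
                continue
            d = edit_distance(h, other, k=max_edit)
            if d == -1:
                continue
            key = (d, -c, other)
            if best_d is None or key < best_d:
                best_d, best_target = key, other
        if best_target is not None:
            merged[best_target] += merged.pop(h)
    return merged


def binomial_min_occurrence(n: int, p: float, alpha: float = 0.001) -> int:
    """Smallest k >= 1 with P(X >= k) <= alpha under Binomial(n, p).

    ``p`` is the per-trial probability of observing a given noise haplotype;
    haplotypes occurring fewer than k times are excluded as noise.  ``p = 0``
    is the degenerate no-noise model, giving k = 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1 or not 0 < alpha <= 1:
        raise ValueError("p and alpha must be probabilities")
    if p == 0:
        return 1
    for k in range(1, n + 2):
        if binom.sf(k - 1, n, p) <= alpha:
            return k
    return n + 1  # pragma: no cover


def coverage_correct(
    filtered_counts: dict[str, int],
    raw_counts: dict[str, int] | None = None,
    n_sequences: int | None = None,
    binomial_p: float | None = None,
    binomial_alpha: float = 0.001,
) -> CopyNumberEstimate:
    """Apply the binomial occurrence threshold, then coverage-correct.

    ``copies = round(count / median(counts))`` with half-away-from-zero
    rounding, floored at 1 (a retained haplotype represents at least one
    genomic unit); the summed copies are the repeat-number estimate.  The
    default binomial noise model uses ``p = 1/n_sequences``.
    """
    if not filtered_counts:
        raise ValueError("no retained haplotypes")
    n = n_sequences if n_sequences is not None else sum(filtered_counts.values())
    p = binomial_p if binomial_p is not None else 1.0 / n
    k_min = binomial_min_occurrence(n, p, binomial_alpha)
    kept = {h: c for h, c in filtered_counts.items() if c >= k_min}
    if not kept:
        raise ValueError("binomial threshold removed all haplotypes")
    counts = np.array(list(kept.values()), dtype=float)
    median = float(np.median(counts))
    raw = raw_counts or filtered_counts
    haps = []
    for h in sorted(filtered_counts, key=lambda h: (-filtered_counts[h], h)):
        fc = filtered_counts[h]
        if h in kept:
            ratio = fc / median
            copies = max(1, int(np.floor(ratio + 0.5)))
        else:
            copies = 0
        haps.append(Haplotype(h, raw.get(h, fc), fc if h in kept else 0, copies))
    return CopyNumberEstimate(haps, n_sequences=n, min_occurrence=k_min)


def estimate_copy_number(
    consensus_sequences: list[str],
    reference: str,
    panel_positions: list[int],
    sample_calls: list[VariantRow],
    min_level: float = DEFAULT_FLOOR,
    floor: float = DEFAULT_FLOOR,
    merge_max_edit: int = 1,
    binomial_p: float | None = None,
    binomial_alpha: float = 0.001,
    matrix: np.ndarray | None = None,
) -> CopyNumberEstimate:
    """Full three-stage pipeline from consensus sequences to copy number."""
    raw = extract_haplotypes(
        consensus_sequences, reference, panel_positions, sample_calls, min_level, matrix
    )
    n = sum(raw.values())
    filtered = noise_filter(raw, n, floor, merge_max_edit)
    est = coverage_correct(
        filtered, raw_counts=raw, n_sequences=n,
        binomial_p=binomial_p, binomial_alpha=binomial_alpha,
    )
    # carry raw counts for haplotypes merged away during noise filtering
    present = {h.alleles for h in est.haplotypes}
    for h, c in raw.items():
        if h not in present:
            est.haplotypes.append(Haplotype(h, c, 0, 0))
    return est


def trio_containment(
    child: CopyNumberEstimate | set[str],
    parent1: CopyNumberEstimate | set[str],
    parent2: CopyNumberEstimate | set[str],
):
    """Child haplotypes absent from both parents (exact string match).

    Operates on retained (noise-filtered) haplotypes; returns
    ``(count, sorted list of private haplotypes)``.
    """

    def retained(x):
        if isinstance(x, CopyNumberEstimate):
            return {h.alleles for h in x.haplotypes if h.copies > 0}
        return set(x)

    private = retained(child) - (retained(parent1) | retained(parent2))
    return len(private), sorted(private)


def distance_matrix(haplotypes: list[str]) -> np.ndarray:
    """Symmetric pairwise edit-distance matrix with zero diagonal."""
    n = len(haplotypes)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(haplotypes[i], haplotypes[j])
            mat[i, j] = mat[j, i] = d
    return mat


def export_distances(haplotypes: list[str], path, names: list[str] | None = None):
    """Write the pairwise edit-distance matrix in square PHYLIP format."""
    from .seqio import write_phylip_distances

    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    mat = distance_matrix(haplotypes)
    if names is None:
        names = [f"hap{i}" for i in range(len(haplotypes))]
    write_phylip_distances(names, mat, path)
    return mat
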