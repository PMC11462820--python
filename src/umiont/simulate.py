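"""Synthetic VNTR amplicon experiments with full ground truth.

The generator emulates a UMI-tagged amplicon experiment on a diploid VNTR
locus: a genome is a set of near-identical repeat units (two alleles of K1
and K2 units) that differ only at a panel of intra-unit SNP positions and,
optionally, at an intra-unit dinucleotide STR.  Each repeat unit is tagged
with a terminal UMI pair, amplified with per-cycle heritable PCR errors and
optional template-switch chimeras, and sequenced into nanopore-like reads
with substitution/insertion/deletion errors, an optional systematic C->A /
G->T transversion component, and Phred quality strings.

Every emitted read is traceable through a lineage table to the template
molecule and repeat unit it came from; truth tables record per-position
variant levels and per-haplotype copy counts, which downstream modules are
benchmarked against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import encode, reverse_complement
from .design import UmiDesign, draw_umis

# Fixed synthetic 24-bp anchor constants of the read layout
#   5'-[UVP_FWD][UMI][LSP_FWD] - insert - [rc LSP_REV][rc UMI'][rc UVP_REV]-3'
UVP_FWD = "ACGGTCTGACCTGAATCGGATCAC"
LSP_FWD = "TGCTAGGTCACATTGCGAACCTGA"
LSP_REV = "CAGTTGACGCTAATGGCTCAGTAC"
UVP_REV = "GTCAACTGGATCGTTACCAGGCTA"

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# error model


@dataclass
class ErrorModel:
    """Per-base error rates of the amplification + sequencing process.

    ``substitution_rate``/``insertion_rate``/``deletion_rate`` are i.i.d.
    per-base sequencing error probabilities; ``systematic_transversion_rate``
    is an extra per-base probability applied only as C->A and G->T (the
    dominant residual error class of recent nanopore chemistries);
    ``pcr_error_rate`` is per base and per cycle, heritable by progeny;
    ``chimera_rate`` is the per-molecule probability of a template-switch
    artifact.  ``quality_mean`` centres the emitted Phred strings.
    """

    substitution_rate: float = 0.006
    insertion_rate: float = 0.002
    deletion_rate: float = 0.002
    systematic_transversion_rate: float = 0.0
    pcr_error_rate: float = 1e-6
    chimera_rate: float = 0.0
    chemistry_label: str = "V14_SUP"
    quality_mean: float = 20.0

    _SPLIT_SIZE = {"R9_HAC": 12, "V14_HAC": 10, "V14_SUP": 8}

    def __post_init__(self):
        rates = (
            self.substitution_rate,
            self.insertion_rate,
            self.deletion_rate,
            self.systematic_transversion_rate,
            self.pcr_error_rate,
            self.chimera_rate,
        )
        if any(not 0 <= r < 1 for r in rates):
            raise ValueError("all rates must be in [0, 1)")
        if self.total_error_rate >= 0.1:
            raise ValueError("total per-base sequencing error must stay below 0.1")

    @property
    def total_error_rate(self) -> float:
        return (
            self.substitution_rate
            + self.insertion_rate
            + self.deletion_rate
            + self.systematic_transversion_rate
        )

    @property
    def split_size_threshold(self) -> int:
        """Chemistry-specific cluster-size threshold above which clusters are split."""
        return self._SPLIT_SIZE[self.chemistry_label]

    def replace(self, **kwargs) -> "ErrorModel":
        return dataclasses.replace(self, **kwargs)

    # -- built-in chemistry profiles -------------------------------------
    @classmethod
    def r9_hac(cls) -> "ErrorModel":
        """Older chemistry: ~5% per-base error, indel-heavy."""
        return cls(
            substitution_rate=0.02,
            insertion_rate=0.012,
            deletion_rate=0.018,
            systematic_transversion_rate=0.0,
            chemistry_label="R9_HAC",
            quality_mean=13.0,
        )

    @classmethod
    def v14_hac(cls) -> "ErrorModel":
        """~1% per-base error with a small systematic transversion component."""
        return cls(
            substitution_rate=0.006,
            insertion_rate=0.002,
            deletion_rate=0.002,
            systematic_transversion_rate=0.0004,
            chemistry_label="V14_HAC",
            quality_mean=20.0,
        )

    @classmethod
    def v14_sup(cls) -> "ErrorModel":
        return cls(
            substitution_rate=0.004,
            insertion_rate=0.0015,
            deletion_rate=0.0015,
            systematic_transversion_rate=0.0004,
            chemistry_label="V14_SUP",
            quality_mean=22.0,
        )

    @classmethod
    def from_profile(cls, name: str) -> "ErrorModel":
        try:
            return {"R9_HAC": cls.r9_hac, "V14_HAC": cls.v14_hac, "V14_SUP": cls.v14_sup}[name]()
        except KeyError:
            raise ValueError(f"unknown chemistry profile {name!r}") from None


# ---------------------------------------------------------------------------
# genome specification and truth


@dataclass
class StrSpec:
    """An intra-unit short tandem repeat: ``motif`` repeated a per-haplotype
    number of times starting at 1-based reference position ``start``."""

    motif: str = "CA"
    start: int = 0  # chosen automatically if 0
    reference_repeats: int = 12
    repeat_range: tuple[int, int] = (8, 22)


@dataclass
class VntrAlleleSpec:
    """Specification of a diploid VNTR genome.

    ``expansion_blocks`` lists ``(haplotype_index, multiplicity)`` pairs; the
    multiplicities must sum to ``n_units_allele1 + n_units_allele2``.  A
    multiplicity above 1 produces truly identical repeat units, the situation
    coverage correction exists for.  When empty, every unit carries its own
    haplotype.  ``anchor_margin`` keeps panel positions away from the unit
    ends so primer-anchor windows stay invariant.
    """

    unit_length: int = 1200
    n_units_allele1: int = 8
    n_units_allele2: int = 8
    n_variant_positions: int = 12
    expansion_blocks: list[tuple[int, int]] = field(default_factory=list)
    haplotype_alphabet: list[tuple[str, str]] | None = None  # per-position (ref, alt)
    str_spec: StrSpec | None = None
    anchor_margin: int = 60

    @property
    def total_units(self) -> int:
        return self.n_units_allele1 + self.n_units_allele2

    def __post_init__(self):
        if self.n_units_allele1 < 1 or self.n_units_allele2 < 1:
            raise ValueError("each allele needs at least one unit")
        if self.expansion_blocks:
            total = sum(m for _, m in self.expansion_blocks)
            if total != self.total_units:
                raise ValueError(
                    "expansion block multiplicities must sum to the total unit count"
                )
        room = self.unit_length - 2 * self.anchor_margin
        if self.str_spec is not None:
            room -= len(self.str_spec.motif) * self.str_spec.repeat_range[1] + 30
        if room < self.n_variant_positions * 2:
            raise ValueError("unit_length too small to host the variant panel")


@dataclass
class GenomeTruth:
    """A realized genome: per-unit sequences plus the tables downstream
    modules are benchmarked against."""

    reference: str  # base unit (all-reference alleles, reference STR length)
    panel_positions: list[int]  # 1-based positions inside the unit
    unit_haplotype_ids: list[int]
    unit_sequences: list[str]
    haplotype_strings: dict[int, str]  # haplotype id -> allele string over panel
    truth_variants: pd.DataFrame  # position, ref, alt, level, carrying_units, total_units
    truth_haplotypes: pd.DataFrame  # haplotype, count
    str_truth: pd.DataFrame | None = None  # unit_index, repeat_count
    str_spec: StrSpec | None = None

    @property
    def total_units(self) -> int:
        return len(self.unit_sequences)

    def write_tables(self, outdir) -> None:
        from . import seqio

        outdir = seqio.ensure_dir(outdir)
        units = pd.DataFrame(
            {
                "unit_index": range(self.total_units),
                "haplotype_id": self.unit_haplotype_ids,
                "sequence": self.unit_sequences,
            }
        )
        seqio.write_table(units, outdir / "truth_units.tsv")
        seqio.write_table(self.truth_variants, outdir / "truth_variants.tsv")
        seqio.write_table(self.truth_haplotypes, outdir / "truth_haplotypes.tsv")
        if self.str_truth is not None:
            seqio.write_table(self.str_truth, outdir / "truth_str.tsv")
        seqio.write_fasta({"unit": self.reference}, outdir / "reference.fasta")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _build_truth(
    spec: VntrAlleleSpec,
    rng: np.random.Generator,
    haplotype_strings: dict[int, str] | None = None,
    unit_haplotype_ids: list[int] | None = None,
    base_unit: str | None = None,
    panel_positions: list[int] | None = None,
    alleles: list[tuple[str, str]] | None = None,
    str_repeats: dict[int, int] | None = None,
) -> GenomeTruth:
    """Assemble a GenomeTruth; the keyword hooks let trio construction share
    one base unit and haplotype pool across genomes."""
    L = spec.unit_length
    str_spec = spec.str_spec
    if base_unit is None:
        base_unit = _random_seq(rng, L)
        if str_spec is not None:
            start = str_spec.start
            if start == 0:
                start = spec.anchor_margin + 20
                str_spec = dataclasses.replace(str_spec, start=start)
            ref_str = str_spec.motif * str_spec.reference_repeats
            base_unit = (
                base_unit[: start - 1] + ref_str + base_unit[start - 1 + len(ref_str) :]
            )
    if panel_positions is None:
        lo = spec.anchor_margin + 1
        hi = L - spec.anchor_margin
        forbidden: set[int] = set()
        if str_spec is not None:
            str_len = len(str_spec.motif) * str_spec.repeat_range[1]
            forbidden = set(range(str_spec.start - 20, str_spec.start + str_len + 20))
        candidates = [p for p in range(lo, hi + 1) if p not in forbidden]
        panel_positions = _spaced_positions(candidates, spec.n_variant_positions, rng)
    if alleles is None:
        if spec.haplotype_alphabet is not None:
            alleles = spec.haplotype_alphabet
        else:
            alleles = []
            for p in panel_positions:
                ref = base_unit[p - 1]
                alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
                alleles.append((ref, alt))

    blocks = spec.expansion_blocks or [(h, 1) for h in range(spec.total_units)]
    if unit_haplotype_ids is None:
        unit_haplotype_ids = [h for h, mult in blocks for _ in range(mult)]
    n_haps = len(set(unit_haplotype_ids))

    if haplotype_strings is None:
        haplotype_strings = _draw_haplotype_pool(
            sorted(set(unit_haplotype_ids)), panel_positions, alleles, rng
        )

    if str_spec is not None and str_repeats is None:
        lo_r, hi_r = str_spec.repeat_range
        str_repeats = {
            h: int(rng.integers(lo_r, hi_r + 1)) for h in sorted(set(unit_haplotype_ids))
        }

    # realize per-unit sequences
    unit_seqs = []
    str_rows = []
    for idx, h in enumerate(unit_haplotype_ids):
        seq = list(base_unit)
        hap = haplotype_strings[h]
        for (p, allele) in zip(panel_positions, hap):
            seq[p - 1] = allele
        seq = "".join(seq)
        if str_spec is not None:
            n_rep = str_repeats[h]
            ref_len = len(str_spec.motif) * str_spec.reference_repeats
            s = str_spec.start - 1
            seq = seq[:s] + str_spec.motif * n_rep + seq[s + ref_len :]
            str_rows.append((idx, n_rep))
        unit_seqs.append(seq)

    total = len(unit_seqs)
    var_rows = []
    for (p, (ref, alt)) in zip(panel_positions, alleles):
        carrying = sum(
            1 for h in unit_haplotype_ids if haplotype_strings[h][panel_positions.index(p)] == alt
        )
        if carrying > 0:
            var_rows.append((p, ref, alt, carrying / total, carrying, total))
    truth_variants = pd.DataFrame(
        var_rows, columns=["position", "ref", "alt", "level", "carrying_units", "total_units"]
    )
    hap_counts = (
        pd.Series([haplotype_strings[h] for h in unit_haplotype_ids])
        .value_counts()
        .rename_axis("haplotype")
        .reset_index(name="count")
        .sort_values(["count", "haplotype"], ascending=[False, True])
        .reset_index(drop=True)
    )
    str_truth = (
        pd.DataFrame(str_rows, columns=["unit_index", "repeat_count"]) if str_rows else None
    )
    return GenomeTruth(
        reference=base_unit,
        panel_positions=list(panel_positions),
        unit_haplotype_ids=list(unit_haplotype_ids),
        unit_sequences=unit_seqs,
        haplotype_strings=dict(haplotype_strings),
        truth_variants=truth_variants,
        truth_haplotypes=hap_counts,
        str_truth=str_truth,
        str_spec=str_spec,
    )


def _spaced_positions(
    candidates: list[int], n: int, rng: np.random.Generator, min_gap: int = 5
) -> list[int]:
    """Draw n panel positions at least ``min_gap`` apart.

    Adjacent substitutions admit alternative minimum-cost alignments
    (indel pairs instead of two mismatches), which no pairwise-alignment
    pileup can represent stably, so the generator keeps panel positions
    separated.
    """
    chosen: list[int] = []
    pool = list(candidates)
    for _ in range(n):
        if not pool:
            raise ValueError("unit too small to space the variant panel")
        p = int(pool[int(rng.integers(0, len(pool)))])
        chosen.append(p)
        pool = [q for q in pool if abs(q - p) >= min_gap]
    return sorted(chosen)


def _draw_haplotype_pool(hap_ids, panel_positions, alleles, rng) -> dict[int, str]:
    """Distinct allele strings per haplotype; haplotype 0 is all-reference."""
    n_pos = len(panel_positions)
    strings: dict[int, str] = {}
    seen: set[str] = set()
    for h in hap_ids:
        if h == 0:
            s = "".join(ref for ref, _ in alleles)
        else:
            for _ in range(1000):
                picks = rng.random(n_pos) < 0.5
                s = "".join(alt if take else ref for (ref, alt), take in zip(alleles, picks))
                if s not in seen:
                    break
            else:  # pragma: no cover - panel too small for the haplotype count
                raise ValueError("cannot draw distinct haplotypes; enlarge the panel")
        if s in seen:
            raise ValueError("cannot draw distinct haplotypes; enlarge the panel")
        seen.add(s)
        strings[h] = s
    return strings


def make_vntr_genome(spec: VntrAlleleSpec, variant_seed: int) -> GenomeTruth:
    """Generate a diploid VNTR genome with truth tables, deterministic under seed."""
    rng = np.random.default_rng(variant_seed)
    return _build_truth(spec, rng)


# -- scenario helpers -------------------------------------------------------


def single_haplotype_spec(n_units: int = 10, unit_length: int = 1200, **kwargs) -> VntrAlleleSpec:
    """All units identical (the unmixed-plasmid design): one haplotype, no variants."""
    half = max(1, n_units // 2)
    return VntrAlleleSpec(
        unit_length=unit_length,
        n_units_allele1=half,
        n_units_allele2=n_units - half,
        n_variant_positions=0,
        expansion_blocks=[(0, n_units)],
        haplotype_alphabet=[],
        **kwargs,
    )


def mixture_spec(
    n_total_units: int = 200,
    n_minor_units: int = 10,
    n_defining: int = 20,
    unit_length: int = 500,
    anchor_margin: int = 60,
) -> VntrAlleleSpec:
    """Two-haplotype mixture (the plasmid-mixture design): a minor haplotype
    differing from the major at ``n_defining`` positions, at unit fraction
    ``n_minor_units / n_total_units``."""
    if not 0 < n_minor_units < n_total_units:
        raise ValueError("minor units must be a nonempty strict subset")
    half = n_total_units // 2
    return VntrAlleleSpec(
        unit_length=unit_length,
        n_units_allele1=half,
        n_units_allele2=n_total_units - half,
        n_variant_positions=n_defining,
        expansion_blocks=[(0, n_total_units - n_minor_units), (1, n_minor_units)],
        anchor_margin=anchor_margin,
    )


def _mixture_haplotypes(hap_ids, panel_positions, alleles, rng):
    # haplotype 0 all-ref, haplotype 1 alt at every panel position
    return {
        0: "".join(ref for ref, _ in alleles),
        1: "".join(alt for _, alt in alleles),
    }


def make_mixture_genome(spec: VntrAlleleSpec, variant_seed: int) -> GenomeTruth:
    """Genome for :func:`mixture_spec`: the minor haplotype carries the
    alternate allele at every panel position."""
    rng = np.random.default_rng(variant_seed)
    L = spec.unit_length
    base_unit = _random_seq(rng, L)
    lo, hi = spec.anchor_margin + 1, L - spec.anchor_margin
    panel = _spaced_positions(list(range(lo, hi + 1)), spec.n_variant_positions, rng)
    alleles = []
    for p in panel:
        ref = base_unit[p - 1]
        alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        alleles.append((ref, alt))
    haps = _mixture_haplotypes(None, panel, alleles, rng)
    return _build_truth(
        spec,
        rng,
        haplotype_strings=haps,
        base_unit=base_unit,
        panel_positions=panel,
        alleles=alleles,
    )


def make_trio(
    k_father: tuple[int, int] = (8, 12),
    k_mother: tuple[int, int] = (10, 15),
    transmitted: tuple[int, int] = (0, 0),
    unit_length: int = 600,
    n_variant_positions: int = 14,
    variant_seed: int = 0,
) -> dict[str, GenomeTruth]:
    """Mendelian trio over a shared haplotype pool: each parent has two
    alleles (lists of repeat-unit haplotypes); the child inherits one intact
    allele from each parent (no de-novo units, no recombination)."""
    rng = np.random.default_rng(variant_seed)
    n_units_pool = sum(k_father) + sum(k_mother)
    pool_spec = VntrAlleleSpec(
        unit_length=unit_length,
        n_units_allele1=n_units_pool // 2,
        n_units_allele2=n_units_pool - n_units_pool // 2,
        n_variant_positions=n_variant_positions,
    )
    shared = _build_truth(pool_spec, rng)
    base_unit, panel = shared.reference, shared.panel_positions
    alleles = [
        (row.ref, row.alt)
        for row in shared.truth_variants.itertuples()
    ]
    # truth_variants rows only cover carried alts; rebuild full allele list
    alleles = []
    for i, p in enumerate(panel):
        ref = base_unit[p - 1]
        alts = {s[i] for s in shared.haplotype_strings.values()} - {ref}
        alt = sorted(alts)[0] if alts else _BASES[(_BASES.index(ref) + 1) % 4]
        alleles.append((ref, alt))

    hap_ids = sorted(shared.haplotype_strings)
    fa = (hap_ids[: k_father[0]], hap_ids[k_father[0] : sum(k_father)])
    mo_ids = hap_ids[sum(k_father) :]
    mo = (mo_ids[: k_mother[0]], mo_ids[k_mother[0] : sum(k_mother)])
    child_alleles = (fa[transmitted[0]], mo[transmitted[1]])

    def build(allele_pair):
        ids = list(allele_pair[0]) + list(allele_pair[1])
        spec = VntrAlleleSpec(
            unit_length=unit_length,
            n_units_allele1=max(1, len(allele_pair[0])),
            n_units_allele2=max(1, len(allele_pair[1])),
            n_variant_positions=n_variant_positions,
        )
        return _build_truth(
            spec,
            rng,
            haplotype_strings=shared.haplotype_strings,
            unit_haplotype_ids=ids,
            base_unit=base_unit,
            panel_positions=panel,
            alleles=alleles,
        )

    return {
        "father": build(fa),
        "mother": build(mo),
        "child": build(child_alleles),
    }


# ---------------------------------------------------------------------------
# tagging, amplification, sequencing


@dataclass
class Molecule:
    """One UMI-tagged template (or chimeric artifact) after amplification."""

    molecule_id: int
    unit_index: int  # primary unit of origin (5' parent for chimeras)
    sequence: str  # full construct: adapters + UMIs + insert
    umi_start: str
    umi_end: str  # as read on the forward strand (reverse complement of the tag)
    pcr_events: list[tuple[int, str, float]]  # (0-based pos, alt base, inheritance prob)
    is_chimera: bool = False
    partner_unit: int | None = None

    @property
    def umi_key(self) -> str:
        return self.umi_start + self.umi_end


def _assemble(umi1: str, insert: str, umi2: str) -> str:
    # umi2 is given in forward-read (reference) orientation, i.e. the
    # reverse complement of the drawn 3' tag
    return (
        UVP_FWD
        + umi1
        + LSP_FWD
        + insert
        + reverse_complement(LSP_REV)
        + umi2
        + reverse_complement(UVP_REV)
    )


def tag_and_amplify(
    truth: GenomeTruth,
    templates_per_unit: int,
    design: UmiDesign,
    model: ErrorModel,
    cycles: int = 25,
    rng: np.random.Generator | None = None,
) -> list[Molecule]:
    """Tag every repeat unit with ``templates_per_unit`` UMI pairs and amplify.

    PCR errors are drawn per molecule as Poisson(len * rate * cycles) events;
    an event arising in cycle ``c`` (chosen with probability proportional to
    the number of strands synthesized in that cycle) is inherited by a
    sequenced read with probability 2**-c.  With probability ``chimera_rate``
    a molecule is replaced by a template-switch chimera: the 5' part of its
    own insert joined, after skipping at least 10% of the unit, to the 3'
    part of another template's insert, keeping the 5' UMI of one parent and
    the 3' UMI of the other -- the <95%-overlap, UMI-discordant artifact the
    read filters must remove.
    """
    if templates_per_unit <= 0:
        raise ValueError("templates_per_unit must be positive")
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    n_units = truth.total_units
    n_mol = n_units * templates_per_unit
    unit_of = np.repeat(np.arange(n_units), templates_per_unit)
    umis = draw_umis(design, 2 * n_mol, rng)
    cycle_weights = None
    if cycles > 0:
        cycle_weights = np.power(2.0, np.arange(cycles))
        cycle_weights /= cycle_weights.sum()

    molecules: list[Molecule] = []
    for mid in range(n_mol):
        u = int(unit_of[mid])
        insert = truth.unit_sequences[u]
        umi1, umi2_tag = umis[2 * mid], umis[2 * mid + 1]
        umi2 = reverse_complement(umi2_tag)
        is_chimera = False
        partner = None
        if model.chimera_rate > 0 and rng.random() < model.chimera_rate:
            pid = int(rng.integers(0, n_mol - 1))
            if pid >= mid:
                pid += 1
            partner = int(unit_of[pid])
            other = truth.unit_sequences[partner]
            b1 = rng.uniform(0.05, 0.85)
            skip = rng.uniform(0.10, max(0.101, 1 - b1 - 0.05))
            b2 = min(b1 + skip, 0.95)
            insert = insert[: int(b1 * len(insert))] + other[int(b2 * len(other)) :]
            umi2 = reverse_complement(umis[2 * pid + 1])
            is_chimera = True
        seq = _assemble(umi1, insert, umi2)
        events: list[tuple[int, str, float]] = []
        if cycles > 0 and model.pcr_error_rate > 0:
            n_events = rng.poisson(len(seq) * model.pcr_error_rate * cycles)
            for _ in range(n_events):
                pos = int(rng.integers(0, len(seq)))
                c = int(rng.choice(cycles, p=cycle_weights)) + 1
                alt = _BASES[(_BASES.index(seq[pos]) + int(rng.integers(1, 4))) % 4] if seq[pos] in _BASES else "A"
                events.append((pos, alt, 2.0 ** -c))
        molecules.append(
            Molecule(mid, u, seq, umi1, umi2, events, is_chimera, partner)
        )
    return molecules


@dataclass
class ReadDepth:
    """Per-molecule read-count distribution.

    ``negative_binomial`` with mean ``mean`` and dispersion ``dispersion``
    (variance mean + mean^2/dispersion), or ``constant``.
    """

    distribution: str = "negative_binomial"
    mean: float = 30.0
    dispersion: float = 5.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mean <= 0:
            raise ValueError("read depth mean must be positive")
        if self.distribution == "constant":
            return np.full(n, int(round(self.mean)), dtype=np.int64)
        if self.distribution == "negative_binomial":
            p = self.dispersion / (self.dispersion + self.mean)
            return rng.negative_binomial(self.dispersion, p, size=n).astype(np.int64)
        raise ValueError(f"unknown distribution {self.distribution!r}")


_SYS_FROM = {"C": 1, "G": 2}
_SYS_TO = {1: 0, 2: 3}  # C->A, G->T in base codes


def _mutate_read(codes: np.ndarray, model: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. per-base sequencing errors to an encoded sequence."""
    n = codes.size
    out = codes.copy()
    if model.substitution_rate > 0:
        mask = rng.random(n) < model.substitution_rate
        k = int(mask.sum())
        if k:
            out[mask] = (out[mask] + rng.integers(1, 4, k)) % 4
    if model.systematic_transversion_rate > 0:
        mask = rng.random(n) < model.systematic_transversion_rate
        c_mask = mask & (codes == 1)
        g_mask = mask & (codes == 2)
        out[c_mask] = 0  # C->A
        out[g_mask] = 3  # G->T
    keep = np.ones(n, dtype=bool)
    if model.deletion_rate > 0:
        keep = rng.random(n) >= model.deletion_rate
    ins_mask = np.zeros(n, dtype=bool)
    if model.insertion_rate > 0:
        ins_mask = rng.random(n) < model.insertion_rate
    if keep.all() and not ins_mask.any():
        return out
    counts = keep.astype(np.int64) + ins_mask
    ends = np.cumsum(counts)
    total = int(ends[-1])
    starts = ends - counts
    res = np.zeros(total, dtype=np.uint8)
    res[starts[keep]] = out[keep]
    n_ins = int(ins_mask.sum())
    if n_ins:
        res[starts[ins_mask] + keep[ins_mask]] = rng.integers(0, 4, n_ins)
    return res


def sequence_reads(
    pool: list[Molecule],
    model: ErrorModel,
    reads_per_molecule: ReadDepth | None = None,
    rng: np.random.Generator | None = None,
    shuffle: bool = True,
):
    """Emit nanopore-like reads for every molecule in the pool.

    Returns ``(records, lineage)``: a list of :class:`~umiont.seqio.FastqRecord`
    and a lineage DataFrame (read_id, molecule_id, unit_index, is_chimera,
    strand).  Read ids are opaque serial numbers; ground truth lives only in
    the lineage table.  Reads are emitted on a uniformly random strand and
    shuffled so input order carries no signal.
    """
    from .seqio import FastqRecord

    rng = np.random.default_rng() if rng is None else rng
    depth = reads_per_molecule or ReadDepth()
    counts = depth.sample(len(pool), rng)
    records = []
    lineage_rows = []
    serial = 0
    for mol, k in zip(pool, counts):
        codes0 = encode(mol.sequence)
        for _ in range(int(k)):
            codes = codes0
            if mol.pcr_events:
                codes = codes.copy()
                for pos, alt, prob in mol.pcr_events:
                    if rng.random() < prob:
                        codes[pos] = "ACGT".index(alt)
            codes = _mutate_read(codes, model, rng)
            seq = codes.tobytes().translate(bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")).decode()
            strand = "+"
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
                strand = "-"
            quals = np.clip(np.rint(rng.normal(model.quality_mean, 3.0, len(seq))), 2, 50).astype(np.int64)
            rid = f"read_{serial:08d}"
            serial += 1
            records.append(FastqRecord(rid, seq, quals))
            lineage_rows.append((rid, mol.molecule_id, mol.unit_index, mol.is_chimera, strand))
    if shuffle:
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
        lineage_rows = [lineage_rows[i] for i in order]
    lineage = pd.DataFrame(
        lineage_rows, columns=["read_id", "molecule_id", "unit_index", "is_chimera", "strand"]
    )
    return records, lineage


def simulate_experiment(
    truth: GenomeTruth,
    design: UmiDesign,
    model: ErrorModel,
    templates_per_unit: int,
    depth: ReadDepth | None = None,
    cycles: int = 25,
    seed: int = 0,
):
    """Convenience wrapper: tag, amplify and sequence in one call.

    Returns ``(records, lineage, pool)``.
    """
    rng = np.random.default_rng(seed)
    pool = tag_and_amplify(truth, templates_per_unit, design, model, cycles, rng)
    records, lineage = sequence_reads(pool, model, depth, rng)
    return records, lineage, pool


def consensus_pool(
    truth: GenomeTruth,
    molecules_per_unit: int,
    survival: float = 0.95,
    residual_error_rate: float = 1e-4,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Consensus-stage shortcut for estimator studies.

    Emulates the output of the consensus stage directly: each repeat unit
    yields ``Binomial(molecules_per_unit, survival)`` consensus sequences
    (molecules whose clusters met the size cutoff), each an exact copy of the
    unit with residual per-base substitutions at ``residual_error_rate``
    (default 1e-4, i.e. a dataset Q-score of 40, the plateau quality of
    majority consensus at moderate cluster sizes).  Skips read simulation
    entirely, so the
    molecule-sampling statistics of copy-number estimation can be studied at
    scale; it does not exercise clustering or consensus building themselves.
    """
    rng = np.random.default_rng() if rng is None else rng
    out: list[str] = []
    for seq in truth.unit_sequences:
        n = rng.binomial(molecules_per_unit, survival)
        for _ in range(n):
            codes = encode(seq)
            mask = rng.random(codes.size) < residual_error_rate
            if mask.any():
                codes = codes.copy()
                k = int(mask.sum())
                codes[mask] = (codes[mask] + rng.integers(1, 4, k)) % 4
            out.append(codes.tobytes().translate(bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")).decode())
    order = rng.permutation(len(out))
    return [out[i] for i in order]
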