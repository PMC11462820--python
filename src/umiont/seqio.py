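"""Readers/writers for the formats the pipeline touches.

FASTQ (Phred+33), FASTA, a minimal VCF 4.2 subset and header-carrying TSV
tables.  Readers reject malformed records rather than repairing them;
writers are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

_ALLOWED = set("ACGTN")


@dataclass
class FastqRecord:
    id: str
    sequence: str
    qualities: np.ndarray  # per-base Phred integers

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"record {self.id!r}: sequence and qualities differ in length"
            )
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(f"record {self.id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_error_quality(self) -> float:
        """Mean per-base quality in error-probability space.

        Q_mean = -10*log10(mean(10^(-q/10))), the convention of common
        nanopore QC tools; dominated by the worst bases, unlike a plain
        arithmetic mean of Phred values.
        """
        err = np.power(10.0, -self.qualities / 10.0)
        return float(-10.0 * np.log10(err.mean()))


@dataclass
class VariantRow:
    """One called allele on the single-unit reference (1-based position)."""

    position: int
    ref: str
    alt: str
    level: float
    supporting: int
    total: int

    def __post_init__(self):
        if self.total > 0 and not np.isclose(self.level, self.supporting / self.total):
            raise ValueError("level must equal supporting/total")
        if not 0 < self.level <= 1:
            raise ValueError("level must be in (0, 1]")


def read_fastq(path) -> Iterator[FastqRecord]:
    """Stream FASTQ records; raises on a malformed quartet, naming its index."""
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual or not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ quartet at record {idx}")
            seq = seq.strip()
            qual = qual.strip()
            if len(seq) != len(qual):
                raise ValueError(f"malformed FASTQ quartet at record {idx}")
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
            yield FastqRecord(header[1:].strip().split()[0], seq, quals)
            idx += 1


def write_fastq(records: Iterable[FastqRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            qual = (rec.qualities.astype(np.uint8) + 33).tobytes().decode("ascii")
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                if name is None:
                    raise ValueError("FASTA sequence before any header")
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_VARIANT_COLUMNS = ["position", "ref", "alt", "level", "supporting", "total"]


def write_variants(rows: list[VariantRow], path, dialect: str = "tsv") -> None:
    """Write called variants as TSV (documented header) or minimal VCF 4.2.

    Rows must be sorted by position; the VCF dialect carries the variant
    level in an ``AF`` INFO field.
    """
    positions = [r.position for r in rows]
    if positions != sorted(positions):
        raise ValueError("variant rows must be sorted by position")
    if dialect == "tsv":
        df = pd.DataFrame(
            [(r.position, r.ref, r.alt, f"{r.level:.4f}", r.supporting, r.total) for r in rows],
            columns=_VARIANT_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Variant level">\n')
            fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Consensus depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in rows:
                fh.write(
                    f"unit\t{r.position}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                    f"AF={r.level:.4f};DP={r.total}\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_variants(path) -> list[VariantRow]:
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    missing = set(_VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return [
        VariantRow(int(r.position), r.ref, r.alt, float(r.supporting) / float(r.total),
                   int(r.supporting), int(r.total))
        for r in df.itertuples()
    ]


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phylip_distances(names: list[str], matrix: np.ndarray, path) -> None:
    """Square PHYLIP distance matrix (names truncated/padded to 10 chars)."""
    matrix = np.asarray(matrix)
    n = len(names)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match names")
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for name, row in zip(names, matrix):
            label = name[:10].ljust(10)
            fh.write(label + " ".join(f"{v:g}" for v in row) + "\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
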