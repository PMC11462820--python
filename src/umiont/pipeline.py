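"""End-to-end pipeline driver and its configuration.

Stage order: read preparation (filter, align, overlap filter, UMI
extraction) -> round-1 clustering with splitting and the minimum-size
cutoff -> per-cluster consensus -> round-2 duplicate removal -> variant
calling on the consensus pileup -> haplotype extraction and copy-number
estimation -> optional STR extraction.  All randomness in a run flows from
the configuration; reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import configparser
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cons_mod
from . import haplotypes as hap_mod
from . import seqio, strs
from . import variants as var_mod
from .cluster import ClusteringParams, cluster_reads, recluster_consensus
from .design import UmiDesign
from .readprep import prepare_reads, umi_table
from .simulate import ErrorModel

log = logging.getLogger("umiont")


@dataclass
class PipelineConfig:
    chemistry: str = "V14_HAC"
    umi_pattern: str = "TTTVVVVTTVVVVTTVVVVTTVVVVTTT"
    min_read_length: int = 1000
    min_mean_q: float = 9.0
    min_overlap: float = 0.95
    round1_identity: float = 0.80
    round2_identity: float = 0.99
    split_max_edit: int = 2
    split_size_threshold: int = 0  # 0: derive from chemistry (12/10/8)
    min_cluster_reads: int = 20
    min_level: float = 0.0085
    call_indels: bool = False
    haplotype_floor: float = 0.0085
    merge_max_edit: int = 1
    binomial_p: float = 0.0  # 0: use 1/n_sequences
    binomial_alpha: float = 0.001
    str_start: int = 0  # 0: STR stage disabled
    str_end: int = 0
    str_motif: str = "CA"
    seed: int = 0

    def clustering_params(self) -> ClusteringParams:
        split = self.split_size_threshold or ErrorModel.from_profile(
            self.chemistry
        ).split_size_threshold
        return ClusteringParams(
            round1_identity=self.round1_identity,
            round2_identity=self.round2_identity,
            split_max_edit=self.split_max_edit,
            split_size_threshold=split,
            min_cluster_reads=self.min_cluster_reads,
        )

    def design(self) -> UmiDesign:
        return UmiDesign(self.umi_pattern)

    # -- INI-style round-trip --------------------------------------------
    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["umiont"] = {f.name: str(getattr(self, f.name)) for f in fields(self)}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        sec = cp["umiont"]
        kwargs = {}
        for f in fields(cls):
            if f.name not in sec:
                continue
            raw = sec[f.name]
            if f.type == "bool":
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            elif f.type == "int":
                kwargs[f.name] = int(raw)
            elif f.type == "float":
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


@dataclass
class SampleResult:
    """Everything one sample run produces, in memory."""

    tally: dict
    clusters: list
    consensus: list  # retained ConsensusSequence objects after round 2
    n_duplicates_removed: int
    pileup: list
    calls: list
    copy_number: "hap_mod.CopyNumberEstimate | None" = None
    str_records: list = field(default_factory=list)
    matrix: np.ndarray | None = None

    @property
    def consensus_sequences(self) -> list[str]:
        return [c.sequence for c in self.consensus]


def run_sample(
    records,
    reference: str,
    config: PipelineConfig,
    run_haplotypes: bool = True,
) -> SampleResult:
    """Run all pipeline stages on in-memory reads; see module docstring."""
    t0 = time.time()
    params = config.clustering_params()
    design = config.design()

    umi_reads, tally = prepare_reads(
        records,
        reference,
        design,
        min_length=config.min_read_length,
        min_mean_q=config.min_mean_q,
        min_overlap=config.min_overlap,
    )
    log.info("readprep: %s", tally)
    if not umi_reads:
        raise ValueError("readprep rejected every read")

    keys = [r.umi_key for r in umi_reads]
    halves = [(r.umi_start, r.umi_end) for r in umi_reads]
    clusters, dropped = cluster_reads(keys, params, halves=halves)
    tally["clusters_retained"] = len(clusters)
    tally["reads_dropped_small_clusters"] = len(dropped)
    log.info(
        "clustering: %d clusters >= %d reads (%d reads in sub-threshold clusters)",
        len(clusters), params.min_cluster_reads, len(dropped),
    )
    if not clusters:
        raise ValueError("no cluster met the minimum size")

    consensi, n_rej = cons_mod.build_all_consensus(
        clusters, umi_reads, reference, params.min_cluster_reads
    )
    tally["consensus_built"] = len(consensi)

    survivors = recluster_consensus(
        [c.umi_key for c in consensi],
        [c.cluster_size for c in consensi],
        params.round2_identity,
    )
    n_dup = len(consensi) - len(survivors)
    consensi = [consensi[i] for i in survivors]
    tally["duplicates_removed"] = n_dup
    log.info("consensus: %d sequences (%d duplicates removed)", len(consensi), n_dup)

    seqs = [c.sequence for c in consensi]
    matrix, insertions = var_mod.alignment_matrix(seqs, reference)
    columns = var_mod.pileup(seqs, reference, matrix=matrix, insertions=insertions)
    calls = var_mod.call_variants(
        columns, reference, min_level=config.min_level, call_indels=config.call_indels
    )
    tally["variants_called"] = len(calls)

    copy_number = None
    if run_haplotypes and calls:
        panel = hap_mod.panel_from_calls([calls])
        copy_number = hap_mod.estimate_copy_number(
            seqs,
            reference,
            panel,
            calls,
            min_level=config.min_level,
            floor=config.haplotype_floor,
            merge_max_edit=config.merge_max_edit,
            binomial_p=config.binomial_p or None,
            binomial_alpha=config.binomial_alpha,
            matrix=matrix,
        )

    str_records = []
    if config.str_start and config.str_end:
        str_records = strs.extract_strs(
            {f"cons_{c.cluster_id}": c.sequence for c in consensi},
            reference,
            (config.str_start, config.str_end),
            motif=config.str_motif,
        )
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return SampleResult(
        tally=tally,
        clusters=clusters,
        consensus=consensi,
        n_duplicates_removed=n_dup,
        pileup=columns,
        calls=calls,
        copy_number=copy_number,
        str_records=str_records,
        matrix=matrix,
    )


def run_pipeline(config: PipelineConfig, reads_path, reference_path, outdir) -> Path:
    """File-based pipeline: FASTQ + unit FASTA in, result tables out."""
    reads_path, reference_path = Path(reads_path), Path(reference_path)
    for p in (reads_path, reference_path):
        if not p.exists():
            raise FileNotFoundError(p)
    out = seqio.ensure_dir(outdir)
    refs = seqio.read_fasta(reference_path)
    if len(refs) != 1:
        raise ValueError("reference FASTA must contain exactly one unit sequence")
    reference = next(iter(refs.values()))
    records = list(seqio.read_fastq(reads_path))
    result = run_sample(records, reference, config)

    seqio.write_table(
        pd.DataFrame(sorted(result.tally.items()), columns=["stage", "count"]),
        out / "tally.tsv",
    )
    seqio.write_fasta(
        {
            f"cons_{c.cluster_id} size={c.cluster_size} umi={c.umi_key}": c.sequence
            for c in result.consensus
        },
        out / "consensus.fasta",
    )
    rows = sorted(result.calls, key=lambda v: (v.position, v.alt))
    seqio.write_variants(rows, out / "variants.tsv", dialect="tsv")
    seqio.write_variants(rows, out / "variants.vcf", dialect="vcf")
    if result.copy_number is not None:
        seqio.write_table(result.copy_number.as_frame(), out / "haplotypes.tsv")
        summary = pd.DataFrame(
            {
                "stage": ["unique", "noise_filtered", "coverage_corrected"],
                "value": [
                    result.copy_number.unique_count,
                    result.copy_number.filtered_count,
                    result.copy_number.total_copies,
                ],
            }
        )
        seqio.write_table(summary, out / "copy_number.tsv")
        retained = [
            h.alleles for h in result.copy_number.haplotypes if h.copies > 0
        ]
        if len(retained) >= 2:
            hap_mod.export_distances(retained, out / "haplotype_distances.phy")
    if result.str_records:
        seqio.write_table(
            pd.DataFrame(
                [
                    (r.consensus_id, r.sequence, r.repeat_count, r.valid,
                     ";".join(f"{i}:{u}" for i, u in r.degeneration))
                    for r in result.str_records
                ],
                columns=["consensus_id", "str_sequence", "repeat_count", "valid", "degeneration"],
            ),
            out / "strs.tsv",
        )
    config.to_file(out / "config.ini")
    return out
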