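"""Desk-scale validation studies run entirely on simulated data.

Two studies mirror the designs used to characterize the method:

* :func:`consensus_quality_experiment` -- the unmixed-plasmid design: one
  haplotype, every consensus difference is an error; measures the dataset
  Q-score as a function of the minimum UMI cluster size.
* :func:`detection_limit_scan` -- the plasmid-mixture design: a minor
  haplotype defined by a fixed set of positions is titrated down and the
  smallest fraction at which every defining variant is still called at the
  default level threshold is reported.

Both generate their inputs with the package's own simulator and run the
real pipeline stages; they are sized to run on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import consensus as cons_mod
from . import variants as var_mod
from .cluster import ClusteringParams, cluster_reads
from .consensus import QcMetrics
from .design import UmiDesign
from .pipeline import PipelineConfig, run_sample
from .readprep import prepare_reads
from .simulate import (
    ErrorModel,
    ReadDepth,
    make_mixture_genome,
    make_vntr_genome,
    mixture_spec,
    simulate_experiment,
    single_haplotype_spec,
)


@dataclass
class ConsensusQualityResult:
    by_min_size: dict[int, QcMetrics]
    n_molecules: int
    unit_length: int


def consensus_quality_experiment(
    seed: int,
    min_cluster_sizes: tuple[int, ...] = (6, 10),
    n_molecules: int = 500,
    unit_length: int = 1200,
    mean_depth: float = 30.0,
    model: ErrorModel | None = None,
) -> ConsensusQualityResult:
    """Dataset Q-score versus minimum cluster size on a single-haplotype locus.

    Simulates ``n_molecules`` tagged template molecules of one repeat unit
    with a ~1% random error model (no systematic transversion component),
    negative-binomial read depth, runs preparation + two-round clustering
    with splitting + majority consensus, and scores each consensus against
    the unit sequence of the molecule its cluster derives from (lineage
    truth).  Clustering is done once; the cluster-size cutoff is applied per
    requested minimum.
    """
    model = model or ErrorModel.v14_hac().replace(systematic_transversion_rate=0.0)
    n_units = 10
    spec = single_haplotype_spec(n_units=n_units, unit_length=unit_length)
    truth = make_vntr_genome(spec, variant_seed=seed)
    templates_per_unit = int(np.ceil(n_molecules / n_units))
    records, lineage, _ = simulate_experiment(
        truth,
        UmiDesign(),
        model,
        templates_per_unit=templates_per_unit,
        depth=ReadDepth(mean=mean_depth),
        seed=seed + 1,
    )

    reference = truth.reference
    design = UmiDesign()
    umi_reads, _ = prepare_reads(
        records, reference, design, min_length=int(unit_length * 0.8)
    )
    params = ClusteringParams(
        split_size_threshold=model.split_size_threshold,
        min_cluster_reads=min(min_cluster_sizes),
    )
    clusters, _ = cluster_reads(
        [r.umi_key for r in umi_reads],
        params,
        halves=[(r.umi_start, r.umi_end) for r in umi_reads],
    )
    unit_of_read = dict(zip(lineage["read_id"], lineage["unit_index"]))

    built = []  # (cluster_size, consensus sequence, truth sequence)
    for cl in clusters:
        members = [umi_reads[i] for i in cl.members]
        cons = cons_mod.build_consensus(
            members, reference, min_cluster_reads=min(min_cluster_sizes),
            cluster_id=cl.cluster_id,
        )
        if cons is None:
            continue
        units = pd.Series([unit_of_read[m.record.id] for m in members])
        truth_seq = truth.unit_sequences[int(units.mode().iloc[0])]
        built.append((cons.cluster_size, cons.sequence, truth_seq))

    by_min = {}
    for m in min_cluster_sizes:
        sel = [(c, t) for size, c, t in built if size >= m]
        by_min[m] = cons_mod.dataset_q([c for c, _ in sel], [t for _, t in sel])
    return ConsensusQualityResult(by_min, n_molecules, unit_length)


@dataclass
class DetectionScanResult:
    called_per_fraction: dict[float, int]  # minor fraction -> defining variants called
    n_defining: int
    smallest_full_detection: float | None

    @property
    def smallest_full_detection_percent(self) -> float | None:
        if self.smallest_full_detection is None:
            return None
        return 100.0 * self.smallest_full_detection


def detection_limit_scan(
    seed: int,
    fractions: tuple[float, ...] = (0.05, 0.02, 0.01, 0.005),
    n_total_units: int = 200,
    n_defining: int = 20,
    unit_length: int = 500,
    templates_per_unit: int = 50,
    mean_depth: float = 8.0,
    min_cluster_reads: int = 3,
    min_level: float = 0.0085,
    chemistry: str = "V14_SUP",
) -> DetectionScanResult:
    """Titration of a minor haplotype through the full pipeline.

    For each minor fraction, a two-haplotype mixture genome is built with an
    exact unit composition (e.g. 2 of 200 units for 1%), amplified to
    ``n_total_units * templates_per_unit`` template molecules, sequenced and
    run through the pipeline; the number of minor-defining variants called
    above ``min_level`` is recorded.  The smallest fraction at which every
    defining variant is called is the detection limit of the configuration.
    """
    called = {}
    for i, f in enumerate(sorted(fractions, reverse=True)):
        n_minor = max(1, int(round(f * n_total_units)))
        spec = mixture_spec(
            n_total_units=n_total_units,
            n_minor_units=n_minor,
            n_defining=n_defining,
            unit_length=unit_length,
        )
        truth = make_mixture_genome(spec, variant_seed=seed)
        model = ErrorModel.from_profile(chemistry)
        records, _, _ = simulate_experiment(
            truth,
            UmiDesign(),
            model,
            templates_per_unit=templates_per_unit,
            depth=ReadDepth(mean=mean_depth),
            seed=seed + 101 + i,
        )
        cfg = PipelineConfig(
            chemistry=chemistry,
            min_read_length=int(unit_length * 0.6),
            min_cluster_reads=min_cluster_reads,
            min_level=min_level,
        )
        result = run_sample(records, truth.reference, cfg, run_haplotypes=False)
        call_pairs = {(v.position, v.alt) for v in result.calls}
        minor = truth.truth_variants
        defining = {(int(r.position), str(r.alt)) for r in minor.itertuples()}
        called[f] = len(defining & call_pairs)

    full = [f for f, n in called.items() if n == n_defining]
    return DetectionScanResult(
        called_per_fraction=called,
        n_defining=n_defining,
        smallest_full_detection=min(full) if full else None,
    )
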