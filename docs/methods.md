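# Methods

## Model and rationale

A UMI amplicon experiment on a VNTR is modelled as follows. The locus is a
set of K = K1 + K2 repeat units (two alleles) of a common ~0.5–5 kb unit
sequence; units differ only at a panel of intra-unit SNP positions (the
unit's *haplotype*) and, optionally, in the length of an intra-unit CA
repeat. Each unit is tagged with a terminal UMI pair, amplified, and
sequenced; reads are grouped by UMI pair, a majority consensus per group
yields one sequence per template molecule, and all downstream quantities —
variant levels, haplotypes, copy number — are computed over these
consensus sequences.

The *variant level* of an allele is the fraction of consensus sequences
carrying it; for a variant private to one unit of a K-unit locus this is
≈ 1/K. The caller therefore uses a plain level threshold rather than a
diploid genotype model: 0.85% by default, below the 1.25% single-unit level
of an 80-unit locus and above the residual noise floor left after
consensus.

## Pipeline stages and parameters

| Stage | Parameter | Default | Meaning |
|---|---|---|---|
| filter | `min_read_length` | 1000 bp | strict; set ~0.6× amplicon length for short units |
| filter | `min_mean_q` | Q9 | mean in error space: −10·log10(mean per-base error) |
| chimera filter | `min_overlap` | 0.95 | strict lower bound on aligned reference fraction |
| clustering | `round1_identity` | 0.80 | loose, so key errors never split a molecule |
| splitting | `split_size_threshold` | 12/10/8 | by chemistry (R9 HAC / V14 HAC / V14 SUP) |
| splitting | `split_max_edit` | 2 | seed-anchored radius; collision risk < 0.01% |
| consensus | `min_cluster_reads` | 20 | reads required per molecule (6–10 already reach Q40–Q50) |
| round 2 | `round2_identity` | 0.99 | strict; removes consensus duplicates |
| calling | `min_level` | 0.0085 | strict level threshold |
| haplotypes | `floor`, `merge_max_edit` | 0.0085, 1 | sub-floor strings merge into ≤1-edit neighbour |
| haplotypes | `binomial_p`, `alpha` | 1/n, 0.001 | minimal-occurrence tail threshold |

Identity between UMI keys is `1 − d/max(len)` with `d` the Levenshtein
distance. Greedy clustering scans keys in input order and joins the oldest
centroid meeting the threshold. A candidate-shortlist index (exact key
plus a SymSpell-style single-deletion neighbourhood per UMI end) makes this
linear-time; it is exhaustive for joins within 2 edits of a centroid, which
is the only regime that matters under the design's collision bound —
`accelerate=False` restores the exhaustive scan.

Cluster splitting seeds each subcluster with the *most abundant* member key
(ties: first observed) rather than the literal first member: the modal key
of a cluster is the template's true tag with high probability, while an
errored seed would cut its own molecule in two. The alternative file-order
seeding is available (`seed_order="file"`).

The binomial minimal-occurrence rule needs a noise probability `p`; a
literal `p = 0` makes the tail threshold degenerate (k = 1, no filtering),
so the implementation exposes the general rule with defaults
`p = 1/n_sequences`, `α = 0.001` and treats `p = 0` as the explicit
no-filter case.

Coverage correction divides each retained haplotype's count by the median
count and rounds half away from zero with a floor of 1 (a retained
haplotype represents at least one genomic unit); the rounding floor and
half-away convention are deliberate: a haplotype that survived filtering
cannot contribute zero copies.

## Consensus engine

The consensus is a reference-anchored majority vote: each read is projected
onto the unit reference by edit-distance alignment (reference global within
the read, so adapters and UMIs at the read ends are ignored); each
reference position takes the majority base among covering reads, a deletion
only wins as a strict majority, ties fall back to the reference base, and
an insertion is emitted only when the identical inserted string occurs at
the same junction in more than half of the reads. This biases toward the
reference exactly when the data are uninformative. The engine is
deliberately free of trained components; neural polishing could be plugged
in behind `build_consensus` without touching the downstream stages.

Consensus accuracy is summarized by the dataset Q-score,
`error rate = n_differences / (n_sequences × length)`,
`Q = −10·log10(error rate)`, where `n_differences` sums the edit
operations (not alignment columns) of each consensus against its truth. A
perfect consensus set has an infinite Q, so it is reported as the lower
bound `−10·log10(1/total bases)` and flagged; per-sequence Q-scores are
capped at `−10·log10(1/(2·length))` the same way.

## The simulator

The generator emulates the validation designs end to end: unit sequences
are realized from a seeded base unit plus per-haplotype panel alleles;
expansion blocks produce truly identical units; templates are tagged with
UMIs drawn from the configured design and assembled as
`UVP–UMI–LSP–unit–LSP′ᵣᶜ–UMI′ᵣᶜ–UVP′ᵣᶜ` with fixed synthetic 24-bp anchors.
PCR errors arrive as Poisson(length × rate × cycles) events per molecule;
an event in cycle c (chosen ∝ strands synthesized that cycle) is inherited
by each read independently with probability 2⁻ᶜ — a statistical surrogate
for the amplification tree that preserves the heritable-fraction spectrum.
Chimeras model incomplete-extension template switching: the 5′ part of one
insert joined to the 3′ part of another, skipping at least 10% of the
unit, with the two terminal UMIs taken from different parents; smaller
skips are operationally indistinguishable from intact molecules, and this
is the artifact class the > 95%-overlap and cluster-size filters remove.
Reads receive i.i.d. substitutions/indels plus the optional systematic
C→A / G→T component, a uniformly random strand, and Phred strings drawn
N(quality_mean, 3) clipped to [2, 50]; read depth per molecule is
negative-binomial (mean 30, dispersion 5 by default) so that the 6–20
cluster-size regime is exercised.

Built-in chemistry profiles: R9_HAC (~5% error, indel-heavy), V14_HAC
(~1%), V14_SUP (~0.7%), the latter two with a small systematic
transversion component; total error is validated < 10%.

What the simulator does **not** model: pore signal, homopolymer-dependent
error, basecaller confusion structure, duplex pairing, carrier DNA, or
coverage biases along the amplicon. Passing tests therefore demonstrate
the pipeline's algorithmic correctness and its statistical behaviour under
calibrated error rates — not robustness to every sequence-context effect
of real flow cells.

`consensus_pool` additionally emulates the *output* of the consensus stage
directly (per-unit molecule counts with a 95% cluster-survival rate and
residual per-base errors at 1e-4, i.e. dataset Q40 — the plateau quality
of the majority consensus at moderate cluster sizes). It exists so
copy-number estimation can be studied over many replicates without paying
for read simulation, and is used by the estimator property tests with a
fixed per-sample consensus budget (~2000 sequences), mirroring real designs
where total depth, not per-unit depth, is the constant.

## Numerical and degenerate-case choices

- Alignment is unit-cost edit distance throughout (thresholds in this
  method are stated as identities/overlaps, not affine-gap scores); edlib
  provides the distances and paths.
- `overlap_fraction` counts reference bases aligned to read bases
  (match + mismatch columns) over the reference length: a missing-middle
  chimera then scores ≤ 0.90 even though its alignment *spans* the whole
  reference.
- Panel positions in generated genomes are kept ≥ 5 bp apart: adjacent
  substitutions admit equal-cost indel representations that no
  alignment-based pileup resolves stably. Dense SNP clusters are a known
  limitation of the caller.
- Indels are left-aligned before error-profile classification; indel
  alleles are excluded from calling by default.
- Ratios with zero denominators in benchmarking (e.g. precision with no
  calls) are reported as absent, never as 0.
- All randomness flows from explicit seeds; identical configuration and
  inputs give byte-identical outputs.

## Validation studies and problem sizes

The consensus-quality study uses 500 molecules of a 1.2 kb unit at ~30×
molecule depth with the ~1% random-error profile (systematic component
disabled so the measured Q reflects the engine, not the flagged classes);
the detection-limit study titrates a 20-position minor haplotype on a
500 bp unit through 10,000 molecules at ~8× depth with a minimum cluster
size of 3 and a 300 bp length filter (reads of a 500 bp amplicon are
~650 bp). Copy-number recovery uses K ∈ {15, 30, 45} with a 3× expansion
block over 20 seeded replicates. These sizes keep each study within
minutes on one CPU while preserving the statistical regime of the original
designs (levels down to 0.5%, cluster sizes 2–20, K up to 45).

## Known limitations

- The majority consensus ties toward the reference; a true variant
  supported by exactly half of a cluster's reads is suppressed. Larger
  `min_cluster_reads` makes this vanishingly rare.
- Variant levels are per consensus sequence, so copy-number-scale effects
  (identical repeats) must be recovered downstream by coverage correction;
  the correction assumes the median haplotype represents one unit, which
  fails if most haplotypes are multi-copy.
- The UMI-free comparison mode shares the preparation stages, so it
  reflects the calling contrast only, not a fully independent pipeline.
- STR repeat counting assumes a dinucleotide motif between stable flanks;
  stutter and motif interruptions longer than one base per unit are
  flagged but not modelled.
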