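import numpy as np
import pytest

from umiont._align import reverse_complement
from umiont.design import UmiDesign
from umiont.seqio import write_fastq
from umiont.simulate import (
    ErrorModel,
    ReadDepth,
    StrSpec,
    VntrAlleleSpec,
    make_mixture_genome,
    make_trio,
    make_vntr_genome,
    mixture_spec,
    sequence_reads,
    simulate_experiment,
    single_haplotype_spec,
    tag_and_amplify,
)

NOERR = ErrorModel(
    substitution_rate=0.0, insertion_rate=0.0, deletion_rate=0.0,
    systematic_transversion_rate=0.0, pcr_error_rate=0.0,
)


class TestGenome:
    def test_single_haplotype_truth(self):
        truth = make_vntr_genome(single_haplotype_spec(n_units=10, unit_length=800), 1)
        assert truth.total_units == 10
        assert len(set(truth.unit_sequences)) == 1
        assert len(truth.truth_haplotypes) == 1
        assert truth.truth_haplotypes["count"].iloc[0] == 10
        assert truth.truth_variants.empty

    def test_mixture_levels_are_unit_fractions(self):
        # 5% minor in 1000 units: every defining variant at truth level 0.05
        spec = mixture_spec(n_total_units=1000, n_minor_units=50, n_defining=20,
                            unit_length=500)
        truth = make_mixture_genome(spec, 3)
        assert len(truth.truth_variants) == 20
        assert np.allclose(truth.truth_variants["level"], 0.05)
        # truth levels are multiples of 1/total_units
        levels = truth.truth_variants["level"] * truth.total_units
        assert np.allclose(levels, np.round(levels))

    def test_minimum_detectable_level_arithmetic(self):
        spec = VntrAlleleSpec(n_units_allele1=16, n_units_allele2=24, unit_length=900)
        truth = make_vntr_genome(spec, 5)
        assert truth.total_units == 40
        assert 1 / truth.total_units == pytest.approx(0.025)

    def test_units_differ_only_at_panel(self):
        truth = make_vntr_genome(VntrAlleleSpec(unit_length=700, n_variant_positions=6,
                                                n_units_allele1=3, n_units_allele2=3), 9)
        panel0 = {p - 1 for p in truth.panel_positions}
        ref = truth.unit_sequences[0]
        for seq in truth.unit_sequences[1:]:
            assert len(seq) == len(ref)
            diffs = {i for i, (a, b) in enumerate(zip(ref, seq)) if a != b}
            assert diffs <= panel0

    def test_expansion_block_multiplicity_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            VntrAlleleSpec(n_units_allele1=3, n_units_allele2=3,
                           expansion_blocks=[(0, 2), (1, 2)])

    def test_unit_too_small_rejected(self):
        with pytest.raises(ValueError, match="unit_length"):
            VntrAlleleSpec(unit_length=150, n_variant_positions=20)

    def test_determinism_byte_identical(self, tmp_path):
        spec = mixture_spec(n_total_units=10, n_minor_units=1, n_defining=4, unit_length=400)
        outs = []
        for _ in range(2):
            truth = make_mixture_genome(spec, 21)
            records, lineage, _ = simulate_experiment(
                truth, UmiDesign(), ErrorModel.v14_sup(), 3,
                depth=ReadDepth(mean=5), seed=22,
            )
            p = tmp_path / f"{len(outs)}.fastq"
            write_fastq(records, p)
            outs.append((p.read_bytes(), lineage.to_csv(), truth.truth_variants.to_csv()))
        assert outs[0] == outs[1]


class TestTagAndAmplify:
    def _truth(self, n_units=4, seed=2):
        return make_vntr_genome(
            VntrAlleleSpec(unit_length=500, n_units_allele1=n_units // 2,
                           n_units_allele2=n_units - n_units // 2,
                           n_variant_positions=4), seed)

    def test_no_error_no_chimera_progeny_match_template(self, rng):
        truth = self._truth()
        pool = tag_and_amplify(truth, 3, UmiDesign(), NOERR, cycles=0, rng=rng)
        assert len(pool) == 12
        for mol in pool:
            assert not mol.pcr_events and not mol.is_chimera
            assert truth.unit_sequences[mol.unit_index] in mol.sequence
            assert mol.sequence.count(mol.umi_start) >= 1

    def test_pcr_event_count_matches_poisson_oracle(self, rng):
        truth = self._truth()
        model = NOERR.replace(pcr_error_rate=1e-4)
        pool = tag_and_amplify(truth, 50, UmiDesign(), model, cycles=25, rng=rng)
        total_bases = sum(len(m.sequence) for m in pool)
        expected = total_bases * 1e-4 * 25
        observed = sum(len(m.pcr_events) for m in pool)
        assert abs(observed - expected) < 3 * np.sqrt(expected)

    def test_forced_chimeras_have_discordant_umis(self, rng):
        truth = self._truth(n_units=2)
        model = NOERR.replace(chimera_rate=1.0 - 1e-12)
        pool = tag_and_amplify(truth, 1, UmiDesign(), model, cycles=0, rng=rng)
        assert all(m.is_chimera for m in pool)
        for m in pool:
            # 3' UMI comes from the partner molecule, not this template
            assert m.partner_unit is not None

    def test_invalid_template_count_rejected(self, rng):
        with pytest.raises(ValueError):
            tag_and_amplify(self._truth(), 0, UmiDesign(), NOERR, rng=rng)


class TestSequenceReads:
    def test_no_error_reads_equal_molecules(self, rng):
        truth = make_vntr_genome(single_haplotype_spec(4, unit_length=400), 3)
        pool = tag_and_amplify(truth, 2, UmiDesign(), NOERR, cycles=0, rng=rng)
        records, lineage = sequence_reads(pool, NOERR, ReadDepth("constant", 4), rng)
        by_id = {m.molecule_id: m.sequence for m in pool}
        assert len(records) == 8 * 4
        for rec in records:
            row = lineage[lineage.read_id == rec.id].iloc[0]
            expect = by_id[row.molecule_id]
            if row.strand == "-":
                expect = reverse_complement(expect)
            assert rec.sequence == expect

    def test_substitution_rate_calibration_binomial_oracle(self, rng):
        # >=1 Mb of substitution-only reads: mismatch fraction within 3 sd
        truth = make_vntr_genome(single_haplotype_spec(2, unit_length=1000), 4)
        pool = tag_and_amplify(truth, 2, UmiDesign(), NOERR, cycles=0, rng=rng)
        model = NOERR.replace(substitution_rate=0.01)
        records, lineage = sequence_reads(pool, model, ReadDepth("constant", 250), rng)
        by_id = {m.molecule_id: m.sequence for m in pool}
        mismatches = bases = 0
        for rec, row in zip(records, lineage.itertuples()):
            expect = by_id[row.molecule_id]
            seq = rec.sequence if row.strand == "+" else reverse_complement(rec.sequence)
            assert len(seq) == len(expect)
            mismatches += sum(a != b for a, b in zip(seq, expect))
            bases += len(seq)
        assert bases >= 1_000_000
        # substituted bases change identity with prob 1 (draw from other 3)
        sd = np.sqrt(bases * 0.01 * 0.99)
        assert abs(mismatches - bases * 0.01) < 3 * sd

    def test_systematic_component_only_produces_transversions(self, rng):
        truth = make_vntr_genome(single_haplotype_spec(2, unit_length=600), 5)
        pool = tag_and_amplify(truth, 2, UmiDesign(), NOERR, cycles=0, rng=rng)
        model = NOERR.replace(systematic_transversion_rate=0.02)
        records, lineage = sequence_reads(pool, model, ReadDepth("constant", 40), rng)
        by_id = {m.molecule_id: m.sequence for m in pool}
        seen = set()
        for rec, row in zip(records, lineage.itertuples()):
            expect = by_id[row.molecule_id]
            seq = rec.sequence if row.strand == "+" else reverse_complement(rec.sequence)
            for a, b in zip(expect, seq):
                if a != b:
                    seen.add(f"{a}>{b}")
        assert seen <= {"C>A", "G>T"} and seen

    def test_read_count_conservation_and_unique_lineage(self, small_mixture):
        records, lineage = small_mixture["records"], small_mixture["lineage"]
        assert len(records) == len(lineage)
        assert lineage["read_id"].is_unique
        assert {r.id for r in records} == set(lineage["read_id"])
        # every read traces to a real unit
        n_units = small_mixture["truth"].total_units
        assert lineage["unit_index"].between(0, n_units - 1).all()

    def test_error_free_unit_pileup_reproduces_truth_levels(self):
        # direct count over the generated units equals the truth table
        truth = make_mixture_genome(
            mixture_spec(n_total_units=40, n_minor_units=2, n_defining=6, unit_length=400), 8)
        for row in truth.truth_variants.itertuples():
            carrying = sum(
                1 for s in truth.unit_sequences if s[row.position - 1] == row.alt
            )
            assert carrying / truth.total_units == pytest.approx(row.level)


class TestTrioAndStr:
    def test_trio_child_haplotypes_contained_in_parents(self):
        trio = make_trio(variant_seed=13)
        child = set(trio["child"].truth_haplotypes["haplotype"])
        parents = set(trio["father"].truth_haplotypes["haplotype"]) | set(
            trio["mother"].truth_haplotypes["haplotype"]
        )
        assert child <= parents

    def test_str_injection_recorded_in_truth(self):
        spec = VntrAlleleSpec(
            unit_length=800, n_units_allele1=3, n_units_allele2=3,
            n_variant_positions=5, str_spec=StrSpec(),
        )
        truth = make_vntr_genome(spec, 17)
        assert truth.str_truth is not None and len(truth.str_truth) == 6
        for row in truth.str_truth.itertuples():
            seq = truth.unit_sequences[row.unit_index]
            assert "CA" * row.repeat_count in seq


class TestErrorModel:
    def test_builtin_profiles_have_sane_error_totals(self):
        for name, lo, hi in [("R9_HAC", 0.03, 0.08), ("V14_HAC", 0.007, 0.013),
                             ("V14_SUP", 0.005, 0.012)]:
            m = ErrorModel.from_profile(name)
            assert lo < m.total_error_rate < hi
        assert ErrorModel.from_profile("R9_HAC").split_size_threshold == 12
        assert ErrorModel.from_profile("V14_HAC").split_size_threshold == 10
        assert ErrorModel.from_profile("V14_SUP").split_size_threshold == 8

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ErrorModel(substitution_rate=0.2)  # total error too high
        with pytest.raises(ValueError):
            ErrorModel(substitution_rate=-0.1)
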