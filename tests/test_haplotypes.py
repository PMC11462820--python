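import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from umiont.haplotypes import (
    binomial_min_occurrence,
    coverage_correct,
    distance_matrix,
    estimate_copy_number,
    export_distances,
    extract_haplotypes,
    noise_filter,
    trio_containment,
)
from umiont.seqio import VariantRow
from umiont.simulate import (
    VntrAlleleSpec,
    consensus_pool,
    make_trio,
    make_vntr_genome,
)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _calls(pairs, depth=1000):
    rows = []
    for pos, alt, level in pairs:
        k = int(round(level * depth))
        rows.append(VariantRow(pos, "T", alt, k / depth, k, depth))
    return rows


class TestExtractHaplotypes:
    def test_identical_consensus_single_haplotype(self, rng):
        ref = _random_seq(rng, 200)
        panel = [50, 100, 150]
        calls = _calls([(p, "A", 0.5) for p in panel])
        counts = extract_haplotypes([ref] * 100, ref, panel, calls)
        assert counts == {"".join(ref[p - 1] for p in panel): 100}

    def test_subthreshold_position_uses_major_allele_only(self, rng):
        ref = _random_seq(rng, 200)
        pos = 80
        alt = "A" if ref[pos - 1] != "A" else "C"
        variant = ref[: pos - 1] + alt + ref[pos:]
        seqs = [ref] * 995 + [variant] * 5  # 0.5% < 0.85%
        calls = _calls([(pos, alt, 0.005)])
        counts = extract_haplotypes(seqs, ref, [pos], calls)
        assert counts == {ref[pos - 1]: 1000}
        assert alt not in "".join(counts)

    def test_two_groups_counted_separately(self, rng):
        ref = _random_seq(rng, 300)
        panel = [60, 120, 180]
        other = list(ref)
        for p in panel:
            other[p - 1] = "A" if ref[p - 1] != "A" else "C"
        other = "".join(other)
        calls = _calls([(p, other[p - 1], 0.4) for p in panel])
        counts = extract_haplotypes([ref] * 60 + [other] * 40, ref, panel, calls)
        assert sorted(counts.values()) == [40, 60]

    def test_deletion_spanning_panel_position_recorded(self, rng):
        ref = _random_seq(rng, 200)
        pos = 100
        deleted = ref[: pos - 1] + ref[pos:]
        alt = "A" if ref[pos - 1] != "A" else "C"
        variant = ref[: pos - 1] + alt + ref[pos:]
        seqs = [variant] * 60 + [deleted] * 40
        calls = _calls([(pos, alt, 0.6)])
        counts = extract_haplotypes(seqs, ref, [pos], calls)
        assert counts == {alt: 60, "-": 40}

    def test_empty_panel_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_haplotypes(["ACGT"], "ACGT", [], [])


class TestNoiseFilter:
    def test_subthreshold_merged_into_nearest(self):
        counts = {"AAA": 500, "AAT": 5, "CCC": 495}
        merged = noise_filter(counts, 1000)
        assert merged == {"AAA": 505, "CCC": 495}

    def test_all_above_floor_unchanged(self):
        counts = {"AAA": 300, "CCC": 700}
        assert noise_filter(counts, 1000) == counts

    def test_distant_orphan_retained(self):
        counts = {"AAAA": 995, "TTGG": 5}
        assert noise_filter(counts, 1000) == counts

    def test_tie_goes_to_higher_count_target(self):
        counts = {"AAT": 4, "AAA": 600, "ATT": 396}
        merged = noise_filter(counts, 1000)
        assert merged == {"AAA": 604, "ATT": 396}

    @settings(max_examples=40, deadline=None)
    @given(st.dictionaries(st.text(alphabet="ACGT", min_size=3, max_size=3),
                           st.integers(1, 500), min_size=1, max_size=8))
    def test_total_observations_conserved(self, counts):
        n = sum(counts.values())
        merged = noise_filter(counts, n)
        assert sum(merged.values()) == n


class TestBinomialThreshold:
    def test_zero_noise_probability(self):
        assert binomial_min_occurrence(1000, 0.0) == 1

    def test_alpha_one_no_filtering(self):
        assert binomial_min_occurrence(1000, 0.001, alpha=1.0) == 1

    def test_worked_example(self):
        # n=1000, p=0.001: P(X>=5) ~ 0.0037 <= 0.01 < P(X>=4) ~ 0.019
        assert binomial_min_occurrence(1000, 0.001, alpha=0.01) == 5

    @settings(max_examples=40, deadline=None)
    @given(st.integers(10, 300), st.floats(1e-5, 0.05), st.floats(1e-4, 0.5))
    def test_matches_exact_tail_enumeration(self, n, p, alpha):
        def upper_tail(k):
            return sum(
                math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
            )

        k = binomial_min_occurrence(n, p, alpha)
        assert upper_tail(k) <= alpha + 1e-12
        if k > 1:
            assert upper_tail(k - 1) > alpha


class TestCoverageCorrect:
    def test_equal_coverage(self):
        est = coverage_correct({"A": 50, "B": 50}, binomial_p=0.0)
        assert sorted(h.copies for h in est.haplotypes) == [1, 1]
        assert est.total_copies == 2

    def test_expansion_arithmetic(self):
        # counts {10,10,20,40}: median 15 -> ratios {.67,.67,1.33,2.67} -> {1,1,1,3}
        est = coverage_correct({"A": 10, "B": 10, "C": 20, "D": 40}, binomial_p=0.0)
        by_hap = {h.alleles: h.copies for h in est.haplotypes}
        assert by_hap == {"A": 1, "B": 1, "C": 1, "D": 3}
        assert est.total_copies == 6

    def test_single_haplotype_plasmid_case(self):
        est = coverage_correct({"AAAA": 500}, binomial_p=0.0)
        assert est.total_copies == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            coverage_correct({})


class TestCopyNumberRecovery:
    @pytest.mark.parametrize("k_total", [15, 30, 45])
    def test_recovery_within_three_units(self, k_total):
        """Coverage-corrected estimate within +/-3 units of truth in >=90%
        of 20 seeded replicates, with a 3-fold expansion block present.

        Each replicate gets a fixed per-sample consensus budget (~2000
        sequences), as in a real experiment where total sequencing depth,
        not per-unit depth, is the design constant."""
        n_hap = k_total - 2  # one haplotype carries 3 identical units
        blocks = [(h, 1) for h in range(n_hap - 1)] + [(n_hap - 1, 3)]
        spec = VntrAlleleSpec(
            unit_length=500,
            n_units_allele1=k_total // 2,
            n_units_allele2=k_total - k_total // 2,
            n_variant_positions=24,
            expansion_blocks=blocks,
        )
        hits = []
        errors = {"unique": [], "filtered": [], "corrected": []}
        for seed in range(20):
            truth = make_vntr_genome(spec, variant_seed=1000 + seed)
            rng = np.random.default_rng(2000 + seed)
            seqs = consensus_pool(truth, molecules_per_unit=2000 // k_total, rng=rng)
            panel = truth.panel_positions
            calls = [
                VariantRow(int(r.position), r.ref, r.alt, r.level,
                           int(r.carrying_units), int(r.total_units))
                for r in truth.truth_variants.itertuples()
                if r.level > 0.0085
            ]
            est = estimate_copy_number(seqs, truth.reference, panel, calls)
            hits.append(abs(est.total_copies - k_total) <= 3)
            errors["unique"].append(abs(est.unique_count - k_total))
            errors["filtered"].append(abs(est.filtered_count - k_total))
            errors["corrected"].append(abs(est.total_copies - k_total))
        assert np.mean(hits) >= 0.90
        # staged improvement: unique -> noise-filtered -> coverage-corrected
        assert np.mean(errors["corrected"]) <= np.mean(errors["filtered"])
        assert np.mean(errors["filtered"]) <= np.mean(errors["unique"])

    def test_expansion_block_receives_three_copies(self):
        spec = VntrAlleleSpec(
            unit_length=500, n_units_allele1=7, n_units_allele2=8,
            n_variant_positions=14,
            expansion_blocks=[(h, 1) for h in range(12)] + [(12, 3)],
        )
        truth = make_vntr_genome(spec, variant_seed=77)
        rng = np.random.default_rng(78)
        seqs = consensus_pool(truth, molecules_per_unit=40, rng=rng)
        calls = [
            VariantRow(int(r.position), r.ref, r.alt, r.level,
                       int(r.carrying_units), int(r.total_units))
            for r in truth.truth_variants.itertuples()
        ]
        est = estimate_copy_number(seqs, truth.reference, truth.panel_positions, calls)
        expanded = truth.haplotype_strings[12]
        by_hap = {h.alleles: h.copies for h in est.haplotypes}
        assert by_hap[expanded] == 3


class TestTrioContainment:
    @staticmethod
    def _estimate(truth, seed):
        rng = np.random.default_rng(seed)
        seqs = consensus_pool(truth, molecules_per_unit=25, rng=rng)
        calls = [
            VariantRow(int(r.position), r.ref, r.alt, r.level,
                       int(r.carrying_units), int(r.total_units))
            for r in truth.truth_variants.itertuples()
            if r.level > 0.0085
        ]
        return estimate_copy_number(seqs, truth.reference, truth.panel_positions, calls)

    def test_mendelian_trio_no_private_haplotypes(self):
        trio = make_trio(k_father=(6, 8), k_mother=(7, 9), variant_seed=31)
        ests = {k: self._estimate(t, 40 + i) for i, (k, t) in enumerate(trio.items())}
        n_private, listing = trio_containment(
            ests["child"], ests["father"], ests["mother"]
        )
        assert n_private == 0 and listing == []

    def test_forced_novel_haplotype_detected(self):
        child = {"AAAA", "CCCC", "TTTT"}
        assert trio_containment(child, {"AAAA"}, {"CCCC"}) == (1, ["TTTT"])

    def test_identical_sets_no_private(self):
        s = {"AAAA", "CCCC"}
        assert trio_containment(s, s, s)[0] == 0


class TestDistances:
    def test_two_haplotypes_matrix(self, tmp_path):
        mat = export_distances(["AAAA", "ATTA"], tmp_path / "d.phy")
        assert mat.tolist() == [[0, 2], [2, 0]]
        assert (tmp_path / "d.phy").read_text().splitlines()[0] == "2"

    def test_matrix_matches_recomputation(self, rng):
        haps = list({_random_seq(rng, 12) for _ in range(6)})
        mat = distance_matrix(haps)
        from umiont.cluster import edit_distance

        for i in range(len(haps)):
            assert mat[i, i] == 0
            for j in range(len(haps)):
                assert mat[i, j] == mat[j, i] == edit_distance(haps[i], haps[j])

    def test_unique_set_offdiagonal_positive(self, rng):
        haps = list({_random_seq(rng, 10) for _ in range(5)})
        mat = distance_matrix(haps)
        off = mat[~np.eye(len(haps), dtype=bool)]
        assert (off >= 1).all()

    def test_single_haplotype_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_distances(["AAAA"], tmp_path / "d.phy")
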