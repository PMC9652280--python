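"""Strain aggregation, reference scanning, and variant calling."""

import numpy as np
import pytest

from kstrain.compare import (
    ContigScan,
    ReferenceScan,
    StrainKmerSet,
    aggregate,
    call_altered_runs,
    call_insertions,
    scan_reference,
    strain_set,
)
from kstrain.evaluation import brute_force_presence, score_calls
from kstrain.kmers import IndividualKmerSet, canonicalize, genome_kmer_set
from kstrain.simulate import (
    SimulationConfig,
    VariantSpec,
    make_reference,
    plant_variants,
)

# distinct canonical 3-mers used as schematic k-mers
X, Y, Z = "AAC", "AAG", "ACC"


def iset(*kmers):
    return IndividualKmerSet.from_kmers(3, kmers)


class TestAggregate:
    def test_hand_enumerated_counters(self):
        agg = aggregate({"A": [iset(X, Y), iset(X)], "B": [iset(Y), iset(Y, Z)]})
        assert agg.membership() == {X: (2, 0), Y: (1, 2), Z: (0, 1)}
        assert agg.summary[2, 0] == 1
        assert agg.summary[1, 2] == 1
        assert agg.summary[0, 1] == 1
        assert agg.summary[0, 0] == 0

    def test_empty_sets_give_empty_membership(self):
        agg = aggregate({"A": [iset(), iset()], "B": [iset()]})
        assert len(agg) == 0 and agg.summary.sum() == 0

    def test_summary_mass_equals_union_cardinality(self):
        rng = np.random.default_rng(3)
        pool = sorted({canonicalize("".join("ACGT"[i] for i in rng.integers(0, 4, 3)))
                       for _ in range(40)})
        for trial in range(20):
            sets_a = [iset(*(km for km in pool if rng.random() < 0.4))
                      for _ in range(rng.integers(1, 5))]
            sets_b = [iset(*(km for km in pool if rng.random() < 0.4))
                      for _ in range(rng.integers(1, 5))]
            agg = aggregate({"A": sets_a, "B": sets_b})
            union = set().union(*(s.members for s in sets_a + sets_b))
            assert agg.summary.sum() == len(agg) == len(union)
            assert agg.summary[0, 0] == 0

    def test_mixed_k_rejected(self):
        five = IndividualKmerSet.from_kmers(5, ["AACGT"])
        with pytest.raises(ValueError, match="mixed k"):
            aggregate({"A": [iset(X)], "B": [five]})

    def test_requires_two_strains(self):
        with pytest.raises(ValueError):
            aggregate({"A": [iset(X)]})


class TestStrainSet:
    def _agg(self):
        return aggregate({"A": [iset(X, Y), iset(X)], "B": [iset(Y), iset(Y, Z)]})

    def test_majority_selection(self):
        assert strain_set(self._agg(), "A", 2).members == {X}

    def test_m_one_is_union_and_m_n_is_intersection(self):
        agg = self._agg()
        assert strain_set(agg, "B", 1).members == {Y, Z}
        assert strain_set(agg, "B", 2).members == {Y}

    def test_m_out_of_range(self):
        with pytest.raises(ValueError):
            strain_set(self._agg(), "A", 3)
        with pytest.raises(ValueError):
            strain_set(self._agg(), "A", 0)

    def test_unknown_strain(self):
        with pytest.raises(ValueError, match="unknown strain"):
            strain_set(self._agg(), "C", 1)


class TestScanReference:
    def test_complete_strain_set_marks_everything(self):
        ref = {"c": "ACGTACGTACGTTTAGC"}
        sset = StrainKmerSet.from_kmers(3, genome_kmer_set(ref, 3).members)
        scan = scan_reference(ref, sset)
        assert scan.total_altered_bp == 0
        assert scan.contigs["c"].presence.all()

    def test_single_missing_kmer_footprint(self):
        # ref ACGTACGTAC, k=3: windows at 2,3,6,7 are GTA-canonical; with GTA
        # removed from the strain set only bases 8 and 9 lose all cover
        ref = {"c": "ACGTACGTAC"}
        members = genome_kmer_set(ref, 3).members - {"GTA"}
        scan = scan_reference(ref, StrainKmerSet.from_kmers(3, members))
        altered = np.flatnonzero(scan.contigs["c"].altered)
        assert list(altered) == [8, 9]

    def test_contig_shorter_than_k_is_unscannable(self):
        ref = {"tiny": "ACGT"}
        scan = scan_reference(ref, StrainKmerSet.from_kmers(27, []))
        contig = scan.contigs["tiny"]
        assert not contig.presence.any()
        assert contig.absent_start.size == 0
        assert contig.unscannable.all()
        assert scan.total_altered_bp == 0

    def test_ambiguous_bases_are_unscannable_not_altered(self):
        ref = {"c": "ACGTACG" + "N" * 5 + "TTACGGA"}
        sset = StrainKmerSet.from_kmers(3, genome_kmer_set(ref, 3).members)
        scan = scan_reference(ref, sset)
        contig = scan.contigs["c"]
        assert contig.unscannable[7:12].all()
        assert scan.total_altered_bp == 0

    def test_monotone_in_strain_set(self):
        rng = np.random.default_rng(4)
        ref = {"c": "".join("ACGT"[i] for i in rng.integers(0, 4, 400))}
        all_kmers = sorted(genome_kmer_set(ref, 7).members)
        prev = None
        for frac in (0.2, 0.5, 0.8, 1.0):
            members = all_kmers[: int(len(all_kmers) * frac)]
            scan = scan_reference(ref, StrainKmerSet.from_kmers(7, members))
            if prev is not None:
                assert scan.total_altered_bp <= prev
            prev = scan.total_altered_bp

    def test_matches_bruteforce_substring_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(10):
            n = int(rng.integers(300, 2000))
            ref_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            # random strain edits: substitutions plus a deletion
            strain = list(ref_seq)
            for _ in range(int(rng.integers(1, 8))):
                p = int(rng.integers(0, n))
                strain[p] = "ACGT"[int(rng.integers(0, 4))]
            dstart = int(rng.integers(0, n - 30))
            strain_seq = "".join(strain[:dstart] + strain[dstart + int(rng.integers(0, 10)):])
            k = 27
            sset = StrainKmerSet.from_kmers(
                k, genome_kmer_set(strain_seq, k).members)
            scan = scan_reference({"c": ref_seq}, sset)
            oracle = brute_force_presence(ref_seq, [strain_seq], k)
            assert np.array_equal(scan.contigs["c"].presence, oracle)

    def test_label_swap_symmetry(self):
        agg = aggregate({"A": [iset(X, Y)], "B": [iset(Y, Z)]})
        swapped = aggregate({"B": [iset(Y, Z)], "A": [iset(X, Y)]})
        ref = {"c": "AACAAGACC"}
        for strain in ("A", "B"):
            s1 = scan_reference(ref, strain_set(agg, strain, 1))
            s2 = scan_reference(ref, strain_set(swapped, strain, 1))
            assert np.array_equal(s1.contigs["c"].presence, s2.contigs["c"].presence)


def scan_of(altered_positions, length, k=3, absent=None):
    presence = np.ones(length, dtype=bool)
    presence[list(altered_positions)] = False
    absent_start = np.zeros(max(0, length - k + 1), dtype=bool)
    if absent:
        absent_start[list(absent)] = True
    contig = ContigScan(presence=presence, absent_start=absent_start,
                        unscannable=np.zeros(length, dtype=bool))
    return ReferenceScan(k=k, strain="s", contigs={"c": contig})


class TestCallAlteredRuns:
    def test_run_length_encoding(self):
        calls = call_altered_runs(scan_of({10, 11, 12, 50}, 100))
        assert [(c.start, c.end, c.length) for c in calls] == [(10, 13, 3), (50, 51, 1)]
        assert all(c.vclass == "altered_run" for c in calls)

    def test_no_altered_positions(self):
        assert call_altered_runs(scan_of(set(), 100)) == []

    def test_lengths_sum_to_total_altered(self):
        scan = scan_of({1, 2, 3, 7, 20, 21, 99}, 100)
        calls = call_altered_runs(scan)
        assert sum(c.length for c in calls) == 7


class TestCallInsertions:
    def test_absent_run_over_present_bases_is_an_insertion(self):
        # k=3: absent windows 5..6 cover bases [5, 9); no altered bases
        scan = scan_of(set(), 20, k=3, absent={5, 6})
        calls = call_insertions(scan)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.length, c.vclass) == (7, 7, 2, "insertion")

    def test_no_absent_kmers_no_calls(self):
        assert call_insertions(scan_of(set(), 20, k=3)) == []

    def test_absent_run_overlapping_altered_is_not_an_insertion(self):
        scan = scan_of({6}, 20, k=3, absent={4, 5, 6})
        assert call_insertions(scan) == []


@pytest.fixture(scope="module")
def planted():
    k = 27
    ref = make_reference(SimulationConfig(reference_length=20_000, seed=31))
    genome, truth = plant_variants(
        ref, VariantSpec(4, 2, 2, min_spacing=2 * k), seed=32, k=k)
    sset = StrainKmerSet.from_kmers(k, genome_kmer_set(genome, k).members)
    scan = scan_reference(ref, sset)
    return truth, scan, k


class TestPlantedSignatures:
    """Window-geometry exactness on noiseless genomes (exact k-mer sets)."""

    def test_substitutions_and_deletions_exact(self, planted):
        truth, scan, k = planted
        score = score_calls(truth, call_altered_runs(scan), call_insertions(scan), k)
        assert score.recall == 1.0
        assert score.false_positive_calls == 0
        assert score.substitution_exact == 4
        assert score.deletion_exact == 2

    def test_insertions_zero_altered_one_junction_call(self, planted):
        truth, scan, k = planted
        insertions = call_insertions(scan)
        assert len(insertions) == 2
        assert all(c.length == k - 1 and c.start == c.end for c in insertions)
        planted_pos = sorted(v.ref_start for v in truth if v.vclass == "insertion")
        assert sorted(c.start for c in insertions) == planted_pos
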