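import numpy as np
import pytest

from cladesig.core_genome import (Supermatrix, align_progressive, concatenate,
                                  greedy_cluster, pairwise_identity,
                                  resolve_paralogs, select_core,
                                  supermatrix_slice, trim_alignment)
from cladesig.seqio import GAP, AlignedRow, Alignment, SequenceRecord

from conftest import AA, oracle_greedy_partition, random_protein


class TestPairwiseIdentity:
    @pytest.mark.parametrize("a,b,frac,identical,compared", [
        ("ACDE", "ACDE", 1.0, 4, 4),
        ("ACDE", "ACDF", 0.75, 3, 4),
    ])
    def test_global_examples(self, a, b, frac, identical, compared):
        res = pairwise_identity(a, b)
        assert (res.fraction, res.identical, res.compared) == (frac, identical, compared)

    def test_gap_columns_excluded_in_aligned_mode(self):
        res = pairwise_identity("AC-E", "ACDE", mode="aligned")
        assert res == (1.0, 3, 3)

    def test_ambiguity_excluded(self):
        res = pairwise_identity("ACXE", "ACDE", mode="aligned")
        assert res.compared == 3 and res.fraction == 1.0

    def test_zero_compared_is_error(self):
        with pytest.raises(ValueError, match="zero compared"):
            pairwise_identity("--XX", "AC--", mode="aligned")

    def test_aligned_mode_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACDE", "ACD", mode="aligned")


def _mutate_n(rng, seq, n):
    idx = rng.choice(len(seq), size=n, replace=False)
    out = list(seq)
    for i in idx:
        out[i] = AA[(AA.index(out[i]) + 7) % len(AA)]
    return "".join(out)


class TestGreedyCluster:
    def test_singleton(self):
        fams = greedy_cluster([SequenceRecord("a", "g1", "ACDEFGHIKL")])
        assert len(fams) == 1 and fams[0].representative == "a"

    def test_identical_pair_merges(self):
        recs = [SequenceRecord("a", "g1", "ACDEFGHIKL"),
                SequenceRecord("b", "g2", "ACDEFGHIKL")]
        (fam,) = greedy_cluster(recs)
        assert fam.genomes == {"g1", "g2"}

    def test_three_record_partition_matches_oracle(self):
        rng = np.random.default_rng(7)
        a = random_protein(rng, 40)
        b = _mutate_n(rng, a, 8)      # ~80% identity to a
        c = random_protein(rng, 40)   # unrelated
        recs = [SequenceRecord("A", "g1", a), SequenceRecord("B", "g2", b),
                SequenceRecord("C", "g3", c)]
        fams = greedy_cluster(recs)
        got = {frozenset(m.id for m in f.members) for f in fams}
        expected = set(oracle_greedy_partition(
            recs, 0.5, 0.5, lambda x, y: pairwise_identity(x, y).fraction))
        assert got == expected
        assert frozenset({"A", "B"}) in got and frozenset({"C"}) in got

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_property_and_oracle_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        recs = []
        for i in range(n):
            if recs and rng.random() < 0.5:
                parent = recs[int(rng.integers(len(recs)))].residues
                seq = _mutate_n(rng, parent, int(rng.integers(0, len(parent) // 3)))
            else:
                seq = random_protein(rng, int(rng.integers(20, 60)))
            recs.append(SequenceRecord(f"r{i}", f"g{i}", seq))
        fams = greedy_cluster(recs)
        ids = [m.id for f in fams for m in f.members]
        assert sorted(ids) == sorted(r.id for r in recs)  # exact partition
        got = {frozenset(m.id for m in f.members) for f in fams}
        expected = set(oracle_greedy_partition(
            recs, 0.5, 0.5, lambda x, y: pairwise_identity(x, y).fraction))
        assert got == expected


class TestSelectCore:
    def _families(self, rng):
        seq = random_protein(rng, 30)
        fam8 = [SequenceRecord(f"a{i}", f"g{i}", seq) for i in range(8)]
        fam7 = [SequenceRecord(f"b{i}", f"g{i}", seq) for i in range(7)]
        from cladesig.core_genome import ProteinFamily
        return (ProteinFamily("F1", fam8, "a0"), ProteinFamily("F2", fam7, "b0"))

    def test_presence_threshold(self):
        rng = np.random.default_rng(0)
        f8, f7 = self._families(rng)
        genomes = {f"g{i}" for i in range(10)}
        kept = select_core([f8, f7], genomes, 0.8)
        assert [f.family_id for f in kept] == ["F1"]

    def test_paralogs_count_once(self):
        from cladesig.core_genome import ProteinFamily
        seq = "ACDEFGHIKLMNPQRSTVWY"
        fam = ProteinFamily("F1", [
            SequenceRecord("a", "g1", seq), SequenceRecord("b", "g1", seq),
            SequenceRecord("c", "g2", seq)], "a")
        assert select_core([fam], {f"g{i}" for i in range(1, 11)}, 0.3) == []

    def test_monotone_in_min_presence(self):
        rng = np.random.default_rng(1)
        fams = list(self._families(rng))
        genomes = {f"g{i}" for i in range(10)}
        sizes = [len(select_core(fams, genomes, p))
                 for p in (0.1, 0.3, 0.5, 0.7, 0.8, 0.9, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_resolve_paralogs_keeps_closest(self):
        rng = np.random.default_rng(2)
        from cladesig.core_genome import ProteinFamily
        rep = random_protein(rng, 40)
        close = _mutate_n(rng, rep, 2)
        far = _mutate_n(rng, rep, 15)
        fam = ProteinFamily("F1", [
            SequenceRecord("rep", "g1", rep),
            SequenceRecord("far", "g2", far),
            SequenceRecord("close", "g2", close)], "rep")
        resolved = resolve_paralogs(fam)
        assert {m.id for m in resolved.members} == {"rep", "close"}

    def test_empty_genomes_error(self):
        with pytest.raises(ValueError):
            select_core([], set(), 0.8)


class TestAlignProgressive:
    def test_identical_sequences_align_without_gaps(self):
        recs = [SequenceRecord(f"r{i}", f"g{i}", "ACDEFGHIKL") for i in range(3)]
        aln = align_progressive(recs)
        assert aln.n_cols == 10
        assert all(GAP not in r.seq for r in aln.rows)

    def test_known_deletion_recovered(self):
        recs = [SequenceRecord("a", "g1", "ACDEFGHIKL"),
                SequenceRecord("b", "g2", "ACDEGHIKL"),   # F deleted
                SequenceRecord("c", "g3", "ACDEFGHIKL")]
        aln = align_progressive(recs)
        assert aln.n_cols == 10
        row_b = next(r for r in aln.rows if r.id == "b")
        assert row_b.seq.count(GAP) == 1

    def test_degap_recovers_inputs(self):
        rng = np.random.default_rng(3)
        recs = []
        base = random_protein(rng, 50)
        for i in range(5):
            s, e = sorted(rng.integers(5, 45, size=2))
            seq = base[:s] + base[e:] if rng.random() < 0.5 else base
            recs.append(SequenceRecord(f"r{i}", f"g{i}", seq or base))
        aln = align_progressive(recs)
        for i, rec in enumerate(recs):
            assert aln.degapped(i) == rec.residues


class TestTrimAndConcatenate:
    def test_gappy_column_removed(self):
        aln = Alignment([
            AlignedRow("a", "g1", "A-C"),
            AlignedRow("b", "g2", "A-C"),
            AlignedRow("c", "g3", "ADC"),
            AlignedRow("d", "g4", "ADC"),
            AlignedRow("e", "g5", "A-C"),  # col 2: 60% gaps
        ])
        trimmed, kept = trim_alignment(aln, max_gap_fraction=0.5)
        assert kept == [1, 3]
        assert trimmed.rows[0].seq == "AC"

    def test_conserved_alignment_unchanged(self):
        aln = Alignment([AlignedRow("a", "g1", "ACDE"), AlignedRow("b", "g2", "ACDE")])
        trimmed, kept = trim_alignment(aln)
        assert kept == [1, 2, 3, 4] and trimmed.rows[0].seq == "ACDE"

    def test_all_gap_column_always_removed(self):
        aln = Alignment([AlignedRow("a", "g1", "A-C"), AlignedRow("b", "g2", "A-C")])
        _, kept = trim_alignment(aln, max_gap_fraction=1.0)
        assert kept == [1, 3]

    def test_everything_removed_is_error(self):
        aln = Alignment([AlignedRow("a", "g1", "--"), AlignedRow("b", "g2", "--")])
        with pytest.raises(ValueError):
            trim_alignment(aln)

    def _two_families(self):
        f1 = Alignment([AlignedRow("a", "g1", "ACDEFGHIKL"),
                        AlignedRow("b", "g2", "ACDEFGHIKL")])
        f2 = Alignment([AlignedRow("c", "g1", "WYVTSRQPNMLKIHG")])
        return [("F1", f1), ("F2", f2)]

    def test_widths_and_gap_fill(self):
        sm = concatenate(self._two_families(), ["g1", "g2"])
        assert sm.alignment.n_cols == 25
        assert sm.partitions == [("F1", 1, 10), ("F2", 11, 25)]
        g2 = sm.alignment.row_by_genome("g2")
        assert g2.seq[10:] == GAP * 15

    def test_row_slices_recover_members(self):
        sm = concatenate(self._two_families(), ["g1", "g2"])
        assert supermatrix_slice(sm, "g1", "F2") == "WYVTSRQPNMLKIHG"
        assert supermatrix_slice(sm, "g2", "F2") == ""

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            concatenate([], ["g1"])
        with pytest.raises(ValueError):
            concatenate(self._two_families(), [])

    def test_duplicate_genome_in_family_error(self):
        aln = Alignment([AlignedRow("a", "g1", "AC"), AlignedRow("b", "g1", "AC")])
        with pytest.raises(ValueError):
            concatenate([("F1", aln)], ["g1"])
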