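import numpy as np
import pytest

from cladesig.csi_finder import (ScanParams, assess_specificity, check_flanks,
                                 extract_query_window, find_shared_gaps,
                                 records_to_table, scan_pipeline)
from cladesig.seqio import GAP, AlignedRow, Alignment, SequenceRecord
from cladesig.synthetic_data import (SimulationConfig, generate_dataset,
                                     scan_dataset, score_scan)

from conftest import (pool_from_alignment, random_protein, signature_case,
                      two_clade_map, with_gap)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestFindSharedGaps:
    def test_clean_ingroup_deletion(self, rng):
        aln, cm = signature_case(rng, kind="deletion", span=(60, 61))
        (cand,) = find_shared_gaps(aln, cm)
        assert cand.indel_type == "deletion"
        assert (cand.length_min, cand.length_max) == (2, 2)
        assert cand.indel_cols == (60, 61)
        assert cand.outgroup_exceptions == 0
        assert cand.sharing == {f"in{i}": True for i in range(1, 5)} \
            | {f"out{i}": False for i in range(1, 5)}

    def test_outgroup_gap_polarity_is_insertion(self, rng):
        aln, cm = signature_case(rng, kind="insertion", span=(60, 62))
        (cand,) = find_shared_gaps(aln, cm)
        assert cand.indel_type == "insertion"
        assert cand.length_min == 3
        # the sharing group carries the insert: ingroup rows, not outgroup
        assert all(cand.sharing[f"in{i}"] for i in range(1, 5))
        assert not any(cand.sharing[f"out{i}"] for i in range(1, 5))

    def test_one_outgroup_exception_reported_not_exclusive(self, rng):
        aln, cm = signature_case(rng, kind="deletion", extra_out_gapped=1)
        (cand,) = find_shared_gaps(aln, cm)
        assert cand.outgroup_exceptions == 1
        records = scan_pipeline([("P", aln)], cm)
        assert [r.status for r in records] == ["exceptions(1)"]

    def test_widely_shared_gap_is_no_candidate(self, rng):
        aln, cm = signature_case(rng, kind="deletion", extra_out_gapped=3)
        assert find_shared_gaps(aln, cm) == []

    def test_length_range_flag(self, rng):
        spans = [(60, 61), (60, 61), (60, 62), (60, 62)]
        aln, cm = signature_case(rng, kind="deletion", in_spans=spans)
        (cand,) = find_shared_gaps(aln, cm)
        assert cand.status == "rejected" and cand.reason == "length_mismatch"
        (cand,) = find_shared_gaps(aln, cm, ScanParams(allow_length_range=True))
        assert (cand.length_min, cand.length_max) == (2, 3)
        assert cand.status == "candidate"

    def test_partial_ingroup_below_coverage_skipped(self, rng):
        aln, cm = signature_case(rng, kind="deletion")
        # revert two of four ingroup rows to the ungapped state
        base = aln.rows[4].seq
        aln.rows[2] = AlignedRow(aln.rows[2].id, aln.rows[2].genome, base)
        aln.rows[3] = AlignedRow(aln.rows[3].id, aln.rows[3].genome, base)
        assert find_shared_gaps(aln, cm) == []

    def test_missing_ingroup_homolog_counted(self, rng):
        aln, cm = signature_case(rng, kind="deletion")
        aln.rows[3] = AlignedRow(aln.rows[3].id, aln.rows[3].genome,
                                 GAP * aln.n_cols)
        (cand,) = find_shared_gaps(aln, cm)
        assert cand.ingroup_absent == 1
        cm_strict = two_clade_map(max_ingroup_absent=0)
        with pytest.raises(ValueError, match="lack a homolog"):
            find_shared_gaps(aln, cm_strict)

    def test_no_outgroup_rows_error(self, rng):
        aln, cm = signature_case(rng, kind="deletion")
        aln_in_only = Alignment(aln.rows[:4])
        with pytest.raises(ValueError, match="outgroup"):
            find_shared_gaps(aln_in_only, cm)


class TestCheckFlanks:
    def test_conserved_flanks_pass(self, rng):
        aln, cm = signature_case(rng, kind="deletion")
        (cand,) = find_shared_gaps(aln, cm)
        report, ok = check_flanks(cand, aln)
        assert ok
        assert report["left_conserved"] >= 5 and report["right_conserved"] >= 5

    def test_divergent_flank_fails(self, rng):
        from conftest import AA
        aln, cm = signature_case(rng, length=120, span=(60, 61))
        # make every left-flank column of one outgroup row differ
        row = aln.rows[7]
        left = "".join(AA[(AA.index(c) + 1) % len(AA)] for c in row.seq[:59])
        aln.rows[7] = AlignedRow(row.id, row.genome, left + row.seq[59:])
        (cand,) = find_shared_gaps(aln, cm)
        _, ok = check_flanks(cand, aln)
        assert not ok and cand.reason == "flank_not_conserved"

    def test_edge_truncated(self, rng):
        base = random_protein(rng, 60)
        aln, cm = signature_case(rng, length=60, span=(2, 3))
        (cand,) = find_shared_gaps(aln, cm)
        _, ok = check_flanks(cand, aln)
        assert not ok and cand.reason == "edge_truncated"

    def test_majority_rule_tolerates_one_variant(self, rng):
        aln, cm = signature_case(rng, kind="deletion")
        # one substitution in every left-flank column of one outgroup row
        row = aln.rows[7]
        left = "".join("W" if c != "W" else "Y" for c in row.seq[:59])
        aln.rows[7] = AlignedRow(row.id, row.genome, left + row.seq[59:])
        (cand,) = find_shared_gaps(aln, cm)
        _, ok_strict = check_flanks(cand, aln, ScanParams())
        assert not ok_strict
        (cand2,) = find_shared_gaps(aln, cm)
        _, ok_major = check_flanks(
            cand2, aln, ScanParams(conservation_rule="majority",
                                   majority_fraction=0.8))
        assert ok_major


class TestExtractWindow:
    def test_window_bounds_and_containment(self, rng):
        aln, cm = signature_case(rng, length=300, span=(150, 151))
        (cand,) = find_shared_gaps(aln, cm)
        check_flanks(cand, aln)
        extract_query_window(cand, aln)
        n = cand.window_end - cand.window_start + 1
        assert 40 <= n <= 100
        c1, c2 = cand.window_cols
        assert c1 <= 150 and 151 <= c2
        assert cand.window_seq and GAP not in cand.window_seq

    def test_short_protein_flag(self, rng):
        aln, cm = signature_case(rng, length=30, span=(14, 15))
        (cand,) = find_shared_gaps(aln, cm)
        extract_query_window(cand, aln)
        assert "short_protein" in cand.flags
        assert (cand.window_start, cand.window_end) == (1, 28)  # whole top row

    def test_window_capped_at_max_len(self, rng):
        aln, cm = signature_case(rng, length=400, span=(200, 201))
        (cand,) = find_shared_gaps(aln, cm)
        extract_query_window(cand, aln, min_len=100, max_len=100)
        assert cand.window_end - cand.window_start + 1 == 100


class TestAssessSpecificity:
    def _ready_candidate(self, rng, **kwargs):
        aln, cm = signature_case(rng, length=200, span=(100, 101), **kwargs)
        (cand,) = find_shared_gaps(aln, cm)
        check_flanks(cand, aln)
        extract_query_window(cand, aln)
        return aln, cm, cand

    def test_exclusive_on_clean_pool(self, rng):
        aln, cm, cand = self._ready_candidate(rng)
        pool = pool_from_alignment(aln)
        assess_specificity(cand, aln, cm, pool)
        assert cand.status == "exclusive"
        assert cand.specificity["outgroup_sharing"] == 0

    def test_decoy_with_indel_breaks_exclusivity(self, rng):
        aln, cm, cand = self._ready_candidate(rng)
        pool = pool_from_alignment(aln)
        # an outgroup-labelled homolog carrying the ingroup (deleted) state
        pool.append(SequenceRecord("decoy", "out1",
                                   aln.rows[0].seq.replace(GAP, "")))
        assess_specificity(cand, aln, cm, pool)
        assert cand.status == "exceptions(1)"

    def test_empty_pool_undetermined(self, rng):
        aln, cm, cand = self._ready_candidate(rng)
        assess_specificity(cand, aln, cm, [])
        assert cand.status == "undetermined"

    def test_exceptions_allowance_restores_exclusive(self, rng):
        aln, cm, cand = self._ready_candidate(rng)
        pool = pool_from_alignment(aln)
        pool.append(SequenceRecord("decoy", "out1",
                                   aln.rows[0].seq.replace(GAP, "")))
        assess_specificity(cand, aln, cm, pool,
                           ScanParams(max_outgroup_exceptions=1))
        assert cand.status == "exclusive"

    def test_pool_truncated_at_top_n(self, rng):
        aln, cm, cand = self._ready_candidate(rng)
        pool = pool_from_alignment(aln)
        # decoy beyond top_n_pool must not be examined
        pool.append(SequenceRecord("decoy", "out1",
                                   aln.rows[0].seq.replace(GAP, "")))
        assess_specificity(cand, aln, cm, pool,
                           ScanParams(top_n_pool=len(pool) - 1))
        assert cand.status == "exclusive"


@pytest.fixture(scope="module")
def small_dataset():
    return generate_dataset(SimulationConfig(n_families=10, seed=3))


class TestScanPipeline:
    def test_no_events_no_noise_zero_csis(self):
        ds = generate_dataset(SimulationConfig(n_families=5, planted_events=[],
                                               seed=5))
        assert scan_dataset(ds) == []

    def test_planted_events_recovered(self, small_dataset):
        records = scan_dataset(small_dataset)
        scores = score_scan(records, small_dataset.truth)
        assert scores["precision"] == 1.0 and scores["recall"] == 1.0

    def test_reported_length_matches_planted(self, small_dataset):
        records = [r for r in scan_dataset(small_dataset) if r.is_exclusive]
        truth = {(t.family_id, t.clade): t for t in small_dataset.truth}
        for r in records:
            t = truth[(r.protein, r.specificity_group)]
            assert r.length_min == r.length_max == t.length

    def test_tightening_params_never_enlarges_exclusive_set(self, small_dataset):
        def exclusive(params):
            return {(r.protein, r.specificity_group, r.indel_cols)
                    for r in scan_dataset(small_dataset, params)
                    if r.is_exclusive}

        base = exclusive(ScanParams())
        stricter = exclusive(ScanParams(min_flank_conserved=30))
        assert stricter <= base
        no_report = exclusive(ScanParams(report_outgroup_exceptions=0))
        assert no_report <= base

    def test_row_order_invariance_within_groups(self, small_dataset):
        fid = small_dataset.truth[0].family_id
        clade = small_dataset.truth[0].clade
        cm = small_dataset.clade_map_for(clade)
        aln = small_dataset.families[fid].alignment

        def signature(a):
            recs = find_shared_gaps(a, cm)
            return [(r.indel_type, r.length_min, r.indel_cols,
                     dict(sorted(r.sharing.items()))) for r in recs]

        rng = np.random.default_rng(0)
        rows = list(aln.rows)
        in_rows = [r for r in rows[1:] if cm.role(r.genome) == "ingroup"]
        out_rows = [r for r in rows[1:] if cm.role(r.genome) == "outgroup"]
        rng.shuffle(in_rows)
        rng.shuffle(out_rows)
        shuffled = Alignment([rows[0], *out_rows, *in_rows])
        assert signature(aln) == signature(shuffled)

    def test_table_output_schema(self, small_dataset):
        records = scan_dataset(small_dataset)
        table = records_to_table(records)
        assert len(table) == len(records)
        assert {"protein", "indel_size", "indel_position", "status"} \
            <= set(table.columns)
        excl = table[table.status == "exclusive"]
        assert excl.indel_position.str.match(r"\d+-\d+").all()
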