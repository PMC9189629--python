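"""Clonotype caller: V/J assignment, CDR3 extraction, assembly, import/export."""

import numpy as np
import pytest

from spottcr import clonotype as ct
from spottcr import io as sio
from spottcr import simulate as sim
from spottcr.types import (
    ExtractionError,
    JSegment,
    Primer,
    PrimerPool,
    ReadRecord,
    SegmentReference,
    VSegment,
)


def _read(seq, rid="r1"):
    return ReadRecord(rid, seq, "I" * len(seq))


def _amplicon(reference, pool, clone):
    p = {x.v_gene_name: x for x in pool.primers}[clone.v_gene]
    v = reference.v(clone.v_gene)
    j = reference.j(clone.j_gene)
    start = v.sequence.find(p.primer_seq)
    return (
        p.read2_tail + v.sequence[start : v.cys_offset] + clone.cdr3_nt
        + j.sequence[j.phe_offset + 3 :] + reference.constant_prefix
    )


@pytest.fixture(scope="module")
def tiny(tiny_reference, tiny_pool):
    config = sim.SimConfig(n_clones=4, seed=5, spots_per_clone=1, umis_per_clone_spot=1)
    repertoire = sim.make_repertoire(tiny_reference, config)
    return tiny_reference, tiny_pool, repertoire


class TestAssignV:
    def test_exact_amplicon_hits_true_v_with_zero_mismatches(self, tiny):
        reference, pool, repertoire = tiny
        for clone in repertoire:
            aln = ct.assign_v(_read(_amplicon(reference, pool, clone)), reference, pool)
            assert aln is not None
            assert aln.segment_name == clone.v_gene
            assert aln.mismatches == 0

    def test_random_sequence_gets_no_call(self, tiny):
        reference, pool, _ = tiny
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
            assert ct.assign_v(_read(seq), reference, pool) is None

    def test_short_read_gets_no_call(self, tiny):
        reference, pool, _ = tiny
        assert ct.assign_v(_read("ACGT" * 9), reference, pool) is None

    def test_score_consistent_with_unit_match_mismatch(self, tiny):
        reference, pool, repertoire = tiny
        seq = _amplicon(reference, pool, repertoire[0])
        mutated = "G" + seq[1:]  # tail base, outside the V span
        aln = ct.assign_v(_read(mutated), reference, pool)
        span = aln.read_end - aln.read_start
        assert aln.score == span - 2 * aln.mismatches
        assert aln.ref_end - aln.ref_start == span

    def test_agrees_with_brute_force_all_offsets_scan(self, tiny):
        """Independent re-implementation: plain Python scan of every primer
        query at every offset, same acceptance and tie rules."""
        reference, pool, repertoire = tiny
        rng = np.random.default_rng(42)

        def brute_force(seq, max_frac=0.1):
            best = None
            for p in pool.primers:
                v = reference.v(p.v_gene_name)
                start = v.sequence.find(p.primer_seq)
                query = (p.read2_tail + v.sequence[start:])[:60]
                for off in range(11):
                    span = min(len(query), len(seq) - off)
                    if span < 20:
                        continue
                    mm = sum(a != b for a, b in zip(seq[off : off + span], query))
                    if mm / span > max_frac:
                        continue
                    cand = (-(span - 2 * mm), p.v_gene_name, off)
                    if best is None or cand < best:
                        best = cand
            return None if best is None else best[1]

        n_checked = 0
        for _ in range(100):
            clone = repertoire[rng.integers(0, len(repertoire))]
            seq = list(_amplicon(reference, pool, clone))
            for pos in rng.choice(len(seq), size=rng.integers(0, 6), replace=False):
                seq[pos] = "ACGT"[rng.integers(0, 4)]
            seq = "".join(seq)
            expect = brute_force(seq)
            aln = ct.assign_v(_read(seq), reference, pool)
            got = None if aln is None else aln.segment_name
            assert got == expect
            n_checked += 1
        assert n_checked == 100


class TestAssignJ:
    def test_exact_amplicon_hits_true_j(self, tiny):
        reference, pool, repertoire = tiny
        for clone in repertoire:
            rec = _read(_amplicon(reference, pool, clone))
            v_aln = ct.assign_v(rec, reference, pool)
            aln = ct.assign_j(rec, reference, min_offset=v_aln.read_end)
            assert aln is not None
            assert aln.segment_name == clone.j_gene
            assert aln.mismatches == 0

    def test_read_truncated_before_j_gets_no_call(self, tiny):
        reference, pool, repertoire = tiny
        clone = repertoire[0]
        seq = _amplicon(reference, pool, clone)
        v_aln = ct.assign_v(_read(seq), reference, pool)
        # cut right after the V region: fewer than 20 J nt remain
        cut = _read(seq[: v_aln.read_end + 5])
        assert ct.assign_j(cut, reference, min_offset=v_aln.read_end) is None

    def test_identical_segments_tie_to_smallest_name(self):
        jseq = "ACGTACGTAC" * 4 + "TTTGGAGCAGGC" + "ACGT"
        phe = 40
        reference = SegmentReference(
            v_segments=[VSegment("TRBV1", "TGT" + "A" * 97, 0)],
            j_segments=[
                JSegment("TRBJ-B", jseq, phe),
                JSegment("TRBJ-A", jseq, phe),
            ],
        )
        rec = _read(jseq + "GGGG")
        aln = ct.assign_j(rec, reference, min_offset=0)
        assert aln.segment_name == "TRBJ-A"


class TestExtractCdr3:
    def test_simulated_reads_yield_truth_cdr3(self, tiny):
        reference, pool, repertoire = tiny
        for clone in repertoire:
            rec = _read(_amplicon(reference, pool, clone))
            v_aln = ct.assign_v(rec, reference, pool)
            j_aln = ct.assign_j(rec, reference, min_offset=v_aln.read_end)
            nt, aa, productive = ct.extract_cdr3(rec, v_aln, j_aln, reference)
            assert nt == clone.cdr3_nt
            assert aa == clone.cdr3_aa
            assert productive

    def test_out_of_frame_cdr3_is_nonproductive_with_empty_aa(self, tiny):
        reference, pool, repertoire = tiny
        clone = repertoire[0]
        seq = _amplicon(reference, pool, clone)
        v = reference.v(clone.v_gene)
        # delete one base inside the junction: CDR3 length drops to 3k-1
        cys_read = seq.find(clone.cdr3_nt)
        seq2 = seq[: cys_read + 4] + seq[cys_read + 5 :]
        rec = _read(seq2)
        v_aln = ct.assign_v(rec, reference, pool)
        j_aln = ct.assign_j(rec, reference, min_offset=v_aln.read_end)
        nt, aa, productive = ct.extract_cdr3(rec, v_aln, j_aln, reference)
        assert len(nt) % 3 != 0
        assert aa == "" and not productive

    def test_in_frame_stop_is_nonproductive(self, tiny):
        reference, pool, repertoire = tiny
        clone = repertoire[0]
        seq = _amplicon(reference, pool, clone)
        cys_read = seq.find(clone.cdr3_nt)
        seq2 = seq[: cys_read + 3] + "TAA" + seq[cys_read + 6 :]
        rec = _read(seq2)
        v_aln = ct.assign_v(rec, reference, pool)
        j_aln = ct.assign_j(rec, reference, min_offset=v_aln.read_end)
        nt, aa, productive = ct.extract_cdr3(rec, v_aln, j_aln, reference)
        assert "*" in aa and not productive

    def test_anchor_outside_read_raises(self, tiny):
        reference, pool, repertoire = tiny
        clone = repertoire[0]
        seq = _amplicon(reference, pool, clone)
        rec = _read(seq)
        v_aln = ct.assign_v(rec, reference, pool)
        j_aln = ct.assign_j(rec, reference, min_offset=v_aln.read_end)
        truncated = _read(seq[: j_aln.read_start + 1], rid="t")
        with pytest.raises(ExtractionError):
            ct.extract_cdr3(truncated, v_aln, j_aln, reference)


class TestAssembleClones:
    def _assignment(self, rid, v="TRBV1", j="TRBJ1", nt="TGTAAATTT"):
        return ct.ReadAssignment(rid, v, j, nt, "CKF", True)

    def test_identical_keys_collapse_to_one_clone(self):
        clones, rmap = ct.assemble_clones(
            [self._assignment(f"r{i}") for i in range(3)]
        )
        assert len(clones) == 1
        assert clones[0].read_support == 3
        assert set(rmap.values()) == {1}

    def test_single_nt_difference_is_a_new_clone(self):
        clones, _ = ct.assemble_clones(
            [self._assignment("r1"), self._assignment("r2", nt="TGTAACTTT")]
        )
        assert len(clones) == 2

    def test_numbering_by_support_then_first_seen(self):
        assignments = (
            [self._assignment(f"a{i}", nt="TGTAAATTT") for i in range(2)]
            + [self._assignment(f"b{i}", nt="TGTCCCTTT") for i in range(5)]
            + [self._assignment(f"c{i}", nt="TGTGGGTTT") for i in range(2)]
        )
        clones, _ = ct.assemble_clones(assignments)
        assert [c.cdr3_nt for c in clones] == ["TGTCCCTTT", "TGTAAATTT", "TGTGGGTTT"]
        assert [c.clone_id for c in clones] == [1, 2, 3]

    def test_error_free_simulation_recovers_truth_clone_set(self, default_run):
        truth = default_run.truth
        assert {c.key for c in default_run.clones} == {c.key for c in truth.clones}
        truth_by_key = {c.key: c for c in truth.clones}
        read_counts = {}
        for cid, *_ in truth.read_assignments.values():
            if cid is not None:
                read_counts[cid] = read_counts.get(cid, 0) + 1
        for c in default_run.clones:
            t = truth_by_key[c.key]
            assert c.read_support == read_counts[t.clone_id]
            assert c.productive == t.productive
            assert c.cdr3_aa == t.cdr3_aa


class TestExportImport:
    def test_export_file_naming_and_counts(self, tiny, tmp_path):
        reference, pool, repertoire = tiny
        records = []
        rmap = {}
        for i, clone in enumerate(repertoire[:2], start=1):
            for k in range(i):  # clone 1: one read, clone 2: two reads
                rid = f"c{i}r{k}"
                records.append(_read(_amplicon(reference, pool, clone), rid))
                rmap[rid] = i
        r2 = tmp_path / "r2.fastq.gz"
        sio.write_fastq(records, r2)
        paths = ct.export_reads_for_clones(rmap, r2, tmp_path / "reads")
        assert sorted(p.name for p in paths.values()) == [
            "reads_cln0.fastq.gz",
            "reads_cln1.fastq.gz",
        ]
        assert sum(1 for _ in sio.read_fastq(paths[1])) == 1
        assert sum(1 for _ in sio.read_fastq(paths[2])) == 2

    def test_export_import_round_trip(self, default_run, tmp_path):
        table = tmp_path / "clones.tsv"
        sio.write_clones_table(default_run.clones, table)
        ct.export_reads_for_clones(
            default_run.read_to_clone, default_run.r2, tmp_path / "reads"
        )
        clones, rmap = ct.import_mixcr(table, tmp_path / "reads")
        assert {(c.key, c.read_support) for c in clones} == {
            (c.key, c.read_support) for c in default_run.clones
        }
        assert rmap == default_run.read_to_clone

    def test_igkv_hit_gets_chain_other(self, tmp_path):
        table = tmp_path / "clones.tsv"
        table.write_text(
            "cloneId\treadCount\tvGene\tjGene\tnSeqCDR3\taaSeqCDR3\tproductive\tchain\n"
            "1\t4\tIGKV3*00(55.5)\tIGKJ1\tTGTTTT\tCF\ttrue\t\n"
        )
        reads = tmp_path / "reads"
        reads.mkdir()
        sio.write_fastq([_read("ACGT" * 20, "x1")], reads / "reads_cln0.fastq.gz")
        clones, rmap = ct.import_mixcr(table, reads)
        assert clones[0].chain == "other"
        assert clones[0].v_gene == "IGKV3"
        assert rmap == {"x1": 1}

    def test_missing_reads_file_warns_and_maps_nothing(self, tmp_path):
        table = tmp_path / "clones.tsv"
        table.write_text(
            "cloneId\treadCount\tvGene\tjGene\tnSeqCDR3\taaSeqCDR3\tproductive\tchain\n"
            "1\t4\tTRBV1\tTRBJ1\tTGTTTT\tCF\ttrue\tTRB\n"
        )
        reads = tmp_path / "reads"
        reads.mkdir()
        with pytest.warns(UserWarning, match="missing reads file"):
            clones, rmap = ct.import_mixcr(table, reads)
        assert len(clones) == 1 and rmap == {}


class TestNoisyAssignment:
    def test_low_error_reads_keep_true_v_and_j(self, noisy_dataset):
        """At per-base error 0.001 at least 99% of TCR reads get the true V and J."""
        res, _ = noisy_dataset
        truth = res["truth"]
        reference, pool = res["reference"], res["primer_pool"]
        truth_clone = {c.clone_id: c for c in truth.clones}
        n = correct = 0
        for rec in sio.read_fastq(res["r2"]):
            cid, _, _ = truth.read_assignments[rec.read_id]
            if cid is None:
                continue
            n += 1
            v_aln = ct.assign_v(rec, reference, pool)
            j_aln = (
                ct.assign_j(rec, reference, min_offset=v_aln.read_end)
                if v_aln
                else None
            )
            tc = truth_clone[cid]
            if (
                v_aln is not None
                and j_aln is not None
                and v_aln.segment_name == tc.v_gene
                and j_aln.segment_name == tc.j_gene
            ):
                correct += 1
        assert n >= 10_000
        assert correct / n >= 0.99
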