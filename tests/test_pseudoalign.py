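"""Read classification, trim/mismatch robustness, pair resolution, tallying."""

import pytest

from exdel import (
    MappingParams,
    ReadRecord,
    ReadClassification,
    SimulationConfig,
    classify_read,
    map_reads,
    resolve_pair,
    reverse_complement,
    simulate_reads,
    tally,
    trim_check,
    write_fastq,
)

from conftest import oracle_unique_deletion, substring_ec

STRICT = MappingParams(mismatch=0, trim=0, min_overhang=0)


def _read_from(records, rid, start, length, read_id="r"):
    seq = dict(records)[rid][start : start + length]
    return ReadRecord(read_id, seq)


class TestClassifyRead:
    def test_exon_interior_read_hits_all_retaining_transcripts(self, index8, transcriptome8):
        records, deletions = transcriptome8
        # read inside exon 5 of the canonical (exons are 200 bp each)
        read = _read_from(records, "tx1", 4 * 200 + 40, 100)
        c = classify_read(read, index8, STRICT)
        got_ids = {index8.transcripts[o].record_id for o in c.ec}
        # exon 5 is retained unless 5 is inside the deleted run
        expected = {"tx1"} | {
            d.record_id
            for d in deletions
            if not d.spec.first_deleted <= 5 <= d.spec.last_deleted
        }
        assert got_ids == expected
        assert not c.is_unique_deletion

    def test_junction_read_is_unique_to_its_deletion(self, index8, transcriptome8):
        records, deletions = transcriptome8
        d = {x.name: x for x in deletions}["del4_7"]
        read = _read_from(records, d.record_id, d.junction_offset - 50, 100)
        c = classify_read(read, index8, MappingParams())
        assert c.is_unique_deletion
        assert c.deletion_name == "del4_7"
        assert c.mismatches_used == 0

    def test_reverse_complement_reads_classify_identically(self, index8, transcriptome8):
        records, deletions = transcriptome8
        d = {x.name: x for x in deletions}["del4_7"]
        fwd = _read_from(records, d.record_id, d.junction_offset - 50, 100)
        rev = ReadRecord("r_rc", reverse_complement(fwd.sequence))
        assert classify_read(rev, index8, MappingParams()).deletion_name == "del4_7"

    def test_random_sequence_is_unmapped(self, index8):
        read = ReadRecord("junk", "ACGT" * 25)
        c = classify_read(read, index8, MappingParams())
        assert not c.mapped and c.ec == frozenset()

    def test_read_shorter_than_k_is_flagged_too_short(self, index8):
        c = classify_read(ReadRecord("s", "ACGTACGTAC"), index8, MappingParams())
        assert c.status == "too_short" and not c.mapped

    def test_mismatched_unique_read_respects_budget(self, index8, transcriptome8):
        records, deletions = transcriptome8
        d = {x.name: x for x in deletions}["del4_7"]
        base = dict(records)[d.record_id][d.junction_offset - 50 : d.junction_offset + 50]
        seq = list(base)
        seq[0] = "A" if seq[0] != "A" else "C"
        seq[-1] = "A" if seq[-1] != "A" else "C"
        read = ReadRecord("mm2", "".join(seq))
        c2 = classify_read(read, index8, MappingParams(mismatch=2, trim=5))
        assert c2.is_unique_deletion and c2.mismatches_used == 2
        c0 = classify_read(read, index8, MappingParams(mismatch=0, trim=0))
        assert not c0.is_unique_deletion  # demoted to gene-level evidence
        assert c0.mapped and len(c0.ec) > 1


class TestTrimCheck:
    def _junction_read(self, transcriptome8, overhang_left, length=100):
        records, deletions = transcriptome8
        d = {x.name: x for x in deletions}["del4_7"]
        start = d.junction_offset - overhang_left
        return _read_from(records, d.record_id, start, length)

    def test_small_overhang_passes_untrimmed_but_fails_trim5(self, index8, transcriptome8):
        read = self._junction_read(transcriptome8, overhang_left=5)
        loose = MappingParams(mismatch=0, trim=0)
        c = classify_read(read, index8, loose)
        assert c.is_unique_deletion
        assert trim_check(read, c, index8, loose) is True  # trim=0 is the identity
        strict = MappingParams(mismatch=0, trim=5)
        c5 = classify_read(read, index8, strict)
        assert c5.is_unique_deletion
        assert trim_check(read, c5, index8, strict) is False

    def test_generous_overhang_survives_trimming(self, index8, transcriptome8):
        read = self._junction_read(transcriptome8, overhang_left=50)
        params = MappingParams(mismatch=0, trim=5)
        c = classify_read(read, index8, params)
        assert trim_check(read, c, index8, params) is True

    def test_trimmed_below_k_fails_conservatively(self, index8, transcriptome8):
        read = self._junction_read(transcriptome8, overhang_left=18, length=36)
        params = MappingParams(mismatch=0, trim=5)
        c = classify_read(read, index8, params)
        assert c.is_unique_deletion
        assert trim_check(read, c, index8, params) is False

    def test_trim_must_cover_mismatch(self):
        with pytest.raises(ValueError, match="equal or exceed"):
            MappingParams(mismatch=3, trim=2)


class TestResolvePair:
    def _cls(self, ec, unique=False, gene="tx1", deletion=None):
        return ReadClassification(
            ec=frozenset(ec), is_unique_deletion=unique, gene=gene, deletion_name=deletion
        )

    def test_smaller_ec_wins(self):
        unique = self._cls({3}, unique=True, deletion="del4_7")
        broad = self._cls({0, 1, 2})
        assert resolve_pair(unique, broad) is unique
        assert resolve_pair(broad, unique) is unique

    def test_single_mapped_mate_carries_the_pair(self):
        unmapped = ReadClassification(ec=frozenset(), status="unmapped")
        mapped = self._cls({0, 1})
        assert resolve_pair(mapped, unmapped) is mapped
        assert resolve_pair(unmapped, mapped) is mapped

    def test_both_unmapped_stays_unmapped(self):
        u = ReadClassification(ec=frozenset(), status="unmapped")
        assert not resolve_pair(u, u).mapped

    def test_disjoint_singletons_demote_to_gene_level(self):
        a = self._cls({1}, unique=True, deletion="del2")
        b = self._cls({2}, unique=True, deletion="del3")
        merged = resolve_pair(a, b)
        assert merged.mapped and not merged.is_unique_deletion
        assert merged.ec == frozenset({1, 2})

    def test_equal_size_overlapping_ecs_intersect_nonunique(self):
        merged = resolve_pair(self._cls({0, 1}), self._cls({1, 2}))
        assert merged.ec == frozenset({1}) and not merged.is_unique_deletion

    def test_mates_on_different_genes_are_ambiguous(self):
        a = self._cls({0}, gene="tx1")
        b = self._cls({5}, gene="tx2")
        assert resolve_pair(a, b).status == "ambiguous"


class TestTally:
    def test_counts_split_between_uc_and_tc(self, index8):
        mk = lambda **kw: ReadClassification(**kw)
        finals = (
            [mk(ec=frozenset({18}), is_unique_deletion=True, gene="tx1", deletion_name="del4_7")] * 3
            + [mk(ec=frozenset({0, 1}), gene="tx1")] * 7
            + [mk(ec=frozenset(), status="unmapped")] * 2
        )
        counts = tally(finals, index8)["tx1"]
        assert counts.uc["del4_7"] == 3
        assert counts.tc == 7
        assert counts.n_unmapped == 2
        assert counts.mapped_total == 10

    def test_zero_input_gives_all_zero(self, index8):
        counts = tally([], index8)["tx1"]
        assert counts.tc == 0 and all(v == 0 for v in counts.uc.values())


class TestMapReadsEndToEnd:
    def test_deterministic_over_repeat_runs(self, index8, transcriptome8):
        records, deletions = transcriptome8
        cfg = SimulationConfig(
            abundances={"tx1": 0.8, "tx1|del4_7": 0.2}, n_reads=800, seed=5
        )
        reads, _ = simulate_reads(cfg, records)
        c1 = map_reads(reads, index8)["tx1"]
        c2 = map_reads(reads, index8)["tx1"]
        assert c1.uc == c2.uc and c1.tc == c2.tc

    def test_canonical_only_reads_yield_zero_uc(self, index8, transcriptome8):
        records, _ = transcriptome8
        cfg = SimulationConfig(abundances={"tx1": 1.0}, n_reads=500, seed=8)
        reads, _ = simulate_reads(cfg, records)
        counts = map_reads(reads, index8)["tx1"]
        assert all(v == 0 for v in counts.uc.values())
        assert counts.tc == 500

    def test_uc_matches_per_read_origin_oracle(self, index8, transcriptome8):
        """UC equals the geometric truth: origin reads spanning the junction
        with more than `trim` bases on each side (error-free regime)."""
        records, deletions = transcriptome8
        d = {x.name: x for x in deletions}["del4_7"]
        cfg = SimulationConfig(
            abundances={"tx1": 0.9, "tx1|del4_7": 0.1}, n_reads=1000, read_length=100, seed=13
        )
        reads, truth = simulate_reads(cfg, records)
        params = MappingParams(mismatch=0, trim=5)
        counts = map_reads(reads, index8, params)["tx1"]
        j, trim = d.junction_offset, params.trim
        expected = sum(
            1
            for _, src, s in truth.origins
            if src == d.record_id
            and (j - s) > trim
            and (s + cfg.read_length - j) > trim
        )
        assert counts.uc["del4_7"] == expected
        assert counts.mapped_total == cfg.n_reads

    def test_paired_end_mapping_counts_pairs_once(self, index8, transcriptome8):
        records, _ = transcriptome8
        cfg = SimulationConfig(
            abundances={"tx1": 0.9, "tx1|del4_7": 0.1},
            n_reads=400, read_length=75, paired=True, fragment_length=200, seed=21,
        )
        pairs, _ = simulate_reads(cfg, records)
        counts = map_reads(
            (p[0] for p in pairs), index8, MappingParams(), reads2=(p[1] for p in pairs)
        )["tx1"]
        assert counts.paired
        assert counts.mapped_total == cfg.n_reads

    def test_desynchronized_mate_files_raise(self, index8, transcriptome8, tmp_path):
        records, _ = transcriptome8
        cfg = SimulationConfig(abundances={"tx1": 1.0}, n_reads=10, seed=2)
        reads, _ = simulate_reads(cfg, records)
        r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        write_fastq(reads, r1)
        write_fastq(reads[:-1], r2)
        with pytest.raises(ValueError, match="desynchronized"):
            map_reads(str(r1), index8, MappingParams(), reads2=str(r2))

    def test_fastq_and_in_memory_reads_agree(self, index8, transcriptome8, tmp_path):
        records, _ = transcriptome8
        cfg = SimulationConfig(abundances={"tx1": 0.7, "tx1|del2": 0.3}, n_reads=300, seed=17)
        reads, _ = simulate_reads(cfg, records)
        fq = tmp_path / "reads.fastq"
        write_fastq(reads, fq)
        from_file = map_reads(str(fq), index8)["tx1"]
        from_mem = map_reads(reads, index8)["tx1"]
        assert from_file.uc == from_mem.uc and from_file.tc == from_mem.tc


@pytest.fixture(scope="module")
def errored_sample(transcriptome8):
    records, _ = transcriptome8
    cfg = SimulationConfig(
        abundances={"tx1": 0.7, "tx1|del4_7": 0.3},
        n_reads=2000, read_length=100, error_rate=0.01, seed=29,
    )
    reads, _ = simulate_reads(cfg, records)
    return reads


class TestMonotonicity:

    def test_increasing_trim_never_increases_uc(self, index8, transcriptome8):
        records, _ = transcriptome8
        cfg = SimulationConfig(
            abundances={"tx1": 0.8, "tx1|del4_7": 0.2}, n_reads=1500, seed=31
        )
        reads, _ = simulate_reads(cfg, records)
        ucs = [
            map_reads(reads, index8, MappingParams(mismatch=0, trim=t))["tx1"].uc["del4_7"]
            for t in (0, 2, 5, 10, 20)
        ]
        assert all(a >= b for a, b in zip(ucs, ucs[1:]))
        assert ucs[0] > 0

    def test_mismatch_budget_recovers_errored_reads(self, index8, errored_sample):
        uc = {
            mm: map_reads(errored_sample, index8, MappingParams(mismatch=mm, trim=5))[
                "tx1"
            ].uc["del4_7"]
            for mm in (0, 1, 2)
        }
        assert uc[0] <= uc[1] <= uc[2]
        assert uc[2] > uc[0]  # the budget actually rescues reads at 1% error


class TestOracleEquivalence:
    def test_strict_mapping_matches_substring_oracle(self, index5, transcriptome5):
        """mismatch=0, trim=0: a read is unique to deletion d iff it is an
        exact substring of d's sequence and no other transcript's."""
        records, deletions = transcriptome5
        cfg = SimulationConfig(
            abundances={"tx1": 0.4, "tx1|del2_4": 0.3, "tx1|del3": 0.3},
            n_reads=200, read_length=30, seed=37,
        )
        reads, _ = simulate_reads(cfg, records)
        id_of = {i: t.record_id for i, t in enumerate(index5.transcripts)}
        for read in reads:
            c = classify_read(read, index5, STRICT)
            expected_ec = substring_ec(read.sequence, records)
            assert {id_of[o] for o in c.ec} == expected_ec
            assert (c.deletion_name if c.is_unique_deletion else None) == oracle_unique_deletion(
                read.sequence, records
            )
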