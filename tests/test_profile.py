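"""Profiles: insert-size arithmetic, pair filters, null estimation, format."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from joindel.config import RunConfig
from joindel.profile import (
    InsertSizeHistogram,
    ReadPairRecord,
    SampleProfile,
    compute_insert_size,
    default_sampling_regions,
    estimate_null_distribution,
    passes_quality_filters,
    read_profile,
    write_profile,
)

HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": 10_000_000}],
    }
)


def _aln(
    pos,
    cigar="100M",
    flag=99,
    mapq=60,
    mate_pos=None,
    tlen=300,
):
    a = pysam.AlignedSegment(HEADER)
    a.query_name = "q"
    a.reference_id = 0
    a.reference_start = pos
    a.cigarstring = cigar
    a.flag = flag
    a.mapping_quality = mapq
    a.next_reference_id = 0
    a.next_reference_start = mate_pos if mate_pos is not None else pos
    a.template_length = tlen
    a.query_sequence = "A" * sum(
        n for op, n in a.cigartuples if op in (0, 1, 4)
    )
    return a


class TestComputeInsertSize:
    def test_plain_pair_yields_span(self):
        fwd = _aln(1000, "100M", flag=99)
        rev = _aln(1200, "100M", flag=147)  # reference_end = 1300
        assert compute_insert_size(fwd, rev) == 300

    def test_clips_extend_both_ends(self):
        fwd = _aln(1000, "5S95M", flag=99)  # left clip 5
        rev = _aln(1210, "90M10S", flag=147)  # ref end 1300, right clip 10
        assert compute_insert_size(fwd, rev) == 315

    def test_degenerate_pair_rejected(self):
        fwd = _aln(0, "1M", flag=99)
        rev = _aln(0, "1M", flag=147)
        # rev ends at 1, fwd starts at 0 -> insert 1 is the minimum; an
        # inverted pair (rev fully left of fwd) is rejected
        fwd_late = _aln(500, "100M", flag=99)
        rev_early = _aln(100, "100M", flag=147)
        assert compute_insert_size(fwd_late, rev_early) is None

    def test_different_contigs_rejected(self):
        header2 = pysam.AlignmentHeader.from_dict(
            {"SQ": [{"SN": "chr1", "LN": 10_000_000}, {"SN": "chr2", "LN": 10_000_000}]}
        )
        fwd = _aln(1000)
        rev = _aln(1200, flag=147)
        rev.reference_id = 0
        fwd2 = pysam.AlignedSegment(header2)
        fwd2.reference_id = 1
        fwd2.reference_start = 1000
        fwd2.cigarstring = "100M"
        fwd2.flag = 99
        assert compute_insert_size(fwd2, rev) is None

    def test_translation_invariance(self):
        for shift in (0, 17, 1234):
            fwd = _aln(1000 + shift, "100M", flag=99)
            rev = _aln(1200 + shift, "100M", flag=147)
            assert compute_insert_size(fwd, rev) == 300


class TestQualityFilters:
    def test_primary_fr_pair_passes(self, config):
        assert passes_quality_filters(_aln(100, mate_pos=400), config)

    def test_duplicate_fails(self, config):
        assert not passes_quality_filters(_aln(100, flag=99 | 1024), config)

    def test_low_mapq_fails(self, config):
        assert not passes_quality_filters(_aln(100, mapq=10, mate_pos=400), config)
        assert passes_quality_filters(
            _aln(100, mapq=10, mate_pos=400), RunConfig(min_mapq=10)
        )

    @pytest.mark.parametrize("flag", [99 | 256, 99 | 2048, 99 | 512, 4 | 1, 99 ^ 1])
    def test_secondary_supplementary_qcfail_unpaired_fail(self, config, flag):
        assert not passes_quality_filters(_aln(100, flag=flag, mate_pos=400), config)

    def test_rf_orientation_fails(self, config):
        # reverse read left of its forward mate start
        assert not passes_quality_filters(
            _aln(100, flag=99, mate_pos=50), config
        )


class TestNullDistribution:
    def test_degenerate_stream(self):
        recs = [ReadPairRecord(0, p, 300) for p in range(2000)]
        hists = estimate_null_distribution(
            recs, [("chr1", 0, 10_000)], [("chr1", 10_000_000)], min_pairs=100
        )
        h = hists[0]
        assert h.counts == {300: 2000}
        assert h.mean == 300 and h.stddev == 0

    def test_normal_sample_recovers_parameters(self):
        rng = np.random.default_rng(5)
        inserts = np.rint(rng.normal(450, 15, 10_000)).astype(int)
        recs = [ReadPairRecord(0, i, int(v)) for i, v in enumerate(inserts)]
        h = estimate_null_distribution(
            recs, [("chr1", 0, 100_000)], [("chr1", 10_000_000)]
        )[0]
        assert abs(h.mean - 450) < 1.0
        assert abs(h.stddev - 15) < 0.5

    def test_empty_region_intersection_errors(self):
        recs = [ReadPairRecord(0, p, 300) for p in range(2000)]
        with pytest.raises(ValueError, match="insufficient|no pairs"):
            estimate_null_distribution(
                recs, [("chr1", 100_000, 200_000)], [("chr1", 10_000_000)]
            )

    def test_too_few_pairs_errors(self):
        recs = [ReadPairRecord(0, p, 300) for p in range(10)]
        with pytest.raises(ValueError, match="insufficient"):
            estimate_null_distribution(
                recs, [("chr1", 0, 10_000)], [("chr1", 10_000_000)], min_pairs=1000
            )

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        inserts = np.rint(rng.normal(450, 15, 3000)).astype(int)
        recs = [ReadPairRecord(0, i, int(v)) for i, v in enumerate(inserts)]
        h1 = estimate_null_distribution(
            recs, [("chr1", 0, 10_000)], [("chr1", 10_000_000)]
        )[0]
        h2 = estimate_null_distribution(
            recs[::-1], [("chr1", 0, 10_000)], [("chr1", 10_000_000)]
        )[0]
        assert h1 == h2

    def test_default_sampling_regions_are_contig_middles(self):
        regions = default_sampling_regions([("chr1", 1000), ("chr2", 500)])
        assert regions == [("chr1", 200, 800), ("chr2", 100, 400)]


def _make_profile(records, seqdict=None):
    prof = SampleProfile(
        sample_id="S1",
        sequence_dictionary=seqdict or [("chr1", 10_000_000), ("chr2", 5_000_000)],
        histograms={0: InsertSizeHistogram({300: 10, 310: 5})},
        read_len=100,
    )
    by_contig = {}
    for r in records:
        by_contig.setdefault(r.contig_id, []).append(r)
    for cid, rs in by_contig.items():
        prof.add_records(
            cid,
            [r.fwd_start for r in rs],
            [r.insert_size for r in rs],
            [r.read_group for r in rs],
        )
    return prof


class TestProfileFormat:
    def test_round_trip_identity(self, tmp_path):
        records = [
            ReadPairRecord(0, 100, 300),
            ReadPairRecord(0, 70_000, 310),
            ReadPairRecord(1, 5, 300),
        ]
        prof = _make_profile(records)
        path = str(tmp_path / "p.jdp")
        write_profile(prof, path)
        assert read_profile(path).equals(prof)

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 1),
                st.integers(0, 2_000_000),
                st.integers(1, 20_000),
                st.integers(0, 0),
            ),
            max_size=60,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, data):
        records = [ReadPairRecord(*t) for t in data]
        prof = _make_profile(records)
        path = str(tmp_path_factory.mktemp("jdp") / "p.jdp")
        write_profile(prof, path)
        assert read_profile(path).equals(prof)

    def test_seek_yields_records_at_or_after_position(self, tmp_path):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.integers(0, 500_000, 500))
        records = [ReadPairRecord(0, int(s), 300) for s in starts]
        prof = _make_profile(records)
        path = str(tmp_path / "p.jdp")
        write_profile(prof, path)
        back = read_profile(path)
        for pos in (0, 1234, 250_000, 499_999):
            got = [r.fwd_start for r in back.seek("chr1", pos)]
            expected = [int(s) for s in starts if s >= pos]
            assert got == expected

    def test_seek_past_last_record_is_empty(self, tmp_path):
        prof = _make_profile([ReadPairRecord(0, 100, 300)])
        path = str(tmp_path / "p.jdp")
        write_profile(prof, path)
        assert list(read_profile(path).seek("chr1", 101)) == []

    def test_version_mismatch_names_versions(self, tmp_path):
        prof = _make_profile([ReadPairRecord(0, 100, 300)])
        path = str(tmp_path / "p.jdp")
        write_profile(prof, path)
        raw = bytearray(open(path, "rb").read())
        raw[4:6] = (99).to_bytes(2, "little")
        open(path, "wb").write(bytes(raw))
        with pytest.raises(ValueError, match="expected 1.*found 99"):
            read_profile(path)

    def test_truncated_file_errors(self, tmp_path):
        prof = _make_profile([ReadPairRecord(0, 100, 300)])
        path = str(tmp_path / "p.jdp")
        write_profile(prof, path)
        raw = open(path, "rb").read()
        open(path, "wb").write(raw[: len(raw) - 10])
        with pytest.raises(ValueError, match="truncated|magic"):
            read_profile(path)

    def test_not_a_profile_errors(self, tmp_path):
        path = str(tmp_path / "x.jdp")
        open(path, "wb").write(b"NOPE")
        with pytest.raises(ValueError, match="magic"):
            read_profile(path)


class TestProfileFromAlignments:
    def test_sam_ingestion_matches_simulation(self, tmp_path):
        from joindel.simulate import (
            simulate_deletion_set,
            simulate_genotypes,
            simulate_read_pairs,
            write_sam,
        )

        length = 300_000
        deletions = simulate_deletion_set(
            2, contig_length=length, len_range=(800, 1500), seed=3
        )
        cohort = simulate_genotypes(deletions, 1, seed=4)
        pairs = simulate_read_pairs(
            deletions, cohort, contig_length=length, coverage=10, seed=5
        )
        starts, inserts = pairs[cohort.sample_ids[0]]
        sam = str(tmp_path / "s.sam")
        write_sam(cohort.sample_ids[0], starts, inserts, "chr21", length, 150, sam)
        from joindel.profile import profile_from_alignments

        prof = profile_from_alignments(sam, RunConfig(min_sample_pairs=100))
        assert prof.sequence_dictionary == [("chr21", length)]
        assert prof.read_len == 150
        # every simulated pair within the insert cap is recovered
        got = prof.records_by_contig[0]
        assert len(got["start"]) == len(starts)
        assert np.array_equal(np.sort(got["start"]), np.sort(starts))
        assert abs(prof.histograms[0].mean - 450) < 3

    def test_profile_is_compact_relative_to_sam(self, tmp_path):
        from joindel.simulate import (
            simulate_deletion_set,
            simulate_genotypes,
            simulate_read_pairs,
            write_sam,
        )

        length = 1_000_000
        deletions = simulate_deletion_set(
            2, contig_length=length, len_range=(800, 1500), seed=3
        )
        cohort = simulate_genotypes(deletions, 1, seed=4)
        pairs = simulate_read_pairs(
            deletions, cohort, contig_length=length, coverage=30, seed=5
        )
        starts, inserts = pairs[cohort.sample_ids[0]]
        sam = str(tmp_path / "s.sam")
        write_sam(cohort.sample_ids[0], starts, inserts, "chr21", length, 150, sam)
        from joindel.profile import profile_from_alignments
        import os

        prof = profile_from_alignments(sam, RunConfig(min_sample_pairs=100))
        jdp = str(tmp_path / "s.jdp")
        write_profile(prof, jdp)
        assert os.path.getsize(jdp) < 0.05 * os.path.getsize(sam)
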