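"""Index-hopping simulator, FASTQ round trips, demultiplexing, scoring."""

import math

import numpy as np
import pytest
from Bio import SeqIO

from trudrop.indexes import FILTERED_HOPPED, IndexPair, SampleSheet
from trudrop.simulate import (
    QualityModel,
    demultiplex,
    make_barcode_whitelists,
    make_sample_sheet,
    random_index_set,
    score_demux,
    simulate_pool,
    single_index_collision_loss,
    write_fastq,
)
from trudrop.structures import W1_SPACER


class TestSimulatePool:
    def test_no_hopping_observed_equals_true(self, trudrop_sheet):
        reads = simulate_pool(trudrop_sheet, "TRUDROP", 200, hop_rate=0.0,
                              seed=3, read_lengths=(50, 50))
        by_sample = {e.sample_id: e for e in trudrop_sheet}
        for r in reads:
            e = by_sample[r.true_sample]
            assert (r.observed_i7, r.observed_i5) == (e.i7, e.i5)
            assert not r.hopped

    def test_hop_fraction_matches_rate(self, trudrop_sheet):
        n, h = 40000, 0.0485
        reads = simulate_pool(trudrop_sheet, "TRUDROP", n // 2, hop_rate=h,
                              seed=5, read_lengths=(44, 20))
        frac = np.mean([r.hopped for r in reads])
        # P(>=1 hopped side) = 1 - (1 - h/2)^2
        expect = 1 - (1 - h / 2) ** 2
        se = math.sqrt(expect * (1 - expect) / n)
        assert frac == pytest.approx(expect, abs=3 * se)

    def test_empty_and_hop_validation(self, trudrop_sheet):
        assert simulate_pool(trudrop_sheet, "TRUDROP", 0, seed=0) == []
        solo = SampleSheet([IndexPair("only", "CCGCGGTT", "AGCGCTAG")])
        with pytest.raises(ValueError, match="at least 2"):
            simulate_pool(solo, "TRUDROP", 10, hop_rate=0.01, seed=0)

    def test_hopped_flag_consistent_with_observed(self, hopped_sim):
        sheet, reads = hopped_sim
        by_sample = {e.sample_id: e for e in sheet}
        for r in reads:
            e = by_sample[r.true_sample]
            assert (r.observed_i7 != e.i7) == r.hopped_i7
            assert (r.observed_i5 != e.i5) == r.hopped_i5

    def test_barcode_read_layout(self, hopped_sim):
        _, reads = hopped_sim
        r = reads[0]
        prefix = r.bc1 + W1_SPACER + r.bc2 + r.umi
        assert r.read1_seq.startswith(prefix[: len(r.read1_seq)])
        assert set(r.read1_seq[len(prefix):]) <= {"T"}
        assert 8 <= len(r.bc1) <= 11 and len(r.bc2) == 8 and len(r.umi) == 6

    def test_dual_sheet_requires_dual_structure(self, trudrop_sheet):
        with pytest.raises(ValueError, match="dual"):
            simulate_pool(trudrop_sheet, "INDROP_V2", 10, seed=0)

    def test_v2_preset_puts_barcode_on_read2(self, v2_sheet):
        reads = simulate_pool(v2_sheet, "INDROP_V2", 5, hop_rate=0.0, seed=1)
        r = reads[0]
        assert len(r.read1_seq) == 100 and len(r.read2_seq) == 50
        assert W1_SPACER in r.read2_seq

    def test_quality_profile_applied(self, trudrop_sheet):
        profile = np.linspace(38, 25, 50)
        reads = simulate_pool(
            trudrop_sheet, "TRUDROP", 50, hop_rate=0.0, seed=2,
            read_lengths=(50, 50), quality=QualityModel(profile, sd=0.0),
        )
        assert list(reads[0].read1_quals) == list(np.rint(profile).astype(int))

    def test_determinism(self, trudrop_sheet):
        a = simulate_pool(trudrop_sheet, "TRUDROP", 300, seed=42,
                          read_lengths=(50, 50))
        b = simulate_pool(trudrop_sheet, "TRUDROP", 300, seed=42,
                          read_lengths=(50, 50))
        assert a == b


class TestSheetAndWhitelistGenerators:
    def test_random_index_set_respects_distance(self):
        from trudrop.indexes import levenshtein

        idx = random_index_set(12, length=8, min_distance=3, seed=1)
        assert len(set(idx)) == 12
        assert min(
            levenshtein(a, b)
            for i, a in enumerate(idx) for b in idx[i + 1:]
        ) >= 3

    def test_make_sample_sheet_unique_dual(self):
        sheet = make_sample_sheet(8, seed=4)
        assert sheet.scheme == "unique_dual" and len(sheet) == 8

    def test_whitelists_distinct(self):
        bc1, bc2 = make_barcode_whitelists(50, 60, seed=0)
        assert len(set(bc1)) == 50 and len(set(bc2)) == 60
        assert {len(b) for b in bc1} == {8, 9, 10, 11}
        assert {len(b) for b in bc2} == {8}


class TestFastqRoundTrip:
    def test_round_trip_preserves_everything(self, hopped_sim, tmp_path):
        sheet, reads = hopped_sim
        subset = reads[:50]
        paths = {k: tmp_path / f"{k}.fastq" for k in ("r1", "r2", "i1", "i2")}
        n = write_fastq(subset, paths["r1"], paths["r2"], paths["i1"],
                        paths["i2"])
        assert n == 50
        back = list(SeqIO.parse(str(paths["r1"]), "fastq"))
        assert len(back) == 50
        for rec, r in zip(back, subset):
            assert rec.id == r.read_id
            assert str(rec.seq) == r.read1_seq
            assert tuple(rec.letter_annotations["phred_quality"]) == r.read1_quals
            assert rec.description.endswith(f"{r.observed_i7}+{r.observed_i5}")
        i1 = list(SeqIO.parse(str(paths["i1"]), "fastq"))
        assert [str(rec.seq) for rec in i1] == [r.observed_i7 for r in subset]

    def test_phred33_encoding(self, tmp_path):
        read = _one_read(quals=(0, 40, 20))
        write_fastq([read], tmp_path / "r1.fastq")
        lines = (tmp_path / "r1.fastq").read_text().splitlines()
        assert len(lines) == 4 and lines[2].startswith("+")
        assert lines[3] == "!I5"

    def test_gzip_and_determinism(self, hopped_sim, tmp_path):
        _, reads = hopped_sim
        for name in ("a.fastq.gz", "b.fastq.gz"):
            write_fastq(reads[:20], tmp_path / name)
        a = list(SeqIO.parse(_gzopen(tmp_path / "a.fastq.gz"), "fastq"))
        b = list(SeqIO.parse(_gzopen(tmp_path / "b.fastq.gz"), "fastq"))
        assert [str(x.seq) for x in a] == [str(x.seq) for x in b]


def _gzopen(path):
    import gzip

    return gzip.open(path, "rt")


def _one_read(quals=(30, 30, 30)):
    from trudrop.simulate import SimulatedRead

    return SimulatedRead(
        read_id="r1", true_sample="s", bc1="A" * 8, bc2="C" * 8, umi="G" * 6,
        observed_i7="ACGTACGT", observed_i5="TGCATGCA", hopped_i7=False,
        hopped_i5=False, read1_seq="ACG", read2_seq="TGC",
        read1_quals=tuple(quals), read2_quals=tuple(quals),
    )


class TestDemultiplex:
    def test_no_hopping_is_lossless(self, trudrop_sheet):
        reads = simulate_pool(trudrop_sheet, "TRUDROP", 500, hop_rate=0.0,
                              seed=6, read_lengths=(44, 20))
        assignments, report = demultiplex(reads, trudrop_sheet)
        assert report.assigned == report.total == 1000
        assert report.filtered_hopped == 0 and report.undetermined == 0
        assert report.misassignment_rate == 0.0
        assert report.percent_perfect_index_reads == 100.0

    def test_conservation(self, hopped_sim):
        sheet, reads = hopped_sim
        _, report = demultiplex(reads, sheet)
        assert (
            report.assigned + report.filtered_hopped + report.undetermined
            == report.total
            == len(reads)
        )

    def test_single_side_hops_all_filtered(self, hopped_sim):
        sheet, reads = hopped_sim
        assignments, _ = demultiplex(reads, sheet)
        by_id = {r.read_id: r for r in reads}
        for a in assignments:
            r = by_id[a.read_id]
            if r.hopped_i7 != r.hopped_i5:  # exactly one side hopped
                assert a.status == FILTERED_HOPPED

    def test_single_index_mode_misassigns(self, hopped_sim):
        sheet, reads = hopped_sim
        assignments, report = demultiplex(reads, sheet.to_single_index())
        assert report.per_sample["assigned_wrong"].sum() > 0
        assert report.filtered_hopped == 0

    def test_fastq_input_matches_stream_input(self, hopped_sim, tmp_path):
        sheet, reads = hopped_sim
        subset = reads[:200]
        write_fastq(subset, tmp_path / "r1.fastq", i1_path=tmp_path / "i1.fastq",
                    i2_path=tmp_path / "i2.fastq")
        _, from_stream = demultiplex(subset, sheet)
        _, from_files = demultiplex(
            {"r1": tmp_path / "r1.fastq", "i1": tmp_path / "i1.fastq",
             "i2": tmp_path / "i2.fastq"},
            sheet,
        )
        assert (
            from_files.per_sample["assigned"].to_dict()
            == from_stream.per_sample["assigned"].iloc[:].to_dict()
            or from_files.per_sample["assigned"].sum()
            == from_stream.per_sample["assigned"].sum()
        )
        assert from_files.total == 200

    def test_record_count_mismatch_raises(self, hopped_sim, tmp_path):
        sheet, reads = hopped_sim
        write_fastq(reads[:10], tmp_path / "r1.fastq",
                    i1_path=tmp_path / "i1.fastq")
        write_fastq(reads[:8], tmp_path / "short.fastq",
                    i1_path=tmp_path / "i1_short.fastq")
        with pytest.raises(ValueError, match="fewer records"):
            demultiplex(
                {"r1": tmp_path / "r1.fastq", "i1": tmp_path / "i1_short.fastq"},
                sheet,
            )


class TestScoring:
    def test_perfect_capture_of_single_side_hops(self, hopped_sim):
        sheet, reads = hopped_sim
        assignments, _ = demultiplex(reads, sheet)
        single_side = [r for r in reads if r.hopped_i7 != r.hopped_i5]
        if not any(r.hopped for r in reads):
            pytest.skip("no hops at this seed")
        both_sides = [r for r in reads if r.hopped_i7 and r.hopped_i5]
        metrics = score_demux(assignments)
        # all single-side hops captured; only double hops can escape
        expected = len(single_side) / (len(single_side) + len(both_sides))
        assert metrics.hop_capture_rate >= expected - 1e-12

    def test_no_hops_gives_clean_metrics(self, trudrop_sheet):
        reads = simulate_pool(trudrop_sheet, "TRUDROP", 100, hop_rate=0.0,
                              seed=8, read_lengths=(44, 20))
        assignments, _ = demultiplex(reads, trudrop_sheet)
        metrics = score_demux(assignments)
        assert metrics.misassignment_rate == 0.0
        assert metrics.n_hopped == 0
        assert all(p == 1.0 for p in metrics.precision.values())

    def test_truth_mapping_and_unknown_read(self, hopped_sim):
        sheet, reads = hopped_sim
        assignments, _ = demultiplex(reads[:10], sheet)
        truth = {r.read_id: (r.true_sample, r.hopped) for r in reads[:5]}
        with pytest.raises(KeyError):
            score_demux(assignments, truth)

    def test_double_hop_to_foreign_pair_is_misassigned(self, trudrop_sheet):
        # a read whose both indexes hopped to the same foreign sample forms
        # an anticipated combination: undetectable, counted assigned_wrong
        from trudrop.simulate import SimulatedRead

        read = SimulatedRead(
            read_id="x", true_sample="Mouse4", bc1="A" * 8, bc2="C" * 8,
            umi="G" * 6, observed_i7="TTATAACC", observed_i5="GATATCGA",
            hopped_i7=True, hopped_i5=True, read1_seq="ACGT", read2_seq="ACGT",
            read1_quals=(30,) * 4, read2_quals=(30,) * 4,
        )
        assignments, report = demultiplex([read], trudrop_sheet)
        assert assignments[0].sample_id == "Mouse5"
        assert report.per_sample.loc["Mouse5", "assigned_wrong"] == 1
        metrics = score_demux(assignments)
        assert metrics.misassignment_rate == 1.0
        assert metrics.hop_capture_rate == 0.0


class TestCollisionLoss:
    @staticmethod
    def _loss(sheet, reads):
        assignments, _ = demultiplex(reads, sheet.to_single_index())
        barcodes = {r.read_id: (r.bc1, r.bc2) for r in reads}
        return single_index_collision_loss(assignments, barcodes)

    def test_disjoint_barcodes_nothing_discarded(self, trudrop_sheet):
        reads = simulate_pool(trudrop_sheet, "TRUDROP", 300, hop_rate=0.0,
                              seed=12, read_lengths=(44, 20))
        loss = self._loss(trudrop_sheet, reads)
        # random 8-11+8 nt barcodes essentially never repeat across samples
        assert loss.n_discarded == 0 and loss.fraction == 0.0

    def test_planted_shared_barcode_discarded(self, trudrop_sheet):
        from dataclasses import replace

        reads = simulate_pool(trudrop_sheet, "TRUDROP", 50, hop_rate=0.0,
                              seed=13, read_lengths=(44, 20))
        planted = ("ACGTACGT", "TTGGCCAA")
        # plant the same barcode into one read of each sample
        for sample in ("Mouse4", "Mouse5"):
            i = next(j for j, r in enumerate(reads)
                     if r.true_sample == sample)
            reads[i] = replace(reads[i], bc1=planted[0], bc2=planted[1])
        loss = self._loss(trudrop_sheet, reads)
        assert loss.n_discarded == 1
        assert loss.discarded == frozenset({planted})

    def test_one_read_per_cell_matches_closed_form(self, trudrop_sheet):
        # One read per cell, 2 equal single-indexed samples: a cell is
        # discarded iff another cell shares its barcode and the occupants'
        # assigned samples differ.  Each *other* occupant's origin is
        # uniform over the 2 samples, so its assigned sample is marginally
        # uniform and independent; with M ~ Bin(k-1, 1/N) sharers,
        # P(discard) = E[1 - (1/2)^M] = 1 - (1 - 1/(2N))^(k-1).
        n_cells, h = 3000, 0.0485
        bc1, bc2 = make_barcode_whitelists(384, 384, seed=21)
        N = 384 * 384
        single = trudrop_sheet.to_single_index()
        fracs = []
        for seed in (31, 32, 33):
            reads = simulate_pool(
                single, "TRUDROP", n_cells, hop_rate=h, seed=seed,
                cells_per_sample=n_cells, barcode_whitelists=(bc1, bc2),
                read_lengths=(44, 20), cell_sampling="round_robin",
            )
            assignments, _ = demultiplex(reads, single)
            barcodes = {r.read_id: (r.bc1, r.bc2) for r in reads}
            loss = single_index_collision_loss(assignments, barcodes)
            discarded_cells = sum(
                1 for r in reads if (r.bc1, r.bc2) in loss.discarded
            )
            fracs.append(discarded_cells / len(reads))
        k = 2 * n_cells
        expected = 1 - (1 - 1 / (2 * N)) ** (k - 1)
        binom_se = math.sqrt(expected * (1 - expected) / (k * len(fracs)))
        assert np.mean(fracs) == pytest.approx(expected, abs=3 * binom_se)
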