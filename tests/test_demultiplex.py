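import pytest

from autoshi.demultiplex import (
    DemuxParams,
    check_collisions,
    demultiplex_run,
    match_barcode,
)
from autoshi.fastq_io import BarcodeSpec, Read, write_fastq
from helpers import brute_collides, mk, naive_match, random_read, random_seq


class TestMatchBarcode:
    def test_exact_match_strips_barcode(self):
        specs = [BarcodeSpec("A", "ACGT")]
        sample, mm, trimmed = match_barcode(mk("ACGTTTTT"), specs,
                                            DemuxParams(max_mismatch=0))
        assert (sample, mm, trimmed.seq) == ("A", 0, "TTTT")

    def test_one_mismatch_within_budget(self):
        specs = [BarcodeSpec("A", "ACGT")]
        sample, mm, _ = match_barcode(mk("ACGATTTT"), specs,
                                      DemuxParams(max_mismatch=1))
        assert (sample, mm) == ("A", 1)

    def test_barcode_n_matches_any_base_free(self):
        specs = [BarcodeSpec("A", "ANGT")]
        sample, mm, _ = match_barcode(mk("ATGTCCCC"), specs,
                                      DemuxParams(max_mismatch=0))
        assert (sample, mm) == ("A", 0)

    def test_read_n_costs_against_concrete_barcode(self):
        specs = [BarcodeSpec("A", "ACGT")]
        assert match_barcode(mk("NCGTAAAA"), specs,
                             DemuxParams(max_mismatch=0))[0] is None
        assert match_barcode(mk("NCGTAAAA"), specs,
                             DemuxParams(max_mismatch=1))[0] == "A"

    def test_tied_minimum_is_unassigned(self):
        specs = [BarcodeSpec("A", "AAAA"), BarcodeSpec("B", "AAAT")]
        # read at distance 1 from both barcodes
        sample, _, trimmed = match_barcode(mk("AAACGGGG"), specs,
                                           DemuxParams(max_mismatch=1))
        assert sample is None
        assert trimmed.seq == "AAACGGGG"  # nothing stripped

    def test_internal_search_window(self):
        specs = [BarcodeSpec("A", "ACGT")]
        read = mk("TTACGTCCCC")
        assert match_barcode(read, specs, DemuxParams(0, 0))[0] is None
        sample, _, trimmed = match_barcode(read, specs, DemuxParams(0, 2))
        assert sample == "A"
        assert trimmed.seq == "CCCC"

    def test_oracle_equivalence_on_random_reads(self, rng):
        """Matcher agrees with an exhaustive scorer over all specs."""
        for trial in range(20):
            k = int(rng.integers(4, 9))
            specs = [
                BarcodeSpec(f"s{i}", random_seq(rng, k)) for i in range(4)
            ]
            params = DemuxParams(max_mismatch=int(rng.integers(0, 3)))
            for _ in range(10):
                read = random_read(rng, 20)
                got = match_barcode(read, specs, params)[0]
                want = naive_match(read, specs, params.max_mismatch)[0]
                assert got == want


class TestCollisions:
    def test_disjoint_barcodes_do_not_collide(self):
        specs = [BarcodeSpec("A", "AAAA"), BarcodeSpec("B", "TTTT")]
        assert check_collisions(specs, 1) == []
        assert not brute_collides("AAAA", "TTTT", 1)

    def test_adjacent_barcodes_collide(self):
        specs = [BarcodeSpec("A", "AAAA"), BarcodeSpec("B", "AAAT")]
        assert check_collisions(specs, 1) == [("A", "B")]

    def test_distance_two_barcodes_collide_at_one_mismatch(self):
        specs = [BarcodeSpec("A", "AAAA"), BarcodeSpec("B", "AATT")]
        assert check_collisions(specs, 1) == [("A", "B")]
        assert brute_collides("AAAA", "AATT", 1)

    def test_agrees_with_brute_force_enumeration(self, rng):
        from autoshi.demultiplex import _pair_confusable
        for _ in range(25):
            L = int(rng.integers(3, 6))
            b1, b2 = random_seq(rng, L), random_seq(rng, L)
            for m in (0, 1, 2):
                assert _pair_confusable(b1, b2, m) == brute_collides(b1, b2, m)

    def test_iupac_barcodes_use_expansion(self):
        # R = A|G: "AAAR" and "AAAG" share the read "AAAG" at zero mismatches
        specs = [BarcodeSpec("A", "AAAR"), BarcodeSpec("B", "AAAG")]
        assert check_collisions(specs, 0) == [("A", "B")]


class TestDemultiplexRun:
    def _lane(self, tmp_path, rng, n=60, error=False):
        specs = [BarcodeSpec("alpha", "ACGTAC"), BarcodeSpec("beta", "TGCATG")]
        truth = []
        reads1, reads2 = [], []
        for i in range(n):
            spec = specs[i % 2]
            bc = spec.barcode_fwd
            if error and i % 5 == 0:
                bc = "T" + bc[1:] if bc[0] != "T" else "A" + bc[1:]
            reads1.append(mk(bc + random_seq(rng, 30), rid=f"r{i}"))
            reads2.append(random_read(rng, 36, rid=f"r{i}"))
            truth.append(spec.sample_id)
        p1, p2 = tmp_path / "lane_R1.fastq", tmp_path / "lane_R2.fastq"
        write_fastq(reads1, p1)
        write_fastq(reads2, p2)
        return [p1, p2], specs, truth

    def test_conservation_and_truth_recovery(self, tmp_path, rng):
        paths, specs, truth = self._lane(tmp_path, rng)
        report = demultiplex_run(paths, specs, DemuxParams(max_mismatch=1),
                                 tmp_path / "out")
        assert sum(report.assigned.values()) + report.unassigned == report.total
        assert report.total == 2 * len(truth)
        # error-free lane: composition matches the generator exactly
        assert report.assigned["alpha"] == 2 * truth.count("alpha")
        assert report.assigned["beta"] == 2 * truth.count("beta")
        assert report.unassigned == 0
        assert (tmp_path / "out" / "alpha.R1.fastq").exists()
        assert (tmp_path / "out" / "demux_report.tsv").exists()

    def test_injected_errors_within_budget_still_recovered(self, tmp_path, rng):
        paths, specs, truth = self._lane(tmp_path, rng, error=True)
        report = demultiplex_run(paths, specs, DemuxParams(max_mismatch=1),
                                 tmp_path / "out")
        assert report.unassigned == 0
        assert report.assigned["alpha"] == 2 * truth.count("alpha")

    def test_mate_count_mismatch_is_hard_error(self, tmp_path, rng):
        paths, specs, _ = self._lane(tmp_path, rng, n=10)
        # drop the last record from R2
        lines = paths[1].read_text().splitlines(keepends=True)
        paths[1].write_text("".join(lines[:-4]))
        with pytest.raises(ValueError, match="mate-count"):
            demultiplex_run(paths, specs, DemuxParams(1), tmp_path / "out")

    def test_paired_barcode_disagreement_unassigned(self, tmp_path, rng):
        specs = [BarcodeSpec("A", "AAAAAA", "CCCCCC"),
                 BarcodeSpec("B", "GGGGGG", "TTTTTT")]
        r1 = [mk("AAAAAA" + random_seq(rng, 20))]   # matches A forward...
        r2 = [mk("TTTTTT" + random_seq(rng, 20))]   # ...but B reverse
        p1, p2 = tmp_path / "x_R1.fastq", tmp_path / "x_R2.fastq"
        write_fastq(r1, p1)
        write_fastq(r2, p2)
        report = demultiplex_run([p1, p2], specs, DemuxParams(1),
                                 tmp_path / "out")
        assert report.unassigned == 2
        assert sum(report.assigned.values()) == 0

    def test_zero_mismatch_disjoint_barcodes_partition(self, rng):
        """No read can be assignable to two samples at max_mismatch=0."""
        specs = [BarcodeSpec(f"s{i}", random_seq(rng, 6)) for i in range(6)]
        specs = list({s.barcode_fwd: s for s in specs}.values())
        params = DemuxParams(max_mismatch=0)
        for _ in range(200):
            read = random_read(rng, 12)
            hits = [
                s.sample_id for s in specs
                if naive_match(read, [s], 0)[0] is not None
            ]
            assert len(hits) <= 1
            assert match_barcode(read, specs, params)[0] == (
                hits[0] if hits else None
            )
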