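import hashlib
from pathlib import Path

import pytest

from autoshi.fixtures import FixtureSpec, generate_run
from autoshi.learn import (
    AMPLICON,
    SHOTGUN,
    UNSTITCHABLE,
    LearnConfig,
    LearnedParams,
    classify_library,
    compute_bounds,
    detect_pairs,
    learn_all,
    learn_quality,
)
from autoshi.stitcher import OverlapStats
from helpers import mk


def stats_for(mean, sd, cv, n_pairs=100, n_stitched=60):
    return OverlapStats({}, n_pairs, n_stitched, mean, sd, cv)


class TestDetectPairs:
    def test_r1_r2_pattern(self):
        pairing = detect_pairs(["s1_R1.fastq", "s1_R2.fastq"])
        assert pairing == {"s1": ("s1_R1.fastq", "s1_R2.fastq")}

    def test_odd_file_count_is_single_end(self):
        assert detect_pairs(["a.fastq", "b.fastq", "c.fastq"]) is None

    def test_underscore_pattern_two_pairs(self):
        files = ["s1_1.fastq", "s1_2.fastq", "s2_1.fastq", "s2_2.fastq"]
        pairing = detect_pairs(files)
        assert pairing == {
            "s1": ("s1_1.fastq", "s1_2.fastq"),
            "s2": ("s2_1.fastq", "s2_2.fastq"),
        }

    def test_even_but_unpairable_is_single_end(self):
        assert detect_pairs(["a.fastq", "b.fastq"]) is None

    def test_first_matching_pattern_wins(self):
        # "R1/R2" is tried before "_1/_2", so the R-token is the one removed
        pairing = detect_pairs(["s_1_R1.fastq", "s_1_R2.fastq"])
        assert pairing == {"s_1": ("s_1_R1.fastq", "s_1_R2.fastq")}


class TestClassifyLibrary:
    def test_high_cv_with_good_stitching_is_shotgun(self):
        assert classify_library(stats_for(148.6, 20.62, 0.139)) == SHOTGUN

    def test_low_cv_with_good_stitching_is_amplicon(self):
        stats = stats_for(254.4, 15.7, 0.062, n_pairs=100, n_stitched=97)
        assert classify_library(stats) == AMPLICON

    def test_cv_threshold_is_strict(self):
        assert classify_library(stats_for(200, 20, 0.10)) == SHOTGUN

    def test_poor_stitch_fraction_is_unstitchable(self):
        stats = stats_for(150, 10, 0.07, n_pairs=100, n_stitched=20)
        assert classify_library(stats) == UNSTITCHABLE

    def test_scale_free(self):
        """Multiplying all merged lengths by a constant keeps the call."""
        for scale in (1, 3, 10):
            lengths = [100 * scale, 104 * scale, 96 * scale] * 20
            stats = OverlapStats.from_lengths(lengths, 60)
            assert classify_library(stats) == AMPLICON


class TestComputeBounds:
    def test_two_sd_band(self):
        stats = stats_for(254.4, 15.7, 0.062)
        assert compute_bounds(stats) == (223, 286)

    def test_degenerate_distribution(self):
        assert compute_bounds(stats_for(150.0, 0.0, 0.0)) == (150, 150)

    def test_lower_bound_floored_at_min_overlap(self):
        assert compute_bounds(stats_for(20.0, 8.0, 0.4)) == (10, 36)

    def test_requires_two_stitches(self):
        with pytest.raises(ValueError):
            compute_bounds(stats_for(100.0, 5.0, 0.05, n_stitched=1))


class TestLearnQuality:
    def test_uniform_quality(self):
        reads = [mk("ACGTACGTACGTACGTACGTACGT", 30)]
        assert learn_quality(reads) == (30, 30)

    def test_filter_qual_floors_dataset_mean(self):
        # mean base quality 36.3 -> filter threshold 36
        reads = [mk("A" * 10, (36,) * 7 + (37,) * 3)]
        assert learn_quality(reads)[0] == 36

    def test_trim_qual_is_floored_midpoint_of_mean_and_terminus(self):
        # 40-nt read: terminus (first+last 10) at 32, middle 20 at 40
        quals = (32,) * 10 + (40,) * 20 + (32,) * 10
        reads = [mk("A" * 40, quals)]
        assert learn_quality(reads) == (36, 34)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            learn_quality([])


class TestRendering:
    @pytest.mark.parametrize("params", [
        LearnedParams(False, "TruSeq2", True, 36, 36),
        LearnedParams(True, "Nextera", False, 36, 34),
        LearnedParams(False, "None", True, 34, 31),
        LearnedParams(False, "TruSeq2", True, 36, 33,
                      min_overlap_bound=239, max_overlap_bound=269,
                      amplicon_mode=True),
    ])
    def test_round_trip(self, params):
        assert LearnedParams.parse(params.render()) == params

    def test_table_vocabulary(self):
        p = LearnedParams(True, "Nextera", False, 36, 34)
        assert p.render() == ("-SE --adaptor Nextera --flash False "
                              "--allow_outies False --filter_qual 36 "
                              "--trim_qual 34")


class TestLearnAll:
    def _checksums(self, path):
        return {
            f.name: hashlib.md5(f.read_bytes()).hexdigest()
            for f in Path(path).iterdir()
        }

    def test_amplicon_run_fully_characterised(self, tmp_path):
        spec = FixtureSpec(seed=11, n_fragments=400, read_len=300,
                           insert_mean=253, insert_sd=4, adaptor="Nextera",
                           contaminant_fraction=0.01, name="amp")
        generate_run(spec, tmp_path)
        before = self._checksums(tmp_path)
        params, info = learn_all(tmp_path)
        assert self._checksums(tmp_path) == before  # inputs untouched
        assert not params.single_end
        assert params.adaptor == "Nextera"
        assert params.do_stitch
        assert params.amplicon_mode
        assert params.min_overlap_bound <= 253 <= params.max_overlap_bound
        assert info["classification"] == AMPLICON

    def test_shotgun_run_classified_without_bounds(self, tmp_path):
        spec = FixtureSpec(seed=12, n_fragments=400, read_len=100,
                           insert_mean=150, insert_sd=21, adaptor="TruSeq2",
                           spike_fraction=0.25, name="sho")
        generate_run(spec, tmp_path)
        params, info = learn_all(tmp_path)
        assert params.adaptor == "TruSeq2"
        assert params.do_stitch
        assert not params.amplicon_mode
        assert params.min_overlap_bound is None
        assert info["classification"] == SHOTGUN

    def test_odd_file_count_is_learned_single_end(self, tmp_path):
        spec = FixtureSpec(seed=13, n_fragments=300, read_len=100,
                           insert_mean=150, insert_sd=21, adaptor="Nextera",
                           spike_fraction=0.3, name="se")
        generate_run(spec, tmp_path / "gen")
        solo = tmp_path / "solo"
        solo.mkdir()
        (solo / "reads.fastq").write_bytes(
            (tmp_path / "gen" / "se_R1.fastq").read_bytes()
        )
        params, _ = learn_all(solo)
        assert params.single_end
        assert not params.do_stitch
        assert params.adaptor == "Nextera"
        assert params.render().startswith("-SE ")

    def test_empty_directory_is_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            learn_all(tmp_path)
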