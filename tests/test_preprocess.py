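"""Preprocessing: trimming, barcode handling, alignment and deduplication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nexuskit.config import PipelineConfig, SimConfig
from nexuskit.preprocess import (GenomeIndex, MalformedReadError, RawRead,
                                 deduplicate, extract_barcode, filter_mapq,
                                 naive_align, process_reads, quality_trim,
                                 read_sam_tags, tags_to_frame)
from nexuskit.simulate import (plant_sites, reverse_complement,
                               simulate_genome, simulate_nexus_reads)


def _read(qualities, seq=None):
    seq = seq if seq is not None else "A" * len(qualities)
    return RawRead("r1", seq, list(qualities))


def brute_force_trim_point(quals, window, threshold):
    """Independent oracle: first window (5'->3') with mean below threshold."""
    for i in range(len(quals) - window + 1):
        if sum(quals[i:i + window]) / window < threshold:
            return i
    return len(quals)


class TestQualityTrim:
    def test_high_quality_read_capped_at_59(self, pipe):
        out = quality_trim(_read([35] * 70), pipe)
        assert len(out) == 59

    def test_short_read_dropped(self, pipe):
        assert quality_trim(_read([35] * 20), pipe) is None

    def test_truncation_at_first_bad_window(self, pipe):
        quals = [35] * 30 + [10] * 10
        expected = brute_force_trim_point(quals, 4, 20)
        out = quality_trim(_read(quals), pipe)
        assert out is not None and len(out) == expected

    def test_matches_brute_force_on_random_qualities(self, pipe, rng):
        for _ in range(200):
            n = int(rng.integers(4, 80))
            quals = list(rng.integers(2, 41, size=n))
            cut = brute_force_trim_point(quals, pipe.qual_window,
                                         pipe.qual_threshold)
            out = quality_trim(_read(quals), pipe)
            if cut < pipe.min_len:
                assert out is None
            else:
                assert len(out) == min(cut, pipe.max_len)

    def test_never_lengthens_and_respects_bounds(self, pipe, rng):
        for _ in range(100):
            n = int(rng.integers(1, 100))
            quals = list(rng.integers(2, 41, size=n))
            out = quality_trim(_read(quals), pipe)
            if out is not None:
                assert pipe.min_len <= len(out) <= min(n, pipe.max_len)

    def test_malformed_read_rejected(self):
        with pytest.raises(MalformedReadError):
            RawRead("r1", "ACGT", [35, 35])


class TestExtractBarcode:
    @pytest.mark.parametrize("length,insert_len", [(59, 50), (30, 21)])
    def test_split_lengths(self, pipe, length, insert_len):
        barcode, insert = extract_barcode(_read([35] * length), pipe)
        assert len(barcode) == 9 and len(insert) == insert_len

    def test_barcode_only_read_dropped(self, pipe):
        assert extract_barcode(_read([35] * 9), pipe) is None

    def test_split_preserves_sequence(self, pipe):
        read = RawRead("r1", "ACGTACGTA" + "G" * 21, [35] * 30)
        barcode, insert = extract_barcode(read, pipe)
        assert barcode == "ACGTACGTA"
        assert insert.sequence == "G" * 21
        assert len(insert.qualities) == 21


class TestNaiveAlign:
    def test_unique_forward_match(self):
        genome = simulate_genome(SimConfig(genome_length=5000, seed=1))
        insert = genome[1000:1050]
        index = GenomeIndex.from_genome(genome)
        tag = naive_align(RawRead("r", insert, [35] * 50), index)
        # a random 50-mer is unique w.h.p.; the seeded genome satisfies it
        assert (tag.strand, tag.stop5, tag.mapq) == ("+", 1000, 42)

    def test_reverse_match_reports_rightmost_base(self):
        genome = simulate_genome(SimConfig(genome_length=5000, seed=2))
        insert = reverse_complement(genome[2000:2050])
        index = GenomeIndex.from_genome(genome)
        tag = naive_align(RawRead("r", insert, [35] * 50), index)
        assert (tag.strand, tag.stop5, tag.mapq) == ("-", 2049, 42)

    def test_multimapper_gets_mapq_zero_and_is_filtered(self, pipe):
        genome = "A" * 1000 + "CCCGGGTTTACGTACGTACG" + "A" * 1000 \
            + "CCCGGGTTTACGTACGTACG" + "A" * 1000
        index = GenomeIndex.from_genome(genome)
        tag = naive_align(RawRead("r", "CCCGGGTTTACGTACGTACG", [35] * 20),
                          index)
        assert tag.mapq == 0
        frame = tags_to_frame([tag])
        assert len(filter_mapq(frame, pipe)) == 0

    def test_no_match_returns_none(self):
        index = GenomeIndex.from_genome("ACGT" * 500)
        assert naive_align(RawRead("r", "TTTTTTTTTT", [35] * 10), index) is None

    def test_empty_insert_rejected(self):
        index = GenomeIndex.from_genome("ACGT" * 500)
        with pytest.raises(MalformedReadError):
            naive_align(RawRead("r", "", []), index)


class TestFilterMapq:
    def test_boundary_values(self, pipe):
        frame = pd.DataFrame({
            "chrom": ["chr1"] * 3, "strand": ["+"] * 3, "stop5": [1, 2, 3],
            "barcode": ["AAA"] * 3, "mapq": [20, 21, 42]})
        kept = filter_mapq(frame, pipe)
        assert list(kept["mapq"]) == [21, 42]

    def test_empty_input(self, pipe):
        frame = pd.DataFrame(columns=["chrom", "strand", "stop5", "barcode",
                                      "mapq"])
        assert len(filter_mapq(frame, pipe)) == 0


def _tag_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand", "stop5", "barcode",
                                       "mapq"])


class TestDeduplicate:
    def test_same_key_collapsed(self):
        frame = _tag_frame([("chr1", "+", 100, "AAACCCGGG", 42)] * 2)
        assert len(deduplicate(frame)) == 1

    def test_distinct_barcodes_retained(self):
        frame = _tag_frame([("chr1", "+", 100, "AAACCCGGG", 42),
                            ("chr1", "+", 100, "TTTCCCGGG", 42)])
        assert len(deduplicate(frame)) == 2

    def test_missing_barcode_rejected(self):
        frame = _tag_frame([("chr1", "+", 100, "", 42)])
        with pytest.raises(ValueError):
            deduplicate(frame)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(
        st.sampled_from(["chr1", "chr2"]), st.sampled_from(["+", "-"]),
        st.integers(0, 5), st.sampled_from(["AAA", "CCC", "GGG"])),
        max_size=30))
    def test_matches_unique_key_oracle(self, tags):
        frame = _tag_frame([(c, s, p, b, 42) for c, s, p, b in tags])
        deduped = deduplicate(frame)
        keys = list(zip(deduped["chrom"], deduped["strand"],
                        deduped["stop5"], deduped["barcode"]))
        # brute-force: first occurrence of each unique key, in input order
        seen, expected = set(), []
        for key in [(c, s, p, b) for c, s, p, b in tags]:
            if key not in seen:
                seen.add(key)
                expected.append(key)
        assert keys == expected

    def test_idempotent(self, rng):
        rows = [("chr1", rng.choice(["+", "-"]), int(rng.integers(0, 50)),
                 "".join(rng.choice(list("ACGT"), 3)), 42)
                for _ in range(200)]
        frame = _tag_frame(rows)
        once = deduplicate(frame)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)


def test_dedup_rate_matches_simulated_duplication(small_sim, pipe):
    """Post-dedup tag count ~ (1-d) * total on jitter-free simulator output."""
    cfg = SimConfig(**{**small_sim.__dict__, "duplication_rate": 0.25,
                       "border_jitter": 0, "background_read_rate": 0.0})
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    records, expected = simulate_nexus_reads(genome, truth, "CORT", "MR", cfg)
    frame = _tag_frame([(r["chrom"], r["strand"], r["stop5"], r["barcode"], 42)
                        for _, r in expected.iterrows()])
    deduped = deduplicate(frame)
    total = len(frame)
    assert abs(len(deduped) / total - 0.75) < 0.02


def test_process_reads_end_to_end_counts(small_sim, pipe):
    genome, truth = plant_sites(simulate_genome(small_sim), small_sim)
    records, expected = simulate_nexus_reads(genome, truth, "CORT", "MR",
                                             small_sim)
    raw = [RawRead(r.read_id, r.sequence, [ord(c) - 33 for c in r.quality])
           for r in records]
    index = GenomeIndex.from_genome(genome, small_sim.chrom)
    tags, log = process_reads(raw, index, pipe)
    assert log["input_reads"] == len(records)
    assert log["final_tags"] == len(tags)
    # filtering never creates reads
    assert log["final_tags"] <= log["aligned"] <= log["input_reads"]
    n_unique = len(expected.drop_duplicates(
        subset=["chrom", "strand", "stop5", "barcode"]))
    # every simulated unique molecule should align (exact reads, Q35)
    assert log["final_tags"] == n_unique


def test_read_sam_tags_conventions(tmp_path):
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
        "r1:AAACCCGGG\t0\tchr1\t101\t42\t10M\t*\t0\t0\tACGTACGTAC\t"
        "IIIIIIIIII\n"
        "r2:TTTCCCGGG\t16\tchr1\t201\t42\t10M\t*\t0\t0\tACGTACGTAC\t"
        "IIIIIIIIII\n")
    tags = read_sam_tags(sam)
    assert list(tags["strand"]) == ["+", "-"]
    assert list(tags["stop5"]) == [100, 209]     # SAM is 1-based
    assert list(tags["barcode"]) == ["AAACCCGGG", "TTTCCCGGG"]
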