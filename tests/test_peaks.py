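"""Peak calling: stop profiles, Poisson local-lambda test, FDR, replicates."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from nexuskit.config import PipelineConfig, SimConfig
from nexuskit.evaluate import summit_recovery
from nexuskit.peaks import (Peak, StopProfile, bh_fdr, build_stop_profile,
                            call_peaks, read_narrowpeak, reproducible_peaks,
                            write_narrowpeak)
from nexuskit.pipeline import run_pipeline
from nexuskit.preprocess import GenomeIndex, process_reads
from nexuskit.simulate import plant_sites, simulate_genome


def _tags(rows):
    return pd.DataFrame(rows, columns=["chrom", "strand", "stop5", "barcode",
                                       "mapq"])


class TestStopProfile:
    def test_counts_at_position(self):
        tags = _tags([("chr1", "+", 100, f"b{i}", 42) for i in range(3)])
        prof = build_stop_profile(tags, {"chr1": 200})["chr1"]
        assert prof.plus[100] == 3 and prof.minus.sum() == 0

    def test_empty_tags_give_zero_profile(self):
        tags = _tags([])
        prof = build_stop_profile(tags, {"chr1": 50})["chr1"]
        assert prof.total == 0

    def test_matches_brute_force_tally(self, rng):
        rows = [("chr1", rng.choice(["+", "-"]), int(rng.integers(0, 1000)),
                 "b", 42) for _ in range(1000)]
        prof = build_stop_profile(_tags(rows), {"chr1": 1000})["chr1"]
        expected_plus = np.zeros(1000, int)
        expected_minus = np.zeros(1000, int)
        for _, s, p, _, _ in rows:
            (expected_plus if s == "+" else expected_minus)[p] += 1
        assert np.array_equal(prof.plus, expected_plus)
        assert np.array_equal(prof.minus, expected_minus)
        assert prof.total == 1000

    def test_out_of_bounds_position_rejected(self):
        tags = _tags([("chr1", "+", 500, "b", 42)])
        with pytest.raises(ValueError):
            build_stop_profile(tags, {"chr1": 100})


class TestBhFdr:
    def test_step_up_hand_computation(self):
        # q_i = min over j with p_j >= p_i of p_j * n / rank_j
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        q = bh_fdr(p)
        assert np.allclose(q, [0.05] * 5)

    def test_single_pvalue_unchanged(self):
        assert np.allclose(bh_fdr([0.03]), [0.03])

    def test_all_equal_pvalues_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_monotone_in_p(self, rng):
        p = rng.random(100)
        q = q_of = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q_of[order]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _uniform_profile(L, spacing, chrom="chr1"):
    plus = np.zeros(L, dtype=np.int64)
    plus[::spacing] = 1
    return {chrom: StopProfile(chrom, plus, np.zeros(L, dtype=np.int64))}


class TestCallPeaks:
    def test_identical_profiles_give_no_peaks(self, pipe):
        prof = _uniform_profile(200_000, 50)
        ctrl = _uniform_profile(200_000, 50)
        assert call_peaks(prof, ctrl, pipe) == []

    def test_enriched_window_pvalue_matches_poisson_tail(self, pipe):
        # uniform rate of 2 tags per 100 bp window + a 28-tag spike:
        # lambda_local = genome-wide rate, p = Poisson upper tail
        L = 200_000
        treatment = _uniform_profile(L, 50)
        treatment["chr1"].plus[100_013] += 28
        control = _uniform_profile(L, 50)
        peaks = call_peaks(treatment, control, pipe)
        assert len(peaks) == 1
        pk = peaks[0]
        t_total = L // 50 + 28
        scale = t_total / (L // 50)
        lam = 2 * scale          # window-scale control rate, depth-scaled
        expected_p = poisson.sf(30 - 1, lam)
        assert np.isclose(pk.pvalue, expected_p, rtol=1e-9)
        assert pk.qvalue < 0.05
        assert pk.start <= 100_013 <= pk.end

    def test_zero_depth_control_requires_pseudocount(self, pipe):
        L = 10_000
        treatment = _uniform_profile(L, 100)
        control = {"chr1": StopProfile("chr1", np.zeros(L, int),
                                       np.zeros(L, int))}
        with pytest.raises(ValueError, match="pseudocount"):
            call_peaks(treatment, control, pipe, pseudocount=0.0)
        # with the default pseudocount it runs
        call_peaks(treatment, control, pipe)

    def test_monotonicity_scaling_treatment_keeps_peak(self, pipe):
        L = 50_000
        treatment = _uniform_profile(L, 100)
        treatment["chr1"].plus[20_000] += 40
        control = _uniform_profile(L, 100)
        before = call_peaks(treatment, control, pipe)
        assert any(p.start <= 20_000 < p.end for p in before)
        doubled = {"chr1": StopProfile(
            "chr1", treatment["chr1"].plus * 2, treatment["chr1"].minus * 2)}
        after = call_peaks(doubled, control, pipe)
        assert any(p.start <= 20_000 < p.end for p in after)

    def test_peak_geometry_invariants(self, pipe, small_sim):
        res = run_pipeline(small_sim, pipe, conditions=("CORT",),
                           factors=("MR",))
        peaks = res.peaks_for("MR", "CORT")
        assert peaks
        L = small_sim.genome_length
        for pk in peaks:
            assert pk.width == pipe.peak_width
            assert 0 <= pk.start and pk.end <= L
            assert pk.start <= pk.summit < pk.end
            assert pk.qvalue >= pk.pvalue

    def test_planted_sites_recovered(self, pipe, small_sim):
        res = run_pipeline(small_sim, pipe, conditions=("CORT",),
                           factors=("MR",))
        rec = summit_recovery(res.truth, res.peaks_for("MR", "CORT"),
                              "CORT", "MR", tolerance=50)
        assert rec.recovery_rate >= 0.9
        assert rec.false_rate <= 0.1

    def test_null_simulation_rarely_yields_peaks(self, pipe):
        """Treatment and control drawn from the same uniform rate."""
        L = 20_000
        n_hits = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            profs = []
            for _ in range(2):
                plus = np.bincount(rng.integers(0, L, 100),
                                   minlength=L).astype(np.int64)
                minus = np.bincount(rng.integers(0, L, 100),
                                    minlength=L).astype(np.int64)
                profs.append({"chr1": StopProfile("chr1", plus, minus)})
            if call_peaks(profs[0], profs[1], pipe):
                n_hits += 1
        assert n_hits / runs <= 0.1


class TestReproduciblePeaks:
    @staticmethod
    def _peak(start, end, name):
        return Peak("chr1", start, end, (start + end) // 2, 1e-6, 1e-5, 5.0,
                    name)

    def test_identical_replicates_keep_everything(self):
        pooled = [self._peak(0, 100, "A"), self._peak(200, 300, "B")]
        reps = [pooled, pooled, pooled]
        assert len(reproducible_peaks(pooled, reps)) == 2

    def test_single_replicate_support_excluded(self):
        pooled = [self._peak(0, 100, "A")]
        reps = [[self._peak(0, 100, "A")], [], []]
        assert reproducible_peaks(pooled, reps, min_support=2) == []

    def test_toy_sets_match_overlap_oracle(self):
        a, b, c = (self._peak(0, 100, "A"), self._peak(200, 300, "B"),
                   self._peak(400, 500, "C"))
        pooled = [a, b, c]
        reps = [[a, b], [b, c], [b]]
        kept = reproducible_peaks(pooled, reps, min_support=2)
        assert [p.name for p in kept] == ["B"]

    def test_min_support_validation(self):
        with pytest.raises(ValueError):
            reproducible_peaks([], [[]], min_support=2)


def test_narrowpeak_round_trip(tmp_path, pipe, small_sim):
    res = run_pipeline(small_sim, pipe, conditions=("CORT",), factors=("MR",))
    peaks = res.peaks_for("MR", "CORT")
    path = tmp_path / "peaks.narrowPeak"
    write_narrowpeak(peaks, path)
    loaded = read_narrowpeak(path)
    assert [(p.chrom, p.start, p.end, p.summit) for p in loaded] == \
        [(p.chrom, p.start, p.end, p.summit) for p in peaks]
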