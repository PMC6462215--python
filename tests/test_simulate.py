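"""Simulator: determinism, planted-site statistics, read geometry."""

import numpy as np
import pytest

from nexuskit.config import ConfigError, SimConfig
from nexuskit.simulate import (GRE_CONSENSUS, plant_sites, reverse_complement,
                               simulate_genome, simulate_input_reads,
                               simulate_nexus_reads)


def test_genome_deterministic_under_fixed_seed():
    cfg = SimConfig(genome_length=1000, gc_content=0.5, seed=1)
    assert simulate_genome(cfg) == simulate_genome(cfg)
    other = SimConfig(genome_length=1000, gc_content=0.5, seed=2)
    assert simulate_genome(cfg) != simulate_genome(other)


def test_genome_gc_limit_cases():
    only_gc = simulate_genome(SimConfig(genome_length=2000, gc_content=1.0,
                                        seed=3))
    assert set(only_gc) <= {"G", "C"}
    only_at = simulate_genome(SimConfig(genome_length=2000, gc_content=0.0,
                                        seed=3))
    assert set(only_at) <= {"A", "T"}


def test_genome_gc_fraction_within_binomial_error():
    n = 1_000_000
    gc = 0.41
    seq = simulate_genome(SimConfig(genome_length=n, gc_content=gc, seed=5))
    observed = (seq.count("G") + seq.count("C")) / n
    sd = np.sqrt(gc * (1 - gc) / n)
    assert abs(observed - gc) <= 3 * sd


def test_genome_rejects_nonpositive_or_tiny_length():
    with pytest.raises(ConfigError):
        SimConfig(genome_length=0)
    with pytest.raises(ConfigError):
        simulate_genome(SimConfig(genome_length=999))


def test_plant_sites_zero_sites_leaves_genome_unchanged():
    cfg = SimConfig(genome_length=10_000, n_sites=0, seed=1)
    genome = simulate_genome(cfg)
    out, truth = plant_sites(genome, cfg)
    assert out == genome
    assert len(truth) == 0


def test_plant_sites_motif_forced_everywhere():
    cfg = SimConfig(genome_length=60_000, n_sites=30, motif_fraction=1.0,
                    seed=2)
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    core_left, core_right = "AGAACA", "TGTTCT"
    for site in truth.sites:
        mid = site.interval.midpoint
        planted = genome[mid - 7:mid + 8]
        assert planted.startswith(core_left) and planted.endswith(core_right)
        assert site.has_motif


def test_plant_sites_truth_geometry():
    cfg = SimConfig(genome_length=100_000, n_sites=50, protected_width=24,
                    seed=3)
    _, truth = plant_sites(simulate_genome(cfg), cfg)
    starts = []
    for s in truth.sites:
        assert s.border_minus - s.border_plus == 24
        assert s.interval.start == s.border_plus
        assert s.interval.end == s.border_minus
        starts.append(s.interval.start)
    # non-overlapping and sorted
    assert starts == sorted(starts)
    for a, b in zip(truth.sites, truth.sites[1:]):
        assert a.interval.end <= b.interval.start


def test_cobound_fraction_within_binomial_error():
    cfg = SimConfig(genome_length=600_000, n_sites=500,
                    co_binding_fraction=0.66, seed=11)
    _, truth = plant_sites(simulate_genome(cfg), cfg)
    bound = truth.bound_sites("CORT", "MR") + truth.bound_sites("CORT", "GR")
    bound_ids = {s.site_id for s in bound}
    co = sum(1 for s in truth.sites
             if s.bound["CORT"]["MR"] and s.bound["CORT"]["GR"])
    frac = co / len(bound_ids)
    sd = np.sqrt(0.66 * 0.34 / len(bound_ids))
    assert abs(frac - 0.66) <= 3 * sd


def test_plant_sites_rejects_overcrowding():
    cfg = SimConfig(genome_length=5000, n_sites=50, seed=1)
    with pytest.raises(ConfigError):
        plant_sites(simulate_genome(cfg), cfg)


def test_reads_zero_bound_zero_background_gives_zero_reads():
    cfg = SimConfig(genome_length=20_000, n_sites=5, background_read_rate=0.0,
                    occupancy={c: {"MR": 0.0, "GR": 0.0}
                               for c in ("vehicle", "CORT", "washout")},
                    seed=4)
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    records, expected = simulate_nexus_reads(genome, truth, "CORT", "MR", cfg)
    assert records == [] and len(expected) == 0


def test_reads_unknown_condition_or_factor_rejected():
    cfg = SimConfig(genome_length=20_000, n_sites=2, seed=4)
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    with pytest.raises(ValueError):
        simulate_nexus_reads(genome, truth, "mock", "MR", cfg)
    with pytest.raises(ValueError):
        simulate_nexus_reads(genome, truth, "CORT", "ER", cfg)


def test_duplication_free_reads_have_distinct_triples():
    # At barcode length 9 the collision probability among 100 reads at one
    # site is ~ C(100,2)/4^9 < 2e-2 per strandwise position; the chosen seed
    # draws distinct (position, strand, barcode) triples, and dedup keys on
    # exactly that triple.
    cfg = SimConfig(genome_length=20_000, n_sites=1, duplication_rate=0.0,
                    background_read_rate=0.0, reads_per_bound_site=100,
                    co_binding_fraction=1.0, seed=6)
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    _, expected = simulate_nexus_reads(genome, truth, "CORT", "MR", cfg)
    triples = set(zip(expected["stop5"], expected["strand"],
                      expected["barcode"]))
    assert len(triples) == len(expected) == 100


def test_washout_gr_reads_far_below_cort():
    cfg = SimConfig(genome_length=100_000, n_sites=50,
                    background_read_rate=0.0, seed=8)
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    _, cort = simulate_nexus_reads(genome, truth, "CORT", "GR", cfg)
    _, wash = simulate_nexus_reads(genome, truth, "washout", "GR", cfg)
    assert len(wash) < 0.2 * len(cort)


def test_jitter_free_stops_sit_exactly_on_borders():
    cfg = SimConfig(genome_length=50_000, n_sites=10, border_jitter=0,
                    duplication_rate=0.0, background_read_rate=0.0, seed=9)
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    _, expected = simulate_nexus_reads(genome, truth, "CORT", "MR", cfg)
    by_site = {s.site_id: s for s in truth.sites}
    for _, row in expected.iterrows():
        site = by_site[row["origin"]]
        if row["strand"] == "+":
            assert row["stop5"] == site.border_plus
        else:
            assert row["stop5"] == site.border_minus


def test_read_count_scales_linearly_without_jitter_or_duplication():
    base = dict(genome_length=50_000, n_sites=10, border_jitter=0,
                duplication_rate=0.0, background_read_rate=0.0, seed=9)
    genome = None
    counts = {}
    for r in (20, 40):
        cfg = SimConfig(reads_per_bound_site=r, **base)
        g, truth = plant_sites(simulate_genome(cfg), cfg)
        _, expected = simulate_nexus_reads(g, truth, "CORT", "MR", cfg)
        n_bound = len(truth.bound_sites("CORT", "MR"))
        assert len(expected) == n_bound * r
        counts[r] = len(expected)
    assert counts[40] == 2 * counts[20]


def test_read_sequences_match_genome():
    cfg = SimConfig(genome_length=30_000, n_sites=5, border_jitter=0,
                    duplication_rate=0.0, background_read_rate=0.0, seed=10)
    genome, truth = plant_sites(simulate_genome(cfg), cfg)
    records, expected = simulate_nexus_reads(genome, truth, "CORT", "MR", cfg)
    for rec, (_, row) in zip(records, expected.iterrows()):
        assert rec.sequence[:9] == row["barcode"]
        insert = rec.sequence[9:]
        if row["strand"] == "+":
            assert genome[row["stop5"]:row["stop5"] + 50] == insert
        else:
            assert reverse_complement(
                genome[row["stop5"] - 49:row["stop5"] + 1]) == insert


def test_input_reads_deterministic_and_roughly_uniform():
    cfg = SimConfig(genome_length=100_000, input_read_rate=5.0, n_sites=0,
                    seed=12)
    genome = simulate_genome(cfg)
    r1, e1 = simulate_input_reads(genome, cfg)
    r2, e2 = simulate_input_reads(genome, cfg)
    assert [x.sequence for x in r1] == [x.sequence for x in r2]
    # ~5 reads/kb over 100 kb -> ~500; Poisson 5 sigma bounds
    assert 350 <= len(e1) <= 680
    left = (e1["stop5"] < 50_000).mean()
    assert 0.4 <= left <= 0.6
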