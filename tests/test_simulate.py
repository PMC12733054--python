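"""Ground-truthed simulator: genome, meiosis, error model and truth tables."""

import numpy as np
import pandas as pd
import pytest

from g2h.coding import code_matrix, find_polymorphic_loci
from g2h.simulate import (
    SimConfig,
    SimConfigError,
    flip_codes,
    rasterize_donor_to_blocks,
    simulate_population,
    truth_metrics,
)

TINY = dict(
    n_chrom=2,
    chrom_lengths_bp=(4_000_000, 3_000_000),
    genetic_lengths_cM=(90.0, 80.0),
    n_blocks_total=60,
    mean_snps_per_block=4.0,
)


def test_config_validation():
    with pytest.raises(SimConfigError):
        SimConfig(error_rate=1.5)
    with pytest.raises(SimConfigError):
        SimConfig(generation=3)
    with pytest.raises(SimConfigError):
        SimConfig(pop_size=0)
    with pytest.raises(SimConfigError):
        SimConfig(n_chrom=3, chrom_lengths_bp=(100,), genetic_lengths_cM=(1.0,))


def test_simulation_is_deterministic():
    cfg = SimConfig(**TINY, pop_size=4, seed=9)
    a = simulate_population(cfg)
    b = simulate_population(cfg)
    assert a.locus_table.df.equals(b.locus_table.df)
    assert a.block_map.df.equals(b.block_map.df)
    assert a.truth.donor_segments.equals(b.truth.donor_segments)
    assert a.truth.true_rp_fraction.equals(b.truth.true_rp_fraction)


def test_genome_structure(small_sim):
    bm = small_sim.block_map
    # seamless tiling validated by the BlockMap constructor; lengths must
    # match the chromosome table exactly
    bm.validate_against(small_sim.chrom_table)
    lt = small_sim.locus_table
    assert lt.samples[:2] == ["RP", "DP"]
    assert len(lt.samples) == 2 + small_sim.config.pop_size


def test_parents_fully_polymorphic(small_sim):
    lt = small_sim.locus_table
    poly = find_polymorphic_loci(lt, "RP", "DP")
    assert poly.n == lt.n_loci  # every simulated SNP separates the parents


def test_error_free_progeny_have_no_donor_homozygotes():
    cfg = SimConfig(**TINY, pop_size=6, error_rate=0.0, missing_rate=0.0, seed=21)
    sim = simulate_population(cfg)
    poly = find_polymorphic_loci(sim.locus_table, "RP", "DP")
    samples = [s for s in sim.locus_table.samples if s not in ("RP", "DP")]
    coded = code_matrix(sim.locus_table, samples, poly)
    # donor chromatin in a backcross is heterozygous: only codes 1 and 2
    assert set(np.unique(coded)) <= {1, 2}


def test_bc1_allele_fraction_and_crossover_rate():
    cfg = SimConfig(
        n_chrom=1,
        chrom_lengths_bp=(5_000_000,),
        genetic_lengths_cM=(200.0,),
        n_blocks_total=40,
        mean_snps_per_block=2.0,
        pop_size=300,
        error_rate=0.0,
        missing_rate=0.0,
        seed=33,
    )
    sim = simulate_population(cfg)
    # allele-dosage RP fraction centres on 0.75 in BC1
    mean = sim.truth.true_rp_allele_fraction.mean()
    assert abs(mean - 0.75) < 0.03
    # crossovers per meiosis ~ Poisson(2 Morgans)
    rate = len(sim.truth.crossovers) / cfg.pop_size
    assert abs(rate - 2.0) < 3 * np.sqrt(2.0 / cfg.pop_size)


def test_bc2_recovers_more_than_bc1():
    base = dict(**TINY, pop_size=40, error_rate=0.0, missing_rate=0.0, seed=13)
    bc1 = simulate_population(SimConfig(**base, generation=1))
    bc2 = simulate_population(SimConfig(**base, generation=2))
    assert bc2.truth.true_rp_fraction.mean() > bc1.truth.true_rp_fraction.mean()


def test_snapped_crossovers_land_on_interior_boundaries():
    cfg = SimConfig(
        **TINY,
        pop_size=10,
        error_rate=0.0,
        missing_rate=0.0,
        seed=5,
        snap_crossovers=True,
        end_margin_blocks=3,
    )
    sim = simulate_population(cfg)
    bdf = sim.block_map.df
    for chrom, sub in bdf.groupby("chrom", sort=False):
        ends = sub["end"].to_numpy()
        n = len(sub)
        allowed = set(ends[max(cfg.end_margin_blocks - 1, 0) : n - cfg.end_margin_blocks])
        xs = sim.truth.crossovers.loc[sim.truth.crossovers["chrom"] == chrom, "pos"]
        assert set(xs.astype(int)) <= allowed


def test_rasterize_matches_brute_force():
    rng = np.random.default_rng(8)
    for _ in range(100):
        n = int(rng.integers(3, 20))
        bounds = np.sort(rng.choice(np.arange(1, 1000), size=n - 1, replace=False))
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [1000]))
        k = int(rng.integers(0, 4))
        pts = np.sort(rng.integers(0, 1001, size=2 * k))
        ivs = pts.reshape(-1, 2)
        ivs = ivs[ivs[:, 1] > ivs[:, 0]]
        got = rasterize_donor_to_blocks(ivs, starts, ends)
        want = np.zeros(n, dtype=bool)
        for b in range(n):
            cov = sum(
                max(0, min(e, ends[b]) - max(s, starts[b])) for s, e in ivs
            )
            want[b] = 2 * cov > ends[b] - starts[b]
        assert (got == want).all()


def test_truth_metrics_consistency():
    cfg = SimConfig(**TINY, pop_size=5, error_rate=0.0, missing_rate=0.0, seed=2)
    sim = simulate_population(cfg)
    tm = truth_metrics(sim.truth, sim.block_map).set_index("sample")
    assert ((tm["true_wgbr_blocks"] >= 0) & (tm["true_wgbr_blocks"] <= 1)).all()
    assert (tm["n_fragments_blocks"] >= 0).all()
    # an individual with no donor segments has block-truth WGBR exactly 1
    for sample in tm.index:
        segs = sim.truth.donor_segments
        if segs[segs["sample"] == sample].empty:
            assert tm.loc[sample, "true_wgbr_blocks"] == 1.0
            assert tm.loc[sample, "n_fragments_blocks"] == 0


def test_flip_codes_only_swaps_informative():
    rng = np.random.default_rng(1)
    codes = np.array([0, 1, 2, 1, 2, 0] * 100, dtype=np.uint8)
    out = flip_codes(codes, 0.5, rng)
    assert ((codes == 0) == (out == 0)).all()  # zeros untouched
    changed = codes != out
    assert changed.any()
    assert (out[changed] == 3 - codes[changed]).all()
    same = flip_codes(codes, 0.0, rng)
    assert (same == codes).all()


def test_missingness_rate_applied():
    cfg = SimConfig(**TINY, pop_size=8, error_rate=0.0, missing_rate=0.2, seed=6)
    sim = simulate_population(cfg)
    samples = [s for s in sim.locus_table.samples if s not in ("RP", "DP")]
    frac = np.mean(
        [np.mean(sim.locus_table.calls(s) == "NN") for s in samples]
    )
    assert abs(frac - 0.2) < 0.03
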