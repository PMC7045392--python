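"""The synthetic-data generator: closed forms, noise moments, determinism."""

import dataclasses

import numpy as np
import pytest

from csdrmfa.genome import ChromosomeMap, ECOLI_K12, circular_distance
from csdrmfa.mfa import loess_fit, normalize_by_mode
from csdrmfa.peaks import call_orik_peaks, ori_ter_ratio
from csdrmfa.rlfs import find_rlfs, merge_loci
from csdrmfa.simulate import (
    ExpressionScenario,
    ReplicationScenario,
    expected_copy_number,
    expression_presets,
    make_gene_table,
    simulate_coverage,
    simulate_expression,
    synthesize_genome_with_rlfs,
)
from csdrmfa.collision import head_on_fraction
from csdrmfa.variants import detect_inversions


@pytest.fixture()
def circle():
    return ChromosomeMap("c", 1_000_000, oriC_position=250_000,
                         dif_position=750_000, ter_region=(700_000, 800_000))


class TestExpectedCopyNumber:
    def test_formula_endpoints(self, circle):
        scen = ReplicationScenario(chrom=circle, origins=((250_000, 1.0),),
                                   amplitudes=(1.5,))
        assert expected_copy_number(scen, 250_000) == pytest.approx(2.0 ** 1.5)
        assert expected_copy_number(scen, 750_000) == pytest.approx(1.0)  # antipode

    def test_flat_scenario_unity(self, circle):
        scen = ReplicationScenario(chrom=circle, origins=((250_000, 1.0),),
                                   amplitudes=(0.0,))
        pos = np.linspace(1, circle.length, 57)
        assert np.allclose(expected_copy_number(scen, pos), 1.0)

    def test_two_antipodal_origins_symmetric(self, circle):
        scen = ReplicationScenario(
            chrom=circle, origins=((250_000, 0.5), (750_000 + 1, 0.5)),
            amplitudes=(1.0, 1.0),
        )
        grid = np.arange(100) * (circle.length // 100) + 1.0
        c = expected_copy_number(scen, grid)
        # direct formula evaluation on the same grid
        L = circle.length
        direct = np.zeros(100)
        for o, w, a in ((250_000, 0.5, 1.0), (750_001, 0.5, 1.0)):
            d = np.minimum((grid - o) % L, (o - grid) % L)
            direct += w * 2.0 ** (a * (1 - d / (L / 2)))
        assert np.allclose(c, direct)
        assert abs(c.max() - c[np.argmin(np.abs(grid - 750_001))]) < 0.02

    def test_deletion_zero_inversion_reflected(self, circle):
        scen = ReplicationScenario(
            chrom=circle, origins=((250_000, 1.0),), amplitudes=(1.0,),
            inversions=((500_000, 600_000),), deletions=((50_000, 60_000),),
        )
        assert expected_copy_number(scen, 55_000) == 0.0
        # reference position y inside the flip reads the sample at a+b-y
        base = dataclasses.replace(scen, inversions=(), deletions=())
        y = 520_000
        assert expected_copy_number(scen, y) == pytest.approx(
            expected_copy_number(base, 500_000 + 600_000 - y)
        )

    def test_ter_trap_plateau(self, circle):
        scen = ReplicationScenario(chrom=circle, origins=((250_000, 1.0),),
                                   amplitudes=(1.0,), ter_trap=True,
                                   trap_peak_log2=0.8)
        inside = expected_copy_number(scen, 750_000)
        just_outside = expected_copy_number(scen, 805_000)
        assert inside == pytest.approx(2.0 ** 0.8, rel=1e-6)
        assert inside > just_outside

    def test_position_out_of_range_rejected(self, circle):
        scen = ReplicationScenario(chrom=circle, origins=((250_000, 1.0),),
                                   amplitudes=(1.0,))
        with pytest.raises(ValueError, match="outside"):
            expected_copy_number(scen, circle.length + 1)

    def test_weights_must_sum_to_one(self, circle):
        with pytest.raises(ValueError, match="weights"):
            ReplicationScenario(chrom=circle, origins=((1, 0.5), (2, 0.6)),
                                amplitudes=(1.0, 1.0))


class TestSimulateCoverage:
    def test_determinism(self, circle):
        scen = ReplicationScenario(chrom=circle, origins=((250_000, 1.0),),
                                   amplitudes=(1.0,), seed=99)
        a = simulate_coverage(scen, bin_size=1000)
        b = simulate_coverage(scen, bin_size=1000)
        assert np.array_equal(a.counts, b.counts)

    def test_poisson_limit_variance(self, circle):
        """dispersion -> inf: per-bin variance approaches the mean."""
        scen = ReplicationScenario(chrom=circle, origins=((250_000, 1.0),),
                                   amplitudes=(0.0,), depth_per_bin=100,
                                   dispersion=1e6, seed=7)
        counts = simulate_coverage(scen, bin_size=100).counts  # 10^4 bins
        # moments of Poisson(100) over n=10^4: var within 3 sigma
        n = len(counts)
        se_var = 100 * np.sqrt(2 / (n - 1))  # var of sample variance ~ 2 sigma^4/n
        assert abs(counts.var(ddof=1) - 100) < 3 * se_var

    def test_mean_matches_expectation(self, circle):
        scen = ReplicationScenario(chrom=circle, origins=((250_000, 1.0),),
                                   amplitudes=(1.0,), depth_per_bin=200,
                                   dispersion=50)
        c = expected_copy_number(scen, np.array([250_500.0]))
        cc = expected_copy_number(
            scen, simulate_coverage(scen, bin_size=1000).midpoints).mean()
        mu = 200 * float(c[0]) / cc
        draws = np.array([
            simulate_coverage(dataclasses.replace(scen, seed=s), bin_size=1000).counts[250]
            for s in range(200)
        ])
        sd = np.sqrt(mu + mu**2 / 50)
        assert abs(draws.mean() - mu) < 3 * sd / np.sqrt(200)


class TestSimulateExpression:
    def test_balanced_construction_half(self, circle, rng):
        # equal levels, balanced strands: p_ho ~ 0.5
        genes = tuple(
            dataclasses.replace(g) for g in make_gene_table(
                circle, n_mrna=400, rrn_operons={}, leading_bias=0.5, seed=14)
        )
        expr = simulate_expression(ExpressionScenario(genes=genes, rrna_ratio=2,
                                                      seed=15))
        sc = head_on_fraction(expr, list(genes), (1, circle.length), 250_000, circle)
        assert sc.p_ho == pytest.approx(0.5, abs=0.05)

    def test_codirectional_rrna_low_pho(self, circle):
        # rRNA placed co-directional to the scoring origin at 100:1 levels
        rrn = {"rrnX": (300_000, "+"), "rrnY": (400_000, "+"), "rrnZ": (900_000, "-")}
        genes = make_gene_table(circle, n_mrna=50, rrn_operons=rrn,
                                leading_bias=0.5, seed=16)
        expr = simulate_expression(ExpressionScenario(genes=genes, rrna_ratio=100,
                                                      seed=17))
        sc = head_on_fraction(expr, list(genes), (1, circle.length), 250_000, circle,
                              gene_class_filter="rRNA")
        assert sc.p_ho < 0.05

    def test_zero_noise_limit(self, circle):
        genes = make_gene_table(circle, n_mrna=30, rrn_operons={}, seed=18)
        expr = simulate_expression(
            ExpressionScenario(genes=genes, base_level=123.0, rrna_ratio=20,
                               dispersion=np.inf, seed=19)
        )
        assert all(v == 123.0 for v in expr.values())


class TestSynthesizeGenome:
    def test_planted_m1_cassettes_recovered(self):
        placements = [(i * 18_000 + 5_000, "m1", "+") for i in range(5)]
        seq, truth = synthesize_genome_with_rlfs(100_000, placements, gc=0.25, seed=31)
        loci = merge_loci(find_rlfs(seq))
        for t in truth:
            assert any(lc.start <= t["start"] <= lc.end or
                       abs(lc.start - t["start"]) < 1000 for lc in loci)
        assert len(loci) >= 5

    def test_minus_strand_recovered_with_strand(self):
        seq, truth = synthesize_genome_with_rlfs(20_000, [(8_000, "m2", "-")],
                                                 gc=0.25, seed=32)
        sites = find_rlfs(seq, models=("m2",))
        minus = [s for s in sites if s.strand == "-"]
        assert any(abs(s.span[0] - 8_000) < 500 for s in minus)

    def test_low_gc_background_rarely_spawns_m2(self):
        hits = 0
        for seed in range(20):
            seq, _ = synthesize_genome_with_rlfs(100_000, [], gc=0.25, seed=seed)
            hits += bool(find_rlfs(seq, models=("m2",)))
        assert hits <= 1

    def test_colliding_placements_rejected(self):
        with pytest.raises(ValueError, match="collides"):
            synthesize_genome_with_rlfs(10_000, [(100, "m1", "+"), (150, "m1", "+")],
                                        seed=1)


class TestPresets:
    def test_wild_type_ori_ter_band(self, presets):
        b = normalize_by_mode(simulate_coverage(presets["wild-type-like"], bin_size=1000))
        assert 2.3 <= ori_ter_ratio(loess_fit(b)) <= 2.7

    def test_stationary_no_peaks(self, presets):
        b = normalize_by_mode(simulate_coverage(presets["stationary-like"], bin_size=1000))
        assert call_orik_peaks(loess_fit(b)) == []

    def test_suppressor_peak_and_inversion(self, presets):
        scen = presets["suppressor-like"]
        b = normalize_by_mode(simulate_coverage(scen, bin_size=1000))
        (inv,) = detect_inversions(b)
        assert abs(inv.start - 3_420_000) <= 25_000
        assert abs(inv.end - 4_200_000) <= 25_000
        prof = loess_fit(b, inversions=[(inv.start, inv.end)])
        peaks = call_orik_peaks(prof)
        assert any(
            circular_distance(p.position, 4_510_000, scen.chrom.length) <= 50_000
            for p in peaks
        )

    def test_expression_presets_reproduce_strain_ordering(self):
        """Head-on burden: cSDR parent >> inverted suppressor; wild type low."""
        region = (3_300_000, 4_250_000)
        eps = expression_presets(seed=0)
        scores = {}
        for name, cfg in eps.items():
            expr = simulate_expression(cfg["expr"])
            scores[name] = {
                cls: head_on_fraction(expr, list(cfg["genes"]), region,
                                      cfg["origin"], ECOLI_K12,
                                      gene_class_filter=cls).p_ho
                for cls in ("all", "rRNA")
            }
        assert scores["csdr-parent-like"]["all"] > 0.5
        assert scores["csdr-parent-like"]["rRNA"] > 0.7
        assert scores["suppressor-like"]["rRNA"] < scores["csdr-parent-like"]["rRNA"]
        assert scores["wild-type-like"]["all"] < scores["csdr-parent-like"]["all"]
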