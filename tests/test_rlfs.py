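"""QmRLFS m1/m2 site prediction and the peak-proximity permutation test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from csdrmfa.genome import ChromosomeMap
from csdrmfa.rlfs import (
    DEFAULT_PARAMS,
    find_rlfs,
    merge_loci,
    proximity_permutation_test,
    reverse_complement,
)


# -- brute-force oracle ------------------------------------------------------


def brute_force_riz(seq, g_min, params=DEFAULT_PARAMS):
    """All valid RIZ intervals by checking every (start, end) substring.

    A valid RIZ starts and ends with a maximal G-tract of >= g_min,
    contains >= 3 such tracts with consecutive inter-tract gaps of 1-10
    nt (gap content is unconstrained: shorter G-runs count as linker),
    and has overall G-density >= 50%. Quadratic scan, independent of
    the tract-chain implementation.
    """
    import re as _re

    n = len(seq)
    # a RIZ must start and end exactly on a maximal G-run of >= g_min, so
    # only run boundaries need checking; the definition itself is applied
    # directly to each candidate substring
    run_bounds = [(m.start(), m.end()) for m in _re.finditer("G+", seq)
                  if m.end() - m.start() >= g_min]
    out = set()
    for s, _ in run_bounds:
        for _, e in run_bounds:
            if e <= s:
                continue
            sub = seq[s:e]
            runs = [(m.start(), m.end()) for m in _re.finditer("G+", sub)]
            tracts = [(a, b) for a, b in runs if b - a >= g_min]
            if len(tracts) < params.min_tracts:
                continue
            if tracts[0][0] != 0 or tracts[-1][1] != len(sub):
                continue
            gaps = [tracts[i + 1][0] - tracts[i][1] for i in range(len(tracts) - 1)]
            if not all(params.tract_linker_min <= g <= params.tract_linker_max for g in gaps):
                continue
            if sub.count("G") / len(sub) < params.riz_g_density:
                continue
            out.add((s, e))
    return out


def chain_riz_set(seq, g_min):
    """RIZ intervals from the implementation's candidate enumeration."""
    from csdrmfa.rlfs import _riz_candidates

    cands, _ = _riz_candidates(seq, g_min, DEFAULT_PARAMS)
    return {(s, e) for s, e, _ in cands}


class TestRIZOracle:
    @pytest.mark.parametrize("seed", range(100))
    def test_riz_equivalence_random_strings(self, seed):
        """Tract-chain RIZ enumeration matches the quadratic oracle."""
        rng = np.random.default_rng(seed)
        # G-rich alphabet so tracts are common in short strings
        seq = "".join(rng.choice(list("GGGACT"), size=200))
        for model, g_min in (("m1", 3), ("m2", 4)):
            assert chain_riz_set(seq, g_min) == brute_force_riz(seq, g_min)


def make_cassette(rng, tract="GGGG", rez_len=300, rez_g=0.45):
    riz = tract + "AATTA" + tract + "AATTA" + tract
    linker = "".join(rng.choice(list("ACT"), size=20))
    rez = np.array(list("".join(rng.choice(list("ACT"), size=rez_len))))
    rez[rng.choice(rez_len, size=int(rez_len * rez_g), replace=False)] = "G"
    return riz + linker + "".join(rez)


class TestFindRLFS:
    def test_poly_a_empty(self):
        assert find_rlfs("A" * 10_000) == []

    def test_worked_cassette_one_site_per_model(self, rng):
        """Three G4-tracts + qualifying REZ: one merged site per model."""
        cassette = make_cassette(rng)
        seq = "".join(rng.choice(list("ACT"), size=150)) + cassette \
            + "".join(rng.choice(list("ACT"), size=150))
        sites = find_rlfs(seq)
        plus = [s for s in sites if s.strand == "+"]
        assert sorted(s.model for s in plus) == ["m1", "m2"]
        assert all(s.riz[0] >= 151 for s in plus)
        # RIZ/linker/REZ adjacent and in transcription order
        for s in plus:
            assert s.riz[1] < s.rez[0]
            assert s.linker == (s.riz[1] + 1, s.rez[0] - 1)

    def test_m2_requires_four_g_tracts(self, rng):
        cassette = make_cassette(rng, tract="GGG")
        seq = "".join(rng.choice(list("ACT"), size=100)) + cassette \
            + "".join(rng.choice(list("ACT"), size=100))
        models = {s.model for s in find_rlfs(seq) if s.strand == "+"}
        assert models == {"m1"}

    def test_strand_symmetry(self, rng):
        """Sites on the reverse complement mirror the forward sites."""
        cassette = make_cassette(rng)
        seq = "".join(rng.choice(list("ACT"), size=200)) + cassette \
            + "".join(rng.choice(list("ACT"), size=137))
        fwd = find_rlfs(seq)
        rev = find_rlfs(reverse_complement(seq))
        L = len(seq)

        def key(sites):
            return sorted(
                (s.model, s.strand, s.riz, s.rez) for s in sites
            )

        def mirror(sites):
            flip = {"+": "-", "-": "+"}
            return sorted(
                (s.model, flip[s.strand],
                 (L - s.riz[1] + 1, L - s.riz[0] + 1),
                 (L - s.rez[1] + 1, L - s.rez[0] + 1))
                for s in sites
            )

        assert key(fwd) == mirror(rev)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            find_rlfs("GGGAGGGAGGG")

    def test_rez_respects_linker_and_search_limits(self, rng):
        # REZ further than 50 nt downstream of the RIZ: no site
        riz = "GGGG" + "AT" + "GGGG" + "AT" + "GGGG"
        far = "".join(rng.choice(list("ACT"), size=80))
        rez = "G" * 60 + ("GAT" * 40)
        seq = ("".join(rng.choice(list("ACT"), size=100)) + riz + far + rez
               + "".join(rng.choice(list("ACT"), size=100)))
        sites = [s for s in find_rlfs(seq, models=("m2",)) if s.strand == "+"]
        # the only qualifying REZ start is beyond the 50-nt linker limit,
        # but a shorter REZ window that includes 'far' fails 40% density
        assert all(s.rez[0] - s.riz[1] - 1 <= 50 for s in sites)


class TestMergeLoci:
    def test_disjoint_m1_sites_stay_distinct(self, rng):
        from csdrmfa.simulate import synthesize_genome_with_rlfs

        seq, truth = synthesize_genome_with_rlfs(
            30_000, [(5_000, "m1", "+"), (20_000, "m1", "+")], gc=0.2, seed=8
        )
        loci = merge_loci(find_rlfs(seq))
        assert len(loci) == 2
        assert all(lc.models == frozenset({"m1"}) for lc in loci)

    def test_overlapping_m1_m2_merge_to_both(self, rng):
        cassette = make_cassette(rng)  # G4 tracts satisfy m1 and m2
        seq = "".join(rng.choice(list("ACT"), size=200)) + cassette \
            + "".join(rng.choice(list("ACT"), size=200))
        loci = merge_loci(find_rlfs(seq))
        both = [lc for lc in loci if lc.models == frozenset({"m1", "m2"})]
        assert len(both) >= 1


class ToyChrom:
    pass


class TestProximityPermutationTest:
    def test_loci_covering_everything_degenerate(self, toy_chrom):
        res = proximity_permutation_test(
            [100_000, 500_000], [(1, toy_chrom.length)], toy_chrom,
            radius=10_000, n=200, seed=1,
        )
        assert res.degenerate and res.observed_count == 2 and res.p_one_tailed == 1.0

    def test_exact_enumeration_toy_circle(self):
        """Permutation moments match exhaustive enumeration on a toy circle."""
        chrom = ChromosomeMap("t", 1000, oriC_position=1, dif_position=500,
                              ter_region=(400, 600))
        locus = [(100, 150)]
        radius = 75
        # exhaustive: single-peak hit probability over all L positions
        hits = np.array([
            1 if (100 <= p <= 150) or min((100 - p) % 1000, (p - 100) % 1000,
                                          (150 - p) % 1000, (p - 150) % 1000) <= radius
            else 0
            for p in range(1, 1001)
        ])
        # exact null for 2 iid peaks: Binomial(2, q)
        q = hits.mean()
        exact_mean, exact_sd = 2 * q, np.sqrt(2 * q * (1 - q))
        res = proximity_permutation_test([120, 800], locus, chrom,
                                         radius=radius, n=4000, seed=3)
        mc_se = exact_sd / np.sqrt(4000)
        assert abs(res.null_mean - exact_mean) <= 3 * mc_se
        assert res.null_sd == pytest.approx(exact_sd, rel=0.1)
        assert res.observed_count == 1  # 120 within 75 of the locus; 800 not

    def test_determinism(self, ecoli):
        a = proximity_permutation_test([1_000_000], [(500_000, 510_000)], ecoli, seed=9)
        b = proximity_permutation_test([1_000_000], [(500_000, 510_000)], ecoli, seed=9)
        assert a == b

    def test_radius_monotonicity(self, ecoli):
        peaks = [100_000, 900_000, 2_500_000, 4_000_000]
        loci = [(800_000, 820_000), (3_900_000, 3_950_000)]
        counts = [
            proximity_permutation_test(peaks, loci, ecoli, radius=r, n=100, seed=2).observed_count
            for r in (10_000, 50_000, 150_000, 400_000)
        ]
        assert counts == sorted(counts)

    def test_null_calibration_p_uniform(self, ecoli):
        """With peaks drawn from the null, one-tailed p is ~uniform.

        Enough peaks that the count statistic has fine-grained support
        (the p distribution of a small discrete count is unavoidably
        lumpy regardless of calibration).
        """
        rng = np.random.default_rng(77)
        loci = [(400_000, 430_000), (1_200_000, 1_210_000), (2_800_000, 2_850_000),
                (3_500_000, 3_505_000), (4_500_000, 4_520_000)]
        pvals = []
        for rep in range(200):
            peaks = rng.integers(1, ecoli.length + 1, size=100)
            res = proximity_permutation_test(peaks, loci, ecoli, n=300, seed=rep)
            pvals.append(res.p_one_tailed)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_needs_peaks_and_permutations(self, ecoli):
        with pytest.raises(ValueError, match="peak"):
            proximity_permutation_test([], [(1, 10)], ecoli, seed=1)
        with pytest.raises(ValueError, match="100"):
            proximity_permutation_test([5], [(1, 10)], ecoli, n=10, seed=1)


@pytest.fixture()
def toy_chrom():
    return ChromosomeMap("toy", 1_000_000, oriC_position=800_000,
                         dif_position=300_000, ter_region=(200_000, 400_000))
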