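"""Two-locus EM haplotype frequencies and adjacent-pair r² summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpladder import ldstats
from snpladder import simdata as sd
from tests.conftest import tiny_map


def grid_search_r2(d1, d2, n_coarse=2001, refinements=3):
    """Independent 1-D likelihood maximization over f_AB.

    Allele frequencies are fixed at their sample values (the margins are
    preserved by the two-locus EM); the coupling haplotype frequency is
    scanned on a grid with local refinement. Genotype-pair probabilities are
    computed by enumerating the 4x4 haplotype pairings.
    """
    d1 = np.asarray(d1)
    d2 = np.asarray(d2)
    ok = (d1 != sd.MISSING) & (d2 != sd.MISSING)
    d1, d2 = d1[ok], d2[ok]
    n = len(d1)
    p_a = d1.mean() / 2
    p_b = d2.mean() / 2
    counts = np.zeros((3, 3))
    for a, b in zip(d1, d2):
        counts[a, b] += 1

    # haplotype dosage contribution: index 0=AB,1=Ab,2=aB,3=ab
    hap_a = np.array([1, 1, 0, 0])
    hap_b = np.array([1, 0, 1, 0])

    def loglik(f_ab):
        f = np.array(
            [f_ab, p_a - f_ab, p_b - f_ab, 1 - p_a - p_b + f_ab]
        )
        if np.any(f < -1e-12):
            return -np.inf
        f = np.clip(f, 1e-300, None)
        probs = np.zeros((3, 3))
        for i in range(4):
            for j in range(4):
                probs[hap_a[i] + hap_a[j], hap_b[i] + hap_b[j]] += f[i] * f[j]
        with np.errstate(divide="ignore"):
            logp = np.where(counts > 0, np.log(np.clip(probs, 1e-300, None)), 0.0)
        return float((counts * logp).sum())

    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    grid = np.linspace(lo, hi, n_coarse)
    for _ in range(refinements):
        vals = np.array([loglik(f) for f in grid])
        best = grid[int(np.argmax(vals))]
        width = (grid[1] - grid[0]) * 2
        grid = np.linspace(max(lo, best - width), min(hi, best + width), 201)
    vals = np.array([loglik(f) for f in grid])
    f_ab = grid[int(np.argmax(vals))]
    D = f_ab - p_a * p_b
    return D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))


def _sample_pair(rng, n=80):
    """Random two-locus genotypes from random haplotype frequencies."""
    while True:
        f = rng.dirichlet([1, 1, 1, 1])
        hap_a = np.array([1, 1, 0, 0])
        hap_b = np.array([1, 0, 1, 0])
        h1 = rng.choice(4, size=n, p=f)
        h2 = rng.choice(4, size=n, p=f)
        d1 = hap_a[h1] + hap_a[h2]
        d2 = hap_b[h1] + hap_b[h2]
        if 0 < d1.mean() / 2 < 1 and 0 < d2.mean() / 2 < 1:
            return d1.astype(np.int16), d2.astype(np.int16)


class TestEmHaplotypeFreqs:
    def test_perfect_coupling(self):
        d1 = np.array([0, 2] * 20, dtype=np.int16)
        res = ldstats.em_haplotype_freqs(d1, d1)
        assert res.r2 == pytest.approx(1.0)
        assert res.freqs[0] == pytest.approx(0.5)
        assert res.freqs[3] == pytest.approx(0.5)

    def test_independent_loci(self):
        """All nine genotype combinations equally frequent: D = 0, r² = 0."""
        d1, d2 = [], []
        for a in range(3):
            for b in range(3):
                d1 += [a] * 4
                d2 += [b] * 4
        res = ldstats.em_haplotype_freqs(
            np.array(d1, np.int16), np.array(d2, np.int16)
        )
        assert res.D == pytest.approx(0.0, abs=1e-9)
        assert res.r2 == pytest.approx(0.0, abs=1e-9)

    def test_matches_grid_oracle_with_double_hets(self):
        rng = np.random.default_rng(11)
        done = 0
        while done < 5:
            d1, d2 = _sample_pair(rng)
            if not np.any((d1 == 1) & (d2 == 1)):
                continue
            res = ldstats.em_haplotype_freqs(d1, d2)
            assert res.converged
            assert res.r2 == pytest.approx(grid_search_r2(d1, d2), abs=1e-4)
            done += 1

    def test_unambiguous_sample_equals_gamete_count_r2(self):
        """With no double heterozygotes the haplotypes are fully determined,
        so the EM solution must equal the direct gamete-count r²."""
        rng = np.random.default_rng(13)
        done = 0
        while done < 5:
            d1, d2 = _sample_pair(rng)
            keep = ~((d1 == 1) & (d2 == 1))
            d1, d2 = d1[keep], d2[keep]
            if not (0 < d1.mean() / 2 < 1 and 0 < d2.mean() / 2 < 1):
                continue
            # enumerate gametes: het/hom combinations resolve uniquely
            gametes = []
            for a, b in zip(d1, d2):
                if a == 1 and b != 1:
                    gametes += [(1, b // 2), (0, b // 2)]
                elif b == 1 and a != 1:
                    gametes += [(a // 2, 1), (a // 2, 0)]
                else:
                    gametes += [(a // 2, b // 2)] * 2
            ga = np.array([g[0] for g in gametes], float)
            gb = np.array([g[1] for g in gametes], float)
            expected = np.corrcoef(ga, gb)[0, 1] ** 2
            res = ldstats.em_haplotype_freqs(d1, d2)
            assert res.r2 == pytest.approx(expected, abs=1e-9)
            done += 1

    def test_gamete_duplicate_sample_equals_dosage_correlation(self):
        """When every individual carries two copies of one gamete the
        dosage correlation coincides with the gamete correlation, so EM r²
        equals the squared dosage correlation exactly."""
        rng = np.random.default_rng(15)
        done = 0
        while done < 5:
            hap_a = np.array([1, 1, 0, 0])
            hap_b = np.array([1, 0, 1, 0])
            h = rng.choice(4, size=60, p=rng.dirichlet([2, 2, 2, 2]))
            d1 = (2 * hap_a[h]).astype(np.int16)
            d2 = (2 * hap_b[h]).astype(np.int16)
            if not (0 < d1.mean() / 2 < 1 and 0 < d2.mean() / 2 < 1):
                continue
            res = ldstats.em_haplotype_freqs(d1, d2)
            assert res.r2 == pytest.approx(ldstats.composite_r2(d1, d2), abs=1e-10)
            done += 1

    @settings(deadline=None, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_r2_bounded_and_flip_invariant(self, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = _sample_pair(rng, n=40)
        r2 = ldstats.em_haplotype_freqs(d1, d2).r2
        assert 0.0 <= r2 <= 1.0
        flipped = ldstats.em_haplotype_freqs((2 - d1).astype(np.int16), d2).r2
        assert flipped == pytest.approx(r2, abs=1e-8)


class TestAdjacentR2:
    def test_pair_count_is_markers_minus_chromosomes(self, filtered_cohort):
        G, mmap, _ = filtered_cohort
        summ = ldstats.adjacent_r2(G, mmap)
        n_chrom = len(mmap.chromosomes)
        assert summ.n_pairs + summ.n_dropped == len(mmap) - n_chrom

    def test_perfect_ld_pair_reaches_one(self):
        rng = np.random.default_rng(17)
        a = rng.integers(0, 3, size=100).astype(np.int16)
        G = sd.GenotypeMatrix(
            dosages=np.stack([a, a], axis=1),
            individual_ids=[f"i{k}" for k in range(100)],
        )
        summ = ldstats.adjacent_r2(G, tiny_map([100, 200]))
        assert summ.pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_single_marker_chromosome_contributes_no_pairs(self):
        rng = np.random.default_rng(19)
        dos = rng.integers(0, 3, size=(50, 3)).astype(np.int16)
        G = sd.GenotypeMatrix(
            dosages=dos, individual_ids=[f"i{k}" for k in range(50)]
        )
        mmap = tiny_map([100, 200, 100], chrom=[1, 1, 2])
        summ = ldstats.adjacent_r2(G, mmap)
        assert summ.n_pairs + summ.n_dropped == 1

    def test_thinning_lowers_mean_r2(self, filtered_cohort):
        """Mean adjacent r² falls as the panel is thinned (LD decays with
        inter-marker distance)."""
        from snpladder.panels import select_equally_spaced

        G, mmap, _ = filtered_cohort
        dense = ldstats.adjacent_r2(G, mmap).mean_r2
        spec = select_equally_spaced(mmap, 80)
        sparse = ldstats.adjacent_r2(
            G.subset_markers(spec.selected_indices),
            mmap.subset(spec.selected_indices),
        ).mean_r2
        assert sparse < dense


class TestBinSummary:
    def _summary(self, r2_d):
        import pandas as pd

        pairs = pd.DataFrame(
            {
                "chromosome": 1,
                "pos1_bp": 0,
                "pos2_bp": 0,
                "d_mb": [d for _, d in r2_d],
                "r2": [r for r, _ in r2_d],
            }
        )
        return ldstats.LDSummary(pairs=pairs)

    def test_hand_aggregation(self):
        summ = self._summary([(0.1, 0.05), (0.5, 0.05), (0.2, 0.15)])
        out = ldstats.bin_summary(summ, bin_edges_mb=(0, 0.1, 0.2))
        assert out.loc[0, "mean_r2"] == pytest.approx(0.3)
        assert out.loc[0, "frac_r2_gt_0.3"] == pytest.approx(0.5)
        assert out.loc[1, "mean_r2"] == pytest.approx(0.2)
        assert out.loc[1, "frac_r2_gt_0.3"] == pytest.approx(0.0)

    def test_constant_r2_gives_full_fraction(self):
        summ = self._summary([(0.4, 0.05), (0.4, 0.3), (0.4, 2.0)])
        out = ldstats.bin_summary(summ)
        nonempty = out[out["n_pairs"] > 0]
        assert (nonempty["frac_r2_gt_0.3"] == 1.0).all()

    def test_default_edges(self):
        assert ldstats.DEFAULT_BIN_EDGES_MB == (0.0, 0.1, 0.2, 0.5, 1.0)

    def test_half_open_bins_and_overflow(self):
        summ = self._summary([(0.1, 0.1), (0.2, 1.0), (0.3, 1.5)])
        out = ldstats.bin_summary(summ)
        # d = 0.1 goes to [0.1, 0.2); d >= 1.0 goes to overflow
        assert out.loc[1, "n_pairs"] == 1
        assert out.iloc[-1]["n_pairs"] == 2

    def test_empty_bin_flagged_nan(self):
        summ = self._summary([(0.1, 0.05)])
        out = ldstats.bin_summary(summ)
        assert np.isnan(out.loc[2, "mean_r2"])

    def test_cumulative_ranges(self):
        summ = self._summary([(0.1, 0.05), (0.5, 0.15), (0.4, 0.7)])
        out = ldstats.cumulative_summary(summ, upper_edges_mb=(0.1, 1.0))
        assert out.loc[0, "mean_r2"] == pytest.approx(0.1)
        assert out.loc[1, "mean_r2"] == pytest.approx(1.0 / 3)

    def test_bad_edges_rejected(self):
        summ = self._summary([(0.1, 0.05)])
        with pytest.raises(ValueError):
            ldstats.bin_summary(summ, bin_edges_mb=(0.2, 0.1))
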