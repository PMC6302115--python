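"""Pairwise r² estimators, pair enumeration, decay binning and threshold."""

import numpy as np
import pandas as pd
import pytest

from ldpopsize.ld import (bin_ld, decay_threshold_distance, pairwise_ld,
                          r2_at_distances, r2_em, r2_genotypic,
                          adjacent_ld_summary)

from conftest import make_panel


def pearson_r2_by_hand(x, y):
    """Direct Pearson arithmetic (sums of products), independent of numpy.corrcoef."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    syy = sum(v * v for v in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = (n * sxx - sx * sx) * (n * syy - sy * sy)
    return num * num / den


def haplotype_count_r2(nAB, nAb, naB, nab):
    tot = nAB + nAb + naB + nab
    pAB, pA, pB = nAB / tot, (nAB + nAb) / tot, (nAB + naB) / tot
    D = pAB - pA * pB
    return D * D / (pA * (1 - pA) * pB * (1 - pB))


def genotypes_from_haplotype_counts(counts, rng=None):
    """Diploids built by pairing identical haplotypes (phase-unambiguous)."""
    haps = ([(1, 1)] * counts[0] + [(1, 0)] * counts[1]
            + [(0, 1)] * counts[2] + [(0, 0)] * counts[3])
    if rng is not None:
        haps = [haps[i] for i in rng.permutation(len(haps))]
    gi = [haps[2 * k][0] + haps[2 * k + 1][0] for k in range(len(haps) // 2)]
    gj = [haps[2 * k][1] + haps[2 * k + 1][1] for k in range(len(haps) // 2)]
    return gi, gj


class TestR2Genotypic:
    def test_identical_vectors(self):
        assert r2_genotypic([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_sign_invariance(self):
        assert r2_genotypic([0, 0, 2, 2], [2, 2, 0, 0]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 3, 25)
        y = np.clip(x + rng.integers(-1, 2, 25), 0, 2)
        if np.ptp(y) == 0:
            return
        assert r2_genotypic(x, y) == pytest.approx(
            pearson_r2_by_hand(list(x), list(y)), rel=1e-12)

    def test_pairwise_complete_missing_handling(self):
        x = [0, 1, 2, -1, 2]
        y = [0, 1, 2, 2, -1]
        assert r2_genotypic(x, y) == pytest.approx(1.0)

    def test_monomorphic_raises(self):
        with pytest.raises(ValueError, match="monomorphic"):
            r2_genotypic([1, 1, 1, 1], [0, 1, 2, 0])

    def test_allele_relabeling_invariance(self, rng):
        x = rng.integers(0, 3, 40)
        y = np.clip(x + rng.integers(-1, 2, 40), 0, 2)
        assert r2_genotypic(x, y) == pytest.approx(r2_genotypic(2 - x, y))


class TestR2Em:
    def test_worked_haplotype_example(self):
        # 40 AB / 10 Ab / 10 aB / 40 ab: D = 0.4 - 0.25 = 0.15, r2 = 0.36
        gi, gj = genotypes_from_haplotype_counts((40, 10, 10, 40))
        assert r2_em(gi, gj) == pytest.approx(0.36, abs=1e-9)

    def test_complete_ld(self):
        gi, gj = genotypes_from_haplotype_counts((60, 0, 0, 40))
        assert r2_em(gi, gj) == pytest.approx(1.0)

    def test_independent_loci(self):
        # haplotype freqs equal products of allele freqs -> D = 0
        gi, gj = genotypes_from_haplotype_counts((25, 25, 25, 25))
        assert r2_em(gi, gj) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("counts", [(40, 10, 10, 40), (50, 30, 10, 10),
                                        (70, 10, 15, 5), (30, 30, 20, 20)])
    def test_equals_haplotype_count_r2_without_double_hets(self, counts):
        gi, gj = genotypes_from_haplotype_counts(counts)
        assert r2_em(gi, gj) == pytest.approx(haplotype_count_r2(*counts), abs=1e-8)

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        gi, gj = genotypes_from_haplotype_counts((40, 25, 20, 15), rng)
        gi = np.asarray(gi)
        assert r2_em(gi, gj) == pytest.approx(r2_em(2 - gi, gj), abs=1e-9)

    def test_scrambled_phase_recovers_haplotypic_r2(self):
        """EM on phase-scrambled genotypes tracks the true haplotypic r².

        Haplotype pools with random frequencies are sampled for n = 200
        diploids; pairing haplotypes at random destroys phase, and the EM
        estimate is compared with the r² of the known haplotype counts.
        """
        rng = np.random.default_rng(11)
        errs = []
        trials = 0
        while trials < 300:
            f = rng.dirichlet([1, 1, 1, 1])
            n_hap = 400
            counts = rng.multinomial(n_hap, f)
            pA = (counts[0] + counts[1]) / n_hap
            pB = (counts[0] + counts[2]) / n_hap
            if min(pA, 1 - pA, pB, 1 - pB) < 0.1:
                continue
            trials += 1
            truth = haplotype_count_r2(*counts)
            gi, gj = genotypes_from_haplotype_counts(counts, rng)
            errs.append(abs(r2_em(gi, gj) - truth))
        assert np.mean(errs) < 0.02


class TestPairwiseLd:
    def test_three_markers_give_three_pairs(self, rng):
        d = rng.integers(0, 3, size=(30, 3)).astype(np.int8)
        pairs = pairwise_ld(make_panel(d), 10_000_000)
        assert len(pairs) == 3

    def test_cross_chromosome_pairs_excluded(self, rng):
        d = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        pairs = pairwise_ld(make_panel(d, chroms=["1", "2"]), 10_000_000)
        assert len(pairs) == 0

    def test_distance_cutoff(self, rng):
        d = rng.integers(0, 3, size=(30, 3)).astype(np.int8)
        panel = make_panel(d, positions=[1_000, 40_000, 2_000_000])
        pairs = pairwise_ld(panel, 100_000)
        assert len(pairs) == 1
        assert pairs["distance_bp"].iloc[0] == 39_000

    def test_matches_per_pair_brute_force(self, random_panel):
        pairs = pairwise_ld(random_panel, 10_000_000)
        mm = random_panel.markers
        expected = {}
        for i in range(len(mm)):
            for j in range(i + 1, len(mm)):
                if mm.chromosome[i] != mm.chromosome[j]:
                    continue
                try:
                    expected[(i, j)] = r2_genotypic(random_panel.dosages[:, i],
                                                    random_panel.dosages[:, j])
                except ValueError:
                    pass
        got = {(r.idx_i, r.idx_j): r.r2 for r in pairs.itertuples()}
        assert set(got) == set(expected)
        for k in expected:
            assert got[k] == pytest.approx(expected[k], rel=1e-10)

    def test_em_estimator_path(self, rng):
        d = rng.integers(0, 3, size=(40, 5)).astype(np.int8)
        pairs = pairwise_ld(make_panel(d), 10_000_000, estimator="em")
        for row in pairs.itertuples():
            assert row.r2 == pytest.approx(
                r2_em(d[:, row.idx_i], d[:, row.idx_j]), abs=1e-9)


def pairs_frame(distances, r2s, idx_i=None, idx_j=None, chrom="1"):
    n = len(distances)
    return pd.DataFrame({
        "chromosome": [chrom] * n,
        "idx_i": idx_i if idx_i is not None else np.arange(n),
        "idx_j": idx_j if idx_j is not None else np.arange(n) + 1,
        "marker_i": [f"m{i}" for i in range(n)],
        "marker_j": [f"m{i+1}" for i in range(n)],
        "distance_bp": distances,
        "r2": r2s,
        "n_used": [50] * n,
    })


class TestBinLd:
    def test_simple_two_bins(self):
        curve = bin_ld(pairs_frame([10_000, 150_000], [0.5, 0.1]))
        t = curve.nonempty()
        assert list(t["mean_r2"]) == [0.5, 0.1]
        assert list(t["bin_start"]) == [0, 100_000]

    def test_pair_count_conservation(self, rng):
        d = rng.integers(1, 10_000_000, 1000)
        curve = bin_ld(pairs_frame(d, rng.random(1000)))
        assert curve.table["n_pairs"].sum() == 1000

    def test_matches_grouped_brute_force(self, rng):
        d = rng.integers(1, 10_000_000, 1000)
        r2 = rng.random(1000)
        curve = bin_ld(pairs_frame(d, r2))
        df = pd.DataFrame({"d": d, "r2": r2})
        df["bin"] = np.minimum(df["d"] // 100_000, 99)
        grouped = df.groupby("bin")["r2"].mean()
        for b, mean in grouped.items():
            assert curve.table["mean_r2"].iloc[int(b)] == pytest.approx(mean)

    def test_r2_at_distances_reads_containing_bin(self, rng):
        d = rng.integers(1, 10_000_000, 500)
        curve = bin_ld(pairs_frame(d, rng.random(500)))
        tab = r2_at_distances(curve, [100_000, 1_000_000])
        assert tab["mean_r2"].iloc[0] == pytest.approx(curve.table["mean_r2"].iloc[1])
        assert tab["mean_r2"].iloc[1] == pytest.approx(curve.table["mean_r2"].iloc[10])


class TestDecayThreshold:
    def test_linear_interpolation(self):
        curve = bin_ld(pairs_frame([50_000, 150_000], [0.25, 0.15]))
        assert decay_threshold_distance(curve, 0.2) == pytest.approx(100_000)

    def test_curve_starting_below_threshold_is_undefined(self):
        curve = bin_ld(pairs_frame([50_000, 150_000], [0.1, 0.05]))
        assert decay_threshold_distance(curve, 0.2) is None

    def test_never_crossing_is_undefined(self):
        curve = bin_ld(pairs_frame([50_000, 150_000], [0.6, 0.5]))
        assert decay_threshold_distance(curve, 0.2) is None


class TestAdjacentSummary:
    def test_mean_of_adjacent_pairs_only(self):
        # adjacent pairs (0,1) and (1,2) with r2 0.2/0.4; (0,2) must be ignored
        pairs = pd.concat([
            pairs_frame([10_000], [0.2], idx_i=[0], idx_j=[1]),
            pairs_frame([10_000], [0.4], idx_i=[1], idx_j=[2]),
            pairs_frame([20_000], [0.9], idx_i=[0], idx_j=[2]),
        ], ignore_index=True)
        mm = make_panel(np.zeros((1, 3), dtype=np.int8)).markers
        out = adjacent_ld_summary(pairs, mm)
        genome = out[out["chromosome"] == "genome"].iloc[0]
        assert genome["mean_r2"] == pytest.approx(0.3)
        assert genome["n_pairs"] == 2

    def test_single_chromosome_genome_equals_chromosome(self, rng):
        d = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        panel = make_panel(d)
        pairs = pairwise_ld(panel, 10_000_000)
        out = adjacent_ld_summary(pairs, panel.markers)
        c1 = out[out["chromosome"] == "1"].iloc[0]
        genome = out[out["chromosome"] == "genome"].iloc[0]
        assert c1["mean_r2"] == pytest.approx(genome["mean_r2"])
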