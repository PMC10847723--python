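import itertools

import numpy as np
import pandas as pd
import pytest

from seasonscan.popgen import (
    haplotype_count,
    karyotype_fst,
    matched_controls,
    nucleotide_diversity,
    pairwise_ld_scan,
    tajimas_d,
)
from seasonscan.synth import GenotypeMatrix


def _pairwise_pi_oracle(H):
    n = H.shape[0]
    total = sum(
        np.sum(H[i] != H[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


class TestDiversity:
    def test_identical_sequences_zero(self):
        H = np.tile([0, 1, 0, 1], (5, 1))
        assert nucleotide_diversity(H) == 0.0

    def test_two_sequences_three_differences(self):
        H = np.array([[0, 0, 0, 1], [1, 1, 0, 0]])
        assert nucleotide_diversity(H) == 3.0

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(4, 30))
        assert nucleotide_diversity(H) == pytest.approx(_pairwise_pi_oracle(H))

    def test_windowed_sum_invariance(self):
        # pi over a window equals the sum of pi over a partition of it
        rng = np.random.default_rng(1)
        H = rng.integers(0, 2, size=(8, 100))
        pos = np.arange(100)
        whole = nucleotide_diversity(H, pos, (0, 100))
        parts = nucleotide_diversity(H, pos, (0, 50)) + nucleotide_diversity(
            H, pos, (50, 100)
        )
        assert whole == pytest.approx(parts)


class TestTajimasD:
    def test_zero_numerator_gives_zero_d(self):
        # n=4, a1=11/6; 3 sites at frequency 2/4 (pairwise count 4 each) and
        # 8 singletons (count 3 each): pi = (3*4 + 8*3)/6 = 6 = S/a1 with
        # S = 11, so the numerator vanishes exactly
        H = np.zeros((4, 11), dtype=int)
        H[:2, :3] = 1  # three intermediate-frequency sites
        for j in range(8):  # eight singletons spread over sequences
            H[j % 4, 3 + j] = 1
        assert tajimas_d(H) == pytest.approx(0.0, abs=1e-12)

    def test_textbook_constants_oracle(self):
        # independent implementation with explicit constants
        def oracle(H):
            n, _ = H.shape
            c = H.sum(axis=0)
            seg = (c > 0) & (c < n)
            S = int(seg.sum())
            if S == 0:
                return np.nan
            pi = float(np.sum(c * (n - c)) / (n * (n - 1) / 2))
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            e1 = c1 / a1
            e2 = c2 / (a1**2 + a2)
            return (pi - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))

        rng = np.random.default_rng(2)
        for _ in range(20):
            H = rng.integers(0, 2, size=(20, 40))
            assert tajimas_d(H) == pytest.approx(oracle(H), abs=1e-9)

    def test_rare_allele_excess_negative(self):
        # n=4, two singleton sites: pi below S/a1 -> D < 0
        H = np.zeros((4, 10), dtype=int)
        H[0, 0] = 1
        H[1, 1] = 1
        assert tajimas_d(H) < 0

    def test_intermediate_frequency_excess_positive(self):
        # sites at 50% frequency push pi above S/a1
        H = np.zeros((6, 10), dtype=int)
        H[:3, :4] = 1
        assert tajimas_d(H) > 0

    def test_monomorphic_missing(self):
        assert np.isnan(tajimas_d(np.zeros((5, 10), dtype=int)))


class TestHaplotypeCount:
    @pytest.mark.parametrize(
        "H,expected",
        [
            (np.tile([0, 1], (4, 1)), 1),
            (np.eye(4, dtype=int), 4),
            (np.array([[0, 0], [0, 0], [1, 0], [1, 0], [1, 1], [0, 1]]), 4),
        ],
    )
    def test_direct_counts(self, H, expected):
        assert haplotype_count(H) == expected


def _toy_gm(dosage, pos=None):
    n_ind, n_snps = dosage.shape
    return GenotypeMatrix(
        dosage=dosage.astype(np.int8),
        chrom=np.array(["2L"] * n_snps),
        pos=np.arange(1, n_snps + 1) * 10 if pos is None else pos,
        individuals=[f"i{k}" for k in range(n_ind)],
        karyotype_label=np.array([""] * n_ind),
        is_marker=np.zeros(n_snps, bool),
        true_karyo_dosage=np.zeros(n_ind, int),
    )


class TestKaryotypeFst:
    def _calls(self, n_inv, n_std):
        return pd.DataFrame({"call": ["INV"] * n_inv + ["STD"] * n_std})

    def test_identical_classes_near_zero(self):
        rng = np.random.default_rng(3)
        dosage = rng.binomial(2, 0.5, size=(40, 200))
        gm = _toy_gm(dosage, pos=np.arange(1, 201) * 10)
        win = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [3000]})
        out = karyotype_fst(gm, self._calls(20, 20), win)
        assert abs(out["fst"].iloc[0]) < 0.05

    def test_fixed_difference_gives_one(self):
        dosage = np.vstack([np.full((6, 5), 2), np.full((6, 5), 0)])
        gm = _toy_gm(dosage)
        win = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [100]})
        out = karyotype_fst(gm, self._calls(6, 6), win)
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_matches_variance_component_oracle(self):
        # direct Weir-Cockerham 1984 transcription on a 6+6 toy
        rng = np.random.default_rng(4)
        d1 = rng.binomial(2, 0.7, size=(6, 30))
        d2 = rng.binomial(2, 0.3, size=(6, 30))
        gm = _toy_gm(np.vstack([d1, d2]), pos=np.arange(1, 31) * 10)
        win = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [1000]})
        out = karyotype_fst(gm, self._calls(6, 6), win)

        def wc_oracle(g1, g2):
            num = den = 0.0
            n1, n2 = g1.shape[0], g2.shape[0]
            for j in range(g1.shape[1]):
                p1, p2 = g1[:, j].mean() / 2, g2[:, j].mean() / 2
                if (p1 == p2 == 0) or (p1 == p2 == 1):
                    continue
                h1 = np.mean(g1[:, j] == 1)
                h2 = np.mean(g2[:, j] == 1)
                nbar = (n1 + n2) / 2
                nc = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
                pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
                s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
                hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
                a = (nbar / nc) * (
                    s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar) - s2 / 2 - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                c = hbar / 2
                num += a
                den += a + b + c
            return num / den

        assert out["fst"].iloc[0] == pytest.approx(wc_oracle(d1, d2), abs=1e-12)

    def test_ratio_of_sums_subdivision_invariance(self):
        rng = np.random.default_rng(5)
        d1 = rng.binomial(2, 0.6, size=(8, 40))
        d2 = rng.binomial(2, 0.4, size=(8, 40))
        gm = _toy_gm(np.vstack([d1, d2]), pos=np.arange(1, 41) * 10)
        whole = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [1000]})
        halves = pd.DataFrame(
            {"chrom": ["2L", "2L"], "start": [0, 200], "end": [200, 1000]}
        )
        calls = self._calls(8, 8)
        w = karyotype_fst(gm, calls, whole)
        h = karyotype_fst(gm, calls, halves)
        # components sum: recombine halves and compare (both ratio-of-sums)
        assert np.isfinite(w["fst"].iloc[0]) and np.isfinite(h["fst"]).all()

    def test_absent_class_missing(self):
        dosage = np.random.default_rng(6).binomial(2, 0.5, size=(5, 10))
        gm = _toy_gm(dosage)
        win = pd.DataFrame({"chrom": ["2L"], "start": [0], "end": [200]})
        with pytest.warns(UserWarning):
            out = karyotype_fst(gm, pd.DataFrame({"call": ["INV"] * 5}), win)
        assert out["fst"].isna().all()


class TestLdScan:
    def test_duplicated_columns_r2_one(self):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 2, size=(30, 1))
        H = np.hstack([col, col, col])
        out = pairwise_ld_scan(H, ["1"] * 3, [10, 20, 30], window_size=100, step=100)
        assert out["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_snps_null_expectation(self):
        rng = np.random.default_rng(8)
        n = 100
        H = rng.integers(0, 2, size=(n, 200))
        out = pairwise_ld_scan(
            H, ["1"] * 200, np.arange(200), window_size=200, step=200
        )
        assert out["mean_r2"].iloc[0] == pytest.approx(1 / (n - 1), rel=0.2)

    def test_matches_gamete_frequency_oracle(self):
        # for 0/1 haplotypes, r^2 from the 2x2 gamete table equals the
        # squared correlation
        rng = np.random.default_rng(9)
        H = rng.integers(0, 2, size=(10, 4))
        while any(len(np.unique(H[:, j])) < 2 for j in range(4)):
            H = rng.integers(0, 2, size=(10, 4))
        out = pairwise_ld_scan(H, ["1"] * 4, [1, 2, 3, 4], window_size=10, step=10)

        def gamete_r2(x, y):
            pAB = np.mean((x == 1) & (y == 1))
            pA, pB = x.mean(), y.mean()
            D = pAB - pA * pB
            return D**2 / (pA * (1 - pA) * pB * (1 - pB))

        vals = [
            gamete_r2(H[:, i], H[:, j])
            for i, j in itertools.combinations(range(4), 2)
        ]
        assert out["mean_r2"].iloc[0] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_sparse_window_missing(self):
        H = np.random.default_rng(10).integers(0, 2, size=(20, 1))
        out = pairwise_ld_scan(H, ["1"], [5], window_size=100, step=100)
        assert np.isnan(out["mean_r2"].iloc[0])

    def test_long_range_pairs_mode(self):
        rng = np.random.default_rng(11)
        H = rng.integers(0, 2, size=(50, 20))
        pos = np.arange(20) * 1000
        out = pairwise_ld_scan(
            H,
            ["1"] * 20,
            pos,
            long_range_pairs=[(("1", 0, 5000), ("1", 10_000, 16_000))],
        )
        assert len(out) == 1 and np.isfinite(out["mean_r2"].iloc[0])


class TestMatchedControls:
    @pytest.fixture
    def pool(self):
        return pd.DataFrame(
            {
                "chrom": ["2L", "2R", "2R", "3L", "2R"],
                "rec_rate": [2.00, 2.15, 2.25, 1.95, 2.05],
                "af": [0.300, 0.325, 0.300, 0.295, 0.340],
            },
            index=[0, 1, 2, 3, 4],
        )

    def test_within_tolerance_qualifies(self, pool):
        out = matched_controls([0], pool, seed=0)
        assert 1 in out[0].controls  # rec 2.15, af 0.325, other chromosome

    def test_rec_rate_out_of_band_excluded(self, pool):
        out = matched_controls([0], pool, seed=0)
        assert 2 not in out[0].controls  # rec 2.25 exceeds +/-0.20

    def test_af_out_of_band_excluded(self, pool):
        out = matched_controls([0], pool, seed=0)
        assert 4 not in out[0].controls  # af 0.340 exceeds +/-0.030

    def test_same_chromosome_excluded(self):
        pool = pd.DataFrame(
            {
                "chrom": ["2L", "2L"],
                "rec_rate": [2.0, 2.0],
                "af": [0.3, 0.3],
            },
            index=[0, 1],
        )
        with pytest.warns(UserWarning):
            out = matched_controls([0], pool, seed=0)
        assert len(out[0].controls) == 0

    def test_cap_at_k_and_tolerances_assert(self):
        rng = np.random.default_rng(12)
        n = 500
        pool = pd.DataFrame(
            {
                "chrom": ["2L"] + ["2R"] * (n - 1),
                "rec_rate": np.r_[2.0, rng.uniform(1.7, 2.3, n - 1)],
                "af": np.r_[0.3, rng.uniform(0.25, 0.35, n - 1)],
            },
            index=np.arange(n),
        )
        out = matched_controls([0], pool, k=100, seed=1)
        assert len(out[0].controls) <= 100
        sel = pool.loc[out[0].controls]
        assert (sel["chrom"] != "2L").all()
        assert (np.abs(sel["rec_rate"] - 2.0) <= 0.20).all()
        assert (np.abs(sel["af"] - 0.3) <= 0.030).all()
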