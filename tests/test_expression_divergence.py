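"""Expression divergence: PCC, percentile co-expression calls, NG86 Ka/Ks
vs brute-force oracle, Ks binning and rank tests."""

import math

import numpy as np
import pandas as pd
import pytest

from bahdscape.expression_divergence import (
    ExpressionMatrix,
    ParalogPair,
    align_codons,
    bin_and_test,
    call_coexpression,
    codon_sites,
    ks_bin_label,
    ng86_ka_ks,
    pairwise_pcc,
)
from bahdscape.synthetic_data import SimConfig, simulate_paralog_pair
from _oracles import bh_adjust, kruskal_h, ks_statistic, ng86_brute

_NONSTOP = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
            if a + b + c not in ("TAA", "TAG", "TGA")]


def random_cds(rng, n_codons):
    return "".join(_NONSTOP[i]
                   for i in rng.integers(0, len(_NONSTOP), n_codons))


def matrix_from(values, genes=None):
    values = np.asarray(values, float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestPairwisePcc:
    def test_exact_linear_and_antilinear(self):
        pcc = pairwise_pcc(matrix_from([[1, 2, 3], [2, 4, 6], [3, 2, 1]]))
        assert pcc.iloc[0, 1] == pytest.approx(1.0)
        assert pcc.iloc[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(pcc), 1.0)

    def test_hand_evaluated_pearson(self):
        pcc = pairwise_pcc(matrix_from([[1, 2, 3], [1, 3, 2]]))
        assert pcc.iloc[0, 1] == pytest.approx(0.5)

    def test_zero_variance_row_gives_na(self):
        pcc = pairwise_pcc(matrix_from([[1, 2, 3], [5, 5, 5]]))
        assert math.isnan(pcc.iloc[0, 1])
        assert pcc.iloc[0, 0] == 1.0

    def test_fewer_than_three_samples_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            pairwise_pcc(matrix_from([[1, 2], [2, 1]]))

    def test_symmetric(self, rng):
        pcc = pairwise_pcc(matrix_from(rng.standard_normal((8, 12))))
        assert np.allclose(pcc.values, pcc.values.T)


class TestCallCoexpression:
    @staticmethod
    def matrix_with_pair_pccs(values):
        # fabricate a symmetric matrix whose upper triangle holds exactly
        # the given pair values, padding with NaN (excluded pairs)
        n = 2
        while n * (n - 1) // 2 < len(values):
            n += 1
        arr = np.full((n, n), np.nan)
        np.fill_diagonal(arr, 1.0)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                if k < len(values):
                    arr[i, j] = arr[j, i] = values[k]
                k += 1
        return pd.DataFrame(arr, index=[f"g{i:02d}" for i in range(n)],
                            columns=[f"g{i:02d}" for i in range(n)])

    def test_interpolated_percentile_and_strict_flags(self):
        values = [round(0.01 * k, 2) for k in range(1, 101)]
        calls = call_coexpression(self.matrix_with_pair_pccs(values))
        assert calls.positive_threshold == pytest.approx(
            np.percentile(values, 95))
        flagged = {p for p in calls.positive_pairs}
        expected_n = sum(1 for v in values if v > calls.positive_threshold)
        assert len(flagged) == expected_n

    def test_degenerate_identical_pccs(self):
        values = [0.5] * 45
        calls = call_coexpression(self.matrix_with_pair_pccs(values))
        assert calls.positive_threshold == calls.negative_threshold
        assert calls.positive_pairs == [] and calls.negative_pairs == []

    def test_order_invariance(self, rng):
        mat = matrix_from(rng.standard_normal((10, 15)))
        pcc = pairwise_pcc(mat)
        perm = rng.permutation(10)
        shuffled = ExpressionMatrix(
            [mat.gene_ids[i] for i in perm], mat.sample_ids,
            mat.values[perm])
        calls_a = call_coexpression(pcc)
        calls_b = call_coexpression(pairwise_pcc(shuffled))
        assert set(calls_a.positive_pairs) == set(calls_b.positive_pairs)
        assert set(calls_a.negative_pairs) == set(calls_b.negative_pairs)


class TestNg86:
    def test_identical_pair_zero(self):
        res = ng86_ka_ks("ATGAAACCC", "ATGAAACCC")
        assert res.ka == 0.0 and res.ks == 0.0
        assert math.isnan(res.ka_ks)

    def test_saturated_single_codon(self):
        # GGN is all glycine: S=1 per codon, one synonymous difference
        res = ng86_ka_ks("GGG", "GGA")
        assert math.isnan(res.ks) and res.saturated_s
        assert res.s_sites == pytest.approx(1.0)

    def test_counts_match_brute_force_oracle(self, rng):
        for _ in range(30):
            a = random_cds(rng, 30)
            b = random_cds(rng, 30)
            # gap-free comparison: same-length CDS with an identity
            # protein alignment so codons pair positionally
            n = len(a) // 3
            ident = ("M" * n, "M" * n)  # placeholder equal-length rows
            res = ng86_ka_ks(a, b, protein_alignment=ident)
            S, N, Sd, Nd = ng86_brute(
                [a[i:i + 3] for i in range(0, len(a), 3)],
                [b[i:i + 3] for i in range(0, len(b), 3)])
            assert res.s_sites == pytest.approx(S, abs=1e-9)
            assert res.n_sites == pytest.approx(N, abs=1e-9)
            assert res.s_diffs == pytest.approx(Sd, abs=1e-9)
            assert res.n_diffs == pytest.approx(Nd, abs=1e-9)

    def test_symmetry_is_exact(self, rng):
        for _ in range(10):
            a = random_cds(rng, 40)
            b = random_cds(rng, 40)
            n = len(a) // 3
            ident = ("M" * n, "M" * n)
            r1 = ng86_ka_ks(a, b, ident)
            r2 = ng86_ka_ks(b, a, ident)

            def same(x, y):
                return x == y or (math.isnan(x) and math.isnan(y))

            assert same(r1.ka, r2.ka) and same(r1.ks, r2.ks)
            assert r1.s_sites == r2.s_sites
            assert r1.s_diffs == r2.s_diffs

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_ka_ks("ATGTAAAAA", "ATGAAAAAA")

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            ng86_ka_ks("ATGA", "ATGC")

    def test_gap_columns_dropped(self):
        # alignment M-K vs MQK: middle column gapped, dropped pairwise
        res = ng86_ka_ks("ATGAAA", "ATGCAAAAA",
                         protein_alignment=("M-K", "MQK"))
        assert res.s_sites + res.n_sites == pytest.approx(6.0)
        assert res.ka == 0.0 and res.ks == 0.0

    def test_generator_truth_recovered(self, rng):
        cfg = SimConfig(seed=5)
        for target in (0.1, 0.3):
            a, b, true_ks, _ = simulate_paralog_pair(cfg, target, 300, rng)
            res = ng86_ka_ks(a, b)
            assert res.ks == pytest.approx(true_ks, rel=0.25)


def make_pair(i, pcc, ks):
    return ParalogPair(gene_a=f"a{i:03d}", gene_b=f"b{i:03d}", pcc=pcc,
                       ka=0.1 * ks, ks=ks, ka_ks=0.1, ks_bin=ks_bin_label(ks))


class TestBinAndTest:
    def test_bin_labels_half_open(self):
        assert ks_bin_label(0.0) == "[0.0, 0.2)"
        assert ks_bin_label(0.2) == "[0.2, 0.4)"
        assert ks_bin_label(0.19999) == "[0.0, 0.2)"
        assert ks_bin_label(float("nan")) == "NA"

    def test_kruskal_matches_rank_formula(self):
        pairs = [make_pair(i, v, ks)
                 for i, (v, ks) in enumerate(
                     [(1, 0.1), (2, 0.1), (3, 0.1),
                      (4, 0.5), (5, 0.5), (6, 0.5)])]
        summary = bin_and_test(pairs)
        assert summary.kruskal_wallis_H == pytest.approx(
            kruskal_h([[1, 2, 3], [4, 5, 6]]))

    def test_identical_samples_ks_zero(self):
        pcc = [0.1, 0.2, 0.3]
        pairs = [make_pair(i, v, 0.1) for i, v in enumerate(pcc)]
        pairs += [make_pair(i + 10, v, 0.3) for i, v in enumerate(pcc)]
        summary = bin_and_test(pairs)
        row = summary.pairwise_ks.iloc[0]
        assert row.D == 0.0 and row.p_value == 1.0

    def test_ks_statistic_matches_ecdf_oracle(self, rng):
        x = list(rng.standard_normal(12))
        y = list(rng.standard_normal(15) + 0.5)
        pairs = [make_pair(i, v, 0.1) for i, v in enumerate(x)]
        pairs += [make_pair(100 + i, v, 0.5) for i, v in enumerate(y)]
        summary = bin_and_test(pairs)
        row = summary.pairwise_ks.iloc[0]
        assert row.D == pytest.approx(ks_statistic(x, y), abs=1e-12)

    def test_bh_adjustment_matches_step_up(self):
        # three bins engineered to give three pairwise tests
        rng = np.random.default_rng(3)
        pairs = []
        for k, loc in ((0.1, 0.0), (0.3, 1.0), (0.5, 2.0)):
            for i in range(8):
                pairs.append(make_pair(len(pairs),
                                       float(rng.normal(loc, 0.3)), k))
        summary = bin_and_test(pairs)
        raw = list(summary.pairwise_ks.p_value)
        assert list(summary.pairwise_ks.p_adjusted) == pytest.approx(
            bh_adjust(raw))

    def test_saturated_pairs_excluded_from_fit(self):
        pairs = [make_pair(i, 0.1 * i, 0.1 + 0.05 * i) for i in range(6)]
        pairs.append(ParalogPair(gene_a="x1", gene_b="x2", pcc=0.9,
                                 ka=0.1, ks=float("nan"),
                                 ka_ks=float("nan"), ks_bin="NA"))
        summary = bin_and_test(pairs)
        assert not math.isnan(summary.slope)
        assert "NA" not in summary.pairwise_ks.bin_a.tolist()

    def test_single_bin_skips_rank_tests(self):
        pairs = [make_pair(i, 0.1 * i, 0.02 + 0.03 * i) for i in range(5)]
        summary = bin_and_test(pairs)
        assert math.isnan(summary.kruskal_wallis_H)
        assert summary.pairwise_ks.empty
        assert not math.isnan(summary.r_squared)
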