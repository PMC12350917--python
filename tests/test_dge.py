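"""DGE statistics: LG2FC, variance-gated t-tests, BH, classification, ORA."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from palateseq.dge import (
    DGEConfig,
    benjamini_hochberg,
    classify_deg,
    log2_fold_change,
    log2p1_transform,
    over_representation,
    read_gene_sets,
    run_dge,
    variance_gated_t_test,
    volcano_table,
)
from palateseq.roi import DensityMatrix


# ---------------------------------------------------------------------------
# independent oracles


def ttest_oracle(a, b, f_alpha=0.05):
    """Textbook-formula F gate + Student/Welch t-test, coded from scratch."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    if va >= vb:
        fstat, dfn, dfd = va / vb, na - 1, nb - 1
    else:
        fstat, dfn, dfd = vb / va, nb - 1, na - 1
    f_p = min(1.0, 2.0 * (1.0 - stats.f.cdf(fstat, dfn, dfd)))
    if f_p < f_alpha:
        # Welch with Welch–Satterthwaite df
        se2 = va / na + vb / nb
        t = (a.mean() - b.mean()) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        branch = "welch"
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
        branch = "student"
    p = 2.0 * stats.t.sf(abs(t), df)
    return f_p, branch, t, p


def bh_oracle(p):
    """Step-up adjustment by direct evaluation of min_{j>=i} (m/j) p_(j)."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        adj[idx] = min(
            min(m / rank_j * p[order[rank_j - 1]] for rank_j in range(rank_i, m + 1)),
            1.0,
        )
    return adj


def hypergeom_tail_oracle(M, K, N, k):
    """P(X >= k) for X ~ Hypergeom(M, K, N) by exact rational arithmetic."""
    total = Fraction(0)
    for j in range(k, min(K, N) + 1):
        total += Fraction(math.comb(K, j) * math.comb(M - K, N - j), math.comb(M, N))
    return float(total)


def density_matrix(values, genes, group, area=6400.0):
    counts = pd.DataFrame(np.asarray(values), columns=genes)
    counts.index = pd.Index([f"{group}{i}" for i in range(len(counts))], name="roi_id")
    meta = pd.DataFrame(
        {"shelf": "PL", "domain": "NP", "area_um2": area}, index=counts.index
    )
    return DensityMatrix(counts=counts, meta=meta, group=group)


# ---------------------------------------------------------------------------


class TestLog2FoldChange:
    def test_ratio_of_two_is_one(self):
        assert log2_fold_change(0.02, 0.01, 0.0) == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        assert log2_fold_change(0.015, 0.015, 0.0) == 0.0

    def test_zero_numerator_with_default_pseudocount(self):
        # log2((0 + 1/6400) / (0.01 + 1/6400)) = log2(1/65) ≈ −6.0224
        got = log2_fold_change(0.0, 0.01, 1.0 / 6400.0)
        assert got == pytest.approx(math.log2(0.00015625 / 0.01015625), abs=1e-12)
        assert got == pytest.approx(-6.0224, abs=5e-4)

    def test_zero_denominator_without_pseudocount_errors(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log2_fold_change(0.01, 0.0, 0.0)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-0.01, 0.01)


class TestLog2p1:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (7.0, 3.0)])
    def test_known_values(self, x, expected):
        assert log2p1_transform([x])[0] == pytest.approx(expected)

    def test_monotone(self):
        x = np.linspace(0, 10, 50)
        assert (np.diff(log2p1_transform(x)) > 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2p1_transform([-0.1])


class TestVarianceGatedTTest:
    def test_identical_groups(self):
        res = variance_gated_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.branch == "student"
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_all_zero_is_degenerate(self):
        res = variance_gated_t_test([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        assert res.degenerate and res.p == 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            variance_gated_t_test([1.0], [1.0, 2.0])

    def test_unequal_variances_take_welch_branch(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 10, 6)
        b = rng.normal(0, 1, 6)
        res = variance_gated_t_test(a, b)
        f_p, branch, t, p = ttest_oracle(a, b)
        assert res.branch == branch == "welch"
        assert res.variance_p == pytest.approx(f_p, abs=1e-10)
        assert res.t == pytest.approx(t, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_textbook_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            na, nb = rng.integers(3, 12, 2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 5), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 5), nb)
            res = variance_gated_t_test(a, b)
            f_p, branch, t, p = ttest_oracle(a, b)
            assert res.branch == branch
            assert abs(res.variance_p - f_p) < 1e-10
            assert abs(res.t - t) < 1e-10
            assert abs(res.p - p) < 1e-10

    def test_equal_variance_equal_n_branches_agree(self):
        # when sample variances are exactly equal and n equal, Welch's t and
        # df coincide with Student's, so both branches give identical results
        a = np.array([1.0, 2.0, 4.0, 7.0])
        b = a + 3.0  # identical variance by construction
        s_t, s_p = stats.ttest_ind(a, b, equal_var=True)
        w_t, w_p = stats.ttest_ind(a, b, equal_var=False)
        assert s_t == pytest.approx(w_t, abs=1e-12)
        assert s_p == pytest.approx(w_p, abs=1e-12)
        res = variance_gated_t_test(a, b)
        assert res.t == pytest.approx(s_t, abs=1e-12)


class TestBenjaminiHochberg:
    def test_hand_enumerated_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert benjamini_hochberg([0.031])[0] == pytest.approx(0.031)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_oracle_and_monotone(self, p):
        adj = benjamini_hochberg(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 100))
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(benjamini_hochberg(p), adj, atol=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "lfc,p,expected",
        [
            (8.369539, 0.008112, "up"),  # reported Tnn whole-shelf pair
            (7.12479, 0.00019, "up"),  # reported Fmod oral-domain pair
            (0.5, 0.001, "ns"),
            (-2.0, 0.01, "down"),
            (2.0, 0.2, "ns"),
            (1.0, 0.001, "ns"),  # threshold is strict
        ],
    )
    def test_volcano_rules(self, lfc, p, expected):
        assert classify_deg(lfc, p) == expected


class TestRunDGE:
    def test_identical_matrices_all_ns(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(50, (6, 5))
        a = density_matrix(counts, list("abcde"), "A")
        b = density_matrix(counts, list("abcde"), "B")
        res = run_dge(a, b)
        assert (res["lfc"] == 0).all()
        assert (res["class"] == "ns").all()

    def test_gene_mismatch_lists_difference(self):
        a = density_matrix([[1, 2], [3, 4]], ["x", "y"], "A")
        b = density_matrix([[1, 2], [3, 4]], ["x", "z"], "B")
        with pytest.raises(ValueError, match="'y', 'z'"):
            run_dge(a, b)

    def test_decomposes_into_individual_operations(self):
        rng = np.random.default_rng(2)
        cfg = DGEConfig()
        ca = rng.poisson(40, (6, 8))
        cb = rng.poisson(60, (6, 8))
        genes = [f"g{i}" for i in range(8)]
        a = density_matrix(ca, genes, "A")
        b = density_matrix(cb, genes, "B")
        res = run_dge(a, b, cfg).set_index("gene")
        praw = {}
        for i, g in enumerate(genes):
            xa = ca[:, i] / 6400.0
            xb = cb[:, i] / 6400.0
            assert res.loc[g, "lfc"] == pytest.approx(
                log2_fold_change(xa.mean(), xb.mean(), cfg.pseudocount)
            )
            t = variance_gated_t_test(
                log2p1_transform(xa), log2p1_transform(xb), cfg.f_alpha
            )
            assert res.loc[g, "p_raw"] == pytest.approx(t.p)
            assert res.loc[g, "branch"] == t.branch
            praw[g] = t.p
        adj = benjamini_hochberg([praw[g] for g in genes])
        np.testing.assert_allclose(res["p_adj"].to_numpy(), adj)

    def test_swapping_groups_negates_lfc_and_swaps_classes(self):
        rng = np.random.default_rng(3)
        ca = rng.poisson(30, (6, 10))
        cb = rng.poisson(30, (6, 10)) * rng.choice([1, 8], 10)
        genes = [f"g{i}" for i in range(10)]
        a = density_matrix(ca, genes, "A")
        b = density_matrix(cb, genes, "B")
        fwd = run_dge(a, b).set_index("gene")
        rev = run_dge(b, a).set_index("gene")
        np.testing.assert_allclose(fwd["lfc"], -rev["lfc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], atol=1e-12)
        swap = {"up": "down", "down": "up", "ns": "ns"}
        assert [swap[c] for c in fwd["class"]] == list(rev["class"])

    def test_degenerate_genes_flagged_never_significant(self):
        a = density_matrix([[0, 5], [0, 6], [0, 7]], ["dead", "ok"], "A")
        b = density_matrix([[0, 50], [0, 60], [0, 70]], ["dead", "ok"], "B")
        res = run_dge(a, b).set_index("gene")
        assert res.loc["dead", "degenerate"]
        assert res.loc["dead", "p_raw"] == 1.0
        assert res.loc["dead", "class"] == "ns"

    def test_volcano_table_matches_classification_p(self):
        rng = np.random.default_rng(4)
        a = density_matrix(rng.poisson(40, (6, 4)), list("abcd"), "A")
        b = density_matrix(rng.poisson(90, (6, 4)), list("abcd"), "B")
        cfg = DGEConfig(use_adjusted_p_for_class=True)
        res = run_dge(a, b, cfg)
        vt = volcano_table(res, cfg)
        np.testing.assert_allclose(vt["neg_log10_p"], -np.log10(res["p_adj"]))


class TestOverRepresentation:
    def test_zero_overlap_not_significant(self):
        uni = {f"g{i}" for i in range(50)}
        res = over_representation({"g0", "g1"}, {"S": {"g40", "g41"}}, uni)
        assert res.loc[0, "p"] == 1.0
        assert not res.loc[0, "significant"]

    def test_single_gene_overlap_blocked_by_count_rule(self):
        uni = {f"g{i}" for i in range(1000)}
        res = over_representation({"g0"}, {"S": {"g0"}}, uni)
        assert res.loc[0, "p"] < 0.05
        assert res.loc[0, "overlap"] == 1
        assert not res.loc[0, "significant"]

    def test_hit_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            over_representation({"zzz"}, {}, {"g0"})

    def test_matches_exhaustive_enumeration(self):
        # universe of 20, set of 5, 5 hits, overlap 4: enumerate all C(20,5)
        # draws and count those sharing >= 4 members with the set
        uni = [f"g{i}" for i in range(20)]
        gene_set = set(uni[:5])
        hits = set(uni[1:5]) | {uni[10]}
        res = over_representation(hits, {"S": gene_set}, set(uni))
        assert res.loc[0, "overlap"] == 4
        favourable = sum(
            1 for combo in itertools.combinations(uni, 5)
            if len(gene_set & set(combo)) >= 4
        )
        expected = favourable / math.comb(20, 5)
        assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(
            hypergeom_tail_oracle(20, 5, 5, 4), abs=1e-12
        )

    def test_read_gene_sets(self, tmp_path):
        p = tmp_path / "sets.tsv"
        p.write_text("wnt\tWnt5a,Wnt16, Dkk1\necm\tCol1a1,Eln\n")
        sets = read_gene_sets(p)
        assert sets == {"wnt": {"Wnt5a", "Wnt16", "Dkk1"}, "ecm": {"Col1a1", "Eln"}}
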