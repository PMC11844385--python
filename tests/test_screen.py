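import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sortscreen import (
    empirical_fdr_hits,
    gene_stats,
    make_quasi_genes,
    mann_whitney_u,
    normalize_counts,
    replicate_concordance,
    sgrna_lfc,
)


def enumeration_oracle(x, y):
    """Exhaustive permutation Mann-Whitney: U and two-sided p by brute force.

    Enumerates all C(n+m, n) assignments of the pooled values to the x
    slots and computes the two-sided p as twice the smaller tail of the
    exact U distribution (tie-free inputs only).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    pooled = np.concatenate([x, y])
    u_obs = sum(1.0 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum(1.0 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    cdf = (us <= u_obs).mean()
    sf = (us >= u_obs).mean()
    return u_obs, min(1.0, 2 * min(cdf, sf))


class TestNormalizeCounts:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [10, 30, 60]})
        norm = normalize_counts(counts, pseudocount=0)
        assert np.allclose(norm["s"], [1e5, 3e5, 6e5])

    def test_samples_sum_to_1e6(self, rng):
        counts = pd.DataFrame(rng.integers(0, 500, size=(40, 3)),
                              columns=["a", "b", "c"])
        norm = normalize_counts(counts, pseudocount=1)
        assert np.allclose(norm.sum(axis=0), 1e6, rtol=1e-9)

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame({"s": rng.integers(1, 100, size=20)})
        n1 = normalize_counts(counts, pseudocount=0)
        n2 = normalize_counts(counts * 10, pseudocount=0)
        pd.testing.assert_frame_equal(n1, n2)

    def test_all_zero_sample_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(pd.DataFrame({"s": [0, 0]}), pseudocount=1)


class TestSgRNALfc:
    def test_equal_counts_give_zero(self, tiny_library):
        v = np.full(tiny_library.n_elements, 100.0)
        phen = sgrna_lfc(v, v, tiny_library)
        assert np.allclose(phen["lfc"], 0)
        assert phen["is_ntc"].sum() == 3

    def test_fourfold_gives_two(self, tiny_library):
        low = np.full(tiny_library.n_elements, 50.0)
        phen = sgrna_lfc(4 * low, low, tiny_library)
        assert np.allclose(phen["lfc"], 2)

    def test_antisymmetric_under_bin_swap(self, tiny_library, rng):
        hi = rng.uniform(1, 100, tiny_library.n_elements)
        lo = rng.uniform(1, 100, tiny_library.n_elements)
        fwd = sgrna_lfc(hi, lo, tiny_library)["lfc"]
        rev = sgrna_lfc(lo, hi, tiny_library)["lfc"]
        assert np.allclose(fwd, -rev)

    def test_length_mismatch_is_error(self, tiny_library):
        with pytest.raises(ValueError, match="match"):
            sgrna_lfc([1.0], [1.0], tiny_library)


class TestMakeQuasiGenes:
    NTC_IDS = [f"NTC_sg{i:03d}" for i in range(250)]

    def test_seeded_determinism(self):
        a = make_quasi_genes(self.NTC_IDS, k=5, n_quasi=50, seed=9)
        b = make_quasi_genes(self.NTC_IDS, k=5, n_quasi=50, seed=9)
        assert a == b
        c = make_quasi_genes(self.NTC_IDS, k=5, n_quasi=50, seed=10)
        assert a != c

    def test_every_quasi_gene_has_k_members(self):
        for q in make_quasi_genes(self.NTC_IDS, k=5, n_quasi=200, seed=1):
            assert len(q.members) == 5
            assert set(q.members) <= set(self.NTC_IDS)

    def test_sampling_is_uniform(self):
        """Selection frequencies over many draws pass a chi-square GOF test."""
        quasi = make_quasi_genes(self.NTC_IDS, k=5, n_quasi=10_000, seed=4)
        draws = pd.Series(
            [m for q in quasi for m in q.members]
        ).value_counts().reindex(self.NTC_IDS, fill_value=0)
        _, p = sps.chisquare(draws)
        assert p > 0.001

    def test_empty_ntc_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            make_quasi_genes([], k=5, n_quasi=10, seed=0)


class TestMannWhitneyU:
    def test_spec_example_against_enumeration(self):
        x, y = [1.2, 3.4], [0.1, 0.5, 2.0]
        u, p = mann_whitney_u(x, y, method="exact")
        u_exp, p_exp = enumeration_oracle(x, y)
        assert u == u_exp == 5
        assert p == pytest.approx(p_exp)

    def test_identical_multisets_give_half_nm(self):
        x = [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, x)
        assert u == len(x) ** 2 / 2

    def test_complete_separation_matches_enumeration(self):
        x, y = [4.0, 5.0, 6.0], [1.0, 2.0, 3.0]
        u, p = mann_whitney_u(x, y, method="exact")
        u_exp, p_exp = enumeration_oracle(x, y)
        assert u == u_exp == 9
        assert p == pytest.approx(p_exp)  # the extreme tail, 2/20

    @pytest.mark.parametrize("n,m", [(n, m) for n in range(1, 10)
                                     for m in range(1, 10) if n + m <= 10])
    def test_exact_equals_enumeration_all_small_sizes(self, n, m):
        rng = np.random.default_rng(1000 * n + m)
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            u, p = mann_whitney_u(x, y, method="exact")
            u_exp, p_exp = enumeration_oracle(x, y)
            assert u == pytest.approx(u_exp)
            assert p == pytest.approx(p_exp)

    @pytest.mark.parametrize("n,m", [(3, 4), (5, 5), (2, 8)])
    def test_exact_matches_scipy(self, n, m):
        rng = np.random.default_rng(n * 100 + m)
        x, y = rng.normal(size=n), rng.normal(size=m)
        u, p = mann_whitney_u(x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_asymptotic_close_to_scipy(self):
        rng = np.random.default_rng(77)
        x, y = rng.normal(0.5, 1, 40), rng.normal(0, 1, 60)
        u, p = mann_whitney_u(x, y, method="asymptotic")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ties_use_half_pair_counting(self):
        u, _ = mann_whitney_u([1.0, 2.0], [2.0, 0.0])
        assert u == 2.5  # one win over 0.0 twice, one half for the tie at 2.0

    def test_all_identical_returns_p_one(self):
        _, p = mann_whitney_u([1.0] * 5, [1.0] * 5)
        assert p == 1.0

    def test_exact_with_ties_is_error(self):
        with pytest.raises(ValueError, match="tie"):
            mann_whitney_u([1.0, 2.0], [2.0, 3.0], method="exact")

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def phenotype_frame(gene_lfcs: dict, ntc_lfcs):
    rows = []
    for gene, lfcs in gene_lfcs.items():
        for i, v in enumerate(lfcs):
            rows.append((f"{gene}_sg{i}", gene, False, v))
    for i, v in enumerate(ntc_lfcs):
        rows.append((f"NTC_sg{i:03d}", "NTC", True, v))
    return pd.DataFrame(rows, columns=["sgrna", "gene", "is_ntc", "lfc"])


class TestGeneStats:
    def test_null_gene_scores_near_zero(self):
        ntc = np.concatenate([np.linspace(-1, 1, 20)])  # symmetric about 0
        phen = phenotype_frame({"G1": [0.0] * 5}, ntc)
        res = gene_stats(phen, [])
        row = res.iloc[0]
        assert row["p_value"] > 0.5
        assert abs(row["gene_score"]) < 0.5

    def test_gene_score_is_lfc_times_neglog10p(self):
        rng = np.random.default_rng(12)
        phen = phenotype_frame({"G1": rng.normal(2, 0.1, 5)}, rng.normal(0, 1, 50))
        res = gene_stats(phen, [])
        row = res.iloc[0]
        assert row["gene_score"] == pytest.approx(
            row["lfc_gene"] * -np.log10(row["p_value"])
        )

    def test_quasi_of_one_repeated_ntc_keeps_its_lfc(self):
        from sortscreen import QuasiGene

        ntc = np.linspace(-1, 1, 10)
        phen = phenotype_frame({"G1": [0.1] * 3}, ntc)
        target = phen.loc[phen["is_ntc"], "sgrna"].iloc[4]
        target_lfc = phen.loc[phen["sgrna"] == target, "lfc"].iloc[0]
        q = QuasiGene(id="q0", members=(target,) * 5)
        res = gene_stats(phen, [q])
        row = res[res["gene"] == "q0"].iloc[0]
        assert row["lfc_gene"] == pytest.approx(target_lfc)
        assert row["is_quasi"]

    def test_median_aggregate(self):
        phen = phenotype_frame({"G1": [0.0, 0.0, 10.0]}, np.linspace(-1, 1, 12))
        res = gene_stats(phen, [], aggregate="median")
        assert res.iloc[0]["lfc_gene"] == 0.0

    def test_missing_quasi_member_is_error(self):
        from sortscreen import QuasiGene

        phen = phenotype_frame({"G1": [0.1]}, [0.0, 0.1])
        with pytest.raises(ValueError, match="ghost"):
            gene_stats(phen, [QuasiGene(id="q", members=("ghost",) * 5)])


class TestEmpiricalFdr:
    @staticmethod
    def results_frame(real_p, quasi_p, real_lfc=None):
        if real_lfc is None:
            real_lfc = [1.0] * len(real_p)
        rows = [(f"G{i}", l, p, False) for i, (p, l) in enumerate(zip(real_p, real_lfc))]
        rows += [(f"q{i}", 0.0, p, True) for i, p in enumerate(quasi_p)]
        frame = pd.DataFrame(rows, columns=["gene", "lfc_gene", "p_value", "is_quasi"])
        frame["gene_score"] = frame["lfc_gene"] * -np.log10(frame["p_value"])
        return frame

    def test_clean_separation_is_a_hit(self):
        res = self.results_frame([0.001], [1.0, 1.0, 1.0, 1.0])
        ctx, annotated = empirical_fdr_hits(res, alpha=0.10)
        assert ctx.p_cutoff == pytest.approx(0.001)
        assert annotated.loc[~annotated["is_quasi"], "hit_direction"].iloc[0] == "increase"

    def test_alpha_zero_requires_strict_undercut(self):
        res = self.results_frame([0.01, 0.5], [0.02, 0.3, 0.9])
        ctx, annotated = empirical_fdr_hits(res, alpha=0.0)
        assert ctx.p_cutoff == pytest.approx(0.01)  # 0.01 undercuts every quasi p
        res2 = self.results_frame([0.05, 0.5], [0.02, 0.3, 0.9])
        ctx2, _ = empirical_fdr_hits(res2, alpha=0.0)
        assert ctx2.p_cutoff is None

    def test_direction_follows_lfc_sign(self):
        res = self.results_frame([0.001, 0.001], [1.0] * 4, real_lfc=[2.0, -2.0])
        _, annotated = empirical_fdr_hits(res, alpha=0.10)
        real = annotated[~annotated["is_quasi"]]
        assert list(real["hit_direction"]) == ["increase", "decrease"]

    def test_monotonized_curve_and_nested_hits(self, rng):
        real_p = rng.uniform(size=200) ** 2  # enriched near 0
        quasi_p = rng.uniform(size=200)
        res = self.results_frame(real_p, quasi_p)
        ctx, _ = empirical_fdr_hits(res, alpha=0.10)
        assert (np.diff(ctx.curve["fdr"]) >= -1e-12).all()  # non-decreasing in t
        hit_sets = []
        for alpha in (0.05, 0.10, 0.25):
            _, annotated = empirical_fdr_hits(res, alpha=alpha)
            hit_sets.append(set(
                annotated.loc[annotated["hit_direction"] != "none", "gene"]
            ))
        assert hit_sets[0] <= hit_sets[1] <= hit_sets[2]

    def test_null_calibration(self):
        """Real and quasi p from one distribution: hit fraction stays <= alpha."""
        rng = np.random.default_rng(2024)
        fractions = []
        for _ in range(50):
            res = self.results_frame(rng.uniform(size=100), rng.uniform(size=100))
            _, annotated = empirical_fdr_hits(res, alpha=0.10)
            real = annotated[~annotated["is_quasi"]]
            fractions.append((real["hit_direction"] != "none").mean())
        assert np.mean(fractions) <= 0.10 + 0.02

    def test_no_quasi_entries_is_error(self):
        res = self.results_frame([0.01], [])
        with pytest.raises(ValueError, match="quasi"):
            empirical_fdr_hits(res, alpha=0.1)


class TestReplicateConcordance:
    @staticmethod
    def results(scores):
        return pd.DataFrame({
            "gene": [f"G{i}" for i in range(len(scores))],
            "gene_score": scores,
            "is_quasi": False,
        })

    def test_self_concordance_is_one(self, rng):
        a = self.results(rng.normal(size=20))
        assert replicate_concordance(a, a) == pytest.approx(1.0)

    def test_negated_scores_give_minus_one(self, rng):
        a = self.results(rng.normal(size=20))
        b = a.copy()
        b["gene_score"] = -b["gene_score"]
        assert replicate_concordance(a, b) == pytest.approx(-1.0)

    def test_independent_scores_are_uncorrelated(self, rng):
        a = self.results(rng.normal(size=1000))
        b = self.results(rng.normal(size=1000))
        assert abs(replicate_concordance(a, b)) < 0.1

    def test_too_few_shared_genes_is_error(self):
        a = self.results([1.0, 2.0])
        with pytest.raises(ValueError, match="3"):
            replicate_concordance(a, a)
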