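"""Profile similarity, function prediction and the companion statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnscreen import profiles


def _zmatrix(values, genes=None, conditions=None):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    conditions = conditions or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=conditions)


class TestProfileSimilarity:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        table = _zmatrix(rng.normal(size=(5, 12)))
        sim = profiles.profile_similarity(table, min_overlap=5)
        assert np.allclose(np.diag(sim), 1.0)

    def test_anti_correlated_profiles(self):
        x = np.arange(12, dtype=float)
        table = _zmatrix(np.vstack([x, -x]))
        sim = profiles.profile_similarity(table, min_overlap=5)
        assert sim.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_bruteforce_pearson_oracle(self):
        rng = np.random.default_rng(1)
        table = _zmatrix(rng.normal(size=(20, 10)))
        sim = profiles.profile_similarity(table, min_overlap=2)
        for i, j in itertools.combinations(range(20), 2):
            expected = stats.pearsonr(table.iloc[i], table.iloc[j]).statistic
            assert sim.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_min_overlap_marks_pairs_undefined(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(3, 12))
        values[0, 6:] = np.nan
        values[1, :6] = np.nan
        table = _zmatrix(values)
        sim = profiles.profile_similarity(table, min_overlap=3)
        assert np.isnan(sim.iloc[0, 1])  # no shared conditions
        assert np.isfinite(sim.iloc[0, 2])


class TestPrecisionRecall:
    def test_perfectly_ranked_standard(self):
        genes = list("abcd")
        sim = pd.DataFrame(0.0, index=genes, columns=genes)
        sim.loc["a", "b"] = sim.loc["b", "a"] = 0.9
        term_sets = {"T": {"a", "b"}, "U": {"c"}, "V": {"d"}}
        pr = profiles.precision_recall(sim, term_sets)
        assert pr.precision_at(1) == 1.0

    def test_hand_computed_curve(self):
        # 5 pairs, co-annotated at ranks 1 and 3
        genes = list("abcd")
        sim = pd.DataFrame(np.nan, index=genes, columns=genes)
        pairs = [("a", "b", 0.9, True), ("a", "c", 0.8, False),
                 ("a", "d", 0.7, True), ("b", "c", 0.6, False),
                 ("b", "d", 0.5, False)]
        for x, y, s, _ in pairs:
            sim.loc[x, y] = sim.loc[y, x] = s
        np.fill_diagonal(sim.values, 1.0)
        sim.loc["c", "d"] = sim.loc["d", "c"] = np.nan
        term_sets = {"T": {"a", "b"}, "U": {"a", "d"}, "W": {"c"}}
        pr = profiles.precision_recall(sim, term_sets)
        assert len(pr.table) == 5
        assert list(np.round(pr.table["precision"], 3)) == [1.0, 0.5, 0.667, 0.5, 0.4]

    def test_precision_at_full_recall_equals_background(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(15)]
        sim = pd.DataFrame(rng.normal(size=(15, 15)), index=genes, columns=genes)
        sim = (sim + sim.T) / 2
        term_sets = {"T": set(genes[:5]), "U": set(genes[5:])}
        pr = profiles.precision_recall(sim, term_sets)
        assert pr.table["precision"].iloc[-1] == pr.background

    def test_random_scores_track_background(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(40)]
        term_sets = {"T": set(genes[:12]), "U": set(genes[12:25]),
                     "V": set(genes[25:])}
        precisions = []
        for _ in range(30):
            vals = rng.normal(size=(40, 40))
            sim = pd.DataFrame((vals + vals.T) / 2, index=genes, columns=genes)
            pr = profiles.precision_recall(sim, term_sets)
            precisions.append(pr.precision_at(100))
            background = pr.background
        se = np.std(precisions, ddof=1) / np.sqrt(len(precisions))
        assert abs(np.mean(precisions) - background) < 4 * se + 0.02

    def test_no_annotated_genes_rejected(self):
        sim = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(profiles.EmptyStandardError):
            profiles.precision_recall(sim, {"T": {"z"}})


class TestClusterConditions:
    def test_identical_columns_merge_first_at_zero_height(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(30, 1))
        values = np.hstack([base, base, base, rng.normal(size=(30, 2))])
        table = _zmatrix(values, conditions=list("ABCDE"))
        clust = profiles.cluster_conditions(table, top_n=30)
        link = clust.condition_linkage
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert link[1, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(link[0, 0]), int(link[0, 1]), int(link[1, 0]), int(link[1, 1])}
        assert merged <= {0, 1, 2, 5}  # the three identical columns + their cluster

    def test_carbon_blocks_are_monophyletic(self):
        rng = np.random.default_rng(6)
        carbons = ["glucose"] * 4 + ["galactose"] * 4 + ["ribose"] * 4
        signal = {c: rng.normal(size=200) for c in ("glucose", "galactose", "ribose")}
        cols = {}
        for i, c in enumerate(carbons):
            cols[f"{c[:3]}{i}"] = 2 * signal[c] + rng.normal(size=200) * 0.5
        table = pd.DataFrame(cols)
        clust = profiles.cluster_conditions(table, top_n=150)
        from scipy.cluster.hierarchy import fcluster
        labels = fcluster(clust.condition_linkage, t=3, criterion="maxclust")
        groups = {}
        for lab, c in zip(labels, carbons):
            groups.setdefault(lab, set()).add(c)
        assert all(len(v) == 1 for v in groups.values())
        assert len(groups) == 3

    def test_top_n_exceeding_gene_count_rejected(self):
        table = _zmatrix(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError):
            profiles.cluster_conditions(table, top_n=10)


class TestHypergeometricOverlap:
    def test_disjoint_small_sets_have_p_one(self):
        k, p = profiles.hypergeometric_overlap({"a"}, {"b"}, 100)
        assert k == 0
        assert p == pytest.approx(1.0)

    def test_closed_form_complete_overlap(self):
        k, p = profiles.hypergeometric_overlap({"a", "b"}, {"a", "b"}, 5)
        assert k == 2
        assert p == pytest.approx(0.1)  # 1 / C(5,2)

    @pytest.mark.parametrize("n_universe", [6, 9, 12])
    def test_matches_enumeration_oracle(self, n_universe):
        universe = [f"u{i}" for i in range(n_universe)]
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = set(rng.choice(universe, rng.integers(1, n_universe), replace=False))
            b = set(rng.choice(universe, rng.integers(1, n_universe), replace=False))
            k, p = profiles.hypergeometric_overlap(a, b, n_universe)
            # brute force: enumerate all placements of |b| among the universe
            total = hits = 0
            for combo in itertools.combinations(universe, len(b)):
                total += 1
                hits += len(a & set(combo)) >= k
            assert p == pytest.approx(hits / total, rel=1e-9)

    def test_set_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            profiles.hypergeometric_overlap({"a", "b"}, {"c"}, 1)


class TestEnrichment:
    def test_single_term_uncorrected(self):
        bg = {f"g{i}" for i in range(20)}
        term_sets = {"T": {f"g{i}" for i in range(5)}}
        out = profiles.enrichment({"g0", "g1", "g2"}, term_sets, bg)
        _, p = profiles.hypergeometric_overlap({"g0", "g1", "g2"}, term_sets["T"], 20)
        assert out.loc["T", "p_corrected"] == pytest.approx(p)

    def test_bonferroni_bound(self):
        bg = {f"g{i}" for i in range(20)}
        term_sets = {"T": {f"g{i}" for i in range(4)},
                     "U": {f"g{i}" for i in range(4, 9)},
                     "V": {"g19"}}
        out = profiles.enrichment({"g0", "g1", "g2", "g3"}, term_sets, bg)
        for term in term_sets:
            assert out.loc[term, "p_corrected"] <= min(1.0, out.loc[term, "p"] * 3) + 1e-12
        assert out.loc["T", "p_corrected"] == pytest.approx(
            min(1.0, out.loc["T", "p"] * 3))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            profiles.enrichment({"a"}, {"T": {"a"}}, set())


class TestGeneSetSignTest:
    def _matrix(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        gal = [f"galactose:c{i}" for i in range(7)]
        rib = [f"ribose:c{i}" for i in range(7)]
        vals = np.hstack([rng.normal(-0.5, 0.1, (30, 7)),
                          rng.normal(0.5, 0.1, (30, 7))])
        return pd.DataFrame(vals, index=genes, columns=gal + rib), gal, rib

    def test_fourteen_of_fourteen_closed_form(self):
        table, gal, rib = self._matrix()
        res = profiles.gene_set_sign_test(table, set(table.index), gal, rib)
        assert res.n_match == 14 and res.n_total == 14
        assert res.p == pytest.approx(0.5 ** 14)
        assert res.p == pytest.approx(6.10e-5, rel=1e-2)

    def test_seven_of_fourteen_tail_sum(self):
        table, gal, rib = self._matrix()
        res = profiles.gene_set_sign_test(table, set(table.index), rib, gal)
        assert res.n_match == 0
        # exact binomial: P(X >= 7 | n=14) computed for a half-split check
        expected = sum(stats.binom.pmf(k, 14, 0.5) for k in range(7, 15))
        assert stats.binom.sf(6, 14, 0.5) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n, k", [(5, 3), (14, 14), (30, 17)])
    def test_matches_exact_binomial_oracle(self, n, k):
        expected = sum(stats.binom.pmf(j, n, 0.5) for j in range(k, n + 1))
        assert stats.binom.sf(k - 1, n, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_empty_group_b_tests_group_a_only(self):
        table, gal, rib = self._matrix()
        res = profiles.gene_set_sign_test(table, set(table.index), gal, [])
        assert res.n_total == 7 and res.n_match == 7
        assert res.p == pytest.approx(0.5 ** 7)

    def test_overlapping_groups_rejected(self):
        table, gal, rib = self._matrix()
        with pytest.raises(ValueError):
            profiles.gene_set_sign_test(table, set(table.index), gal, gal)


class TestCrossProfileSimilarity:
    def _matrices(self, seed=9, n_genes=150):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        env = pd.DataFrame(rng.normal(size=(6, n_genes)),
                           index=[f"cond{i}" for i in range(6)], columns=genes)
        qry = pd.DataFrame(rng.normal(size=(30, n_genes)),
                           index=[f"q{i}" for i in range(30)], columns=genes)
        return env, qry

    def test_profile_vectors_unit_after_normalization(self):
        env, _ = self._matrices()
        normed = profiles.bidirectional_unit_normalize(env)
        rows = np.linalg.norm(normed, axis=1)
        assert np.all(np.abs(rows - 1) < 1e-9)

    def test_square_matrix_balances_both_dimensions(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(size=(25, 25)))
        normed = profiles.bidirectional_unit_normalize(m)
        assert np.all(np.abs(np.linalg.norm(normed, axis=1) - 1) < 0.05)
        assert np.all(np.abs(np.linalg.norm(normed, axis=0) - 1) < 0.05)

    def test_identical_query_attains_condition_maximum(self):
        env, qry = self._matrices()
        qry.iloc[0] = env.iloc[2]
        res = profiles.cross_profile_similarity(env, qry)
        assert res.similarity.loc["cond2"].idxmax() == "q0"

    def test_swapping_inputs_transposes_output(self):
        env, qry = self._matrices()
        a = profiles.cross_profile_similarity(env, qry).similarity
        b = profiles.cross_profile_similarity(qry, env).similarity
        assert np.allclose(a.to_numpy(), b.to_numpy().T, atol=1e-12)

    def test_planted_shared_signature_lands_in_top_decile(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            genes = [f"g{i}" for i in range(200)]
            signature = rng.normal(size=200)
            env = pd.DataFrame(rng.normal(size=(5, 200)),
                               index=[f"cond{i}" for i in range(5)], columns=genes)
            env.iloc[0] += 2 * signature
            qry = pd.DataFrame(rng.normal(size=(40, 200)),
                               index=[f"q{i}" for i in range(40)], columns=genes)
            for j in range(3):
                qry.iloc[j] += 2 * signature
            res = profiles.cross_profile_similarity(env, qry)
            ok += set(res.top_queries["cond0"]) >= {"q0", "q1", "q2"}
        assert ok >= 9

    def test_small_shared_universe_rejected(self):
        env, qry = self._matrices(n_genes=150)
        with pytest.raises(profiles.SharedUniverseError):
            profiles.cross_profile_similarity(env.iloc[:, :50], qry.iloc[:, :50])


class TestLiquidAssay:
    def _assay(self, strain, rates_by_cond, wells=(0,)):
        rows = []
        for cond, rate in rates_by_cond.items():
            for w in wells:
                for t in (0, 2, 4, 6, 8, 10, 12):
                    od = min(rate * 10, rate * t)  # saturates at t=10
                    rows.append((strain, cond, w, float(t), od))
        return profiles.LiquidAssay(pd.DataFrame(
            rows, columns=["strain", "condition", "well", "time_h", "od"]))

    def test_rate_formula(self):
        # OD reaching max 1.0 at 10 h -> 0.1 per hour
        t = [0, 2, 4, 6, 8, 10, 12]
        od = [0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.0]
        assert profiles.liquid_growth_rate(t, od) == pytest.approx(0.1, rel=0.06)

    def test_mutant_identical_to_wildtype_scores_one(self):
        conds = {"glucose:ammonium": 0.1, "galactose:urea": 0.05}
        mut = self._assay("mutX", conds, wells=(0, 1))
        wt = self._assay("WT", conds, wells=(0, 1, 2))
        scores = profiles.liquid_adjusted_score(mut, wt)
        assert np.allclose(scores.loc["mutX"], 1.0)

    def test_condition_specific_deficit(self):
        wt = self._assay("WT", {"glucose:ammonium": 0.1, "galactose:urea": 0.1})
        mut = self._assay("mutX", {"glucose:ammonium": 0.1, "galactose:urea": 0.05})
        scores = profiles.liquid_adjusted_score(mut, wt)
        assert scores.loc["mutX", "galactose:urea"] == pytest.approx(0.5, rel=1e-6)
        assert scores.loc["mutX", "glucose:ammonium"] == pytest.approx(1.0)

    def test_zero_wildtype_rate_rejected(self):
        wt = self._assay("WT", {"glucose:ammonium": 0.0})
        mut = self._assay("mutX", {"glucose:ammonium": 0.1})
        with pytest.raises(profiles.UndefinedScoreError):
            profiles.liquid_adjusted_score(mut, wt)
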