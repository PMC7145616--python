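import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tseakit import (ContractError, GeneScoreTable, chi2_enrichment,
                     gsea_validate, make_tag_sets, run_tsea,
                     select_top_tissues)
from tseakit.enrich import TSEAResult
from tseakit.specificity import TissueSpecificSets


def _score_table(pvalues: dict, study_id="s"):
    df = pd.DataFrame({"pvalue": pd.Series(pvalues), "n_snps": 1, "status": "ok"})
    df.index.name = "gene_id"
    return GeneScoreTable(study_id, df, min_genes=0)


class TestTagSets:
    def test_strict_threshold_membership(self):
        gs = _score_table({"a": 0.05, "b": 0.049, "c": 0.5})
        tags = make_tag_sets(gs)
        assert tags.sets[0.05]["genes"] == {"b"}

    def test_nestedness_and_qualification(self):
        rng = np.random.default_rng(0)
        pv = {f"g{i}": p for i, p in enumerate(rng.uniform(0, 1, 2000) ** 4)}
        tags = make_tag_sets(_score_table(pv))
        thr = tags.thresholds
        for loose, strict in zip(thr, thr[1:]):
            assert tags.sets[strict]["genes"] <= tags.sets[loose]["genes"]
        for t in thr:
            n = len(tags.sets[t]["genes"])
            assert tags.sets[t]["qualified"] == (20 <= n <= 3000)

    @pytest.mark.parametrize("n,qualified", [(19, False), (20, True),
                                             (3000, True), (3001, False)])
    def test_size_bounds(self, n, qualified):
        pv = {f"g{i}": 1e-6 for i in range(n)}
        pv.update({f"h{i}": 0.9 for i in range(5)})
        tags = make_tag_sets(_score_table(pv))
        assert tags.sets[1e-5]["qualified"] is qualified

    def test_study_without_qualified_set_excluded(self):
        tags = make_tag_sets(_score_table({"a": 1e-9, "b": 0.5}))
        assert tags.excluded


class TestChi2Enrichment:
    def test_overlap_at_expectation_gives_half(self):
        universe = {f"g{i}" for i in range(100)}
        tag = {f"g{i}" for i in range(50)}          # half the universe
        tissue = {f"g{i}" for i in range(25, 75)}   # overlap 25 = expected
        res = chi2_enrichment(tag, tissue, universe)
        assert res["pvalue"] == 0.5 and res["statistic"] == 0.0

    def test_matches_textbook_2x2_computation(self):
        universe = {f"g{i}" for i in range(1000)}
        tissue = {f"g{i}" for i in range(50)}
        tag = {f"g{i}" for i in range(30, 130)}     # overlap 20
        res = chi2_enrichment(tag, tissue, universe)
        # direct Pearson statistic on the table [[20, 80], [30, 870]]
        table = np.array([[20, 80], [30, 870]])
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        x2 = ((table - exp) ** 2 / exp).sum()
        assert res["statistic"] == pytest.approx(x2, abs=1e-10)
        assert res["pvalue"] == pytest.approx(stats.chi2.sf(x2, 1) / 2, abs=1e-10)
        assert res["overlap"] == 20

    def test_scipy_contingency_oracle(self):
        universe = {f"g{i}" for i in range(500)}
        tissue = {f"g{i}" for i in range(40)}
        tag = {f"g{i}" for i in range(25, 125)}
        res = chi2_enrichment(tag, tissue, universe)
        a = res["overlap"]
        table = [[a, 100 - a], [40 - a, 500 - 140 + a]]
        x2_ref = stats.chi2_contingency(table, correction=False).statistic
        assert res["statistic"] == pytest.approx(x2_ref, rel=1e-12)

    def test_depletion_direction(self):
        universe = {f"g{i}" for i in range(200)}
        tag = {f"g{i}" for i in range(50)}
        tissue = {f"g{i}" for i in range(150, 200)}  # overlap 0
        res = chi2_enrichment(tag, tissue, universe)
        assert res["pvalue"] > 0.5

    def test_direction_agrees_with_hypergeometric(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(300)]
        for _ in range(25):
            tag = set(rng.choice(universe, 60, replace=False))
            tissue = set(rng.choice(universe, 40, replace=False))
            res = chi2_enrichment(tag, tissue, set(universe))
            assert (res["overlap"] > res["expected"]) == (res["pvalue"] < 0.5) \
                or res["overlap"] == res["expected"]

    def test_agrees_with_fisher_when_cells_large(self):
        universe = {f"g{i}" for i in range(2000)}
        for tag_n, tis_n, ov in [(400, 300, 80), (500, 500, 150), (300, 200, 30)]:
            tag = {f"g{i}" for i in range(tag_n)}
            shift = tag_n - ov
            tissue = {f"g{i}" for i in range(shift, shift + tis_n)}
            res = chi2_enrichment(tag, tissue, universe)
            a = res["overlap"]
            table = [[a, tag_n - a], [tis_n - a, 2000 - tag_n - tis_n + a]]
            _, fp = stats.fisher_exact(table, alternative="greater")
            if res["pvalue"] < 0.5:
                assert res["pvalue"] == pytest.approx(fp, abs=0.02)

    def test_empty_inputs_are_contract_errors(self):
        with pytest.raises(ContractError):
            chi2_enrichment({"a"}, {"a"}, set())
        with pytest.raises(ContractError):
            chi2_enrichment({"zz"}, {"a"}, {"a", "b"})


class TestRunTsea:
    def _tissue_sets(self, sets):
        return TissueSpecificSets("panel", 0.05, sets)

    def test_single_tissue_single_row(self):
        gs = _score_table({f"g{i}": 0.001 for i in range(30)}
                          | {f"h{i}": 0.9 for i in range(70)})
        tags = make_tag_sets(gs)
        universe = set(gs.table.index)
        res = run_tsea(tags, self._tissue_sets({"A": {"g0", "g1", "h0"}}), universe)
        assert list(res.pvalues.index) == ["A"]

    def test_unqualified_thresholds_absent(self):
        gs = _score_table({f"g{i}": 0.03 for i in range(25)}
                          | {f"h{i}": 0.9 for i in range(75)})
        tags = make_tag_sets(gs)
        res = run_tsea(tags, self._tissue_sets({"A": {"g0"}}), set(gs.table.index))
        assert np.isfinite(res.pvalues.loc["A", 0.05])
        assert np.isnan(res.pvalues.loc["A", 1e-5])

    def test_null_type_i_error_calibrated(self):
        """Random TAG draws at realistic margins (18000-gene universe, 5%
        tissue sets, 1000-gene TAGs): ~5% of P-values fall below 0.05."""
        rng = np.random.default_rng(17)
        universe = np.array([f"g{i}" for i in range(18_000)])
        uni = set(universe)
        tissue = set(rng.choice(universe, 900, replace=False))
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            tag = set(rng.choice(universe, 1000, replace=False))
            p = chi2_enrichment(tag, tissue, uni)["pvalue"]
            hits += p < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.02)


class TestGsea:
    def test_top_ranked_tag_gives_maximal_es(self):
        scores = pd.Series(np.linspace(5, 0.1, 50), index=[f"g{i}" for i in range(50)])
        tag = {"g0", "g1", "g2"}
        res = gsea_validate(scores, tag, n_perm=2000, seed=1)
        assert res.es == pytest.approx(1.0)
        assert res.perm_p == pytest.approx(1 / 2001)
        assert set(res.leading_edge) == tag

    def test_exhaustive_enumeration_matches_monte_carlo(self):
        """All C(10,2)=45 placements enumerated; MC permutation P within
        binomial error of the exact enumeration P."""
        rng = np.random.default_rng(2)
        scores = pd.Series(np.sort(rng.uniform(0.5, 3, 10))[::-1],
                           index=[f"g{i}" for i in range(10)])
        tag = {"g1", "g4"}
        n_perm = 4000
        res = gsea_validate(scores, tag, n_perm=n_perm, seed=3)

        # independent oracle: recompute ES by the running-sum definition
        def brute_es(positions):
            w = scores.to_numpy()
            hits = set(positions)
            nr = sum(w[i] for i in hits)
            run, best = 0.0, 0.0
            for i in range(10):
                run += w[i] / nr if i in hits else -1.0 / 8
                if abs(run) > abs(best):
                    best = run
            return best

        obs = brute_es([1, 4])
        assert res.es == pytest.approx(obs, abs=1e-12)
        all_es = [brute_es(c) for c in itertools.combinations(range(10), 2)]
        same = [e for e in all_es if (e > 0) == (obs > 0)]
        exact_p = sum(abs(e) >= abs(obs) for e in same) / len(all_es)
        se = np.sqrt(exact_p * (1 - exact_p) / n_perm)
        assert res.perm_p == pytest.approx(exact_p, abs=3 * se + 1 / n_perm)

    def test_random_tag_nes_magnitude_near_one(self):
        rng = np.random.default_rng(9)
        scores = pd.Series(rng.standard_normal(200),
                           index=[f"g{i}" for i in range(200)]).abs()
        nes = []
        for rep in range(40):
            tag = set(rng.choice(scores.index, 15, replace=False))
            res = gsea_validate(scores, tag, n_perm=300, seed=rep)
            nes.append(abs(res.nes))
        assert np.mean(nes) == pytest.approx(1.0, abs=0.15)

    def test_oversized_tag_is_contract_error(self):
        scores = pd.Series([3.0, 2.0], index=["a", "b"])
        with pytest.raises(ContractError):
            gsea_validate(scores, {"a", "b", "c"}, n_perm=10)

    def test_nes_sign_matches_es(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.standard_normal(60),
                           index=[f"g{i}" for i in range(60)])
        tag = {f"g{i}" for i in range(50, 60)}   # bottom-ranked genes
        res = gsea_validate(scores, tag, n_perm=500, seed=5)
        assert np.sign(res.nes) == np.sign(res.es)
        assert res.perm_p >= 1 / 501


class TestSelectTopTissues:
    def _result(self, pmat, counts):
        return TSEAResult("s", "p", pmat, counts)

    def test_three_smallest_distinct_minima(self):
        pmat = pd.DataFrame({0.05: [0.5, 0.01, 0.2, 0.03, 0.4]},
                            index=list("ABCDE"))
        counts = {(t, 0.05): {"overlap": 1} for t in "ABCDE"}
        top = select_top_tissues(self._result(pmat, counts), 3)
        assert top == ["B", "D", "C"]

    def test_tie_broken_by_overlap_then_name(self):
        pmat = pd.DataFrame({0.05: [0.01, 0.01, 0.01]}, index=list("CAB"))
        counts = {("C", 0.05): {"overlap": 5}, ("A", 0.05): {"overlap": 9},
                  ("B", 0.05): {"overlap": 5}}
        top = select_top_tissues(self._result(pmat, counts), 2)
        assert top == ["A", "B"]

    def test_k_larger_than_tissue_count(self):
        pmat = pd.DataFrame({0.05: [0.2, 0.1]}, index=["A", "B"])
        counts = {(t, 0.05): {"overlap": 1} for t in "AB"}
        assert len(select_top_tissues(self._result(pmat, counts), 10)) == 2
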