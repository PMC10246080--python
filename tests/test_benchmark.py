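"""Closure-aware confusion counts, perturbation, stability, exact Mann-Whitney."""

import itertools
import random

import numpy as np
import pytest
from scipy import stats as sps

from genesum import (
    EvalConfig,
    EnrichmentRow,
    GeneDescription,
    GeneSet,
    confusion,
    exact_mann_whitney,
    filter_standard,
    jaccard_terms,
    perturb_gene_set,
    swap_descriptions,
)


def rows_from_pvalues(p_adjs):
    return [
        EnrichmentRow(term=f"T{i}", k=1, n_sample=5, K=2, N=50, p_raw=p / 2, p_adj=p, rank=i + 1)
        for i, p in enumerate(p_adjs)
    ]


class TestFilterStandard:
    def test_cutoff_then_top_n(self):
        rows = rows_from_pvalues([0.001, 0.01, 0.2, 0.6, 1.0])
        assert filter_standard(rows, EvalConfig(top_n=10, p_cutoff=0.05)) == ["T0", "T1"]

    def test_n_equals_one_keeps_top_hit(self):
        rows = rows_from_pvalues([0.001, 0.01, 0.2, 0.6, 1.0])
        assert filter_standard(rows, EvalConfig(top_n=1, p_cutoff=0.05)) == ["T0"]

    def test_permissive_config_keeps_everything(self):
        rows = rows_from_pvalues([0.001, 0.01, 0.2, 0.6, 1.0])
        assert len(filter_standard(rows, EvalConfig(top_n=10**6, p_cutoff=1.0))) == 5

    def test_raw_p_mode(self):
        rows = rows_from_pvalues([0.08, 0.9])  # raw p are 0.04, 0.45
        assert filter_standard(rows, EvalConfig(p_cutoff=0.05, use_adjusted_p=False)) == ["T0"]


def brute_force_confusion(predicted, standard, ontology, closure):
    """Literal transcription of the true/false positive/negative definition."""

    def match(t_pred, t_ann):
        if t_pred == t_ann:
            return True
        if not closure:
            return False
        return t_pred in ontology.ancestors(t_ann) or t_pred in ontology.descendants(t_ann)

    tp = sum(1 for t_ann in standard if any(match(p, t_ann) for p in predicted))
    fn = sum(1 for t_ann in standard if not any(match(p, t_ann) for p in predicted))
    fp = sum(1 for p in predicted if not any(match(p, t_ann) for t_ann in standard))
    return tp, fp, fn


class TestConfusion:
    def test_identity_case(self, mini_ontology):
        cfg = EvalConfig()
        report = confusion({"MINI:0000002", "MINI:0000003"},
                           ["MINI:0000002", "MINI:0000003"], mini_ontology, cfg)
        assert (report.tp, report.fp, report.fn) == (2, 0, 0)
        assert report.precision == report.recall == report.f1 == 1.0
        assert report.has_hit == report.has_top_hit == 1

    def test_ancestor_counts_with_closure(self, toy_ontology):
        report = confusion({"T1"}, ["T2"], toy_ontology, EvalConfig(closure_matching=True))
        assert (report.tp, report.fp, report.fn) == (1, 0, 0)
        assert report.has_top_hit == 1

    def test_ancestor_misses_without_closure(self, toy_ontology):
        report = confusion({"T1"}, ["T2"], toy_ontology, EvalConfig(closure_matching=False))
        assert (report.tp, report.fp, report.fn) == (0, 1, 1)
        assert report.precision == report.recall == report.f1 == 0.0
        assert report.has_top_hit == 0

    def test_empty_standard_and_empty_predicted(self, toy_ontology):
        cfg = EvalConfig()
        empty_standard = confusion({"T1"}, [], toy_ontology, cfg)
        assert (empty_standard.recall, empty_standard.has_top_hit) == (0.0, 0)
        empty_predicted = confusion(set(), ["T1"], toy_ontology, cfg)
        assert (empty_predicted.precision, empty_predicted.fn) == (0.0, 1)

    @pytest.mark.parametrize("closure", [True, False])
    def test_exhaustive_subsets_match_brute_force(self, mini_ontology, closure):
        ids = sorted(mini_ontology.terms)
        cfg = EvalConfig(closure_matching=closure)
        subsets = [
            set(c) for r in range(len(ids) + 1) for c in itertools.combinations(ids, r)
        ]
        # standard lists: all permul-free orderings are equivalent for counts
        for predicted in subsets:
            for standard_set in subsets:
                standard = sorted(standard_set)
                report = confusion(predicted, standard, mini_ontology, cfg)
                assert (report.tp, report.fp, report.fn) == brute_force_confusion(
                    predicted, standard, mini_ontology, closure
                )

    def test_metric_bounds_on_random_cases(self, mini_ontology):
        rng = random.Random(99)
        ids = sorted(mini_ontology.terms)
        for _ in range(1000):
            predicted = set(rng.sample(ids, rng.randint(0, len(ids))))
            standard = rng.sample(ids, rng.randint(0, len(ids)))
            cfg = EvalConfig(closure_matching=rng.random() < 0.5)
            r = confusion(predicted, standard, mini_ontology, cfg)
            assert 0 <= r.precision <= 1 and 0 <= r.recall <= 1 and 0 <= r.f1 <= 1
            assert r.has_top_hit <= r.has_hit
            assert r.tp + r.fn == len(standard)


class TestJaccard:
    def test_partial_overlap(self):
        assert jaccard_terms({"x", "y"}, {"y", "z"}) == pytest.approx(1 / 3)

    def test_identical_and_disjoint(self):
        assert jaccard_terms({"a"}, {"a"}) == 1.0
        assert jaccard_terms({"a"}, {"b"}) == 0.0

    def test_both_empty_defined_as_one(self):
        assert jaccard_terms(set(), set()) == 1.0


class TestPerturbation:
    @pytest.mark.parametrize("size, expected_r", [(3, 1), (20, 2), (200, 20)])
    def test_ten_percent_rule(self, size, expected_r):
        gs = GeneSet(name="s", taxon="x", genes=[f"g{i}" for i in range(size)])
        pool = {f"p{i}" for i in range(300)}
        perturbed = perturb_gene_set(gs, pool, fraction=0.1, seed=1)
        assert len(perturbed.genes) == size
        assert sum(1 for a, b in zip(gs.genes, perturbed.genes) if a != b) == expected_r
        assert len(set(perturbed.genes)) == size  # replacements are distinct

    def test_seed_reproducible(self):
        gs = GeneSet(name="s", taxon="x", genes=[f"g{i}" for i in range(20)])
        pool = {f"p{i}" for i in range(50)}
        a = perturb_gene_set(gs, pool, seed=42)
        b = perturb_gene_set(gs, pool, seed=42)
        assert a.genes == b.genes
        c = perturb_gene_set(gs, pool, seed=43)
        assert a.genes != c.genes

    def test_fraction_zero_is_noop(self):
        gs = GeneSet(name="s", taxon="x", genes=["g1", "g2", "g3"])
        assert perturb_gene_set(gs, {"p1"}, fraction=0.0).genes == gs.genes

    def test_insufficient_pool_is_error(self):
        gs = GeneSet(name="s", taxon="x", genes=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError):
            perturb_gene_set(gs, {"g1", "g2"}, fraction=0.5, seed=0)


class TestSwapDescriptions:
    def donor(self, i):
        return GeneDescription(symbol=f"d{i}", source="narrative", text=f"endocytosis text {i}")

    def test_symbols_kept_texts_foreign(self):
        descs = [GeneDescription(f"g{i}", "narrative", f"glycolysis text {i}") for i in range(5)]
        donors = [self.donor(i) for i in range(3)]
        swapped = swap_descriptions(descs, donors, seed=0)
        assert [d.symbol for d in swapped] == [d.symbol for d in descs]
        donor_texts = {d.text for d in donors}
        assert all(d.text in donor_texts for d in swapped)

    def test_single_donor_degenerate(self):
        descs = [GeneDescription(f"g{i}", "narrative", "orig") for i in range(4)]
        swapped = swap_descriptions(descs, [self.donor(0)], seed=5)
        assert {d.text for d in swapped} == {"endocytosis text 0"}

    def test_seed_contract(self):
        descs = [GeneDescription(f"g{i}", "narrative", "orig") for i in range(6)]
        donors = [self.donor(i) for i in range(4)]
        assert swap_descriptions(descs, donors, seed=9) == swap_descriptions(descs, donors, seed=9)

    def test_empty_pool_is_error(self):
        with pytest.raises(ValueError):
            swap_descriptions([self.donor(0)], [], seed=0)


def brute_force_mw(x, y, alternative):
    """Independent oracle: enumerate arrangements over scipy midranks."""
    pooled = list(x) + list(y)
    ranks = sps.rankdata(pooled)
    observed = ranks[: len(x)].sum()
    stats = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(len(pooled)), len(x))
    ]
    if alternative == "greater":
        return np.mean([s >= observed - 1e-9 for s in stats])
    return np.mean([s <= observed + 1e-9 for s in stats])


class TestExactMannWhitney:
    def test_worked_example_one_sixth(self):
        res = exact_mann_whitney([1, 2], [3, 4], alternative="less")
        assert res.exact
        assert res.pvalue == pytest.approx(1 / 6)

    def test_single_tied_pair(self):
        for alt in ("greater", "less"):
            assert exact_mann_whitney([5], [5], alternative=alt).pvalue == 1.0

    def test_extreme_shift_hits_combinatorial_floor(self):
        x = [100, 101, 102]
        y = [1, 2, 3, 4]
        res = exact_mann_whitney(x, y, alternative="greater")
        assert res.pvalue == pytest.approx(1 / 35)  # 1 / C(7,3)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            exact_mann_whitney([], [1], alternative="greater")

    def test_matches_enumeration_including_ties(self):
        rng = random.Random(77)
        for _ in range(60):
            nx = rng.randint(1, 5)
            ny = rng.randint(1, 10 - nx)
            x = [rng.randint(0, 4) for _ in range(nx)]  # small range: many ties
            y = [rng.randint(0, 4) for _ in range(ny)]
            for alt in ("greater", "less"):
                res = exact_mann_whitney(x, y, alternative=alt)
                assert res.exact
                assert res.pvalue == pytest.approx(brute_force_mw(x, y, alt))

    def test_matches_scipy_exact_without_ties(self):
        rng = random.Random(13)
        for _ in range(20):
            values = rng.sample(range(1000), 10)
            x, y = values[:4], values[4:]
            ours = exact_mann_whitney(x, y, alternative="greater").pvalue
            theirs = sps.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(float(theirs))

    def test_large_samples_use_flagged_approximation(self):
        x = list(range(15))
        y = list(range(5, 20))
        res = exact_mann_whitney(x, y, alternative="greater")
        assert not res.exact
        assert 0 <= res.pvalue <= 1
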