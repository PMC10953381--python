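"""Margin, occurrence, shortlist, growth correlation and the ensemble."""

import math

import numpy as np
import pandas as pd
import pytest

from loadsense import (
    ClassifierSpec,
    CVConfig,
    EnsembleConfig,
    ExpressionMatrix,
    LoadsenseError,
    PanelRecord,
    growth_correlation,
    margin,
    normalize_by_reference,
    occurrence_count,
    panel_size_study,
    run_ensemble,
    select_reference_samples,
    shortlist,
)


def margin_oracle(values, panel_rows, labels, sign_rule="strict"):
    """Brute-force double loop over all (load-stress, other) sample pairs."""
    sub = values[panel_rows, :]
    I = np.where(labels)[0]
    J = np.where(~labels)[0]
    mean_dir = np.sign(sub[:, I].mean(axis=1) - sub[:, J].mean(axis=1))
    best = math.inf
    for i in I:
        for j in J:
            diff = sub[:, i] - sub[:, j]
            d = float(np.linalg.norm(diff))
            if sign_rule == "strict":
                ok = all(
                    np.sign(dk) == mk and np.sign(dk) != 0 and mk != 0
                    for dk, mk in zip(diff, mean_dir)
                )
            else:
                ok = np.prod(np.sign(diff) * mean_dir) == 1
            best = min(best, d if ok else -d)
    return best


def expr_from_array(values):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestMargin:
    @pytest.mark.parametrize("sign_rule", ["strict", "product"])
    def test_matches_bruteforce_on_random_data(self, sign_rule):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n_samples = int(rng.integers(4, 15))
            n_genes = int(rng.integers(2, 5))
            values = rng.normal(size=(n_genes, n_samples))
            labels = np.zeros(n_samples, dtype=bool)
            labels[: int(rng.integers(1, n_samples))] = True
            labels = rng.permutation(labels)
            if labels.all() or not labels.any():
                continue
            expr = expr_from_array(values)
            panel = [f"g{i}" for i in range(n_genes)]
            got = margin(expr, panel, labels, sign_rule=sign_rule)
            want = margin_oracle(values, list(range(n_genes)), labels, sign_rule)
            assert got == pytest.approx(want, abs=1e-12)

    def test_zero_distance_pair_gives_zero(self):
        values = np.array([[1.0, 1.0, 3.0], [2.0, 2.0, 4.0]])
        expr = expr_from_array(values)
        assert margin(expr, ["g0", "g1"], np.array([True, False, False])) == 0.0

    def test_invariances(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=(3, 12))
        labels = np.array([True] * 5 + [False] * 7)
        expr = expr_from_array(values)
        base = margin(expr, ["g0", "g1", "g2"], labels)
        # gene order within the panel is irrelevant
        assert margin(expr, ["g2", "g0", "g1"], labels) == pytest.approx(base)
        # permuting samples within each class is irrelevant
        perm = np.concatenate([rng.permutation(5), 5 + rng.permutation(7)])
        expr_p = expr_from_array(values[:, perm])
        assert margin(expr_p, ["g0", "g1", "g2"], labels[perm]) == pytest.approx(base)
        # scaling expression by c > 0 scales the magnitude, keeps the sign
        expr_s = expr_from_array(3.0 * values)
        assert margin(expr_s, ["g0", "g1", "g2"], labels) == pytest.approx(3.0 * base)

    def test_missing_gene_and_empty_class_abort(self):
        expr = expr_from_array(np.zeros((2, 4)))
        with pytest.raises(LoadsenseError, match="zz"):
            margin(expr, ["zz"], np.array([True, False, False, False]))
        with pytest.raises(LoadsenseError, match="class"):
            margin(expr, ["g0"], np.array([True, True, True, True]))

    def test_planted_pair_beats_random_panels(self):
        """A strongly planted pair has positive margin, random panels do not.

        The margin is an all-pairs minimum, so its sign is governed by the
        single worst sample pair: with n1*n0 pairs and per-gene difference
        noise sd*sqrt(2), a positive margin needs the per-pair sign-flip
        probability Phi(-effect/(sd*sqrt(2))) to be small against the number
        of pairs.  The compendium here (6 x 24 pairs, effect 6x noise sd)
        satisfies that with large headroom.
        """
        from loadsense import CompendiumConfig, generate_compendium

        comp = generate_compendium(
            CompendiumConfig(
                seed=21,
                n_genes=60,
                n_studies=2,
                samples_per_study=15,
                n_reference_per_study=2,
                n_loadstress_samples=6,
                planted_genes=(0, 1),
                effect_size=3.0,
                noise_sd=0.5,
                n_gene_sets=6,
                n_imodulons=4,
            )
        )
        refs = select_reference_samples(comp.samples)
        norm = normalize_by_reference(comp.expression, comp.samples, refs)
        labels = comp.samples["is_loadstress"].to_numpy().astype(bool)
        planted = comp.truth["planted_genes"]
        planted_margin = margin(norm, planted, labels)
        assert planted_margin > 0
        rng = np.random.default_rng(0)
        others = [g for g in norm.gene_ids if g not in planted]
        random_margins = [
            margin(norm, rng.choice(others, size=2, replace=False), labels)
            for _ in range(100)
        ]
        assert planted_margin > np.median(random_margins)


class TestOccurrence:
    def test_order_insensitive_counting(self):
        counted = occurrence_count(
            [(frozenset({"a", "b"}), "M1"), (frozenset({"b", "a"}), "M2"), ({"a", "c"}, "M1")]
        )
        assert counted[frozenset({"a", "b"})] == (2, {"M1", "M2"})
        assert counted[frozenset({"a", "c"})] == (1, {"M1"})

    def test_empty_input(self):
        assert occurrence_count([]) == {}

    def test_forty_identical_runs(self):
        counted = occurrence_count([(frozenset({"dadX", "stpA"}), "RGIFE-RF")] * 40)
        assert counted[frozenset({"dadX", "stpA"})][0] == 40


class TestShortlist:
    def make_records(self):
        return [
            PanelRecord(frozenset({"nhaA", "eco"}), ["RFE-RF"], 32, 0.993, margin=0.397),
            PanelRecord(frozenset({"a", "b"}), ["RFE-SVM"], 1, 0.97, margin=0.5),
            PanelRecord(frozenset({"c", "d"}), ["RGIFE-RF"], 2, 0.99, margin=0.05),
            PanelRecord(frozenset({"e", "f"}), ["RGIFE-RF"], 5, 0.985, margin=0.397),
        ]

    def test_filter_and_sort(self):
        table = shortlist(self.make_records(), f1_min=0.98, margin_min=0.1)
        assert table["genes"].tolist() == ["eco;nhaA", "e;f"]  # margin tie -> f1 desc
        assert table["margin"].tolist() == [0.397, 0.397]

    def test_empty_records(self):
        assert shortlist([]).empty


class TestGrowthCorrelation:
    def make_inputs(self, expr_values):
        n = len(expr_values)
        growth = np.linspace(0.4, 1.0, n)
        expr = ExpressionMatrix(
            pd.DataFrame([expr_values], index=["g"], columns=[f"s{i}" for i in range(n)])
        )
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "study_id": ["A"] * n,
                "condition": ["load_stress"] * n,
                "is_reference": [False] * n,
                "is_loadstress": [True] * n,
                "growth_rate": growth,
            }
        )
        return expr, samples, growth

    def test_perfect_linear(self):
        _, samples, growth = self.make_inputs([0] * 5)
        expr, samples, growth = self.make_inputs(list(2 * growth + 1))
        r, p, reason = growth_correlation(expr, samples, "g")
        assert r == pytest.approx(1.0)
        assert reason is None

    def test_perfect_anti_linear(self):
        _, _, growth = self.make_inputs([0] * 5)
        expr, samples, _ = self.make_inputs(list(-growth))
        r, _, _ = growth_correlation(expr, samples, "g")
        assert r == pytest.approx(-1.0)

    def test_constant_expression_missing_with_reason(self):
        expr, samples, _ = self.make_inputs([1.0] * 5)
        r, p, reason = growth_correlation(expr, samples, "g")
        assert math.isnan(r) and reason == "constant_expression"

    def test_too_few_samples_abort(self):
        expr, samples, _ = self.make_inputs([1.0, 2.0])
        with pytest.raises(LoadsenseError, match=">= 3"):
            growth_correlation(expr, samples, "g")


class TestPanelSizeStudy:
    def test_grouping_and_median_oracle(self):
        records = [
            PanelRecord(frozenset({"a", "b"}), ["M"], 1, 0.9),
            PanelRecord(frozenset({"c", "d"}), ["M"], 1, 0.8),
            PanelRecord(frozenset({"e", "f", "g"}), ["M"], 1, 0.7),
        ]
        summary = panel_size_study(records)
        pooled = summary[summary["model"] == "all"].set_index("size")
        assert pooled.loc[2, "count"] == 2 and pooled.loc[3, "count"] == 1
        # sort-based median oracle
        vals = sorted([0.9, 0.8])
        assert pooled.loc[2, "median"] == pytest.approx(sum(vals) / 2)
        assert pooled.loc[3, "median"] == pytest.approx(0.7)

    def test_empty(self):
        assert panel_size_study([]).empty


@pytest.fixture(scope="module")
def normalized(small_compendium):
    comp = small_compendium
    refs = select_reference_samples(comp.samples)
    return comp, normalize_by_reference(comp.expression, comp.samples, refs)


class TestRunEnsemble:

    def scaled_config(self, seed=0):
        return EnsembleConfig(
            rfe_sizes=(2,),
            rfe_repetitions=2,
            rgife_repetitions=2,
            size_retention=(2, 6),
            base_seed=seed,
        )

    def test_scaled_down_contract_and_determinism(self, normalized):
        comp, norm = normalized
        clf = [ClassifierSpec("linear_svm")]
        cv = CVConfig(n_folds=10)
        records = run_ensemble(norm, comp.samples, self.scaled_config(), classifiers=clf, cv=cv)
        assert records
        for rec in records:
            assert 2 <= rec.size <= 6
            assert set(rec.genes) <= set(norm.gene_ids)
            assert 0.0 <= rec.f1 <= 1.0
            assert rec.occurrence >= 1
        again = run_ensemble(norm, comp.samples, self.scaled_config(), classifiers=clf, cv=cv)
        assert [(r.genes, r.occurrence, r.f1) for r in records] == [
            (r.genes, r.occurrence, r.f1) for r in again
        ]
        # occurrences sum to the number of retained selections
        assert sum(r.occurrence for r in records) >= len(records)

    def test_identical_panels_merge(self):
        counted = occurrence_count(
            [(frozenset({"x", "y"}), "RGIFE-RF"), (frozenset({"y", "x"}), "RFE-RF")]
        )
        occ, labels = counted[frozenset({"x", "y"})]
        assert occ == 2 and labels == {"RGIFE-RF", "RFE-RF"}
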