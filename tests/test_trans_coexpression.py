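"""Co-expression network, module detection, archetypes, enrichment."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from saltlnc import expression_de as de
from saltlnc import synthetic_data as sd
from saltlnc import trans_coexpression as tc


def hypergeom_tail_oracle(k, K, N_cat, N):
    """P(X >= k), X ~ Hypergeometric(N, N_cat, K), from binomial coefficients."""
    total = comb(N, K)
    return sum(
        comb(N_cat, x) * comb(N - N_cat, K - x)
        for x in range(k, min(K, N_cat) + 1)
    ) / total


class TestZscore:
    def test_simple_profile_scales_to_unit_sd(self):
        z = tc.zscore_profiles(pd.DataFrame([[1.0, 2.0, 3.0, 4.0]]))
        row = z.to_numpy()[0]
        assert row.mean() == pytest.approx(0.0, abs=1e-12)
        assert row.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_profile_becomes_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = tc.zscore_profiles(pd.DataFrame([[2.0, 2.0, 2.0, 2.0]]))
        assert (z.to_numpy() == 0).all()

    def test_random_rows_recompute(self, rng):
        mat = pd.DataFrame(rng.normal(size=(50, 4)))
        z = tc.zscore_profiles(mat).to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1, atol=1e-12)


class TestNetwork:
    def test_identical_profiles_have_unit_adjacency_and_tom(self):
        profiles = pd.DataFrame([[1, 2, 3, 4], [2, 4, 6, 8]], dtype=float)
        a = tc.soft_adjacency(profiles)
        assert a.iloc[0, 1] == pytest.approx(1.0)
        tom = tc.topological_overlap(a)
        assert tom.iloc[0, 1] == pytest.approx(1.0)
        assert tom.iloc[0, 0] == 1.0

    def test_orthogonal_profiles_have_zero_overlap(self):
        profiles = pd.DataFrame([[1, -1, 1, -1], [1, 1, -1, -1]], dtype=float)
        a = tc.soft_adjacency(profiles)
        assert a.iloc[0, 1] == pytest.approx(0.0)
        assert tc.topological_overlap(a).iloc[0, 1] == pytest.approx(0.0)

    def test_tom_matches_triple_loop_oracle(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(20, 4)))
        a = tc.soft_adjacency(profiles).to_numpy()
        tom = tc.topological_overlap(tc.soft_adjacency(profiles)).to_numpy()
        n = len(a)
        k = [sum(a[i][u] for u in range(n)) for i in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert tom[i][j] == 1.0
                    continue
                num = sum(a[i][u] * a[u][j] for u in range(n)) + a[i][j]
                den = min(k[i], k[j]) + 1 - a[i][j]
                assert tom[i][j] == pytest.approx(num / den, abs=1e-10)

    def test_tom_symmetry_and_range(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(30, 4)))
        tom = tc.topological_overlap(tc.soft_adjacency(profiles)).to_numpy()
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12

    def test_zero_variance_profile_excluded_with_warning(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(5, 4)), index=list("abcde"))
        profiles.loc["c"] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            a = tc.soft_adjacency(profiles)
        assert "c" not in a.index

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError, match="3 conditions"):
            tc.soft_adjacency(pd.DataFrame([[1.0, 2.0]]))


class TestModules:
    def _planted_blocks(self, rng, n_per_block=15, noise=0.35):
        # mutually orthogonal zero-mean shapes of equal amplitude: between-
        # block correlation ~0, within-block ~0.95 at this noise level
        shapes = np.array(
            [[-3, -1, 1, 3], [1, -1, -1, 1], [-1, 3, -3, 1]], dtype=float
        )
        shapes = 3.0 * shapes / np.linalg.norm(shapes, axis=1, keepdims=True)
        rows, names = [], []
        for b, shape in enumerate(shapes):
            for i in range(n_per_block):
                rows.append(shape + rng.normal(0, noise, size=4))
                names.append(f"b{b}_{i}")
        return pd.DataFrame(rows, index=names)

    def test_recovers_three_planted_blocks(self, rng):
        profiles = tc.zscore_profiles(self._planted_blocks(rng))
        tom = tc.topological_overlap(tc.soft_adjacency(profiles))
        modules = tc.detect_modules(tom, profiles, min_module_size=10)
        assert len(modules) == 3
        for m in modules:
            blocks = {name.split("_")[0] for name in m.members}
            assert len(blocks) == 1

    def test_identical_profiles_collapse_to_one_module(self):
        profiles = pd.DataFrame(
            np.tile([1.0, 2.0, 3.0, 4.0], (12, 1)),
            index=[f"f{i}" for i in range(12)],
        )
        tom = tc.topological_overlap(tc.soft_adjacency(profiles))
        modules = tc.detect_modules(tom, profiles)
        assert len(modules) == 1 and len(modules[0].members) == 12

    def test_memberships_invariant_to_feature_order(self, rng):
        profiles = tc.zscore_profiles(self._planted_blocks(rng))
        perm = profiles.sample(frac=1, random_state=3)
        def memberships(p):
            tom = tc.topological_overlap(tc.soft_adjacency(p))
            return {
                frozenset(m.members)
                for m in tc.detect_modules(tom, p, min_module_size=10)
            }
        assert memberships(profiles) == memberships(perm)


class TestArchetypes:
    def test_centroid_equal_to_reference_gets_its_label(self):
        refs = tc.archetype_references()
        for name in refs.index:
            m = tc.CoexpressionModule("m", ["x"], refs.loc[name].to_numpy())
            tc.assign_archetypes([m])
            assert m.archetype == name

    def test_negated_reference_is_not_matched_to_itself(self):
        refs = tc.archetype_references()
        m = tc.CoexpressionModule("m", ["x"], -refs.loc["M1"].to_numpy())
        tc.assign_archetypes([m])
        assert m.archetype != "M1"

    def test_weakly_correlated_centroid_stays_unassigned(self):
        m = tc.CoexpressionModule("m", ["x"], np.array([1.0, -1.0, 1.0, -1.0]))
        tc.assign_archetypes([m])
        assert m.archetype == "unassigned"

    def test_planted_archetype_groups_label_correctly(self, small_dataset):
        truth = small_dataset.truth
        em = de.ExpressionMatrix(
            small_dataset.counts, small_dataset.conditions, small_dataset.lengths()
        )
        profiles = tc.zscore_profiles(
            em.condition_means().loc[sorted(truth.de_archetype)]
        )
        for arch in sorted(set(truth.de_archetype.values())):
            members = [f for f, a in truth.de_archetype.items() if a == arch]
            module = tc.CoexpressionModule(
                "m", members, profiles.loc[members].mean(axis=0).to_numpy()
            )
            tc.assign_archetypes([module])
            assert module.archetype == arch


class TestEnrichment:
    def test_worked_hypergeometric_example(self):
        # module of 10 with 5 hits in a category of 10 within background 100
        cats = {f"g{i}": ("hit" if i < 10 else "other") for i in range(100)}
        module = tc.CoexpressionModule(
            "m", [f"g{i}" for i in range(5)] + [f"g{i}" for i in range(50, 55)],
            np.zeros(4),
        )
        results = {r.category: r for r in tc.enrich_categories(module, cats)}
        expected = hypergeom_tail_oracle(5, 10, 10, 100)
        assert results["hit"].p == pytest.approx(expected, rel=1e-9)

    def test_category_absent_from_module_gives_p_one(self):
        cats = {"a": "x", "b": "y", "c": "y"}
        module = tc.CoexpressionModule("m", ["b"], np.zeros(4))
        results = {r.category: r for r in tc.enrich_categories(module, cats)}
        assert results["x"].p == pytest.approx(1.0)

    def test_module_equal_to_background_gives_p_one_everywhere(self):
        cats = {f"g{i}": ("x" if i % 2 else "y") for i in range(20)}
        module = tc.CoexpressionModule("m", list(cats), np.zeros(4))
        for r in tc.enrich_categories(module, cats):
            assert r.p == pytest.approx(1.0)

    def test_fisher_matches_oracle_on_exhaustive_small_tables(self):
        cats_template = None
        for N in range(2, 16):
            for n_cat in range(0, N + 1):
                for K in range(0, N + 1):
                    cats = {
                        f"g{i}": ("hit" if i < n_cat else "other") for i in range(N)
                    }
                    for k in range(max(0, K + n_cat - N), min(K, n_cat) + 1):
                        members = [f"g{i}" for i in range(k)] + [
                            f"g{i}" for i in range(n_cat, n_cat + K - k)
                        ]
                        module = tc.CoexpressionModule("m", members, np.zeros(4))
                        res = {
                            r.category: r for r in tc.enrich_categories(module, cats)
                        }
                        if "hit" not in res:
                            continue
                        expected = hypergeom_tail_oracle(k, K, n_cat, N)
                        assert res["hit"].p == pytest.approx(expected, rel=1e-9)

    def test_planted_covarying_genes_enrich_their_signature_category(
        self, default_dataset
    ):
        """Genes planted to co-vary with an archetype's lncRNAs carry its
        signature category often enough that the group tests significant."""
        truth = default_dataset.truth
        cats = {
            tid: g.functional_category
            for tid, g in zip(truth.coding_ids, default_dataset.annotation.genes)
            if tid in truth.de_archetype
        }
        for arch, signature in sd.ARCHETYPE_SIGNATURE_CATEGORY.items():
            members = [
                f for f, a in truth.de_archetype.items() if a == arch and f in cats
            ]
            module = tc.CoexpressionModule(f"m_{arch}", members, np.zeros(4))
            results = tc.enrich_categories(module, cats)
            assert signature in tc.significant_categories(results)
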