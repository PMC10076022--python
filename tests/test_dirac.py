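import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metacrit.dirac import (
    differential_rci,
    dirac_table,
    divergence_summary,
    matching_score,
    rank_template,
    rci,
    rmsd_divergence,
)
from metacrit.io import GeneSetCollection

from conftest import expr_from
from oracles import matching_score_oracle, rank_template_oracle, rci_oracle, rmsd_oracle


class TestRankTemplate:
    def test_unanimous_ordering(self):
        m = expr_from([[3, 3, 3], [2, 2, 2], [1, 1, 1]])
        t = rank_template(m, m.sample_ids, m.gene_ids)
        assert set(t.ordered_pairs) == {("g0", "g1"), ("g0", "g2"), ("g1", "g2")}

    def test_exact_tie_orients_lexicographically(self):
        m = expr_from([[1, 2], [2, 1]], genes=["a", "b"])
        t = rank_template(m, m.sample_ids, ["a", "b"])
        assert t.ordered_pairs == [("a", "b")]

    def test_matches_bruteforce_majority(self, rng):
        m = expr_from(rng.normal(size=(6, 50)))
        t = rank_template(m, m.sample_ids, m.gene_ids)
        assert sorted(t.ordered_pairs) == sorted(
            rank_template_oracle(m.data, m.sample_ids)
        )

    def test_too_few_genes_errors(self):
        m = expr_from([[1, 2]])
        with pytest.raises(ValueError, match="fewer than 2"):
            rank_template(m, m.sample_ids, ["g0"], pathway="P")


class TestMatchingScore:
    def test_perfect_and_inverted(self):
        m = expr_from([[3, 3], [2, 2], [1, 1]])
        t = rank_template(m, m.sample_ids, m.gene_ids)
        assert matching_score({"g0": 9, "g1": 5, "g2": 1}, t) == 1.0
        assert matching_score({"g0": 1, "g1": 5, "g2": 9}, t) == 0.0

    def test_ties_count_as_unsatisfied(self):
        m = expr_from([[3, 3], [2, 2]])
        t = rank_template(m, m.sample_ids, m.gene_ids)
        assert matching_score({"g0": 1.0, "g1": 1.0}, t) == 0.0

    def test_partial_match_fraction(self, rng):
        m = expr_from(rng.normal(size=(4, 30)))
        t = rank_template(m, m.sample_ids, m.gene_ids)
        sample = pd.Series(rng.normal(size=4), index=m.gene_ids)
        assert matching_score(sample, t) == pytest.approx(
            matching_score_oracle(sample, t.ordered_pairs)
        )


class TestRCI:
    def test_shared_ordering_gives_one(self, rng):
        base = np.sort(rng.normal(size=5))[::-1]
        m = expr_from(np.tile(base[:, None], 8) + 0.01 * np.arange(8))
        res = rci(m, {"grp": m.sample_ids}, m.gene_ids)
        assert res.rci_by_group["grp"] == 1.0

    def test_matches_oracle_on_random_groups(self, rng):
        m = expr_from(rng.normal(size=(5, 12)))
        groups = {"a": m.sample_ids[:6], "b": m.sample_ids[6:]}
        res = rci(m, groups, m.gene_ids)
        for g, samples in groups.items():
            assert res.rci_by_group[g] == pytest.approx(
                rci_oracle(m.data, samples), abs=1e-12
            )

    def test_monotone_transform_invariance(self, rng):
        m = expr_from(rng.normal(size=(6, 20)))
        groups = {"a": m.sample_ids[:10], "b": m.sample_ids[10:]}
        base = rci(m, groups, m.gene_ids)
        mapped = expr_from(np.exp(m.values) * 3.0 + 1.0)
        again = rci(mapped, groups, mapped.gene_ids)
        assert base.rci_by_group == again.rci_by_group

    def test_own_template_beats_foreign_template(self, rng):
        m = expr_from(rng.normal(size=(5, 40)))
        own_samples = m.sample_ids[:20]
        own = rank_template(m, own_samples, m.gene_ids)
        foreign = rank_template(m, m.sample_ids[20:], m.gene_ids)
        own_scores = np.mean([matching_score(m.data[s], own) for s in own_samples])
        foreign_scores = np.mean(
            [matching_score(m.data[s], foreign) for s in own_samples]
        )
        assert own_scores >= foreign_scores


class TestDifferentialRCI:
    def test_identical_groups_give_p_one(self, rng):
        m = expr_from(rng.normal(size=(4, 12)))
        res = differential_rci(
            m, m.sample_ids[:6], m.sample_ids[:6], m.gene_ids,
            n_perm=100, seed=0,
        )
        assert res.rci_by_group["a"] == res.rci_by_group["b"]
        assert res.p_value == 1.0

    def test_planted_deregulation_detected(self, rng):
        detected = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            base = np.sort(r.normal(size=6))[::-1]
            a = base[:, None] + 0.3 * r.normal(size=(6, 25))
            b = np.empty((6, 25))
            for j in range(25):           # group b: ordering scrambled per sample
                b[:, j] = r.permutation(base) + 0.3 * r.normal(size=6)
            m = expr_from(np.hstack([a, b]))
            res = differential_rci(
                m, m.sample_ids[:25], m.sample_ids[25:], m.gene_ids,
                n_perm=300, seed=seed,
            )
            detected += res.p_value <= 0.01
        assert detected >= 9

    def test_table_applies_bh_across_pathways(self, rng):
        m = expr_from(rng.normal(size=(8, 20)))
        sets = GeneSetCollection({
            "P1": ("", [f"g{i}" for i in range(4)]),
            "P2": ("", [f"g{i}" for i in range(4, 8)]),
        })
        table = dirac_table(m, sets, m.sample_ids[:10], m.sample_ids[10:],
                            n_perm=100, seed=0)
        assert set(table.index) == {"P1", "P2"}
        assert ((table["q_value"] >= 0) & (table["q_value"] <= 1)).all()


class TestRMSD:
    def test_identity_is_zero(self):
        assert rmsd_divergence([2.0, 5.0], [2.0, 5.0]) == 0.0

    def test_printed_example(self):
        assert rmsd_divergence([4.0, 4.0], [1.0, 1.0]) == pytest.approx(2.0)

    def test_matches_oracle(self, rng):
        x = rng.uniform(0.5, 20, size=30)
        y = rng.uniform(0.5, 20, size=30)
        assert rmsd_divergence(x, y) == pytest.approx(rmsd_oracle(x, y), abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_metric_properties_on_log_profiles(self, seed):
        r = np.random.default_rng(seed)
        x, y, z = r.uniform(0.5, 16, size=(3, 10))
        dxy = rmsd_divergence(x, y)
        assert dxy == pytest.approx(rmsd_divergence(y, x), abs=1e-12)
        assert dxy <= rmsd_divergence(x, z) + rmsd_divergence(z, y) + 1e-12

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rmsd_divergence([1.0, 0.0], [1.0, 1.0])


class TestDivergenceSummary:
    def test_enumerated_two_by_two(self, rng):
        m = expr_from(rng.normal(size=(6, 4)))
        groups = {"t": ["s0", "s1"], "n": ["s2", "s3"]}
        s = divergence_summary(m, groups)
        X = m.values

        def d(i, j):
            return np.sqrt(np.mean((X[:, i] - X[:, j]) ** 2))

        assert s.within_group_mean["t"] == pytest.approx(d(0, 1), abs=1e-12)
        assert s.within_group_mean["n"] == pytest.approx(d(2, 3), abs=1e-12)
        expected_between = np.mean([d(0, 2), d(0, 3), d(1, 2), d(1, 3)])
        assert s.between_group_mean == pytest.approx(expected_between, abs=1e-12)
        assert s.percentages["between"] == 100.0

    def test_degenerate_all_identical(self):
        m = expr_from(np.ones((4, 4)))
        with pytest.warns(UserWarning, match="percentages undefined"):
            s = divergence_summary(m, {"a": ["s0", "s1"], "b": ["s2", "s3"]})
        assert s.degenerate and s.percentages["between"] == 0.0

    def test_dispersed_and_displaced_tumors_order(self):
        """Tumors displaced from normals and more dispersed reproduce the
        between > within-tumor > within-normal distance pattern."""
        ok = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            G = 200
            mu = r.uniform(4, 12, G)
            shift = r.normal(0, 2.0, G)
            normal = mu[:, None] + 0.3 * r.standard_normal((G, 12))
            tumor = (mu + shift)[:, None] + 1.2 * r.standard_normal((G, 20))
            m = expr_from(np.hstack([normal, tumor]))
            groups = {"tumor": m.sample_ids[12:], "normal": m.sample_ids[:12]}
            s = divergence_summary(m, groups)
            ok += (
                s.between_group_mean
                > s.within_group_mean["tumor"]
                > s.within_group_mean["normal"]
            )
        assert ok >= 19
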