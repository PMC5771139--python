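"""Differential expression: t-test/ANOVA rules, BH, z-scores, clustering, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlpquant import (
    ValidationError,
    anova_dep,
    bh_adjust,
    exclusive_deps,
    hierarchical_cluster,
    overlap_comparison,
    ttest_dep,
    znormalize,
)


def matrix_from_groups(groups: dict[tuple[str, int], np.ndarray]) -> pd.DataFrame:
    """rows x replicate values per (genotype, age) group -> abundance matrix."""
    cols, data = [], []
    for (genotype, age), block in groups.items():
        block = np.atleast_2d(block)
        for r in range(block.shape[1]):
            cols.append((genotype, age, r + 1))
            data.append(block[:, r])
    frame = pd.DataFrame(np.column_stack(data))
    frame.columns = pd.MultiIndex.from_tuples(
        cols, names=["genotype", "age_months", "replicate"]
    )
    frame.index = pd.Index([f"P{i}" for i in range(len(frame))], name="accession")
    return frame


class TestBHAdjust:
    def test_hand_enumerated_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_saturated(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValidationError):
            bh_adjust([])

    @staticmethod
    def brute_force(p):
        """Literal definition: adj_i = min over j with p_j >= p_i of p_j * m / rank_j."""
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        rank = {idx: pos + 1 for pos, idx in enumerate(order)}
        out = []
        for i in range(m):
            candidates = [
                p[j] * m / rank[j] for j in range(m) if rank[j] >= rank[i]
            ]
            out.append(min(1.0, min(candidates)))
        return out

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), self.brute_force(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(50)
            np.testing.assert_allclose(
                bh_adjust(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    def test_adjusted_at_least_raw(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)


class TestTTest:
    def test_hand_oracle_strong_effect(self):
        matrix = matrix_from_groups({
            ("APT", 10): np.array([[2.0, 2.1, 1.9]]),
            ("WT", 10): np.array([[1.0, 1.1, 0.9]]),
        })
        res = ttest_dep(matrix, "APT", 10)
        assert res.loc["P0", "fold_change"] == pytest.approx(2.0)
        # pooled-variance Student's t = 12.2474, df = 4
        assert res.loc["P0", "p_value"] == pytest.approx(2.552167494419268e-4, rel=1e-9)
        assert bool(res.loc["P0", "significant"])

    def test_identical_groups_not_significant(self):
        matrix = matrix_from_groups({
            ("Tau", 4): np.array([[1.0, 1.2, 0.8]]),
            ("WT", 4): np.array([[1.0, 1.2, 0.8]]),
        })
        res = ttest_dep(matrix, "Tau", 4)
        assert res.loc["P0", "fold_change"] == pytest.approx(1.0)
        assert not bool(res.loc["P0", "significant"])

    def test_zero_variance_equal_means_p_is_one(self):
        matrix = matrix_from_groups({
            ("APT", 7): np.array([[1.0, 1.0, 1.0]]),
            ("WT", 7): np.array([[1.0, 1.0, 1.0]]),
        })
        res = ttest_dep(matrix, "APT", 7)
        assert res.loc["P0", "p_value"] == 1.0
        assert not bool(res.loc["P0", "significant"])

    def test_fold_change_gate_blocks_tiny_effects(self):
        matrix = matrix_from_groups({
            ("APT", 10): np.array([[1.100, 1.101, 1.099]]),
            ("WT", 10): np.array([[1.000, 1.001, 0.999]]),
        })
        res = ttest_dep(matrix, "APT", 10)
        assert res.loc["P0", "p_value"] < 0.01
        assert not bool(res.loc["P0", "significant"])  # FC 1.10 < 1.25

    def test_symmetric_rule_catches_downregulation(self):
        matrix = matrix_from_groups({
            ("APT", 10): np.array([[0.50, 0.52, 0.48]]),
            ("WT", 10): np.array([[1.0, 1.05, 0.95]]),
        })
        res = ttest_dep(matrix, "APT", 10)
        assert res.loc["P0", "fold_change"] < 1
        assert bool(res.loc["P0", "significant"])

    def test_single_replicate_rejected(self):
        matrix = matrix_from_groups({
            ("APT", 10): np.array([[2.0]]), ("WT", 10): np.array([[1.0, 1.1]]),
        })
        with pytest.raises(ValidationError, match="replicates"):
            ttest_dep(matrix, "APT", 10)


class TestAnova:
    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(0)
        matrix = matrix_from_groups({
            ("APT", 10): rng.lognormal(0.2, 0.3, size=(50, 3)),
            ("WT", 10): rng.lognormal(0.0, 0.3, size=(50, 3)),
        })
        anova = anova_dep(matrix, [("WT", 10), ("APT", 10)])
        ttest = ttest_dep(matrix, "APT", 10)
        np.testing.assert_allclose(
            anova["p_value"].to_numpy(), ttest["p_value"].to_numpy(), rtol=1e-9
        )

    def test_constant_rows_have_zero_f(self):
        matrix = matrix_from_groups({
            ("WT", 4): np.array([[1.0, 1.0], [1.0, 2.0]]),
            ("APT", 4): np.array([[1.0, 1.0], [3.0, 4.0]]),
        })
        res = anova_dep(matrix, [("WT", 4), ("APT", 4)])
        assert res.loc["P0", "f_statistic"] == 0.0
        assert res.loc["P0", "p_value"] == 1.0
        assert not bool(res.loc["P0", "significant"])

    def test_single_group_rejected(self):
        matrix = matrix_from_groups({("WT", 4): np.array([[1.0, 2.0]])})
        with pytest.raises(ValidationError, match="2 groups"):
            anova_dep(matrix, [("WT", 4)])

    def test_adjusted_p_dominates_raw(self):
        rng = np.random.default_rng(5)
        matrix = matrix_from_groups({
            ("WT", 4): rng.lognormal(0, 0.2, (100, 3)),
            ("Tau", 4): rng.lognormal(0, 0.2, (100, 3)),
            ("APT", 4): rng.lognormal(0, 0.2, (100, 3)),
        })
        res = anova_dep(matrix, [("WT", 4), ("Tau", 4), ("APT", 4)])
        assert (res["adjusted_p"] >= res["p_value"] - 1e-15).all()


class TestZNormalize:
    def test_simple_row(self):
        frame = pd.DataFrame([[1.0, 2.0, 3.0]], index=["P0"])
        np.testing.assert_allclose(znormalize(frame).loc["P0"], [-1.0, 0.0, 1.0])

    def test_constant_row_maps_to_zeros(self):
        frame = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["A", "B"])
        out = znormalize(frame)
        np.testing.assert_array_equal(out.loc["A"], 0.0)

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(rng.normal(3, 2, size=(40, 12)))
        out = znormalize(frame)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, rtol=1e-12)


class TestHierarchicalCluster:
    def test_separable_profiles_split_perfectly(self):
        up = np.tile([[-1.0, 0.0, 1.0]], (6, 1))
        down = np.tile([[1.0, 0.0, -1.0]], (4, 1))
        frame = pd.DataFrame(np.vstack([up, down]),
                             index=[f"P{i}" for i in range(10)])
        result = hierarchical_cluster(frame, k=2)
        assert set(result.labels.iloc[:6]) == {1}  # larger cluster numbered first
        assert set(result.labels.iloc[6:]) == {2}
        np.testing.assert_allclose(result.profiles.loc[1], [-1.0, 0.0, 1.0])

    def test_k_one_and_invalid_k(self):
        frame = pd.DataFrame(np.eye(4))
        assert (hierarchical_cluster(frame, k=1).labels == 1).all()
        with pytest.raises(ValidationError):
            hierarchical_cluster(frame, k=0)
        with pytest.raises(ValidationError):
            hierarchical_cluster(frame, k=5)

    def test_noiseless_archetypes_recovered(self, noiseless_dataset):
        from adlpquant import (
            compute_normalized_abundance,
            filter_quantifiable,
            merge_technical_duplicates,
            spikein_normalize,
        )

        table, design, truth = noiseless_dataset
        filtered, _ = filter_quantifiable(
            merge_technical_duplicates(spikein_normalize(table, design)), design
        )
        matrix = compute_normalized_abundance(filtered, design)
        result = hierarchical_cluster(znormalize(matrix), k=3)
        archetypes = truth.archetype.loc[result.labels.index]
        # every cluster is archetype-pure and every archetype is one cluster
        table_ = pd.crosstab(result.labels, archetypes)
        assert (table_.gt(0).sum(axis=1) == 1).all()
        assert (table_.gt(0).sum(axis=0) == 1).all()


class TestExclusiveDeps:
    @staticmethod
    def _result(sig: dict[str, bool], fc: dict[str, float]) -> pd.DataFrame:
        idx = pd.Index(sorted(sig), name="accession")
        return pd.DataFrame(
            {"fold_change": [fc[a] for a in idx], "p_value": 0.01,
             "significant": [sig[a] for a in idx]},
            index=idx,
        )

    def _fold_changes(self, values: dict[str, dict[tuple[str, int], float]]):
        cols = pd.MultiIndex.from_tuples(
            sorted({c for v in values.values() for c in v}),
            names=["genotype", "age_months"],
        )
        frame = pd.DataFrame(
            [[values[a][c] for c in cols] for a in sorted(values)],
            index=pd.Index(sorted(values), name="accession"), columns=cols,
        )
        return frame

    def test_rule_enumeration_on_toys(self):
        # A: sig in APT, quiet elsewhere -> kept.  B: sig in APT but APP/PS1
        # FC 1.4 -> dropped.  C: not significant in APT -> dropped.
        results = {
            "APT": {
                4: self._result({"A": True, "B": True, "C": False},
                                {"A": 1.6, "B": 1.5, "C": 1.0}),
                10: self._result({"A": False, "B": False, "C": False},
                                 {"A": 1.1, "B": 1.1, "C": 1.0}),
            },
            "APP_PS1": {4: None, 10: None},
            "Tau": {4: None, 10: None},
        }
        fc = self._fold_changes({
            "A": {("APP_PS1", 4): 1.05, ("Tau", 4): 1.10,
                  ("APP_PS1", 10): 1.0, ("Tau", 10): 1.0},
            "B": {("APP_PS1", 4): 1.40, ("Tau", 4): 1.05,
                  ("APP_PS1", 10): 1.0, ("Tau", 10): 1.0},
            "C": {("APP_PS1", 4): 1.0, ("Tau", 4): 1.0,
                  ("APP_PS1", 10): 1.0, ("Tau", 10): 1.0},
        })
        assert exclusive_deps(results, fc) == {"A"}

    def test_downregulation_in_other_model_also_excludes(self):
        results = {
            "APT": {4: self._result({"A": True}, {"A": 1.6}),
                    10: self._result({"A": False}, {"A": 1.0})},
            "APP_PS1": {}, "Tau": {},
        }
        fc = self._fold_changes({
            "A": {("APP_PS1", 4): 0.70, ("Tau", 4): 1.0,  # 1/0.7 > 1.25
                  ("APP_PS1", 10): 1.0, ("Tau", 10): 1.0},
        })
        assert exclusive_deps(results, fc) == set()

    def test_subset_and_monotone_in_fc_cut(self, dataset):
        from adlpquant import (
            compute_fold_change,
            compute_normalized_abundance,
            filter_quantifiable,
            merge_technical_duplicates,
            spikein_normalize,
        )

        table, design, _ = dataset
        filtered, _ = filter_quantifiable(
            merge_technical_duplicates(spikein_normalize(table, design)), design
        )
        matrix = compute_normalized_abundance(filtered, design)
        fc = compute_fold_change(matrix, design)
        results = {
            g: {a: ttest_dep(matrix, g, a) for a in (4, 10)}
            for g in ("APP_PS1", "Tau", "APT")
        }
        apt_sig = set()
        for a in (4, 10):
            r = results["APT"][a]
            apt_sig |= set(r.index[r["significant"]])
        loose = exclusive_deps(results, fc, fc_cut=1.25)
        tight = exclusive_deps(results, fc, fc_cut=1.10)
        assert loose <= apt_sig
        assert tight <= loose  # shrinks as the quiet threshold tightens

    def test_missing_model_reported(self):
        results = {"APT": {4: self._result({"A": True}, {"A": 1.6}),
                           10: self._result({"A": True}, {"A": 1.6})}}
        with pytest.raises(ValidationError, match="other model"):
            exclusive_deps(results, pd.DataFrame())


class TestOverlapComparison:
    def test_identical_lists(self):
        summary = overlap_comparison({"A": "up", "B": "down"}, {"A": "up", "B": "down"})
        assert summary.overlap_percent == 100.0
        assert summary.concordance_percent == {"down": 100.0, "up": 100.0}

    def test_disjoint_lists(self):
        assert overlap_comparison(["A"], ["B"]).overlap_percent == 0.0

    def test_mixed_direction_enumeration(self):
        summary = overlap_comparison(
            {"A": "up", "B": "up", "C": "down"},
            {"A": "up", "B": "down", "C": "down"},
        )
        assert summary.n_shared == 3
        assert summary.concordance_percent["up"] == pytest.approx(50.0)
        assert summary.concordance_percent["down"] == pytest.approx(100.0)
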