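"""Depth screening, intersection, clustering with bootstrap support."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from oceancog import (
    COGCountMatrix,
    ColumnDesign,
    DatasetMetadata,
    ValidationError,
    cluster_datasets,
    column_depth_cogs,
    intersect_depth_cogs,
    photic_label,
)


def make_matrix(arr, n_ds=None):
    arr = np.asarray(arr)
    cols = [f"d{j}" for j in range(arr.shape[1])]
    counts = pd.DataFrame(
        arr, index=pd.Index([f"COG{i:04d}" for i in range(arr.shape[0])],
                            name="cog_id"),
        columns=cols,
    )
    return COGCountMatrix(counts, counts.sum(axis=0))


class TestColumnScreen:
    def test_equal_columns_yield_empty_set(self):
        arr = np.tile([[100], [200], [50]], (1, 4))
        m = make_matrix(arr)
        col = ColumnDesign("x", ("d0", "d1", "d2", "d3"))
        res = column_depth_cogs(m, col, alpha=0.01)
        assert res.cog_ids == []

    def test_strong_single_cog_detected(self):
        rng = np.random.default_rng(0)
        base = rng.multinomial(50_000, np.full(1000, 1e-3), size=4).T
        arr = base.copy()
        arr[0, 0] = 500  # ~10x the ~50 expected elsewhere
        m = make_matrix(arr)
        res = column_depth_cogs(m, ColumnDesign("x", ("d0", "d1", "d2", "d3")))
        assert "COG0000" in res.cog_ids
        best = res.table[res.table["cog_id"] == "COG0000"]["p_adjusted"].min()
        assert best < 1e-6

    def test_permutation_invariant_to_cog_order(self):
        rng = np.random.default_rng(1)
        arr = rng.multinomial(5000, np.full(50, 0.02), size=3).T
        arr[3] *= 3
        m = make_matrix(arr)
        col = ColumnDesign("x", ("d0", "d1", "d2"))
        res = column_depth_cogs(m, col)
        perm = rng.permutation(50)
        m2 = COGCountMatrix(m.counts.iloc[perm], m.library_size)
        res2 = column_depth_cogs(m2, col)
        assert res.cog_ids == res2.cog_ids

    def test_missing_dataset_rejected(self, small_matrix):
        with pytest.raises(ValidationError):
            column_depth_cogs(small_matrix, ColumnDesign("x", ("ds1", "nope")))

    def test_binomial_flavor_agrees_on_strong_signal(self):
        arr = np.array([[500, 50], [49_500, 49_950]])
        m = make_matrix(arr)
        col = ColumnDesign("x", ("d0", "d1"))
        fisher = column_depth_cogs(m, col, test="fisher")
        binom = column_depth_cogs(m, col, test="binomial")
        assert "COG0000" in fisher.cog_ids
        assert "COG0000" in binom.cog_ids


class TestIntersect:
    def make_set(self, site, cogs):
        from oceancog.depth import DepthCOGSet

        return DepthCOGSet(site=site, cog_ids=sorted(cogs),
                           table=pd.DataFrame(), alpha=0.01)

    def test_simple_intersection(self):
        sets = [self.make_set("a", {"A", "B"}), self.make_set("b", {"B", "C"}),
                self.make_set("c", {"B"})]
        assert intersect_depth_cogs(sets) == ["B"]

    def test_result_subset_of_inputs(self):
        rng = np.random.default_rng(2)
        universes = [set(rng.choice(30, 12, replace=False)) for _ in range(3)]
        sets = [self.make_set(str(i), {f"C{j}" for j in u})
                for i, u in enumerate(universes)]
        inter = set(intersect_depth_cogs(sets))
        for s in sets:
            assert inter <= set(s.cog_ids)

    def test_disjoint_sets_empty(self):
        sets = [self.make_set("a", {"A"}), self.make_set("b", {"B"})]
        assert intersect_depth_cogs(sets) == []

    def test_presence_filter(self):
        sets = [self.make_set("a", {"COG0000", "COG0001"}),
                self.make_set("b", {"COG0000", "COG0001"})]
        arr = np.array([[5, 5, 0, 0], [3, 3, 3, 3]])
        m = make_matrix(arr)
        cols = [ColumnDesign("a", ("d0", "d1")), ColumnDesign("b", ("d2", "d3"))]
        out = intersect_depth_cogs(sets, presence=m, columns=cols)
        assert out == ["COG0001"]  # COG0000 absent from column b


class TestClustering:
    def planted_z(self, seed=0, sep=10.0, n_cogs=60):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=(n_cogs, 6))
        b = rng.normal(sep, 1.0, size=(n_cogs, 6))
        df = pd.DataFrame(
            np.hstack([a, b]),
            index=[f"C{i}" for i in range(n_cogs)],
            columns=[f"g1_{j}" for j in range(6)] + [f"g2_{j}" for j in range(6)],
        )
        return df

    def test_planted_partition_high_support(self):
        z = self.planted_z()
        dendro = cluster_datasets(z, n_boot=100, seed=1)
        left, right = dendro.top_split()
        groups = {frozenset(c for c in z.columns if c.startswith("g1"))}
        groups.add(frozenset(c for c in z.columns if c.startswith("g2")))
        assert {left, right} == groups
        assert dendro.support[left] >= 95 and dendro.support[right] >= 95

    def test_duplicate_datasets_merge_first(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        z["e"] = z["a"]  # exact duplicate
        dendro = cluster_datasets(z, n_boot=10, seed=0)
        first_merge = dendro.clusters()[0]
        assert first_merge == frozenset({"a", "e"})
        assert dendro.linkage[0, 2] == 0.0

    def test_dataset_order_invariance(self):
        z = self.planted_z(seed=4)
        d1 = cluster_datasets(z, n_boot=10, seed=5)
        z_perm = z.iloc[:, ::-1]
        d2 = cluster_datasets(z_perm, n_boot=10, seed=5)
        assert set(d1.clusters()) == set(d2.clusters())

    def test_newick_roundtrip(self):
        z = self.planted_z(seed=6, n_cogs=20)
        dendro = cluster_datasets(z, n_boot=20, seed=7)
        tree = dendropy.Tree.get(data=dendro.to_newick(), schema="newick")
        leaves = {t.label.replace(" ", "_") for t in tree.taxon_namespace}
        assert leaves == set(z.columns)

    def test_too_few_datasets_rejected(self):
        z = pd.DataFrame(np.eye(5)[:, :2], columns=["a", "b"])
        with pytest.raises(ValidationError):
            cluster_datasets(z, n_boot=5, seed=0)


class TestPhoticLabel:
    def test_surface_is_photic(self):
        m = DatasetMetadata("d", "s", 0.0, 200.0, par_surface=1000.0,
                            par_at_depth=1000.0)
        assert photic_label(m) == "photic"

    def test_below_one_percent_is_aphotic(self):
        m = DatasetMetadata("d", "s", 120.0, 200.0, par_surface=1000.0,
                            par_at_depth=9.0)
        assert photic_label(m) == "aphotic"

    def test_boundary_from_attenuation(self):
        # ln(100)/0.046 = 100.11 m: photic just above, aphotic just below
        shallow = DatasetMetadata("a", "s", 100.0, 200.0, par_surface=1000.0,
                                  attenuation_k=0.046)
        deep = DatasetMetadata("b", "s", 100.3, 200.0, par_surface=1000.0,
                               attenuation_k=0.046)
        assert photic_label(shallow) == "photic"
        assert photic_label(deep) == "aphotic"

    def test_underivable_par_rejected(self):
        m = DatasetMetadata("d", "s", 10.0, 200.0, par_surface=1000.0)
        with pytest.raises(ValidationError):
            photic_label(m)
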