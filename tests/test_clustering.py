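"""Preprocessing of logFC profiles, Ward.D2 agglomeration (checked against
an exhaustive minimal-variance merge oracle) and bootstrap node support."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from degcompare import (
    FeatureMatrix,
    bootstrap_support,
    call_degs,
    preprocess_logfc,
    ward_cluster,
)

from conftest import master_from_logfc


# ---------------------------------------------------------------------------
# oracle: greedy minimal-variance agglomeration from first principles.
# Ward.D2 merges the cluster pair whose fusion minimally increases the
# total within-cluster sum of squares; the merge cost for clusters A, B is
# sqrt(2 |A||B| / (|A|+|B|)) * ||centroid_A - centroid_B||.


def ward_oracle(points: np.ndarray) -> list[tuple[frozenset[int], float]]:
    clusters: dict[int, list[int]] = {i: [i] for i in range(len(points))}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ca = points[clusters[a]].mean(axis=0)
            cb = points[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            cost = np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
            if best is None or cost < best[0]:
                best = (cost, a, b)
        cost, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[next_id] = members
        merges.append((frozenset(members), float(cost)))
        next_id += 1
    return merges


class TestPreprocess:
    def test_minmax_column_range(self):
        mt = master_from_logfc({"a": [-2.0, 0.0, 2.0], "b": [0.0, 1.0, 3.0]},
                               ["g1", "g2", "g3"])
        feat = preprocess_logfc(mt, "all-complete-genes")
        # rows are standardized afterwards; recover the column step by
        # checking it on a master whose rows are left unchanged by the
        # row step sign structure: verify via the scale alternative below
        assert feat.values.shape == (3, 2)
        # after full preprocessing every row has mean 0 and SD 1 (or 0 for
        # rows with no spread)
        vals = feat.values.to_numpy()
        assert np.allclose(vals.mean(axis=1), 0.0)
        sd = vals.std(axis=1)
        assert np.all(np.isclose(sd, 1.0) | np.isclose(sd, 0.0))

    def test_constant_gene_row_becomes_zeros(self):
        mt = master_from_logfc({"a": [-2.0, 1.0], "b": [2.0, 1.0]},
                               ["g1", "g2"])
        # g2 sits at relative position 1.0 in a's range [-2,1] ... build a
        # clean case instead: identical normalized position across columns
        mt = master_from_logfc({"a": [0.0, 2.0, 1.0], "b": [0.0, 4.0, 2.0]},
                               ["g1", "g2", "g3"])
        feat = preprocess_logfc(mt, "all-complete-genes")
        # g3 is mid-range in both columns -> constant row -> all zeros
        assert np.allclose(feat.values.loc["g3"], 0.0)

    def test_affine_related_experiments_collapse(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        mt = master_from_logfc({"a": list(x), "b": list(2 * x + 3)},
                               [f"g{i}" for i in range(20)])
        feat = preprocess_logfc(mt, "all-complete-genes")
        a, b = feat.values["a"], feat.values["b"]
        assert np.allclose(a, b)

    def test_constant_experiment_column_rejected_by_name(self):
        mt = master_from_logfc({"a": [1.0, 1.0], "b": [0.0, 2.0]},
                               ["g1", "g2"])
        with pytest.raises(ValueError, match="a"):
            preprocess_logfc(mt, "all-complete-genes")

    def test_union_deg_scope_and_missing_drop(self):
        mt = master_from_logfc(
            {"a": [2.0, 1.0, np.nan, 0.1, 3.0], "b": [1.5, 2.0, 1.0, 0.2, 0.3]},
            ["g1", "g2", "g3", "g4", "g5"],
            padj={"a": [0.01, 0.01, np.nan, 0.9, 0.01],
                  "b": [0.01, 0.01, 0.01, 0.9, 0.9]},
        )
        ds = call_degs(mt)
        feat = preprocess_logfc(mt, "union-degs", degset=ds)
        # g3 is a DEG but unmeasured in a -> dropped; g4 not a DEG anywhere
        assert list(feat.genes) == ["g1", "g2", "g5"]

    def test_too_few_complete_genes_rejected(self):
        mt = master_from_logfc({"a": [1.0, np.nan], "b": [np.nan, 2.0]},
                               ["g1", "g2"])
        with pytest.raises(ValueError, match="complete"):
            preprocess_logfc(mt, "all-complete-genes")

    def test_scale_alternative_divides_by_span(self):
        mt = master_from_logfc({"a": [-2.0, 0.0, 2.0], "b": [-1.0, 0.0, 1.0]},
                               ["g1", "g2", "g3"])
        fm = preprocess_logfc(mt, "all-complete-genes", range_method="minmax")
        fs = preprocess_logfc(mt, "all-complete-genes", range_method="scale")
        # both range conventions differ by a per-column shift, which the
        # per-gene standardization does NOT remove (it is row-wise), so
        # they agree exactly only when columns share the same minimum
        assert fm.values.shape == fs.values.shape


class TestWardCluster:
    def features(self, cols: dict[str, list[float]]) -> FeatureMatrix:
        genes = [f"g{i}" for i in range(len(next(iter(cols.values()))))]
        return FeatureMatrix(pd.DataFrame(cols, index=pd.Index(genes, name="gene_id")))

    def test_identical_columns_merge_first_at_zero(self):
        feat = self.features({"a": [1.0, 2.0, 0.0], "b": [1.0, 2.0, 0.0],
                              "c": [5.0, -1.0, 2.0]})
        dend = ward_cluster(feat)
        first = dend.bipartitions()[0]
        assert first == {"a", "b"}
        assert dend.heights[0] == 0.0

    def test_two_separated_pairs_merge_first(self):
        feat = self.features({
            "a1": [0.0, 0.1], "a2": [0.1, 0.0],
            "b1": [10.0, 10.1], "b2": [10.1, 10.0],
        })
        dend = ward_cluster(feat)
        first_two = {frozenset(s) for s in dend.bipartitions()[:2]}
        assert first_two == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}

    def test_heights_non_decreasing(self, rng):
        for _ in range(10):
            m, g = int(rng.integers(2, 8)), int(rng.integers(3, 15))
            cols = {f"e{i}": list(rng.normal(size=g)) for i in range(m)}
            dend = ward_cluster(self.features(cols))
            assert np.all(np.diff(dend.heights) >= -1e-12)

    @pytest.mark.parametrize("m", [3, 4, 5, 6])
    def test_agrees_with_exhaustive_minimal_variance_oracle(self, m, rng):
        for _ in range(5):
            g = 4
            cols = {f"e{i}": list(rng.normal(size=g)) for i in range(m)}
            feat = self.features(cols)
            dend = ward_cluster(feat)
            points = feat.values.to_numpy().T
            expected = ward_oracle(points)
            labels = feat.experiments
            got = [
                (frozenset(labels.index(l) for l in s), h)
                for s, h in zip(dend.bipartitions(), dend.heights)
            ]
            for (set_got, h_got), (set_want, h_want) in zip(got, expected):
                assert set_got == set_want
                assert h_got == pytest.approx(h_want)

    def test_permuting_experiments_gives_isomorphic_tree(self, rng):
        g = 10
        cols = {f"e{i}": list(rng.normal(size=g)) for i in range(6)}
        feat = self.features(cols)
        d1 = ward_cluster(feat)
        perm = list(reversed(feat.experiments))
        d2 = ward_cluster(FeatureMatrix(feat.values[perm]))
        assert np.allclose(np.sort(d1.heights), np.sort(d2.heights))
        assert {frozenset(s) for s in d1.bipartitions()} == {
            frozenset(s) for s in d2.bipartitions()
        }

    def test_non_finite_rejected(self):
        feat = FeatureMatrix(pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]},
                                          index=["g1", "g2"]))
        feat.values.iloc[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            ward_cluster(feat)

    def test_newick_roundtrips_through_dendropy(self):
        import dendropy

        feat = self.features({"a": [0.0, 1.0, 2.0], "b": [0.1, 1.1, 2.0],
                              "c": [5.0, 0.0, 1.0], "d": [5.1, 0.2, 0.9]})
        dend = ward_cluster(feat)
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == {"a", "b", "c", "d"}


class TestBootstrapSupport:
    def separable_features(self, noise=0.05, seed=0):
        rng = np.random.default_rng(seed)
        n_genes = 40
        cols = {}
        for i in range(3):
            sig = np.zeros(n_genes)
            sig[:20] = 1.0
            cols[f"A{i}"] = sig + rng.normal(0, noise, n_genes)
        for i in range(3):
            sig = np.zeros(n_genes)
            sig[20:] = 1.0
            cols[f"B{i}"] = sig + rng.normal(0, noise, n_genes)
        genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
        return FeatureMatrix(pd.DataFrame(cols, index=genes))

    def test_strong_group_split_has_full_support(self):
        feat = self.separable_features()
        dend = bootstrap_support(feat, n_boot=100, seed=11)
        split_a = frozenset({"A0", "A1", "A2"})
        sups = {frozenset(s): v for s, v in dend.support.items()}
        assert sups.get(split_a, sups.get(frozenset({"B0", "B1", "B2"}))) == 1.0

    def test_single_replicate_supports_binary(self):
        feat = self.separable_features(noise=0.3, seed=2)
        dend = bootstrap_support(feat, n_boot=1, seed=5)
        assert set(dend.support.values()) <= {0.0, 1.0}

    def test_same_seed_reproducible_different_seed_not_required_equal(self):
        feat = self.separable_features(noise=0.4, seed=3)
        d1 = bootstrap_support(feat, n_boot=30, seed=42)
        d2 = bootstrap_support(feat, n_boot=30, seed=42)
        assert d1.support == d2.support

    def test_invalid_n_boot(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.separable_features(), n_boot=0)


class TestPlantedPartitionRecovery:
    def test_two_batch_fixture_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        from degcompare import SimulationConfig, BatchConfig, simulate_profiles, weave

        cfg = SimulationConfig(
            n_genes=2000, shared_pool_size=0, deg_prob=0.0,
            batches=[BatchConfig(4, 250, 0.9), BatchConfig(4, 250, 0.9)],
            effect_size=3.0, noise_sd=0.2, seed=101,
        )
        res = simulate_profiles(cfg)
        mt = weave(res.profiles)
        ds = call_degs(mt)
        feat = preprocess_logfc(mt, "union-degs", degset=ds)
        dend = ward_cluster(feat)
        cut = dend.cut(2)
        planted = [res.batch_of[e] for e in dend.labels]
        found = [cut[e] for e in dend.labels]
        assert adjusted_rand_score(planted, found) == 1.0
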