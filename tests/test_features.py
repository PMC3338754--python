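"""Feature extraction: elementary statistics, searches, and their oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compfeat import (
    ChuangParams,
    CompositeFeature,
    ExpressionDataset,
    Network,
    TaylorParams,
    activity,
    chuang_search,
    chuang_significance_filter,
    feature_values,
    lee_corg,
    lee_rank_pathways,
    mutual_information,
    rank_single_genes,
    taylor_significant_hubs,
    tstat,
)
from compfeat import GeneSetCollection
from compfeat.features import (
    avg_hub_difference,
    default_n_bins,
    hub_difference,
    pearson,
)


def make_ds(columns: dict, labels, name="t"):
    genes = sorted(columns)
    values = np.column_stack([np.asarray(columns[g], float) for g in genes])
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        gene_ids=genes,
        values=values,
        labels=np.asarray(labels, int),
        name=name,
    )


class TestTStat:
    def test_hand_computed(self):
        t = tstat([4, 5, 6], [1, 2, 3])
        assert t == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-4)
        assert t == pytest.approx(3.6742, abs=1e-4)

    def test_symmetry_and_antisymmetry(self):
        assert tstat([1, 2, 3], [1, 2, 3]) == 0.0
        assert tstat([1, 2, 3], [4, 5, 6]) == pytest.approx(-3.6742, abs=1e-4)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            tstat([2, 2, 2], [5, 5, 5])


class TestActivity:
    def test_examples(self):
        ds = make_ds({"g1": [1, 2], "g2": [-1, 2]}, [0, 1])
        act = activity(ds, ["g1", "g2"])
        assert act[0] == pytest.approx(0.0)
        assert act[1] == pytest.approx(4 / np.sqrt(2))

    def test_singleton_is_identity(self):
        ds = make_ds({"g1": [1.5, -2.0, 0.3]}, [0, 1, 0])
        np.testing.assert_allclose(activity(ds, ["g1"]), ds.column("g1"))

    def test_unknown_gene_errors(self):
        ds = make_ds({"g1": [1, 2]}, [0, 1])
        with pytest.raises(KeyError):
            activity(ds, ["nope"])


def mi_oracle(act, labels, n_bins):
    """Independent MI computation via an explicit joint histogram."""
    act = np.asarray(act, float)
    lo, hi = act.min(), act.max()
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] += 1e-12
    joint, _, _ = np.histogram2d(act, labels, bins=[edges, [-0.5, 0.5, 1.5]])
    joint /= joint.sum()
    mi = 0.0
    for b in range(n_bins):
        for c in range(2):
            p = joint[b, c]
            if p > 0:
                mi += p * np.log2(p / (joint[b].sum() * joint[:, c].sum()))
    return mi


class TestMutualInformation:
    def test_perfect_association(self):
        assert mutual_information([-1, -1, 1, 1], [0, 0, 1, 1], 2) == \
            pytest.approx(1.0)

    def test_independence(self):
        assert mutual_information([-1, 1, -1, 1], [0, 0, 1, 1], 2) == \
            pytest.approx(0.0)

    def test_constant_vector_is_zero(self):
        assert mutual_information([2, 2, 2, 2], [0, 1, 0, 1], 4) == 0.0

    def test_matches_joint_histogram_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            k = int(rng.integers(8, 60))
            act = rng.normal(size=k)
            labels = rng.integers(0, 2, size=k)
            if labels.sum() in (0, k):
                labels[0] = 1 - labels[0]
            n_bins = int(rng.integers(2, 9))
            assert mutual_information(act, labels, n_bins) == pytest.approx(
                mi_oracle(act, labels, n_bins), abs=1e-12
            )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounds_for_binary_labels(self, seed):
        rng = np.random.default_rng(seed)
        act = rng.normal(size=20)
        labels = np.array([0, 1] * 10)
        mi = mutual_information(act, labels, 5)
        assert -1e-12 <= mi <= min(np.log2(5), 1.0) + 1e-12


class TestSingleGenes:
    def test_planted_gene_ranks_first(self):
        rng = np.random.default_rng(7)
        labels = np.array([0] * 100 + [1] * 100)
        cols = {f"g{j:02d}": rng.normal(size=200) for j in range(49)}
        cols["g49"] = rng.normal(size=200) + 3.0 * labels
        ds = make_ds(cols, labels)
        ranked = rank_single_genes(ds)
        assert ranked.features[0].name == "g49"

    def test_tied_identical_columns_lexicographic(self):
        col = np.array([0.1, 1.2, -0.5, 2.0, 0.8, -1.0])
        ds = make_ds({"gb": col, "ga": col, "gc": col * 0 + np.arange(6)},
                     [0, 0, 0, 1, 1, 1])
        names = [f.name for f in rank_single_genes(ds).features]
        assert names.index("ga") + 1 == names.index("gb")

    def test_relabeling_equivariance(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(30, 6))
        labels = np.array([0, 1] * 15)
        a = ExpressionDataset([f"s{i}" for i in range(30)],
                              [f"g{j}" for j in range(6)], values, labels)
        mapping = {f"g{j}": f"h{(j + 3) % 6}" for j in range(6)}
        b = ExpressionDataset([f"s{i}" for i in range(30)],
                              [mapping[g] for g in a.gene_ids], values, labels)
        ra = [(mapping[f.name], f.score) for f in rank_single_genes(a).features]
        rb = [(f.name, f.score) for f in rank_single_genes(b).features]
        assert sorted(ra) == sorted(rb)


# -- exhaustive-search oracle for connected subnetworks ---------------------

def connected_subsets(net: Network, max_size: int):
    """Enumerate all connected node subsets up to max_size."""
    out = {frozenset([n]) for n in net.nodes}
    frontier = set(out)
    while frontier:
        nxt = set()
        for sub in frontier:
            if len(sub) >= max_size:
                continue
            nbrs = set()
            for n in sub:
                nbrs.update(net.neighbors(n))
            for n in nbrs - sub:
                nxt.add(sub | {n})
        nxt -= out
        out |= nxt
        frontier = nxt
    return out


class TestChuangSearch:
    def star(self):
        rng = np.random.default_rng(9)
        labels = np.array([0] * 40 + [1] * 40)
        cols = {"center": rng.normal(size=80) + 2.5 * labels}
        for j in range(4):
            cols[f"leaf{j}"] = rng.normal(size=80)
        ds = make_ds(cols, labels)
        net = Network(set(cols), [("center", f"leaf{j}") for j in range(4)])
        return ds, net

    def test_star_keeps_center_alone_and_matches_brute_force(self):
        ds, net = self.star()
        params = ChuangParams(n_null_permutations=0)
        ranked = chuang_search(ds, net, params)
        best = ranked.features[0]
        assert best.member_genes == ("center",)
        n_bins = default_n_bins(ds.n_samples)
        exhaustive = max(
            mutual_information(activity(ds, sorted(sub)), ds.labels, n_bins)
            for sub in connected_subsets(net, 5)
        )
        assert best.score == pytest.approx(exhaustive, abs=1e-12)

    def test_greedy_never_beats_exhaustive(self):
        rng = np.random.default_rng(10)
        for trial in range(5):
            n = 8
            genes = [f"g{j}" for j in range(n)]
            edges = set()
            for j in range(1, n):
                edges.add((genes[rng.integers(j)], genes[j]))
            for _ in range(4):
                a, b = rng.choice(n, 2, replace=False)
                if a != b:
                    edges.add((genes[min(a, b)], genes[max(a, b)]))
            net = Network(genes, edges)
            labels = np.array([0, 1] * 15)
            values = rng.normal(size=(30, n))
            values[labels == 1, : n // 2] += 1.0
            ds = ExpressionDataset([f"s{i}" for i in range(30)], genes,
                                   values, labels)
            ranked = chuang_search(ds, net, ChuangParams(n_null_permutations=0))
            n_bins = default_n_bins(30)
            exhaustive = max(
                mutual_information(activity(ds, sorted(sub)), ds.labels,
                                   n_bins)
                for sub in connected_subsets(net, n)
            )
            assert ranked.features[0].score <= exhaustive + 1e-12

    def test_disconnected_informative_genes_stay_separate(self):
        rng = np.random.default_rng(11)
        labels = np.array([0] * 30 + [1] * 30)
        cols = {
            "a1": rng.normal(size=60) + 2 * labels,
            "a2": rng.normal(size=60),
            "b1": rng.normal(size=60) + 2 * labels,
            "b2": rng.normal(size=60),
        }
        ds = make_ds(cols, labels)
        net = Network(set(cols), [("a1", "a2"), ("b1", "b2")])
        ranked = chuang_search(ds, net, ChuangParams(n_null_permutations=0))
        for f in ranked.features:
            members = set(f.member_genes)
            assert not ({"a1", "b1"} <= members)

    def test_node_order_invariance(self, strong_pair):
        _, datasets, truth = strong_pair
        ds = datasets[0]
        genes = ds.gene_ids[:30]
        rng = np.random.default_rng(12)
        edges = [(genes[rng.integers(30)], genes[rng.integers(30)])
                 for _ in range(50)]
        edges = [e for e in edges if e[0] != e[1]]
        net1 = Network(genes, edges)
        net2 = Network(list(reversed(genes)), list(reversed(edges)))
        p = ChuangParams(n_null_permutations=0)
        r1 = chuang_search(ds, net1, p)
        r2 = chuang_search(ds, net2, p)
        assert [(f.member_genes, f.score) for f in r1.features] == \
            [(f.member_genes, f.score) for f in r2.features]


class TestChuangFilter:
    def test_alpha_one_is_identity(self, strong_pair):
        _, datasets, _ = strong_pair
        ds = datasets[0]
        genes = ds.gene_ids[:20]
        net = Network(genes, [(genes[i], genes[i + 1]) for i in range(19)])
        p = ChuangParams(n_null_permutations=0)
        ranked = chuang_search(ds, net, p)
        out = chuang_significance_filter(
            ranked, ds, net, ChuangParams(n_null_permutations=50, alpha=1.0)
        )
        assert [f.name for f in out.features] == \
            [f.name for f in ranked.features]

    def test_planted_module_survives_null_mostly_filtered(self, strong_pair):
        cfg, datasets, truth = strong_pair
        from compfeat import simulate_network

        net = simulate_network(cfg)
        ds = datasets[0]
        p = ChuangParams(n_null_permutations=100, alpha=0.05, seed=3)
        ranked = chuang_search(ds, net, p)
        kept = chuang_significance_filter(ranked, ds, net, p)
        module = set(truth.module_genes[0])
        # the module-covering top feature survives
        assert any(len(set(f.member_genes) & module) >= 3
                   for f in kept.features)
        assert len(kept) < len(ranked)


class TestLeeCorg:
    def corg_oracle(self, ds, pathway):
        """Prefix-exhaustive re-implementation of the greedy CORG rule."""
        measured = [g for g in pathway if g in set(ds.gene_ids)]
        labels = ds.labels
        ts = {}
        for g in measured:
            col = ds.column(g)
            ts[g] = tstat(col[labels == 1], col[labels == 0])
        lead = min(measured, key=lambda g: (-abs(ts[g]), g))
        descending = ts[lead] >= 0
        ordered = sorted(measured,
                         key=lambda g: ((-ts[g] if descending else ts[g]), g))
        best_prefix, best = None, -np.inf
        for m in range(1, len(ordered) + 1):
            act = activity(ds, ordered[:m])
            s = abs(tstat(act[labels == 1], act[labels == 0]))
            if s > best:
                best_prefix, best = ordered[:m], s
            else:
                break
        return tuple(best_prefix), best

    def test_identical_strong_columns_all_join(self):
        rng = np.random.default_rng(13)
        labels = np.array([0] * 25 + [1] * 25)
        base = 2.0 * labels
        cols = {f"g{j}": base + rng.normal(0, 1, size=50) for j in range(3)}
        ds = make_ds(cols, labels)
        f = lee_corg(ds, sorted(cols))
        oracle_members, oracle_score = self.corg_oracle(ds, sorted(cols))
        assert f.member_genes == oracle_members
        assert f.score == pytest.approx(oracle_score, abs=1e-12)
        assert len(f.member_genes) >= 2

    def test_single_gene_pathway(self):
        ds = make_ds({"g1": [0.1, -0.2, 2.5, 3.0],
                      "gz": [1, 2, 3, 4]}, [0, 0, 1, 1])
        f = lee_corg(ds, ["g1"])
        assert f.member_genes == ("g1",)
        col = ds.column("g1")
        assert f.score == pytest.approx(abs(tstat(col[2:], col[:2])))

    def test_noise_genes_rejected(self):
        rng = np.random.default_rng(14)
        labels = np.array([0] * 50 + [1] * 50)
        cols = {"inf": rng.normal(size=100) + 3.0 * labels}
        for j in range(9):
            cols[f"n{j}"] = rng.normal(size=100)
        ds = make_ds(cols, labels)
        f = lee_corg(ds, sorted(cols))
        oracle_members, oracle_score = self.corg_oracle(ds, sorted(cols))
        assert f.member_genes == oracle_members
        assert f.member_genes[0] == "inf"
        assert len(f.member_genes) <= 3

    def test_matches_prefix_oracle_on_random_pathways(self):
        rng = np.random.default_rng(15)
        labels = np.array([0, 1] * 20)
        for trial in range(10):
            cols = {f"g{j}": rng.normal(size=40) +
                    rng.normal(0, 0.8) * labels for j in range(6)}
            ds = make_ds(cols, labels)
            f = lee_corg(ds, sorted(cols))
            members, score_ = self.corg_oracle(ds, sorted(cols))
            assert f.member_genes == members
            assert f.score == pytest.approx(score_, abs=1e-12)

    def test_score_at_least_best_single_gene(self):
        rng = np.random.default_rng(16)
        labels = np.array([0, 1] * 25)
        cols = {f"g{j}": rng.normal(size=50) + 0.5 * labels for j in range(5)}
        ds = make_ds(cols, labels)
        f = lee_corg(ds, sorted(cols))
        best_single = max(
            abs(tstat(ds.column(g)[labels == 1], ds.column(g)[labels == 0]))
            for g in cols
        )
        assert f.score >= best_single - 1e-12

    def test_rank_pathways_and_empty_collection(self):
        rng = np.random.default_rng(17)
        labels = np.array([0] * 30 + [1] * 30)
        cols = {"a": rng.normal(size=60) + 2 * labels,
                "b": rng.normal(size=60), "c": rng.normal(size=60)}
        ds = make_ds(cols, labels)
        coll = GeneSetCollection({"strong": ["a", "b"], "weak": ["b", "c"]})
        ranked = lee_rank_pathways(ds, coll)
        assert ranked.features[0].name == "strong"
        assert len(lee_rank_pathways(ds, GeneSetCollection({}))) == 0

    def test_unmeasured_pathway_skipped(self):
        ds = make_ds({"g1": [1.0, 2.0, 5.0, 6.0]}, [0, 0, 1, 1])
        assert lee_corg(ds, ["x1", "x2"]) is None


class TestPearsonAndHubs:
    def test_pearson_values(self):
        x = np.array([1.0, 2.0, 3.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)
        assert pearson(x, [1, 2, 4]) == pytest.approx(0.98198, abs=1e-5)

    def test_degenerate_correlation_is_zero(self):
        assert pearson([1, 1, 1], [1, 2, 3]) == 0.0

    def test_full_flip_reaches_bound(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
        ds = make_ds({"h": x, "n": y}, [0, 0, 0, 1, 1, 1])
        d = hub_difference(ds, "h", "n")
        assert d == pytest.approx(-2.0)

    def test_identical_class_distributions_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([0.5, 1.8, 2.1, 0.5, 1.8, 2.1])
        ds = make_ds({"h": x, "n": y}, [0, 0, 0, 1, 1, 1])
        assert hub_difference(ds, "h", "n") == pytest.approx(0.0)

    def test_average_is_arithmetic_mean(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        flip = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
        same = x.copy()
        ds = make_ds({"h": x, "n1": flip, "n2": same}, [0, 0, 0, 1, 1, 1])
        assert avg_hub_difference(ds, "h", ["n1", "n2"]) == pytest.approx(-1.0)

    def test_small_class_errors(self):
        ds = make_ds({"h": [1, 2, 3, 4], "n": [1, 2, 3, 4]}, [0, 0, 1, 1])
        with pytest.raises(ValueError):
            hub_difference(ds, "h", "n")


class TestTaylor:
    def test_hub_without_measured_neighbors_excluded(self):
        rng = np.random.default_rng(18)
        labels = np.array([0] * 10 + [1] * 10)
        ds = make_ds({"h": rng.normal(size=20)}, labels)
        net = Network({"h", "x1", "x2", "x3", "a", "b"},
                      [("h", "x1"), ("h", "x2"), ("h", "x3"), ("a", "b")])
        ranked = taylor_significant_hubs(
            ds, net, TaylorParams(n_label_permutations=50)
        )
        assert len(ranked) == 0

    def test_planted_flip_hub_detected(self):
        rng = np.random.default_rng(19)
        k = 80
        labels = np.array([0] * 40 + [1] * 40)
        f = rng.normal(size=k)
        cols = {"hub": f + 0.3 * rng.normal(size=k)}
        sign = np.where(labels == 1, -1.0, 1.0)
        for j in range(4):
            cols[f"n{j}"] = sign * f + 0.3 * rng.normal(size=k)
        for j in range(10):
            cols[f"z{j}"] = rng.normal(size=k)
        ds = make_ds(cols, labels)
        edges = [("hub", f"n{j}") for j in range(4)]
        edges += [(f"z{j}", f"z{(j + 1) % 10}") for j in range(10)]
        net = Network(set(cols), edges)
        ranked = taylor_significant_hubs(
            ds, net, TaylorParams(n_label_permutations=200, seed=1)
        )
        assert any(f.hub_gene == "hub" for f in ranked.features)


class TestFeatureValues:
    def test_hub_edge_differences(self):
        ds = make_ds({"h": [2.0, 0.0], "n1": [0.5, 0.0], "n2": [-1.0, 0.0]},
                     [0, 1])
        feat = CompositeFeature("hub:h", ("h", "n1", "n2"), 1.0, "hub",
                                hub_gene="h")
        vals = feature_values(ds, feat)
        np.testing.assert_allclose(vals[0], [1.5, 3.0])

    def test_single_gene_identity_and_corg_singleton(self):
        ds = make_ds({"g1": [1.0, -2.0, 0.5, 1.1]}, [0, 0, 1, 1])
        sg = CompositeFeature("g1", ("g1",), 1.0, "single_gene")
        np.testing.assert_allclose(feature_values(ds, sg), ds.column("g1"))
        corg = CompositeFeature("c", ("g1",), 1.0, "corg")
        np.testing.assert_allclose(feature_values(ds, corg), ds.column("g1"))


class TestInvariances:
    def test_sample_and_gene_order_invariance(self, strong_pair):
        _, datasets, _ = strong_pair
        ds = datasets[0]
        rng = np.random.default_rng(20)
        sperm = rng.permutation(ds.n_samples)
        shuffled = ds.subset_samples(sperm)
        gperm = rng.permutation(ds.n_genes)
        reordered = ExpressionDataset(
            shuffled.sample_ids,
            [shuffled.gene_ids[j] for j in gperm],
            shuffled.values[:, gperm],
            shuffled.labels,
            name=ds.name,
        )
        a = rank_single_genes(ds)
        b = rank_single_genes(reordered)
        assert [(f.name, round(f.score, 10)) for f in a.features] == \
            [(f.name, round(f.score, 10)) for f in b.features]

    def test_fingerprint_ignores_test_data(self, strong_pair):
        from compfeat import SingleGeneExtractor

        _, datasets, _ = strong_pair
        train = datasets[0]
        ex = SingleGeneExtractor()
        fp1 = ex.extract(train).source_fingerprint
        # mutate the *other* dataset; training fingerprint must not move
        datasets[1].values[0, 0] += 100.0
        fp2 = ex.extract(train).source_fingerprint
        datasets[1].values[0, 0] -= 100.0
        assert fp1 == fp2
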