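"""The four feature-extraction methods.

* single genes -- rank every gene by the absolute Welch t-statistic
  between the poor- and good-outcome groups;
* subnetwork search (Chuang-style) -- greedy growth of connected
  subnetworks maximizing the mutual information between discretized
  subnetwork activity and the class labels, followed by a three-way
  permutation significance filter;
* CORG search (Lee-style) -- per pathway, a greedy prefix of
  t-ordered genes whose averaged activity maximizes |t|;
* hub correlation differences (Taylor-style) -- high-degree network
  nodes whose hub--interactor expression correlations differ between
  classes, assessed by label permutation.

All scores are computed on the training samples only; extractors carry a
fingerprint of (training data, secondary source, parameters) so leakage
can be audited.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .data import (
    CompositeFeature,
    ExpressionDataset,
    GeneSetCollection,
    Network,
    RankedFeatureList,
)

__all__ = [
    "ChuangParams",
    "TaylorParams",
    "tstat",
    "activity",
    "default_n_bins",
    "mutual_information",
    "rank_single_genes",
    "chuang_search",
    "chuang_significance_filter",
    "lee_corg",
    "lee_rank_pathways",
    "pearson",
    "hub_difference",
    "avg_hub_difference",
    "taylor_candidate_hubs",
    "taylor_significant_hubs",
    "feature_values",
    "SingleGeneExtractor",
    "ChuangExtractor",
    "LeeExtractor",
    "TaylorExtractor",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ChuangParams:
    """Knobs of the subnetwork search.

    ``n_bins=None`` means the floor(log2 k)+1 rule on k training
    samples.  ``improvement_min=0`` demands a strict MI increase per
    growth step.  ``n_null_permutations=0`` disables the significance
    filter (useful for quick pipelines); the conventional setting is
    1000 permutations at alpha 0.05.
    """

    n_bins: int | None = None
    improvement_min: float = 0.0
    max_radius: int = 2
    n_null_permutations: int = 1000
    n_search_permutations: int = 20
    alpha: float = 0.05
    activity_norm: str = "sqrt"   # "sqrt" (sum/sqrt(|S|)) or "mean"
    seed: int = 0


@dataclass
class TaylorParams:
    """Knobs of the hub analysis: candidate-hub fraction by degree,
    label-permutation count for the empirical p-value, and the cutoff."""

    hub_fraction: float = 0.15
    n_label_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def tstat(values_poor, values_good) -> float:
    """Welch t-statistic; positive when the poor-class mean is higher.

    t = (mu1 - mu0) / sqrt(s1^2/k1 + s0^2/k0) with sample (n-1) sds.
    """
    x1 = np.asarray(values_poor, dtype=float)
    x0 = np.asarray(values_good, dtype=float)
    if x1.size < 2 or x0.size < 2:
        raise ValueError("each group needs at least two samples")
    v1 = x1.var(ddof=1)
    v0 = x0.var(ddof=1)
    denom = np.sqrt(v1 / x1.size + v0 / x0.size)
    if denom == 0:
        raise ValueError("both group variances are zero")
    return float((x1.mean() - x0.mean()) / denom)


def _tstat_columns(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized Welch t over the columns of a samples x genes matrix."""
    x1 = values[labels == 1]
    x0 = values[labels == 0]
    if x1.shape[0] < 2 or x0.shape[0] < 2:
        raise ValueError("each class needs at least two samples")
    denom = np.sqrt(
        x1.var(axis=0, ddof=1) / x1.shape[0]
        + x0.var(axis=0, ddof=1) / x0.shape[0]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x1.mean(axis=0) - x0.mean(axis=0)) / denom
    return t


def activity(ds: ExpressionDataset, genes, norm: str = "sqrt") -> np.ndarray:
    """Per-sample aggregate expression of a gene group.

    Default is the sum divided by sqrt(|S|), which keeps the feature
    variance near 1 on z-scored data; ``norm="mean"`` gives the plain
    average.  Both yield identical t-statistics and MI (positive
    scaling), so the choice only matters for classifier geometry.
    """
    genes = list(genes)
    cols = ds.columns(genes)
    total = cols.sum(axis=1)
    if norm == "sqrt":
        return total / np.sqrt(len(genes))
    if norm == "mean":
        return total / len(genes)
    raise ValueError(f"unknown activity norm {norm!r}")


def default_n_bins(n_samples: int) -> int:
    return int(np.floor(np.log2(n_samples))) + 1


def mutual_information(act, labels, n_bins: int) -> float:
    """MI (bits) between equal-width-binned activities and binary labels.

    Bins span [min, max] of the activity vector; a constant vector
    occupies a single bin and scores 0.  The 0*log(0) terms are taken
    as 0.
    """
    act = np.asarray(act, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if n_bins < 2:
        raise ValueError("need at least two bins")
    lo, hi = act.min(), act.max()
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(act, edges[1:-1]), 0, n_bins - 1)
    k = act.size
    joint = np.zeros((n_bins, 2))
    np.add.at(joint, (bins, labels), 1.0)
    joint /= k
    pb = joint.sum(axis=1, keepdims=True)
    pc = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (pb @ pc))
    return float(np.nansum(terms))


def pearson(x, y) -> float:
    """Pearson correlation; degenerate (zero-variance) input maps to 0
    with a logged warning rather than NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        logger.warning("degenerate correlation (zero variance); using 0")
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


# ---------------------------------------------------------------------------
# single genes
# ---------------------------------------------------------------------------

def rank_single_genes(train: ExpressionDataset) -> RankedFeatureList:
    """One feature per gene, scored by |t|, ties broken by gene id."""
    t = _tstat_columns(train.values, train.labels)
    score = np.abs(np.nan_to_num(t, nan=0.0))
    order = sorted(range(train.n_genes),
                   key=lambda j: (-score[j], train.gene_ids[j]))
    feats = [
        CompositeFeature(
            name=train.gene_ids[j],
            member_genes=(train.gene_ids[j],),
            score=float(score[j]),
            kind="single_gene",
        )
        for j in order
    ]
    return RankedFeatureList(feats, method="sg")


# ---------------------------------------------------------------------------
# Chuang-style subnetwork search
# ---------------------------------------------------------------------------

def _bfs_region(net: Network, seed: str, radius: int) -> set:
    region = {seed}
    frontier = {seed}
    for _ in range(radius):
        nxt = set()
        for node in frontier:
            nxt.update(net.neighbors(node))
        nxt -= region
        if not nxt:
            break
        region |= nxt
        frontier = nxt
    return region


def chuang_search(train: ExpressionDataset, net: Network,
                  params: ChuangParams | None = None) -> RankedFeatureList:
    """Greedy subnetwork growth from every node as seed.

    At each step the candidate neighbor (adjacent to the current
    subnetwork, within ``max_radius`` hops of the seed) that maximizes
    the MI of the subnetwork activity is added; growth stops when no
    candidate improves MI by more than ``improvement_min``.  Equal-gain
    ties go to the lexicographically smallest gene id, which makes the
    search deterministic and node-order invariant.  Identical gene sets
    reached from different seeds are deduplicated.
    """
    params = params or ChuangParams()
    net = net.restrict_to(train.gene_ids)
    if net.n_nodes == 0:
        return RankedFeatureList([], method="chuang")
    n_bins = params.n_bins or default_n_bins(train.n_samples)
    labels = train.labels
    gidx = {g: train.gene_index(g) for g in net.nodes}

    found = {}
    for seed in sorted(net.nodes):
        region = _bfs_region(net, seed, params.max_radius)
        members = [seed]
        total = train.values[:, gidx[seed]].copy()
        cur_mi = mutual_information(total, labels, n_bins)
        member_set = {seed}
        while True:
            cands = set()
            for m in members:
                cands.update(net.neighbors(m))
            cands = sorted((cands & region) - member_set)
            best_gene, best_mi = None, -np.inf
            for g in cands:
                cand_act = (total + train.values[:, gidx[g]]) / np.sqrt(
                    len(members) + 1
                )
                mi = mutual_information(cand_act, labels, n_bins)
                if mi > best_mi + 1e-15:
                    best_gene, best_mi = g, mi
            if best_gene is None or best_mi - cur_mi <= params.improvement_min:
                break
            members.append(best_gene)
            member_set.add(best_gene)
            total += train.values[:, gidx[best_gene]]
            cur_mi = best_mi
        key = frozenset(member_set)
        if key not in found or cur_mi > found[key]:
            found[key] = cur_mi

    feats = [
        CompositeFeature(
            name="sub:" + "+".join(sorted(genes)),
            member_genes=tuple(sorted(genes)),
            score=float(mi),
            kind="subnetwork",
        )
        for genes, mi in found.items()
    ]
    feats.sort(key=lambda f: (-f.score, f.member_genes))
    return RankedFeatureList(feats, method="chuang")


def _greedy_subnetwork_to_size(train: ExpressionDataset, net: Network,
                               seed_node: str, size: int, n_bins: int,
                               labels: np.ndarray) -> float | None:
    """MI of a subnetwork grown greedily (as the real search does) from
    ``seed_node`` to exactly ``size`` nodes; None if the component is
    too small.  Growing the null with the same MI-maximizing rule keeps
    it exchangeable with the observed, search-optimized features."""
    members = {seed_node}
    total = train.column(seed_node).astype(float).copy()
    mi = mutual_information(total, labels, n_bins)
    while len(members) < size:
        cands = set()
        for m in members:
            cands.update(net.neighbors(m))
        cands = sorted(cands - members)
        if not cands:
            return None
        best_gene, best_mi = None, -np.inf
        for g in cands:
            act = (total + train.column(g)) / np.sqrt(len(members) + 1)
            cand_mi = mutual_information(act, labels, n_bins)
            if cand_mi > best_mi + 1e-15:
                best_gene, best_mi = g, cand_mi
        members.add(best_gene)
        total += train.column(best_gene)
        mi = best_mi
    return mi


def _null_search_mis(train: ExpressionDataset, net: Network,
                     params: ChuangParams, rng, mode: str) -> dict:
    """MI-by-size of features from full searches on permuted data.

    ``mode="genes"`` shuffles the gene-to-node assignment among the
    measured network nodes; ``mode="labels"`` permutes the class
    labels.  Because the whole greedy search is rerun, the null feature
    population carries the same selection optimism as the observed
    one, which is what makes the quantile comparison calibrated.
    """
    nodes = sorted(net.nodes)
    search_params = ChuangParams(
        n_bins=params.n_bins, improvement_min=params.improvement_min,
        max_radius=params.max_radius, n_null_permutations=0,
        activity_norm=params.activity_norm,
    )
    by_size = {}
    for _ in range(params.n_search_permutations):
        if mode == "genes":
            new_ids = list(train.gene_ids)
            idxs = [train.gene_index(g) for g in nodes]
            shuffled = [nodes[j] for j in rng.permutation(len(nodes))]
            for i, g in zip(idxs, shuffled):
                new_ids[i] = g
            ds = ExpressionDataset(train.sample_ids, new_ids, train.values,
                                   train.labels, name=train.name)
        elif mode == "labels":
            ds = ExpressionDataset(train.sample_ids, train.gene_ids,
                                   train.values,
                                   rng.permutation(train.labels),
                                   name=train.name)
        else:
            raise ValueError(mode)
        for f in chuang_search(ds, net, search_params).features:
            by_size.setdefault(len(f.member_genes), []).append(f.score)
    return by_size


def _size_threshold(by_size: dict, size: int, q: float) -> float:
    """(1-alpha) quantile of the null MIs at the closest available size."""
    if not by_size:
        return np.inf
    if size not in by_size:
        size = min(by_size, key=lambda s: (abs(s - size), -s))
    return float(np.percentile(by_size[size], q))


def chuang_significance_filter(
    feats: RankedFeatureList,
    train: ExpressionDataset,
    net: Network,
    params: ChuangParams | None = None,
) -> RankedFeatureList:
    """Keep subnetworks beating three permutation nulls at ``alpha``.

    1. MI above the (1-alpha) quantile of MI of same-size connected
       subnetworks grown from random seeds with the same greedy
       MI-maximizing rule as the real search;
    2. MI above the size-matched quantile of features produced by the
       full search after permuting the gene-to-node assignment;
    3. MI above the size-matched quantile of features produced by the
       full search under label permutation.

    All three nulls re-apply the search's own optimization, so on data
    with no true association each test passes a fraction ~alpha of the
    observed features.
    """
    params = params or ChuangParams()
    if params.alpha >= 1 or not feats.features:
        return RankedFeatureList(list(feats.features), method=feats.method,
                                 source_fingerprint=feats.source_fingerprint)
    net = net.restrict_to(train.gene_ids)
    n_perm = params.n_null_permutations
    n_bins = params.n_bins or default_n_bins(train.n_samples)
    labels = train.labels
    rng = np.random.default_rng([params.seed, 17])
    q = 100.0 * (1.0 - params.alpha)

    # null 1: greedily grown subnetworks from random seeds, per size
    sizes = sorted({len(f.member_genes) for f in feats.features})
    nodes = sorted(net.nodes)
    null1 = {}
    for size in sizes:
        null = []
        attempts = 0
        while len(null) < n_perm and attempts < 20 * n_perm:
            attempts += 1
            seed_node = nodes[rng.integers(len(nodes))]
            mi = _greedy_subnetwork_to_size(train, net, seed_node, size,
                                            n_bins, labels)
            if mi is not None:
                null.append(mi)
        null1[size] = np.percentile(null, q) if null else np.inf

    null2 = _null_search_mis(train, net, params, rng, mode="genes")
    null3 = _null_search_mis(train, net, params, rng, mode="labels")

    kept = [
        f for f in feats.features
        if f.score > null1[len(f.member_genes)]
        and f.score > _size_threshold(null2, len(f.member_genes), q)
        and f.score > _size_threshold(null3, len(f.member_genes), q)
    ]
    return RankedFeatureList(kept, method=feats.method,
                             source_fingerprint=feats.source_fingerprint)


# ---------------------------------------------------------------------------
# Lee-style CORG search
# ---------------------------------------------------------------------------

def lee_corg(train: ExpressionDataset, pathway, name: str = ""
             ) -> CompositeFeature | None:
    """Greedy condition-responsive-gene subset of one pathway.

    Genes are ordered by t (descending if the largest-|t| gene has a
    positive t, else ascending; |t| ties break lexicographically).  The
    prefix is extended while the |t| of the averaged activity strictly
    increases.  Returns None when no pathway gene is measured.
    """
    measured = [g for g in pathway if g in train._gene_index]
    if not measured:
        return None
    labels = train.labels
    t = _tstat_columns(train.columns(measured), labels)
    t = np.nan_to_num(t, nan=0.0)
    lead = min(range(len(measured)),
               key=lambda i: (-abs(t[i]), measured[i]))
    descending = t[lead] >= 0
    order = sorted(
        range(len(measured)),
        key=lambda i: ((-t[i] if descending else t[i]), measured[i]),
    )
    ordered = [measured[i] for i in order]

    members = [ordered[0]]
    total = train.column(ordered[0]).astype(float).copy()
    best = abs(tstat(total[labels == 1], total[labels == 0]))
    for g in ordered[1:]:
        cand = total + train.column(g)
        act = cand / np.sqrt(len(members) + 1)
        try:
            score = abs(tstat(act[labels == 1], act[labels == 0]))
        except ValueError:
            break
        if score > best:
            members.append(g)
            total = cand
            best = score
        else:
            break
    return CompositeFeature(
        name=name or "corg:" + "+".join(members),
        member_genes=tuple(members),
        score=float(best),
        kind="corg",
    )


def lee_rank_pathways(train: ExpressionDataset, coll: GeneSetCollection,
                      top_k: int | None = None) -> RankedFeatureList:
    """One CORG feature per gene set, ranked by score.

    ``top_k=None`` keeps all sets when the collection is small and the
    best 400 when it is larger (the convention for large curated
    collections); pass an explicit value to override.  Sets with no
    measured gene are skipped with a log notice.
    """
    feats = []
    for set_name in sorted(coll.sets):
        f = lee_corg(train, coll.sets[set_name], name=set_name)
        if f is None:
            logger.info("gene set %s has no measured genes; skipped", set_name)
            continue
        feats.append(f)
    feats.sort(key=lambda f: (-f.score, f.name))
    if top_k is None and len(coll) > 400:
        top_k = 400
    if top_k is not None:
        feats = feats[:top_k]
    return RankedFeatureList(feats, method="lee")


# ---------------------------------------------------------------------------
# Taylor-style hub analysis
# ---------------------------------------------------------------------------

def hub_difference(train: ExpressionDataset, hub: str, interactor: str
                   ) -> float:
    """Class-1 minus class-0 Pearson correlation of hub vs interactor."""
    labels = train.labels
    if (labels == 1).sum() < 3 or (labels == 0).sum() < 3:
        raise ValueError("each class needs at least three samples "
                         "for within-class correlations")
    h = train.column(hub)
    x = train.column(interactor)
    c1 = pearson(h[labels == 1], x[labels == 1])
    c0 = pearson(h[labels == 0], x[labels == 0])
    return c1 - c0


def avg_hub_difference(train: ExpressionDataset, hub: str, neighbors
                       ) -> float:
    """Mean hub difference over the hub's measured interactors."""
    neighbors = list(neighbors)
    if not neighbors:
        raise ValueError("hub has no measured neighbors")
    return float(np.mean([hub_difference(train, hub, n) for n in neighbors]))


def _avg_diff_matrix(hub_col, nbr_cols, labels) -> float:
    """Vectorized average hub difference (degenerate edges contribute 0)."""
    diffs = []
    for cls in (1, 0):
        mask = labels == cls
        h = hub_col[mask]
        x = nbr_cols[mask]
        hc = h - h.mean()
        xc = x - x.mean(axis=0)
        sh = h.std()
        sx = x.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (hc @ xc) / (h.size * sh * sx)
        corr = np.where((sh == 0) | (sx == 0), 0.0, corr)
        diffs.append(corr)
    return float(np.mean(diffs[0] - diffs[1]))


def taylor_candidate_hubs(net: Network, hub_fraction: float = 0.15) -> list:
    """The top ``hub_fraction`` of nodes by degree in the full network,
    ties at the cutoff included, before any expression filtering."""
    if net.n_nodes == 0:
        return []
    degrees = sorted((net.degree(n) for n in net.nodes), reverse=True)
    m = max(1, int(round(hub_fraction * net.n_nodes)))
    cutoff = degrees[min(m, len(degrees)) - 1]
    return sorted(n for n in net.nodes if net.degree(n) >= cutoff)


def taylor_significant_hubs(train: ExpressionDataset, net: Network,
                            params: TaylorParams | None = None
                            ) -> RankedFeatureList:
    """Hubs whose average correlation difference beats a label-permutation
    null.

    Candidate hubs are the top ``hub_fraction`` of nodes by degree in
    the *full* network (ties at the cutoff included), before any
    expression filtering.  Hubs without measured expression or without
    measured neighbors are then excluded.  The empirical p-value is the
    fraction of permutation replicates whose |average difference|
    reaches the observed one; hubs with p < alpha are kept and ranked
    by |average hub difference|.
    """
    params = params or TaylorParams()
    if net.n_nodes == 0:
        return RankedFeatureList([], method="taylor")
    candidates = taylor_candidate_hubs(net, params.hub_fraction)

    measured = set(train.gene_ids)
    labels = train.labels
    if (labels == 1).sum() < 3 or (labels == 0).sum() < 3:
        raise ValueError("each class needs at least three samples")
    rng = np.random.default_rng([params.seed, 23])
    perms = [rng.permutation(labels) for _ in range(params.n_label_permutations)]

    feats = []
    for hub in candidates:
        if hub not in measured:
            continue
        nbrs = [x for x in net.neighbors(hub) if x in measured]
        if not nbrs:
            continue
        hub_col = train.column(hub)
        nbr_cols = train.columns(nbrs)
        obs = _avg_diff_matrix(hub_col, nbr_cols, labels)
        exceed = sum(
            abs(_avg_diff_matrix(hub_col, nbr_cols, p)) >= abs(obs)
            for p in perms
        )
        pval = exceed / max(1, len(perms))
        if pval < params.alpha:
            feats.append(
                CompositeFeature(
                    name=f"hub:{hub}",
                    member_genes=tuple([hub] + nbrs),
                    score=float(abs(obs)),
                    kind="hub",
                    hub_gene=hub,
                )
            )
    feats.sort(key=lambda f: (-f.score, f.name))
    return RankedFeatureList(feats, method="taylor")


# ---------------------------------------------------------------------------
# per-sample feature values
# ---------------------------------------------------------------------------

def feature_values(ds: ExpressionDataset, feature: CompositeFeature,
                   activity_norm: str = "sqrt") -> np.ndarray:
    """Per-sample classifier input for one feature.

    single_gene -> the gene column, shape (k,); subnetwork / corg ->
    the activity, shape (k,); hub -> one column per interactor with
    e(hub) - e(interactor), shape (k, n_interactors).
    """
    if feature.kind == "single_gene":
        return ds.column(feature.member_genes[0])
    if feature.kind in ("subnetwork", "corg"):
        return activity(ds, feature.member_genes, norm=activity_norm)
    if feature.kind == "hub":
        hub = ds.column(feature.hub_gene)
        interactors = [g for g in feature.member_genes if g != feature.hub_gene]
        return np.column_stack([hub - ds.column(g) for g in interactors])
    raise ValueError(f"unknown feature kind {feature.kind!r}")


# ---------------------------------------------------------------------------
# extractor objects (uniform surface for the evaluation protocol)
# ---------------------------------------------------------------------------

def _params_digest(obj) -> str:
    return hashlib.sha256(repr(sorted(asdict(obj).items())).encode()
                          ).hexdigest() if obj is not None else "none"


class _Extractor:
    method = "base"
    secondary_name = "none"

    def _fingerprint(self, train: ExpressionDataset, extra: str) -> str:
        h = hashlib.sha256()
        h.update(train.fingerprint().encode())
        h.update(extra.encode())
        return h.hexdigest()

    def extract(self, train: ExpressionDataset) -> RankedFeatureList:
        raise NotImplementedError

    def selection_universe(self, train: ExpressionDataset) -> frozenset:
        """Background gene pool the signature is selected from."""
        raise NotImplementedError


class SingleGeneExtractor(_Extractor):
    """t-statistic ranking of individual genes; no secondary source."""

    method = "sg"

    def __init__(self, restrict_to=None, secondary_name: str = "none"):
        self.restrict_to = None if restrict_to is None else set(restrict_to)
        self.secondary_name = secondary_name

    def extract(self, train):
        from .data import restrict_genes

        if self.restrict_to is not None:
            train = restrict_genes(train, self.restrict_to)
        ranked = rank_single_genes(train)
        ranked.source_fingerprint = self._fingerprint(
            train, f"sg:{self.secondary_name}"
        )
        return ranked

    def selection_universe(self, train):
        genes = set(train.gene_ids)
        if self.restrict_to is not None:
            genes &= self.restrict_to
        return frozenset(genes)


class ChuangExtractor(_Extractor):
    method = "chuang"

    def __init__(self, network: Network, params: ChuangParams | None = None,
                 secondary_name: str = "network"):
        self.network = network
        self.params = params or ChuangParams()
        self.secondary_name = secondary_name

    def extract(self, train):
        ranked = chuang_search(train, self.network, self.params)
        if self.params.n_null_permutations > 0 and self.params.alpha < 1:
            ranked = chuang_significance_filter(
                ranked, train, self.network, self.params
            )
        ranked.source_fingerprint = self._fingerprint(
            train, self.network.fingerprint() + _params_digest(self.params)
        )
        return ranked

    def selection_universe(self, train):
        return frozenset(self.network.nodes & set(train.gene_ids))


class LeeExtractor(_Extractor):
    method = "lee"

    def __init__(self, collection: GeneSetCollection,
                 top_k: int | None = None,
                 secondary_name: str = "genesets"):
        self.collection = collection
        self.top_k = top_k
        self.secondary_name = secondary_name

    def extract(self, train):
        coll = self.collection.restrict_to(train.gene_ids)
        ranked = lee_rank_pathways(train, coll, top_k=self.top_k)
        ranked.source_fingerprint = self._fingerprint(
            train, self.collection.fingerprint() + f"top_k={self.top_k}"
        )
        return ranked

    def selection_universe(self, train):
        return frozenset(self.collection.gene_universe & set(train.gene_ids))


class TaylorExtractor(_Extractor):
    method = "taylor"

    def __init__(self, network: Network, params: TaylorParams | None = None,
                 secondary_name: str = "network"):
        self.network = network
        self.params = params or TaylorParams()
        self.secondary_name = secondary_name

    def extract(self, train):
        ranked = taylor_significant_hubs(train, self.network, self.params)
        ranked.source_fingerprint = self._fingerprint(
            train, self.network.fingerprint() + _params_digest(self.params)
        )
        return ranked

    def selection_universe(self, train):
        return frozenset(self.network.nodes & set(train.gene_ids))
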