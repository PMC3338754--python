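"""Core data containers and dataset-level transforms.

Expression data are stored samples-by-genes.  Outcome labels follow the
convention 1 = poor outcome (event within five years), 0 = good outcome;
every downstream sign convention (t-statistics, classifier scores) inherits
it.  Secondary data sources come in two flavours: an undirected
:class:`Network` of gene--gene interactions and a :class:`GeneSetCollection`
of named pathways / gene sets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ExpressionDataset",
    "Network",
    "GeneSetCollection",
    "CompositeFeature",
    "RankedFeatureList",
    "znormalize",
    "restrict_genes",
    "merge_datasets",
]


@dataclass(eq=False)
class ExpressionDataset:
    """A samples x genes expression matrix with binary outcome labels.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per row.
    gene_ids : list of str
        One identifier per column; must be unique.
    values : ndarray of shape (n_samples, n_genes)
    labels : ndarray of int
        1 = poor outcome, 0 = good outcome.
    er_status : ndarray of int, optional
        Estrogen-receptor status per sample (1 = positive), if known.
    name : str
        Cohort name, used to prefix sample ids when datasets are merged.
    """

    sample_ids: list
    gene_ids: list
    values: np.ndarray
    labels: np.ndarray
    er_status: np.ndarray | None = None
    name: str = ""

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d samples x genes matrix")
        k, n = self.values.shape
        if k != len(self.sample_ids):
            raise ValueError(
                f"{k} rows but {len(self.sample_ids)} sample ids"
            )
        if n != len(self.gene_ids):
            raise ValueError(f"{n} columns but {len(self.gene_ids)} gene ids")
        if len(set(self.gene_ids)) != n:
            seen, dups = set(), set()
            for g in self.gene_ids:
                if g in seen:
                    dups.add(g)
                seen.add(g)
            raise ValueError(f"duplicate gene ids: {sorted(dups)}")
        if self.labels.shape != (k,):
            raise ValueError("labels must have one entry per sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = good, 1 = poor)")
        if self.er_status is not None:
            self.er_status = np.asarray(self.er_status, dtype=int)
            if self.er_status.shape != (k,):
                raise ValueError("er_status must have one entry per sample")
        self._gene_index = {g: j for j, g in enumerate(self.gene_ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in dataset") from None

    def column(self, gene: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene)]

    def columns(self, genes: Sequence[str]) -> np.ndarray:
        idx = [self.gene_index(g) for g in genes]
        return self.values[:, idx]

    def subset_samples(self, index: np.ndarray, name: str | None = None
                       ) -> "ExpressionDataset":
        """Return a copy restricted to the given sample positions."""
        index = np.asarray(index)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in index],
            gene_ids=list(self.gene_ids),
            values=self.values[index],
            labels=self.labels[index],
            er_status=None if self.er_status is None else self.er_status[index],
            name=self.name if name is None else name,
        )

    def equals(self, other: "ExpressionDataset", rtol: float = 1e-9) -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.allclose(self.values, other.values, rtol=rtol, atol=1e-12)
            and np.array_equal(self.labels, other.labels)
            and (
                (self.er_status is None) == (other.er_status is None)
                and (self.er_status is None
                     or np.array_equal(self.er_status, other.er_status))
            )
        )

    def fingerprint(self) -> str:
        """Content hash, invariant to sample-row order.

        Rows are sorted by sample id and values rounded to 10 decimals
        before hashing, so two datasets holding the same samples in a
        different order fingerprint identically.
        """
        order = np.argsort(np.asarray(self.sample_ids, dtype=object))
        h = hashlib.sha256()
        h.update("\x00".join(self.sample_ids[i] for i in order).encode())
        h.update("\x00".join(self.gene_ids).encode())
        h.update(np.round(self.values[order], 10).tobytes())
        h.update(self.labels[order].astype(np.int64).tobytes())
        if self.er_status is not None:
            h.update(self.er_status[order].astype(np.int64).tobytes())
        return h.hexdigest()


def znormalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize every gene column to mean 0, sd 1 (sample sd, n-1).

    Raises
    ------
    ValueError
        If any gene column is constant (zero standard deviation), naming
        the offending gene(s).
    """
    if ds.n_samples < 2:
        raise ValueError("z-normalization needs at least two samples")
    mean = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        names = [ds.gene_ids[j] for j in bad[:10]]
        raise ValueError(f"constant gene column(s): {names}")
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        gene_ids=list(ds.gene_ids),
        values=(ds.values - mean) / sd,
        labels=ds.labels.copy(),
        er_status=None if ds.er_status is None else ds.er_status.copy(),
        name=ds.name,
    )


def restrict_genes(ds: ExpressionDataset, universe: Iterable[str]
                   ) -> ExpressionDataset:
    """Keep only genes present in ``universe``, preserving column order."""
    universe = set(universe)
    keep = [j for j, g in enumerate(ds.gene_ids) if g in universe]
    if not keep:
        raise ValueError("gene universe does not intersect the dataset")
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        gene_ids=[ds.gene_ids[j] for j in keep],
        values=ds.values[:, keep],
        labels=ds.labels.copy(),
        er_status=None if ds.er_status is None else ds.er_status.copy(),
        name=ds.name,
    )


def merge_datasets(datasets: Sequence[ExpressionDataset]
                   ) -> ExpressionDataset:
    """Pool samples from several cohorts and re-z-normalize the pool.

    All inputs must cover the same gene universe (columns are aligned to
    the first dataset's order).  Sample ids are prefixed with the cohort
    name so they stay unique in the pool.
    """
    if not datasets:
        raise ValueError("no datasets to merge")
    ref = datasets[0]
    ref_set = set(ref.gene_ids)
    blocks, ids, labels, ers = [], [], [], []
    have_er = all(d.er_status is not None for d in datasets)
    for i, d in enumerate(datasets):
        dset = set(d.gene_ids)
        if dset != ref_set:
            diff = sorted(dset.symmetric_difference(ref_set))
            raise ValueError(
                f"gene universes differ; symmetric difference: {diff[:20]}"
            )
        blocks.append(d.columns(ref.gene_ids))
        prefix = d.name or f"ds{i}"
        ids.extend(f"{prefix}:{s}" for s in d.sample_ids)
        labels.append(d.labels)
        if have_er:
            ers.append(d.er_status)
    merged = ExpressionDataset(
        sample_ids=ids,
        gene_ids=list(ref.gene_ids),
        values=np.vstack(blocks),
        labels=np.concatenate(labels),
        er_status=np.concatenate(ers) if have_er else None,
        name="+".join(d.name or f"ds{i}" for i, d in enumerate(datasets)),
    )
    return znormalize(merged)


# ---------------------------------------------------------------------------
# secondary data sources
# ---------------------------------------------------------------------------

def _canon_edge(a: str, b: str) -> tuple:
    return (a, b) if a <= b else (b, a)


@dataclass(eq=False)
class Network:
    """An undirected gene--gene interaction network.

    Edges are stored once as sorted (a, b) tuples; self-loops are
    rejected and both endpoints must be declared nodes.
    """

    nodes: frozenset
    edges: frozenset

    def __init__(self, nodes: Iterable[str], edges: Iterable):
        node_set = frozenset(str(n) for n in nodes)
        canon = set()
        for e in edges:
            a, b = e
            a, b = str(a), str(b)
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) has undeclared endpoint")
            canon.add(_canon_edge(a, b))
        self.nodes = node_set
        self.edges = frozenset(canon)
        self._adj = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict:
        if self._adj is None:
            adj = {n: set() for n in self.nodes}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adj = {n: tuple(sorted(v)) for n, v in adj.items()}
        return self._adj

    def neighbors(self, node: str) -> tuple:
        return self.adjacency()[node]

    def degree(self, node: str) -> int:
        return len(self.adjacency()[node])

    def restrict_to(self, genes: Iterable[str]) -> "Network":
        """Induced subgraph on ``genes`` (typically the measured genes)."""
        keep = self.nodes & set(genes)
        edges = [e for e in self.edges if e[0] in keep and e[1] in keep]
        return Network(keep, edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update("\x00".join(sorted(self.nodes)).encode())
        h.update(
            "\x00".join(f"{a}\x01{b}" for a, b in sorted(self.edges)).encode()
        )
        return h.hexdigest()


@dataclass(eq=False)
class GeneSetCollection:
    """Named gene sets (pathways), each a list of gene ids."""

    sets: Mapping

    def __init__(self, sets: Mapping):
        clean = {}
        for name, genes in sets.items():
            genes = [str(g) for g in genes]
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[str(name)] = genes
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def gene_universe(self) -> frozenset:
        return frozenset(g for genes in self.sets.values() for g in genes)

    def restrict_to(self, genes: Iterable[str]) -> "GeneSetCollection":
        """Drop unmeasured genes; sets that become empty are dropped."""
        genes = set(genes)
        out = {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in genes]
            if kept:
                out[name] = kept
        return GeneSetCollection(out)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.sets):
            h.update(name.encode())
            h.update("\x00".join(self.sets[name]).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("single_gene", "subnetwork", "corg", "hub")


@dataclass(frozen=True)
class CompositeFeature:
    """A named gene group with a discriminative score.

    ``kind`` identifies the extraction method family: ``single_gene``
    (score = |t|), ``subnetwork`` (score = mutual information),
    ``corg`` (score = |t| of the averaged activity) or ``hub``
    (score = |average hub difference|; ``hub_gene`` names the hub).
    """

    name: str
    member_genes: tuple
    score: float
    kind: str
    hub_gene: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "member_genes", tuple(self.member_genes))
        if not self.member_genes:
            raise ValueError("feature has no member genes")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "single_gene" and len(self.member_genes) != 1:
            raise ValueError("single_gene feature must have exactly one gene")
        if self.kind == "hub":
            if self.hub_gene is None or self.hub_gene not in self.member_genes:
                raise ValueError("hub feature requires hub_gene in members")


@dataclass
class RankedFeatureList:
    """Features from one training set, in descending-score order."""

    features: list
    method: str
    source_fingerprint: str = ""

    def __post_init__(self):
        scores = [f.score for f in self.features]
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(scores, scores[1:])):
            raise ValueError("feature scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.features)

    def top(self, n: int) -> list:
        return self.features[:n]
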