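"""Synthetic multi-cohort expression data with known ground truth.

The generator emulates the structure of a multi-cohort breast-cancer
benchmark: several cohorts measure the same gene universe, share a common
set of outcome-associated ("informative") genes, and differ by additive
per-cohort, per-gene batch offsets.  Class labels are imbalanced (poor
outcome is the minority class).  Secondary sources -- an interaction
network and a gene-set collection -- partially overlap the measured gene
universe and carry planted differential modules whose members are
informative genes.

Within a planted module, members share a latent factor; the loading sign
of the non-hub members flips in the poor class (when ``module_corr_flip``
is on), so hub--interactor correlation differences between classes are
non-trivial.  Without some class-dependent correlation structure the
average hub difference would be identically zero in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ExpressionDataset, GeneSetCollection, Network, znormalize

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ground_truth",
    "simulate_cohorts",
    "simulate_network",
    "simulate_genesets",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    Defaults emulate the benchmark's study conditions at desk scale: six
    cohorts of ~100 samples, ~28% poor outcome, moderate batch effects,
    a scale-free-ish interaction network with a tenth of its nodes
    unmeasured, and planted connected modules of informative genes.
    """

    n_cohorts: int = 6
    samples_per_cohort: int = 100
    n_genes: int = 300
    n_informative: int = 30
    effect_size: float = 1.0          # mean shift (sd units) in poor class
    poor_fraction: float = 0.28       # cf. the 20-35% range in real cohorts
    batch_sd: float = 0.3             # per-cohort per-gene offset scale
    network_degree_exponent: float = 2.5
    planted_module_sizes: tuple = (8, 10)
    seed: int = 0
    # structural knobs
    module_factor_loading: float = 0.5
    module_corr_flip: bool = True     # flip interactor loadings in poor class
    unmeasured_fraction: float = 0.10
    module_hub_boost: int = 8         # extra random edges on module hubs
    n_gene_sets: int = 40
    gene_set_size_range: tuple = (10, 40)
    er_positive_prob: float = 0.7
    er_outcome_coupling: float = 0.0  # >0 lowers P(ER+) for poor samples

    def __post_init__(self):
        if not 0 < self.poor_fraction < 1:
            raise ValueError("poor_fraction must be in (0, 1)")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if sum(self.planted_module_sizes) > self.n_informative:
            raise ValueError("planted module genes must fit in informative set")
        if any(s < 2 for s in self.planted_module_sizes):
            raise ValueError("planted modules need at least two genes")
        if self.samples_per_cohort < 8:
            raise ValueError("need at least 8 samples per cohort")
        if not 0 <= self.unmeasured_fraction < 1:
            raise ValueError("unmeasured_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: informative genes, modules and their hubs."""

    informative_genes: list
    module_genes: list          # list of gene-id lists, one per module
    module_hubs: list           # first gene of each module
    planted_set_names: list = field(default_factory=list)
    config: SimulationConfig | None = None


def _gene_ids(n: int) -> list:
    return [f"g{i:06d}" for i in range(1, n + 1)]


def ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Deterministic assignment of informative genes and planted modules.

    Derived from ``cfg.seed`` alone so that cohorts, network and gene
    sets generated from the same config agree on the planted structure.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    genes = _gene_ids(cfg.n_genes)
    informative = sorted(
        rng.choice(genes, size=cfg.n_informative, replace=False).tolist()
    )
    pool = list(informative)
    rng.shuffle(pool)
    modules, start = [], 0
    for size in cfg.planted_module_sizes:
        modules.append(sorted(pool[start:start + size]))
        start += size
    hubs = [m[0] for m in modules]
    return GroundTruth(
        informative_genes=informative,
        module_genes=modules,
        module_hubs=hubs,
        config=cfg,
    )


def simulate_cohorts(cfg: SimulationConfig):
    """Generate the cohorts; returns (datasets, ground_truth).

    Each cohort draws background expression N(batch offset, 1); the
    informative genes get a +effect_size mean shift in poor-outcome
    samples; planted-module members additionally share a latent factor
    (see module docstring).  Each cohort is z-normalized afterwards, as
    the real cohorts are distributed.
    """
    truth = ground_truth(cfg)
    genes = _gene_ids(cfg.n_genes)
    gidx = {g: j for j, g in enumerate(genes)}
    inf_idx = [gidx[g] for g in truth.informative_genes]
    k = cfg.samples_per_cohort
    n_poor = min(max(2, round(cfg.poor_fraction * k)), k - 2)

    datasets = []
    for c in range(cfg.n_cohorts):
        rng = np.random.default_rng([cfg.seed, 202, c])
        labels = np.zeros(k, dtype=int)
        labels[:n_poor] = 1
        rng.shuffle(labels)
        offsets = rng.normal(0.0, cfg.batch_sd, size=cfg.n_genes)
        values = offsets + rng.normal(0.0, 1.0, size=(k, cfg.n_genes))
        if inf_idx:
            values[np.ix_(labels == 1, inf_idx)] += cfg.effect_size
        lam = cfg.module_factor_loading
        for module, hub in zip(truth.module_genes, truth.module_hubs):
            factor = rng.normal(0.0, 1.0, size=k)
            sign = np.ones(k)
            if cfg.module_corr_flip:
                sign[labels == 1] = -1.0
            for g in module:
                j = gidx[g]
                if g == hub:
                    values[:, j] += lam * factor
                else:
                    values[:, j] += lam * sign * factor
        p_er = np.where(
            labels == 1,
            np.clip(cfg.er_positive_prob - cfg.er_outcome_coupling, 0, 1),
            cfg.er_positive_prob,
        )
        er = (rng.random(k) < p_er).astype(int)
        ds = ExpressionDataset(
            sample_ids=[f"c{c}s{i:04d}" for i in range(k)],
            gene_ids=genes,
            values=values,
            labels=labels,
            er_status=er,
            name=f"cohort{c}",
        )
        datasets.append(znormalize(ds))
    return datasets, truth


def _power_law_degrees(rng, n: int, exponent: float, d_max: int) -> np.ndarray:
    """Discrete power-law-ish degree sequence with minimum degree 1."""
    u = rng.random(n)
    deg = np.floor((1.0 - u) ** (-1.0 / (exponent - 1.0))).astype(int)
    deg = np.clip(deg, 1, d_max)
    if deg.sum() % 2:
        deg[rng.integers(n)] += 1
    return deg


def simulate_network(cfg: SimulationConfig) -> Network:
    """Degree-heterogeneous network with planted connected modules.

    ~``unmeasured_fraction`` of the nodes carry ids absent from the
    expression gene universe, emulating proteins without expression
    data.  Each planted module is wired as a star around its hub gene
    (plus sparse chain edges), and the hub receives
    ``module_hub_boost`` extra random attachments so it lands in the
    high-degree (candidate hub) range.
    """
    import networkx as nx

    truth = ground_truth(cfg)
    rng = np.random.default_rng([cfg.seed, 303])
    n_nodes = cfg.n_genes
    n_unmeasured = int(round(cfg.unmeasured_fraction * n_nodes))
    n_measured = n_nodes - n_unmeasured

    module_genes = [g for m in truth.module_genes for g in m]
    other_measured = [g for g in _gene_ids(cfg.n_genes) if g not in set(module_genes)]
    chosen = rng.choice(
        other_measured, size=n_measured - len(module_genes), replace=False
    ).tolist()
    node_ids = module_genes + chosen + [f"u{i:06d}" for i in range(n_unmeasured)]
    node_ids = list(node_ids)
    rng.shuffle(node_ids)

    deg = _power_law_degrees(
        rng, n_nodes, cfg.network_degree_exponent,
        d_max=max(3, int(3 * np.sqrt(n_nodes))),
    )
    g = nx.configuration_model(deg.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    mapping = {i: node_ids[i] for i in range(n_nodes)}
    g = nx.relabel_nodes(g, mapping)

    for module, hub in zip(truth.module_genes, truth.module_hubs):
        members = [x for x in module if x != hub]
        for m in members:
            g.add_edge(hub, m)
        for a, b in zip(members, members[1:]):
            if rng.random() < 0.3:
                g.add_edge(a, b)
        non_members = [x for x in node_ids if x not in set(module)]
        extra = rng.choice(non_members, size=min(cfg.module_hub_boost,
                                                 len(non_members)),
                           replace=False)
        for x in extra:
            g.add_edge(hub, x)

    return Network(g.nodes, g.edges)


def simulate_genesets(cfg: SimulationConfig) -> GeneSetCollection:
    """Gene-set collection with planted enriched sets.

    One planted set per module: the module genes padded with random
    genes to about twice the module size.  The remaining sets are drawn
    uniformly from the gene universe.
    """
    truth = ground_truth(cfg)
    rng = np.random.default_rng([cfg.seed, 404])
    genes = _gene_ids(cfg.n_genes)
    lo, hi = cfg.gene_set_size_range
    sets = {}
    for i, module in enumerate(truth.module_genes):
        pad = rng.choice(
            [g for g in genes if g not in set(module)],
            size=len(module), replace=False,
        ).tolist()
        name = f"planted_module_{i:02d}"
        sets[name] = sorted(module) + pad
        truth.planted_set_names.append(name)
    n_random = max(0, cfg.n_gene_sets - len(sets))
    for i in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        sets[f"set_{i:03d}"] = rng.choice(genes, size=size,
                                          replace=False).tolist()
    return GeneSetCollection(sets)
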