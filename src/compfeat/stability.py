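"""Cross-dataset signature stability with size correction.

A signature is the union of genes in the top-n ranked features extracted
from one cohort.  Overlap between two cohorts' signatures is measured by
the one-sided Fisher exact (hypergeometric) p-value -- interpreted as an
overlap measure, not a hypothesis test, which automatically accounts for
the size of the selection universe -- and by the Jaccard index with an
empirical sampling null of size-matched random signatures.  Because one
composite feature can contain many genes, single-gene signatures are
size-matched per cohort (the best m single genes, with m the composite
signature's gene count) before any comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data import ExpressionDataset
from .features import rank_single_genes

__all__ = [
    "SignatureSet",
    "signature_genes",
    "fisher_overlap",
    "size_matched_sg",
    "jaccard_with_null",
    "stability_report",
]


@dataclass
class SignatureSet:
    dataset_name: str
    method: str
    gene_ids: frozenset
    universe: frozenset

    def __post_init__(self):
        self.gene_ids = frozenset(self.gene_ids)
        self.universe = frozenset(self.universe)
        if not self.gene_ids <= self.universe:
            raise ValueError("signature genes must lie in the universe")


def signature_genes(ds: ExpressionDataset, extractor, top_n: int,
                    universe=None) -> SignatureSet:
    """Union of member genes of the top-n features extracted from ``ds``.

    The default universe is the pool the extractor selects from: all
    measured genes for single genes, the measured genes of the
    secondary source for composite features.
    """
    ranked = extractor.extract(ds)
    genes = set()
    for f in ranked.top(top_n):
        genes.update(f.member_genes)
    if universe is None:
        universe = extractor.selection_universe(ds)
    return SignatureSet(
        dataset_name=ds.name,
        method=extractor.method,
        gene_ids=frozenset(genes),
        universe=frozenset(universe),
    )


def fisher_overlap(a: SignatureSet, b: SignatureSet) -> float:
    """One-sided (enrichment) Fisher exact p of the signature overlap.

    The hypergeometric upper tail P(X >= |a & b|) given |a|, |b| and
    the common universe; smaller p means more surprising overlap.
    """
    if a.universe != b.universe:
        raise ValueError("signatures were selected from different universes")
    overlap = len(a.gene_ids & b.gene_ids)
    m = len(a.universe)
    return float(hypergeom.sf(overlap - 1, m, len(a.gene_ids),
                              len(b.gene_ids)))


def size_matched_sg(ds: ExpressionDataset, m: int,
                    universe=None) -> SignatureSet:
    """The best m single genes by |t| on the full dataset.

    With an explicit ``universe`` the genes are selected from (and the
    overlap measured against) that pool only.
    """
    if universe is not None:
        from .data import restrict_genes

        ds = restrict_genes(ds, universe)
    if m > ds.n_genes:
        raise ValueError(f"requested {m} genes but only {ds.n_genes} measured")
    if m < 1:
        raise ValueError("need m >= 1")
    ranked = rank_single_genes(ds)
    genes = frozenset(f.member_genes[0] for f in ranked.top(m))
    return SignatureSet(
        dataset_name=ds.name,
        method="sg_size_matched",
        gene_ids=genes,
        universe=frozenset(ds.gene_ids if universe is None else universe),
    )


def jaccard_with_null(a: SignatureSet, b: SignatureSet,
                      n_draws: int = 1000, seed: int = 0):
    """Jaccard index plus an empirical p against size-matched random sets.

    The null draws ``n_draws`` pairs of random sets of sizes |a| and
    |b| from the common universe; p = (1 + #{J_null >= J}) / (1 + n).
    """
    if a.universe != b.universe:
        raise ValueError("signatures were selected from different universes")
    inter = len(a.gene_ids & b.gene_ids)
    union = len(a.gene_ids | b.gene_ids)
    j = inter / union if union else 1.0
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(a.universe))
    na, nb = len(a.gene_ids), len(b.gene_ids)
    exceed = 0
    for _ in range(n_draws):
        sa = set(rng.choice(universe, size=na, replace=False))
        sb = set(rng.choice(universe, size=nb, replace=False))
        ji = len(sa & sb) / len(sa | sb)
        if ji >= j:
            exceed += 1
    return j, (1 + exceed) / (1 + n_draws)


def stability_report(datasets, extractors: dict, top_n: int = 50,
                     common_universe: bool = False,
                     jaccard_draws: int = 200, seed: int = 0) -> pd.DataFrame:
    """Pairwise stability table: D cohorts -> C(D, 2) rows per method.

    Columns per unordered cohort pair: Fisher overlap p, Jaccard index
    and its sampling p, and the same Fisher measure for the
    size-matched single-gene control.  ``common_universe=True`` forces
    all methods onto the intersection of their selection universes so
    the overlap measures are directly comparable across methods.
    """
    sigs = {
        name: [signature_genes(d, ex, top_n) for d in datasets]
        for name, ex in extractors.items()
    }
    if common_universe:
        shared = None
        for sig_list in sigs.values():
            for s in sig_list:
                shared = s.universe if shared is None else shared & s.universe
        for sig_list in sigs.values():
            for i, s in enumerate(sig_list):
                sig_list[i] = SignatureSet(
                    s.dataset_name, s.method,
                    s.gene_ids & shared, shared,
                )
    rows = []
    for name, sig_list in sigs.items():
        controls = [
            size_matched_sg(
                d, max(1, len(s.gene_ids)),
                universe=(s.universe if common_universe else None),
            )
            for d, s in zip(datasets, sig_list)
        ]
        for i, j in itertools.combinations(range(len(datasets)), 2):
            fp = fisher_overlap(sig_list[i], sig_list[j])
            jac, jac_p = jaccard_with_null(
                sig_list[i], sig_list[j], n_draws=jaccard_draws,
                seed=seed + 1000 * i + j,
            )
            cp = fisher_overlap(controls[i], controls[j])
            rows.append({
                "method": name,
                "dataset_a": datasets[i].name,
                "dataset_b": datasets[j].name,
                "signature_size_a": len(sig_list[i].gene_ids),
                "signature_size_b": len(sig_list[j].gene_ids),
                "fisher_p": fp,
                "jaccard": jac,
                "jaccard_p": jac_p,
                "sg_control_fisher_p": cp,
            })
    return pd.DataFrame(rows)
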