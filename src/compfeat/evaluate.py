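"""Leakage-free cross-dataset evaluation protocol.

The protocol trains everything -- composite-feature construction, the
choice of the number of features (by inner five-fold cross-validation),
and the final classifier -- on the training dataset alone, and measures
a single AUC on an untouched test dataset.  Three settings: *paired*
(every ordered train/test cohort pair), *merged* (leave one cohort out,
pool and re-normalize the rest) and *ER-stratified* (merged, restricted
to estrogen-receptor-positive samples).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import auc, build_feature_matrix, score, train_classifier
from .data import ExpressionDataset, merge_datasets
from .features import feature_values

__all__ = [
    "EvalRecord",
    "WinLossMatrix",
    "stratified_folds",
    "cv_select_n",
    "train_and_test",
    "paired_setting",
    "merged_setting",
    "er_stratified_setting",
    "win_loss",
    "compare_methods",
    "bonferroni",
]

logger = logging.getLogger(__name__)

FEATURE_GRID_CAP = 400


@dataclass
class EvalRecord:
    """One (train, test) evaluation outcome."""

    method: str
    secondary_source: str
    classifier_kind: str
    train_name: str
    test_name: str
    n_features_policy: str
    n_features_used: int
    auc: float
    feasible: bool = True
    converged: bool = True

    def __post_init__(self):
        if self.feasible and not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")


def _seed_from_fingerprint(ds: ExpressionDataset) -> int:
    return int(ds.fingerprint()[:8], 16) % (2**31)


def stratified_folds(ds: ExpressionDataset, n_folds: int = 5,
                     seed: int | None = None) -> list:
    """Label-stratified fold index arrays.

    Fold assignment is derived from a content hash of the dataset (and
    the canonical, id-sorted sample order), so it is reproducible and
    independent of input row order.
    """
    if seed is None:
        seed = _seed_from_fingerprint(ds)
    rng = np.random.default_rng(seed)
    order = sorted(range(ds.n_samples), key=lambda i: ds.sample_ids[i])
    folds = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.array([i for i in order if ds.labels[i] == cls])
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls} has {idx.size} samples; need >= {n_folds} "
                "for stratified folds"
            )
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def _prefix_matrices(ds: ExpressionDataset, features):
    """Full feature matrix plus cumulative column spans per feature."""
    blocks, columns, spans = [], [], []
    total = 0
    for f in features:
        vals = feature_values(ds, f)
        if vals.ndim == 1:
            vals = vals[:, None]
            columns.append(f.name)
        else:
            interactors = [g for g in f.member_genes if g != f.hub_gene]
            columns.extend(f"{f.name}|{g}" for g in interactors)
        blocks.append(vals)
        total += vals.shape[1]
        spans.append(total)
    values = np.hstack(blocks) if blocks else np.empty((ds.n_samples, 0))
    return values, columns, spans


def cv_select_n(train: ExpressionDataset, extractor, clf_kind: str = "nmc",
                grid=None, n_folds: int = 5, clf_kwargs: dict | None = None,
                return_mean_auc: bool = False):
    """Inner-CV choice of the number of (ranked) features.

    For Taylor features the grid counts feature *sets* (hubs), each of
    which expands to several classifier dimensions.  A fold whose
    extraction yields fewer features than a grid point contributes no
    vote for that point.  Ties go to the smallest n.
    """
    from .classify import FeatureMatrix

    clf_kwargs = clf_kwargs or {}
    folds = stratified_folds(train, n_folds=n_folds)
    votes = {}
    for v in range(n_folds):
        val_idx = folds[v]
        tr_idx = np.concatenate([folds[j] for j in range(n_folds) if j != v])
        tr = train.subset_samples(tr_idx)
        val = train.subset_samples(val_idx)
        if len(set(val.labels)) < 2:
            logger.info("fold %d validation part single-class; skipped", v)
            continue
        ranked = extractor.extract(tr)
        if len(ranked) == 0:
            logger.info("fold %d extracted no features; no votes", v)
            continue
        fold_grid = (
            range(1, min(len(ranked), FEATURE_GRID_CAP) + 1)
            if grid is None
            else [n for n in grid if n <= len(ranked)]
        )
        tr_vals, cols, spans = _prefix_matrices(tr, ranked.features)
        val_vals, _, _ = _prefix_matrices(val, ranked.features)
        for n in fold_grid:
            d = spans[n - 1]
            fm_tr = FeatureMatrix(tr_vals[:, :d], cols[:d], tr.labels)
            clf = train_classifier(fm_tr, clf_kind, **clf_kwargs)
            fm_val = FeatureMatrix(val_vals[:, :d], cols[:d], val.labels)
            votes.setdefault(n, []).append(auc(score(clf, fm_val), val.labels))
    if not votes:
        raise ValueError("no fold produced any features; cannot select n")
    means = {n: float(np.mean(a)) for n, a in votes.items()}
    best = min(means, key=lambda n: (-means[n], n))
    if return_mean_auc:
        return best, means[best]
    return best


def _policy_n(policy) -> int | None:
    """None for 'cv_opt', otherwise the fixed feature count."""
    if policy == "cv_opt":
        return None
    if isinstance(policy, int):
        return policy
    if isinstance(policy, str) and policy.startswith("fixed_"):
        return int(policy.split("_", 1)[1])
    raise ValueError(f"unknown n-features policy {policy!r}")


def train_and_test(train: ExpressionDataset, test: ExpressionDataset,
                   extractor, clf_kind: str = "nmc", policy="cv_opt",
                   grid=None, clf_kwargs: dict | None = None,
                   return_details: bool = False):
    """Run the full protocol for one (train, test) pair.

    With a fixed-n policy the run is recorded as infeasible (AUC NaN)
    when fewer than n features were extracted, rather than silently
    truncating.
    """
    if train is test or (train.name and train.name == test.name):
        raise ValueError("training and test datasets must differ")
    clf_kwargs = clf_kwargs or {}
    policy_name = policy if isinstance(policy, str) else f"fixed_{policy}"
    fixed_n = _policy_n(policy)
    ranked = extractor.extract(train)

    def _infeasible():
        rec = EvalRecord(
            method=extractor.method,
            secondary_source=extractor.secondary_name,
            classifier_kind=clf_kind,
            train_name=train.name,
            test_name=test.name,
            n_features_policy=policy_name,
            n_features_used=0,
            auc=float("nan"),
            feasible=False,
        )
        return (rec, None, ranked) if return_details else rec

    if fixed_n is None:
        if len(ranked) == 0:
            logger.warning("no features extracted on %s", train.name)
            return _infeasible()
        n = cv_select_n(train, extractor, clf_kind=clf_kind, grid=grid,
                        clf_kwargs=clf_kwargs)
    else:
        n = fixed_n
        if len(ranked) < n:
            logger.warning(
                "%s on %s: only %d features, policy needs %d",
                extractor.method, train.name, len(ranked), n,
            )
            return _infeasible()
    feats = ranked.top(n)
    fm_tr = build_feature_matrix(train, feats)
    clf = train_classifier(fm_tr, clf_kind, **clf_kwargs)
    if not clf.converged:
        logger.warning("classifier did not converge on %s", train.name)
    fm_te = build_feature_matrix(test, feats)
    rec = EvalRecord(
        method=extractor.method,
        secondary_source=extractor.secondary_name,
        classifier_kind=clf_kind,
        train_name=train.name,
        test_name=test.name,
        n_features_policy=policy_name,
        n_features_used=n,
        auc=auc(score(clf, fm_te), test.labels),
        converged=clf.converged,
    )
    return (rec, clf, ranked) if return_details else rec


def paired_setting(datasets, extractor, clf_kind: str = "nmc",
                   policy="cv_opt", grid=None,
                   clf_kwargs: dict | None = None) -> list:
    """All ordered (train, test) cohort pairs: D datasets -> D(D-1) records."""
    records = []
    for train, test in itertools.permutations(datasets, 2):
        records.append(
            train_and_test(train, test, extractor, clf_kind=clf_kind,
                           policy=policy, grid=grid, clf_kwargs=clf_kwargs)
        )
    return records


def merged_setting(datasets, extractor, clf_kind: str = "nmc",
                   policy="cv_opt", grid=None,
                   clf_kwargs: dict | None = None) -> list:
    """Leave-one-cohort-out: pool and re-normalize the rest for training."""
    records = []
    for i, test in enumerate(datasets):
        train = merge_datasets([d for j, d in enumerate(datasets) if j != i])
        records.append(
            train_and_test(train, test, extractor, clf_kind=clf_kind,
                           policy=policy, grid=grid, clf_kwargs=clf_kwargs)
        )
    return records


def er_stratified_setting(datasets, extractor, clf_kind: str = "nmc",
                          policy="cv_opt", grid=None,
                          clf_kwargs: dict | None = None) -> list:
    """Merged setting restricted to ER-positive samples.

    Cohorts are filtered to ER-positive cases *before* the training
    pool is merged and re-normalized.  A held-out cohort with no usable
    ER-positive test cases yields an infeasibility record.
    """
    for d in datasets:
        if d.er_status is None:
            raise ValueError(f"dataset {d.name!r} lacks er_status")
    er_subsets = [
        d.subset_samples(np.flatnonzero(d.er_status == 1)) for d in datasets
    ]
    records = []
    for i, test in enumerate(er_subsets):
        if test.n_samples == 0 or len(set(test.labels)) < 2:
            logger.warning("no usable ER+ test cases in %s", datasets[i].name)
            records.append(EvalRecord(
                method=extractor.method,
                secondary_source=extractor.secondary_name,
                classifier_kind=clf_kind,
                train_name="er_pool",
                test_name=datasets[i].name,
                n_features_policy=(policy if isinstance(policy, str)
                                   else f"fixed_{policy}"),
                n_features_used=0,
                auc=float("nan"),
                feasible=False,
            ))
            continue
        pool = [s for j, s in enumerate(er_subsets)
                if j != i and s.n_samples >= 2]
        train = merge_datasets(pool)
        records.append(
            train_and_test(train, test, extractor, clf_kind=clf_kind,
                           policy=policy, grid=grid, clf_kwargs=clf_kwargs)
        )
    return records


@dataclass
class WinLossMatrix:
    """Pairwise win/loss log-ratios between method x source combinations.

    Entry (i, j) = log2((wins_ij + 1) / (losses_ij + 1)) across shared
    (train, test) pairs; draws count for neither.  The +1 smoothing
    keeps all-win/all-loss entries finite; the matrix is antisymmetric
    with a zero diagonal.
    """

    labels: list
    matrix: np.ndarray


def win_loss(records) -> WinLossMatrix:
    by_combo = {}
    for r in records:
        if not r.feasible or not np.isfinite(r.auc):
            continue
        combo = (r.method, r.secondary_source)
        by_combo.setdefault(combo, {})[(r.train_name, r.test_name)] = r.auc
    combos = sorted(by_combo)
    m = len(combos)
    mat = np.zeros((m, m))
    for i, ci in enumerate(combos):
        for j, cj in enumerate(combos):
            if i >= j:
                continue
            shared = by_combo[ci].keys() & by_combo[cj].keys()
            wins = sum(by_combo[ci][k] > by_combo[cj][k] for k in shared)
            losses = sum(by_combo[ci][k] < by_combo[cj][k] for k in shared)
            val = np.log2((wins + 1.0) / (losses + 1.0))
            mat[i, j] = val
            mat[j, i] = -val
    labels = ["{}:{}".format(*c) for c in combos]
    return WinLossMatrix(labels=labels, matrix=mat)


def compare_methods(aucs_a, aucs_b, alternative: str = "two-sided") -> float:
    """Paired Wilcoxon signed-rank p-value over matched AUC vectors.

    ``alternative="greater"`` tests whether A scores higher than B.
    Zero differences are dropped (Wilcoxon convention); an exact null
    is used for small n without ties, a continuity-corrected normal
    approximation otherwise.  Identical vectors return p = 1.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("AUC vectors must be matched pairwise")
    if np.allclose(a, b):
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox",
                         alternative=alternative, correction=True,
                         method="auto")
    return float(res.pvalue)


def bonferroni(p: float, n_comparisons: int) -> float:
    return float(min(1.0, p * n_comparisons))
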