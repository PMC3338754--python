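"""Canned synthetic-benchmark experiments.

Each function sets up a synthetic study with known ground truth, runs the
relevant part of the pipeline end to end, and returns the measured
quantities.  They serve three purposes: validation (the test suite
asserts on their outputs), demonstration (the README's worked example),
and reproducibility (the acceptance script re-runs them from scratch).

Problem sizes are chosen so the full battery completes in minutes on a
single core while leaving the qualitative behavior of each analysis
intact; the methods note documents the sizes used.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from .data import ExpressionDataset
from .evaluate import (
    er_stratified_setting,
    merged_setting,
    paired_setting,
    train_and_test,
)
from .features import (
    ChuangExtractor,
    ChuangParams,
    LeeExtractor,
    SingleGeneExtractor,
    TaylorExtractor,
    TaylorParams,
    avg_hub_difference,
    chuang_search,
    chuang_significance_filter,
    taylor_candidate_hubs,
    taylor_significant_hubs,
)
from .randomize import randomization_experiment
from .simulate import SimulationConfig, simulate_cohorts, simulate_network, \
    simulate_genesets
from .stability import stability_report

__all__ = [
    "protocol_counts",
    "null_calibration",
    "parameter_recovery",
    "leakage_guard",
    "randomization_regimes",
    "stability_size_correction",
]


def _sub_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31)


def protocol_counts(seed: int = 0) -> dict:
    """Record counts of the three evaluation settings plus stability rows.

    Six cohorts in the paired and ER-stratified settings, five in the
    merged setting (mirroring a benchmark where one platform's five
    cohorts can be pooled), and C(6,2) pairwise stability rows.
    """
    cfg = SimulationConfig(
        n_cohorts=6, samples_per_cohort=30, n_genes=40, n_informative=6,
        planted_module_sizes=(), effect_size=1.0,
        seed=_sub_seed(seed, 1),
    )
    datasets, _ = simulate_cohorts(cfg)
    ex = SingleGeneExtractor()
    paired = paired_setting(datasets, ex, policy="fixed_5")
    merged = merged_setting(datasets[:5], ex, policy="fixed_5")
    er = er_stratified_setting(datasets, ex, policy="fixed_5")
    stab = stability_report(datasets, {"sg": SingleGeneExtractor()},
                            top_n=5, jaccard_draws=50)
    return {
        "paired_records": len(paired),
        "merged_records": len(merged),
        "er_records": len(er),
        "stability_pairs": int((stab["method"] == "sg").sum()),
    }


def null_calibration(seed: int = 0) -> dict:
    """Behavior of the pipeline on data with no outcome signal.

    Cross-cohort AUC of the single-gene classifier over 20 cohort pairs
    (should straddle 0.5), and the pass fractions of the subnetwork
    significance filter and the hub permutation test (should not exceed
    their alpha by more than sampling noise).
    """
    cfg = SimulationConfig(
        n_cohorts=5, samples_per_cohort=60, n_genes=80, n_informative=6,
        planted_module_sizes=(), effect_size=0.0,
        seed=_sub_seed(seed, 2),
    )
    datasets, _ = simulate_cohorts(cfg)
    recs = paired_setting(datasets, SingleGeneExtractor(), policy="fixed_10")
    aucs = [r.auc for r in recs if r.feasible]

    net_cfg = SimulationConfig(
        n_cohorts=1, samples_per_cohort=60, n_genes=60, n_informative=5,
        planted_module_sizes=(), effect_size=0.0,
        seed=_sub_seed(seed, 3),
    )
    null_ds = simulate_cohorts(net_cfg)[0][0]
    net = simulate_network(net_cfg)
    cp = ChuangParams(n_null_permutations=100, alpha=0.05,
                      seed=_sub_seed(seed, 4))
    searched = chuang_search(null_ds, net, cp)
    kept = chuang_significance_filter(searched, null_ds, net, cp)
    chuang_frac = len(kept) / max(1, len(searched))

    tp = TaylorParams(n_label_permutations=200, alpha=0.05,
                      seed=_sub_seed(seed, 5))
    hubs_kept = taylor_significant_hubs(null_ds, net, tp)
    restricted = net  # candidate hubs use the full network by definition
    measured = set(null_ds.gene_ids)
    testable = [
        h for h in taylor_candidate_hubs(restricted, tp.hub_fraction)
        if h in measured
        and any(x in measured for x in restricted.neighbors(h))
    ]
    taylor_frac = len(hubs_kept) / max(1, len(testable))
    return {
        "null_auc_mean": float(np.mean(aucs)),
        "n_null_pairs": len(aucs),
        "chuang_null_pass_fraction": chuang_frac,
        "n_chuang_features_tested": len(searched),
        "taylor_null_keep_fraction": taylor_frac,
        "n_taylor_hubs_tested": len(testable),
    }


def _recovery_setup(seed: int):
    cfg = SimulationConfig(
        n_cohorts=2, samples_per_cohort=100, n_genes=150, n_informative=12,
        planted_module_sizes=(10,), effect_size=2.0,
        seed=_sub_seed(seed, 6),
    )
    datasets, truth = simulate_cohorts(cfg)
    net = simulate_network(cfg)
    return cfg, datasets, truth, net


def parameter_recovery(seed: int = 0) -> dict:
    """Recovery of planted structure under a strong, realistic signal.

    Single-gene nearest-mean cross-cohort AUC with the CV-optimized
    feature count; Jaccard overlap of the best greedy subnetworks with
    the planted module; permutation p-value of the planted
    correlation-flip hub.
    """
    cfg, datasets, truth, net = _recovery_setup(seed)
    recs = paired_setting(datasets, SingleGeneExtractor(),
                          clf_kind="nmc", policy="cv_opt", grid=range(1, 31))
    sg_auc = float(np.mean([r.auc for r in recs]))

    ranked = chuang_search(datasets[0], net,
                           ChuangParams(n_null_permutations=0))
    module = set(truth.module_genes[0])
    jaccard = max(
        len(set(f.member_genes) & module) / len(set(f.member_genes) | module)
        for f in ranked.top(10)
    )

    hub = truth.module_hubs[0]
    ds = datasets[0]
    measured = set(ds.gene_ids)
    nbrs = [x for x in net.neighbors(hub) if x in measured]
    obs = abs(avg_hub_difference(ds, hub, nbrs))
    rng = np.random.default_rng(_sub_seed(seed, 7))
    n_perm = 200
    exceed = 0
    for _ in range(n_perm):
        permuted = ExpressionDataset(
            ds.sample_ids, ds.gene_ids, ds.values,
            rng.permutation(ds.labels), name=ds.name,
        )
        if abs(avg_hub_difference(permuted, hub, nbrs)) >= obs:
            exceed += 1
    return {
        "sg_nmc_cross_cohort_auc": sg_auc,
        "n_recovery_pairs": len(recs),
        "chuang_module_recovery_jaccard": float(jaccard),
        "module_size": len(module),
        "taylor_planted_hub_p": exceed / n_perm,
        "n_hub_permutations": n_perm,
    }


def leakage_guard(seed: int = 0) -> dict:
    """Verify that nothing trained depends on the test set.

    The full pipeline (extraction, CV feature-count selection,
    classifier training) is run twice against two different test sets
    -- the real one and pure noise -- and the trained artifacts are
    compared bitwise.
    """
    cfg = SimulationConfig(
        n_cohorts=2, samples_per_cohort=50, n_genes=50, n_informative=6,
        planted_module_sizes=(), effect_size=1.5,
        seed=_sub_seed(seed, 8),
    )
    datasets, _ = simulate_cohorts(cfg)
    train, test = datasets
    rng = np.random.default_rng(_sub_seed(seed, 9))
    noise = ExpressionDataset(
        test.sample_ids, test.gene_ids,
        rng.normal(size=test.values.shape), test.labels,
        name="noise",
    )
    ex = SingleGeneExtractor()
    rec1, clf1, ranked1 = train_and_test(
        train, test, ex, policy="cv_opt", grid=range(1, 11),
        return_details=True,
    )
    rec2, clf2, ranked2 = train_and_test(
        train, noise, ex, policy="cv_opt", grid=range(1, 11),
        return_details=True,
    )
    identical = (
        rec1.n_features_used == rec2.n_features_used
        and ranked1.source_fingerprint == ranked2.source_fingerprint
        and np.array_equal(clf1.params["mean_good"], clf2.params["mean_good"])
        and np.array_equal(clf1.params["mean_poor"], clf2.params["mean_poor"])
    )
    return {
        "leakage_guard_identical": float(identical),
        "n_features_selected": rec1.n_features_used,
    }


def randomization_regimes(seed: int = 0, n_instances: int = 10) -> dict:
    """Real vs. topology-preserving randomized networks, two regimes.

    *Spread* regime: many informative genes scattered over the network
    -- randomized networks then also cover informative genes, so the
    real network offers no advantage and (almost) no instance is
    rejected.  *Module* regime: the signal is confined to one planted
    connected module -- randomization destroys the alignment and the
    real network wins.
    """
    spread_cfg = SimulationConfig(
        n_cohorts=4, samples_per_cohort=40, n_genes=120, n_informative=50,
        planted_module_sizes=(), effect_size=1.0,
        seed=_sub_seed(seed, 10),
    )
    module_cfg = SimulationConfig(
        n_cohorts=4, samples_per_cohort=40, n_genes=120, n_informative=8,
        planted_module_sizes=(8,), effect_size=1.0,
        seed=_sub_seed(seed, 11),
    )
    out = {}
    for label, cfg in (("spread", spread_cfg), ("module", module_cfg)):
        datasets, _ = simulate_cohorts(cfg)
        net = simulate_network(cfg)
        res = randomization_experiment(
            datasets,
            lambda s: ChuangExtractor(s, ChuangParams(n_null_permutations=0)),
            net,
            clf_kind="nmc",
            policy="fixed_3",
            n_instances=n_instances,
            seed=_sub_seed(seed, 12),
        )
        out[f"randomization_rejections_{label}"] = res.n_rejections
        out[f"real_auc_mean_{label}"] = float(np.mean(res.real_aucs))
        out[f"random_auc_mean_{label}"] = float(
            np.mean([np.mean(a) for a in res.instance_aucs])
        ) if res.instance_aucs else float("nan")
    out["n_randomization_instances"] = n_instances
    return out


def stability_size_correction(seed: int = 0) -> dict:
    """Size-matched single-gene control vs. composite signatures.

    On synthetic data with neither module structure nor outcome signal
    (gene sets are random, expression is pure noise), any cross-cohort
    overlap is chance, so composite signatures should not look
    systematically more stable than size-matched single-gene
    signatures: a sign test across cohort pairs of (control Fisher p >
    composite Fisher p) should not reject.  The signal-free setting
    isolates the fairness of the size correction itself; with real
    signal, set-granularity effects can legitimately favor composite
    stability.
    """
    cfg = SimulationConfig(
        n_cohorts=4, samples_per_cohort=60, n_genes=100, n_informative=0,
        planted_module_sizes=(), effect_size=0.0,
        seed=_sub_seed(seed, 13),
    )
    datasets, _ = simulate_cohorts(cfg)
    coll = simulate_genesets(cfg)
    report = stability_report(
        datasets, {"lee": LeeExtractor(coll)}, top_n=10,
        common_universe=True, jaccard_draws=100,
        seed=_sub_seed(seed, 14),
    )
    comp = report["fisher_p"].to_numpy()
    ctrl = report["sg_control_fisher_p"].to_numpy()
    wins = int((ctrl > comp).sum())
    informative_pairs = int((ctrl != comp).sum())
    if informative_pairs == 0:
        p = 1.0
    else:
        p = binomtest(wins, informative_pairs, 0.5,
                      alternative="greater").pvalue
    return {
        "stability_sign_test_p": float(p),
        "n_stability_pairs": len(report),
        "control_worse_count": wins,
    }
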