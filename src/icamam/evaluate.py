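"""Performance measurement: success rates, ROC/AUC, cross-validated
extractor optimization, and the cross-site robustness experiment.

The robustness protocol compares two training regimes on a multi-site
prototype pool:

* **site mode** — the learning set is every prototype from one site and the
  test set is the complement (all other prototypes);
* **OVERALL mode** — learning and test sets are drawn at random from the
  pooled data (default ~90% learning / 10% test).

The learning set is further split 80/20 into train and validation; the ICA
basis and the classifier see only the learning set.  Per-site degradation is
summarized by the relative variation of the test success rate against the
overall reference,

    ``100 * (overall_test - site_test) / overall_test``,

rounded half-up to one decimal (two decimals available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classify import (
    DEFAULT_C_EXPS,
    DEFAULT_GAMMA_EXPS,
    DEFAULT_H_GRID,
    LearningSplit,
    RpropConfig,
    decide,
    grid_search_svm,
    intermediate_threshold,
    predict_scores,
    select_mlp,
)
from .ica_features import features_for, fit_ica_basis

OVERALL = "OVERALL"


def success_rate(predicted: np.ndarray, true: np.ndarray) -> float:
    """Percentage of correct labels."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    return 100.0 * float(np.mean(predicted == true))


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: thresholds descending, (fpr, tpr) from (0,0) to (1,1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, true: np.ndarray) -> ROCCurve:
    """ROC over all distinct score thresholds; trapezoidal AUC.

    Ties produce diagonal segments, so the AUC equals the Mann-Whitney
    statistic with ties counted 1/2.  Raises on single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(true).astype(int)
    P = int((y == 1).sum())
    N = int((y == 0).sum())
    if P == 0 or N == 0:
        raise ValueError("AUC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep one point per distinct score (the last index of each tie group)
    last = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[last] / P]
    fpr = np.r_[0.0, fps[last] / N]
    thresholds = np.r_[np.inf, s_sorted[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def kfold_cv(y: np.ndarray, site: np.ndarray | None = None, k: int = 10,
             seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of the data, by class and (if possible) site.

    When the smallest class-by-site stratum is smaller than ``k`` the
    stratification relaxes to class only (with a warning), and to an
    unstratified partition if even a class is smaller than ``k``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y)
    strata = y.astype(str)
    if site is not None:
        combined = np.char.add(np.char.add(strata, "|"), np.asarray(site, dtype=str))
        if np.min(np.unique(combined, return_counts=True)[1]) >= k:
            strata = combined
        else:
            warnings.warn("class-by-site strata smaller than k; "
                          "stratifying by class only")
    if np.min(np.unique(strata, return_counts=True)[1]) >= k:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in cv.split(np.zeros(len(y)), strata)]
    warnings.warn("a class has fewer members than k; folds are unstratified")
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in cv.split(np.zeros(len(y)))]


# ---------------------------------------------------------------------------
# Classifier training helper shared by the optimizer and the site experiment
# ---------------------------------------------------------------------------

def _fit_classifier(features, split, classifier: str, seed: int,
                    gamma_exps, C_exps, H_grid, restarts,
                    rprop_cfg: RpropConfig | None):
    if classifier == "svm":
        model, table = grid_search_svm(features, split, gamma_exps, C_exps)
    elif classifier == "mlp":
        model, table = select_mlp(features, split, rprop_cfg,
                                  H_grid=H_grid, restarts=restarts, seed=seed)
    else:
        raise ValueError(f"unknown classifier kind {classifier!r}")
    return model, table


def optimize_extractor(
    prototypes_by_size: Mapping[int, Sequence],
    q_grid: Sequence[int] = tuple(range(10, 66, 5)),
    sizes: Sequence[int] = (32, 64),
    classifier: str = "svm",
    k: int = 10,
    seed: int = 0,
    val_fraction: float = 0.2,
    gamma_exps: Sequence[float] = DEFAULT_GAMMA_EXPS,
    C_exps: Sequence[float] = DEFAULT_C_EXPS,
    H_grid: Sequence[int] = DEFAULT_H_GRID,
    restarts: int = 4,
    rprop_cfg: RpropConfig | None = None,
    ica_seed: int = 0,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """k-fold search over (patch size, q) for the best feature extractor.

    For each configuration and fold, an ICA basis is trained on the fold's
    training prototypes only, the classifier is selected on an inner 80/20
    train/validation split, and the fold's test success is recorded.  Returns
    the full score table and the argmax ``(size, q)``; ties prefer smaller q,
    then smaller size.
    """
    if len(q_grid) == 0 or len(sizes) == 0:
        raise ValueError("empty optimization grid")
    rows = []
    best = None  # (neg-score, q, size)
    for size in sizes:
        protos = list(prototypes_by_size[int(size)])
        y = np.array([1 if p.label == "mass" else 0 for p in protos])
        site = np.array([p.site for p in protos])
        folds = kfold_cv(y, site, k=k, seed=seed)
        patches = np.stack([p.patch for p in protos]).reshape(len(protos), -1)
        for q in q_grid:
            fold_scores = []
            for f, (tr, te) in enumerate(folds):
                basis = fit_ica_basis(patches[tr], q, seed=ica_seed)
                F = features_for(protos, basis)
                test_mask = np.zeros(len(y), dtype=bool)
                test_mask[te] = True
                split = LearningSplit.from_test_mask(
                    y, test_mask, val_fraction=val_fraction, seed=seed + f)
                model, _ = _fit_classifier(F, split, classifier, seed + f,
                                           gamma_exps, C_exps, H_grid,
                                           restarts, rprop_cfg)
                scores = predict_scores(model, F.X[te])
                pred = decide(scores, intermediate_threshold(model))
                fold_scores.append(success_rate(pred, y[te]))
            mean_success = float(np.mean(fold_scores))
            rows.append({"size": size, "q": q, "mean_success": mean_success})
            key = (-mean_success, q, size)
            if best is None or key < best:
                best = key
    table = pd.DataFrame(rows)
    return table, (int(best[2]), int(best[1]))


# ---------------------------------------------------------------------------
# Site experiment and robustness report
# ---------------------------------------------------------------------------

@dataclass
class SiteExperimentResult:
    """Trained pipeline plus its rates and ROC for one training regime."""

    site: str
    train_success: float
    val_success: float
    test_success: float
    roc: ROCCurve
    model: object
    basis: object
    split: LearningSplit


def run_site_experiment(
    prototypes: Sequence,
    site: str,
    q: int = 10,
    classifier: str = "svm",
    seed: int = 0,
    test_fraction: float = 0.1,
    val_fraction: float = 0.2,
    gamma_exps: Sequence[float] = DEFAULT_GAMMA_EXPS,
    C_exps: Sequence[float] = DEFAULT_C_EXPS,
    H_grid: Sequence[int] = DEFAULT_H_GRID,
    restarts: int = 4,
    rprop_cfg: RpropConfig | None = None,
) -> SiteExperimentResult:
    """Train and test the full pipeline under one training regime.

    ``site`` names one site (its prototypes form the learning set, tested on
    the complement) or :data:`OVERALL` (random ~90/10 learning/test split).
    The ICA basis and classifier are fit on the learning set only.
    """
    y = np.array([1 if p.label == "mass" else 0 for p in prototypes])
    sites = np.array([p.site for p in prototypes])
    if site == OVERALL:
        strat = np.char.add(np.char.add(y.astype(str), "|"), sites)
        split = LearningSplit.random(y, test_fraction=test_fraction,
                                     val_fraction=val_fraction, seed=seed,
                                     stratify=strat)
    else:
        if site not in set(sites.tolist()):
            raise ValueError(f"unknown site {site!r}")
        split = LearningSplit.from_test_mask(y, sites != site,
                                             val_fraction=val_fraction,
                                             seed=seed)
    learn_idx = np.concatenate([split.train, split.val])
    patches = np.stack([np.asarray(p.patch) for p in prototypes])
    basis = fit_ica_basis(patches[learn_idx].reshape(len(learn_idx), -1),
                          q, seed=seed)
    F = features_for(prototypes, basis)
    model, _ = _fit_classifier(F, split, classifier, seed, gamma_exps,
                               C_exps, H_grid, restarts, rprop_cfg)
    thr = intermediate_threshold(model)

    def rate(idx: np.ndarray) -> float:
        pred = decide(predict_scores(model, F.X[idx]), thr)
        return success_rate(pred, y[idx])

    roc = roc_auc(predict_scores(model, F.X[split.test]), y[split.test])
    return SiteExperimentResult(
        site=site, train_success=rate(split.train),
        val_success=rate(split.val), test_success=rate(split.test),
        roc=roc, model=model, basis=basis, split=split)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (numpy rounds half to even)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class RobustnessReport:
    """Per-site vs overall success rates, AUCs, and relative variations."""

    site_test_rates: dict[str, float]
    overall_test_rate: float
    relative_variation_pct: dict[str, float]
    site_aucs: dict[str, float] | None = None
    overall_auc: float | None = None
    auc_variation_pct: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, rate in self.site_test_rates.items():
            row = {"site": name, "test_success": rate,
                   "relative_variation_pct": self.relative_variation_pct[name]}
            if self.site_aucs is not None:
                row["auc"] = self.site_aucs[name]
                row["auc_variation_pct"] = self.auc_variation_pct[name]
            rows.append(row)
        return pd.DataFrame(rows)


def robustness_report(site_test_rates: Mapping[str, float],
                      overall_test_rate: float,
                      site_aucs: Mapping[str, float] | None = None,
                      overall_auc: float | None = None,
                      decimals: int = 1) -> RobustnessReport:
    """Relative variation of each site's test success against the overall.

    ``100 * (overall - site) / overall`` per site, rounded half-up to
    ``decimals`` places; AUC variations are reported the same way when AUCs
    are given.
    """
    if overall_test_rate <= 0:
        raise ValueError("overall test rate must be positive")
    rel = {name: round_half_up(
        100.0 * (overall_test_rate - r) / overall_test_rate, decimals)
        for name, r in site_test_rates.items()}
    auc_rel = None
    if site_aucs is not None and overall_auc is not None:
        auc_rel = {name: round_half_up(
            100.0 * (overall_auc - a) / overall_auc, decimals)
            for name, a in site_aucs.items()}
    return RobustnessReport(
        site_test_rates=dict(site_test_rates),
        overall_test_rate=float(overall_test_rate),
        relative_variation_pct=rel,
        site_aucs=dict(site_aucs) if site_aucs is not None else None,
        overall_auc=float(overall_auc) if overall_auc is not None else None,
        auc_variation_pct=auc_rel)


def robustness_from_results(site_results: Mapping[str, SiteExperimentResult],
                            overall_result: SiteExperimentResult,
                            decimals: int = 1) -> RobustnessReport:
    """Build a :class:`RobustnessReport` from site-experiment results."""
    return robustness_report(
        {name: r.test_success for name, r in site_results.items()},
        overall_result.test_success,
        site_aucs={name: r.roc.auc for name, r in site_results.items()},
        overall_auc=overall_result.roc.auc,
        decimals=decimals)
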