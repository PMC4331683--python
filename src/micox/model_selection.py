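"""Cross-validated hyperparameter selection and the holdout protocol.

The evaluation protocol: reserve 20% of samples as a holdout validation
set; on the remaining 80%, run 5-fold cross-validation over the grid of
(sigma, lambda, alpha); networks (MI or co-expression) and the
permutation threshold theta are estimated on the four training folds
only, so the held-out fold never leaks into any training artifact.
The configuration with the best fold-averaged mean time-dependent AUC is
refit on the full training set and scored on the holdout with
time-dependent AUC, a 40%/40% high/low-risk split, the log-rank test and
Kaplan-Meier curves.

The MI matrix and theta are computed once per fold and re-thresholded
across the sigma grid; the sigma sweep repeats none of the O(p^2) work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import SurvivalData
from .evaluation import km_curve, logrank_test, split_risk_groups, td_auc
from .information import binarize_outcome
from .netcox import fit_netcox, prognostic_index
from .network import (
    MINetwork,
    PenaltyMatrix,
    build_penalty,
    coexpression_network,
    complete_mi_network,
    filter_network,
    permutation_threshold,
)

__all__ = ["CVConfig", "CVResult", "kfold_split", "cv_grid_search", "holdout_protocol", "COMPLETE"]

#: sentinel sigma value meaning "use the complete, unfiltered MI network"
COMPLETE = "complete"

_DEFAULT_SIGMA_GRID = (COMPLETE, 0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)


@dataclass(frozen=True)
class CVConfig:
    """Grids and protocol parameters for cross-validated model selection."""

    k: int = 5
    holdout_fraction: float = 0.20
    lambda_grid: tuple = (1e-4, 1e-3, 1e-2, 1e-1)
    alpha_grid: tuple = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)
    sigma_grid: tuple = _DEFAULT_SIGMA_GRID
    network_type: str = "mi"  # "mi" | "coexpression" | "none"
    coexpression_cutoff: float = 0.5
    n_bins: int = 3
    n_perm: int = 100
    threshold_months: float = 36.0
    filter_for_cox: bool = True
    stratify: bool = False
    tol: float = 1e-8
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        for name in ("lambda_grid", "alpha_grid", "sigma_grid"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.network_type not in ("mi", "coexpression", "none"):
            raise ValueError("network_type must be 'mi', 'coexpression' or 'none'")


@dataclass(frozen=True)
class CVResult:
    """Leaderboard of configurations and the selected one."""

    leaderboard: pd.DataFrame
    best_sigma: object
    best_lambda: float
    best_alpha: float
    per_fold: pd.DataFrame = field(default=None)

    @property
    def best(self) -> tuple:
        return (self.best_sigma, self.best_lambda, self.best_alpha)


def kfold_split(ids, k: int, seed=None, status=None, stratify: bool = False) -> list:
    """Seeded k-fold partition of sample IDs.

    Folds are disjoint, their union is the full ID set, and sizes differ
    by at most one. With ``stratify=True`` the split balances the event
    indicator ``status`` across folds.
    """
    ids = np.asarray(ids)
    n = ids.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    rng = np.random.default_rng(seed)
    if stratify and status is not None:
        status = np.asarray(status)
        buckets: list = [[] for _ in range(k)]
        slot = 0
        for val in (1, 0):
            members = rng.permutation(np.flatnonzero(status == val))
            for m in members:
                buckets[slot % k].append(m)
                slot += 1
        fold_indices = [np.sort(np.array(b, dtype=np.int64)) for b in buckets]
    else:
        perm = rng.permutation(n)
        fold_indices = [np.sort(chunk) for chunk in np.array_split(perm, k)]
    out = []
    for i in range(k):
        test_idx = fold_indices[i]
        train_idx = np.sort(np.concatenate([fold_indices[j] for j in range(k) if j != i]))
        out.append((ids[train_idx], ids[test_idx]))
    return out


def _fold_networks(expr_tr: pd.DataFrame, surv_tr: SurvivalData, config: CVConfig) -> dict:
    """Networks for one training fold, keyed by sigma grid entries.

    For the MI type: one all-pairs computation and one permutation pass,
    then pure re-thresholding per sigma. Returns {} for network_type
    'none' (ridge).
    """
    if config.network_type == "none":
        return {}
    if config.network_type == "coexpression":
        net = coexpression_network(expr_tr, config.coexpression_cutoff)
        return {COMPLETE: net}
    outcome = binarize_outcome(surv_tr, config.threshold_months)
    complete = complete_mi_network(expr_tr, outcome, config.n_bins)
    theta = permutation_threshold(
        expr_tr, outcome, config.n_bins, config.n_perm, config.seed
    )
    nets = {}
    for sigma in config.sigma_grid:
        if sigma == COMPLETE or sigma is None:
            nets[COMPLETE] = complete
        else:
            nets[sigma] = filter_network(complete, theta, float(sigma))
    return nets


def _cox_training_view(expr_tr, surv_tr, config):
    """Apply the censored-short filter to the Cox fitting data if configured."""
    if not config.filter_for_cox:
        return expr_tr, surv_tr
    outcome = binarize_outcome(surv_tr, config.threshold_months)
    mask = outcome.kept_mask.astype(bool)
    return expr_tr.loc[mask], surv_tr.subset(mask)


def _penalty_for(net: MINetwork | None, alpha: float, p: int, genes) -> PenaltyMatrix:
    if net is None or alpha == 1.0:
        eye = np.eye(p)
        return PenaltyMatrix(
            S=np.zeros((p, p)), L=eye.copy(), Gamma=eye, alpha=1.0,
            row_sums=np.zeros(p), col_sums=np.zeros(p), genes=tuple(genes),
        )
    return build_penalty(net, alpha)


def cv_grid_search(expr: pd.DataFrame, surv: SurvivalData, config: CVConfig) -> CVResult:
    """Grid search over (sigma, lambda, alpha) by k-fold cross-validation.

    Every training artifact -- discretization, MI matrix, theta, network,
    penalty, coefficients -- is computed from the k-1 training folds only.
    The held-out fold contributes nothing but its prognostic indices and
    true survival to the fold's time-dependent AUC.
    """
    genes = tuple(expr.columns)
    p = len(genes)
    folds = kfold_split(
        np.asarray(surv.sample_ids), config.k, config.seed,
        status=surv.status, stratify=config.stratify,
    )
    sigma_entries = (
        list(dict.fromkeys(config.sigma_grid)) if config.network_type == "mi"
        else [COMPLETE] if config.network_type == "coexpression"
        else [COMPLETE]
    )
    alpha_entries = [1.0] if config.network_type == "none" else list(config.alpha_grid)

    records = []
    for fold_id, (train_ids, test_ids) in enumerate(folds):
        surv_tr = surv.subset(train_ids)
        surv_te = surv.subset(test_ids)
        if surv_tr.n_events == 0 or surv_te.n_events == 0:
            raise ValueError(f"fold {fold_id} has no observed events")
        expr_tr = expr.loc[train_ids]
        expr_te = expr.loc[test_ids]
        nets = _fold_networks(expr_tr, surv_tr, config)
        X_fit, s_fit = _cox_training_view(expr_tr, surv_tr, config)
        for sigma in sigma_entries:
            key = COMPLETE if sigma is None else sigma
            net = nets.get(key)
            for alpha in alpha_entries:
                penalty = _penalty_for(net, alpha, p, genes)
                for lam in config.lambda_grid:
                    res = fit_netcox(
                        X_fit, s_fit, lam, penalty, tol=config.tol, max_iter=config.max_iter
                    )
                    pi = prognostic_index(res["beta"], expr_te, genes=genes)
                    auc = td_auc(pi, surv_te)
                    records.append(
                        {
                            "fold": fold_id,
                            "sigma": key,
                            "lambda": lam,
                            "alpha": alpha,
                            "mean_auc": auc.mean_auc,
                            "median_auc": float(np.median(auc.auc_at_t))
                            if auc.auc_at_t.size
                            else np.nan,
                            "n_edges": 0 if net is None else net.n_edges,
                        }
                    )
    per_fold = pd.DataFrame.from_records(records)
    leaderboard = (
        per_fold.groupby(["sigma", "lambda", "alpha"], sort=False)
        .agg(mean_auc=("mean_auc", "mean"), median_auc=("median_auc", "mean"))
        .reset_index()
    )
    # best mean AUC; ties resolved toward stronger regularization
    ranked = leaderboard.sort_values(
        ["mean_auc", "alpha", "lambda"], ascending=[False, False, False], kind="stable"
    )
    best = ranked.iloc[0]
    return CVResult(
        leaderboard=leaderboard.sort_values("mean_auc", ascending=False).reset_index(drop=True),
        best_sigma=best["sigma"],
        best_lambda=float(best["lambda"]),
        best_alpha=float(best["alpha"]),
        per_fold=per_fold,
    )


def _refit(expr_tr, surv_tr, sigma, lam, alpha, config):
    """Fit one configuration on a full training set; returns (beta, net)."""
    genes = tuple(expr_tr.columns)
    nets = _fold_networks(expr_tr, surv_tr, config)
    key = COMPLETE if (sigma is None or sigma == COMPLETE) else sigma
    net = nets.get(key)
    penalty = _penalty_for(net, alpha, len(genes), genes)
    X_fit, s_fit = _cox_training_view(expr_tr, surv_tr, config)
    res = fit_netcox(X_fit, s_fit, lam, penalty, tol=config.tol, max_iter=config.max_iter)
    return res, net


def holdout_protocol(expr: pd.DataFrame, surv: SurvivalData, config: CVConfig) -> dict:
    """Full 80/20 protocol: CV on the training split, refit, evaluate.

    Returns a report dict with the CV result, the refit coefficients, and
    the holdout metrics (time-dependent AUC, 40/40 risk groups, log-rank
    statistic and p-value, Kaplan-Meier step curves per group).
    """
    rng = np.random.default_rng(config.seed)
    ids = np.asarray(surv.sample_ids)
    n = ids.size
    n_holdout = int(round(config.holdout_fraction * n))
    perm = rng.permutation(n)
    holdout_ids = ids[np.sort(perm[:n_holdout])]
    train_ids = ids[np.sort(perm[n_holdout:])]

    expr_tr, expr_ho = expr.loc[train_ids], expr.loc[holdout_ids]
    surv_tr, surv_ho = surv.subset(train_ids), surv.subset(holdout_ids)

    cv = cv_grid_search(expr_tr, surv_tr, config)
    res, net = _refit(expr_tr, surv_tr, cv.best_sigma, cv.best_lambda, cv.best_alpha, config)
    genes = tuple(expr.columns)
    pi = prognostic_index(res["beta"], expr_ho, genes=genes)
    auc = td_auc(pi, surv_ho)
    groups = split_risk_groups(pi, ids=holdout_ids, fraction=0.40)
    stat, pval = logrank_test(groups, surv_ho)
    km_high = km_curve(surv_ho.subset(groups.high_ids))
    km_low = km_curve(surv_ho.subset(groups.low_ids))
    return {
        "config": asdict(config),
        "cv": cv,
        "train_ids": train_ids,
        "holdout_ids": holdout_ids,
        "beta": pd.Series(res["beta"], index=genes, name="beta"),
        "network": net,
        "holdout_pi": pd.Series(pi, index=holdout_ids, name="prognostic_index"),
        "holdout_mean_auc": auc.mean_auc,
        "holdout_auc": auc,
        "risk_groups": groups,
        "logrank_statistic": stat,
        "logrank_p": pval,
        "km_high": km_high,
        "km_low": km_low,
    }
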