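"""Grouped leave-one-chip-out classification, bootstrap AUC, SHAP ranking.

The feature table holds one row per (chip, condition, window) with 26 feature
columns (25 graph features + spike_contrast).  Because the experiment is
paired, features are standardized per chip against that chip's *pre-drug*
windows (mean and sample SD), so the post-drug values express drug-induced
shifts in units of baseline variability.  Classification uses grouped
leave-one-out cross-validation: all windows of one chip -- both conditions --
form the validation set of one split, and hyperparameters are tuned by an
inner grouped CV over the training chips, so no chip ever leaks between train
and validation.  The model score is the lower bound of the bootstrap 95 %
confidence interval of the per-split AUCs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from ._seeds import derive_seed
from .net_features import FEATURE_NAMES
from .shapley import shap_attribute
from .spike_io import POST_DRUG, PRE_DRUG

logger = logging.getLogger(__name__)

KEY_COLUMNS = ("chip_id", "condition", "window_index")
ALL_FEATURES = tuple(FEATURE_NAMES) + ("spike_contrast",)
MODEL_NAMES = ("rf", "xgboost", "svm", "knn", "lr", "nb", "mlp")


def feature_columns(ft: pd.DataFrame) -> list[str]:
    """Feature columns of a table: everything except the key columns."""
    return [c for c in ft.columns if c not in KEY_COLUMNS]


def labels(ft: pd.DataFrame) -> np.ndarray:
    """0 for pre-drug, 1 for post-drug."""
    return (ft["condition"] == POST_DRUG).to_numpy().astype(int)


# ---------------------------------------------------------------------------
# paired standardization
# ---------------------------------------------------------------------------


def paired_standardize(ft: pd.DataFrame, scheme: str = "pre_drug") -> pd.DataFrame:
    """Standardize features per chip, preserving the paired design.

    ``scheme="pre_drug"`` (default): each chip's pre-drug windows define the
    reference mean and sample SD per feature; both conditions are transformed
    with them, so post-drug values are expressed relative to baseline.
    ``scheme="pooled_per_chip"``: mean/SD pooled over both conditions of the
    chip (the alternative reading of collective per-chip scaling).

    A zero reference SD maps the feature to 0 for that chip, with a warning.
    """
    if scheme not in ("pre_drug", "pooled_per_chip"):
        raise ValueError(f"unknown scheme {scheme!r}")
    feats = feature_columns(ft)
    out = ft.copy()
    for chip, grp in ft.groupby("chip_id", sort=False):
        ref = grp[grp["condition"] == PRE_DRUG] if scheme == "pre_drug" else grp
        if len(ref) < 2:
            raise ValueError(
                f"chip {chip!r}: needs >= 2 reference windows to standardize "
                f"(got {len(ref)})"
            )
        mu = ref[feats].mean(axis=0)
        sd = ref[feats].std(axis=0, ddof=1)
        degenerate = sd[sd == 0].index
        if len(degenerate):
            warnings.warn(
                f"chip {chip!r}: zero reference SD for {list(degenerate)}; "
                "standardized values set to 0"
            )
        sd_safe = sd.replace(0.0, np.inf)
        out.loc[grp.index, feats] = (grp[feats] - mu) / sd_safe
    return out


# ---------------------------------------------------------------------------
# models and hyperparameter grids
# ---------------------------------------------------------------------------


def _model_and_grid(name: str, seed: int):
    """Base estimator and a small hyperparameter grid tuned by inner CV."""
    if name == "svm":
        return SVC(kernel="rbf", gamma="scale", random_state=seed), {
            "C": [0.1, 1.0, 10.0]
        }
    if name == "rf":
        return (
            RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1),
            {"max_depth": [None, 8]},
        )
    if name == "xgboost":
        return (
            XGBClassifier(
                n_estimators=200, random_state=seed, n_jobs=1,
                eval_metric="logloss", verbosity=0,
            ),
            {"max_depth": [3, 6]},
        )
    if name == "knn":
        return KNeighborsClassifier(), {"n_neighbors": [3, 5, 9]}
    if name == "lr":
        return (
            LogisticRegression(max_iter=2000, random_state=seed),
            {"C": [0.1, 1.0, 10.0]},
        )
    if name == "nb":
        return GaussianNB(), {}
    if name == "mlp":
        return (
            MLPClassifier(
                hidden_layer_sizes=(100,), early_stopping=True,
                max_iter=500, random_state=seed,
            ),
            {},
        )
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


def _decision_scores(est, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "decision_function"):
        scores = np.asarray(est.decision_function(X), dtype=float)
    else:
        scores = np.asarray(est.predict_proba(X), dtype=float)[:, 1]
    bad = ~np.isfinite(scores)
    if bad.any():
        # e.g. GaussianNB on all-constant features; a constant score means
        # "no information" and yields chance-level AUC
        logger.warning("non-finite decision scores replaced by 0")
        scores[bad] = 0.0
    return scores


@dataclass
class CVReport:
    """Result of one grouped LOO-CV run of one model."""

    model: str
    split_chips: list[str]
    split_aucs: np.ndarray
    auc_lower_ci: float
    best_params: list[dict]
    feature_names: list[str]
    fingerprint: str
    shap_per_split: list[np.ndarray] | None = None
    _fitted: list = field(default_factory=list, repr=False)
    _val_index: list = field(default_factory=list, repr=False)


def auc_lower_ci(
    split_aucs, n_boot: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Lower bound of the percentile-bootstrap CI of the mean split AUC.

    Resamples the per-split AUCs with replacement (same size), and returns
    the ``alpha/2`` percentile of the bootstrap means.
    """
    a = np.asarray(list(split_aucs), dtype=float)
    if a.size == 0:
        raise ValueError("split_aucs must be non-empty")
    if a.size == 1:
        return float(a[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    means = a[idx].mean(axis=1)
    return float(np.percentile(means, 100.0 * alpha / 2.0))


def _inner_grid_search(
    name: str, grid: dict, X, y, groups, seed: int
) -> dict:
    """Pick grid params maximizing mean AUC of an inner leave-one-chip-out CV."""
    combos = [
        dict(zip(grid, values)) for values in product(*grid.values())
    ] or [{}]
    if len(combos) == 1:
        return combos[0]
    inner_chips = np.unique(groups)
    best_combo, best_score = combos[0], -np.inf
    for combo in combos:
        aucs = []
        for chip in inner_chips:
            val = groups == chip
            est, _ = _model_and_grid(name, seed)
            est.set_params(**combo)
            if len(np.unique(y[~val])) < 2:
                continue
            est.fit(X[~val], y[~val])
            if len(np.unique(y[val])) < 2:
                continue
            aucs.append(roc_auc_score(y[val], _decision_scores(est, X[val])))
        score = float(np.mean(aucs)) if aucs else -np.inf
        if score > best_score:
            best_combo, best_score = combo, score
    return best_combo


def grouped_loocv(
    ft: pd.DataFrame,
    model: str,
    seed: int = 0,
    n_boot: int = 1000,
    keep_models: bool = True,
) -> CVReport:
    """Grouped leave-one-chip-out cross-validation of one model family.

    Each chip's windows (both conditions) form the validation set of one
    split; hyperparameters are tuned by an inner grouped CV over the training
    chips.  Per-split AUC comes from the validation decision scores; the
    summary score is :func:`auc_lower_ci` over the splits.
    """
    feats = feature_columns(ft)
    X = ft[feats].to_numpy(dtype=float)
    y = labels(ft)
    groups = ft["chip_id"].to_numpy()
    chips = list(pd.unique(groups))
    if len(chips) < 3:
        raise ValueError(f"grouped LOO-CV needs >= 3 chips, got {len(chips)}")
    _model_and_grid(model, 0)  # validates the model name early

    split_aucs, best_params, fitted, val_indices = [], [], [], []
    for chip in chips:
        val = groups == chip
        train_chips = set(groups[~val])
        assert chip not in train_chips, "leakage: validation chip in training set"
        split_seed = derive_seed(seed, "fit", model, chip)
        _, grid = _model_and_grid(model, split_seed)
        params = _inner_grid_search(
            model, grid, X[~val], y[~val], groups[~val], split_seed
        )
        est, _ = _model_and_grid(model, split_seed)
        est.set_params(**params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[~val], y[~val])
        if len(np.unique(y[val])) < 2:
            raise ValueError(f"chip {chip!r} lacks both conditions in validation")
        auc = roc_auc_score(y[val], _decision_scores(est, X[val]))
        split_aucs.append(float(auc))
        best_params.append(params)
        fitted.append(est)
        val_indices.append(np.flatnonzero(val))

    split_aucs = np.asarray(split_aucs)
    lower = auc_lower_ci(split_aucs, n_boot=n_boot, seed=derive_seed(seed, "boot", model))
    report = CVReport(
        model=model,
        split_chips=[str(c) for c in chips],
        split_aucs=split_aucs,
        auc_lower_ci=lower,
        best_params=best_params,
        feature_names=feats,
        fingerprint=f"{model}|seed={seed}|chips={len(chips)}|rows={len(ft)}",
    )
    if keep_models:
        report._fitted = fitted
        report._val_index = val_indices
    return report


# ---------------------------------------------------------------------------
# SHAP over CV splits
# ---------------------------------------------------------------------------


def compute_split_shap(
    report: CVReport,
    ft: pd.DataFrame,
    seed: int = 0,
    n_permutations: int = 2000,
    background_size: int = 16,
) -> CVReport:
    """Sampled SHAP attributions for the class-1 (post-drug) validation
    windows of every split, using a training-set background per split."""
    if not report._fitted:
        raise ValueError("report has no fitted models; rerun with keep_models=True")
    feats = report.feature_names
    X = ft[feats].to_numpy(dtype=float)
    y = labels(ft)
    shap_per_split = []
    for est, val_idx, chip in zip(report._fitted, report._val_index, report.split_chips):
        rng = np.random.default_rng(derive_seed(seed, "shapbg", report.model, chip))
        train_mask = np.ones(len(ft), dtype=bool)
        train_mask[val_idx] = False
        train_rows = np.flatnonzero(train_mask)
        bg_rows = rng.choice(
            train_rows, size=min(background_size, train_rows.size), replace=False
        )
        background = X[bg_rows]
        class1 = val_idx[y[val_idx] == 1]
        phis = np.stack(
            [
                shap_attribute(
                    lambda rows: _decision_scores(est, rows),
                    X[i],
                    background,
                    mode="sampled",
                    n_permutations=n_permutations,
                    seed=derive_seed(seed, "shap", report.model, chip, int(i)),
                )
                for i in class1
            ]
        ) if class1.size else np.zeros((0, len(feats)))
        shap_per_split.append(phis)
    report.shap_per_split = shap_per_split
    return report


def rank_features(
    shap_per_split: list[np.ndarray],
    feature_names: list[str],
    ft: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Importance ranking from per-split SHAP matrices.

    Per feature: the median across splits of the per-split median absolute
    attribution (over class-1 validation windows), its min and max across
    splits, and the direction of the post-vs-pre feature shift (+1 if the
    feature increased after the drug).
    """
    if not shap_per_split:
        raise ValueError("need at least one split")
    per_split = np.stack(
        [
            np.median(np.abs(s), axis=0) if s.size else np.zeros(len(feature_names))
            for s in shap_per_split
        ]
    )
    med = np.median(per_split, axis=0)
    table = pd.DataFrame(
        {
            "feature": feature_names,
            "median_abs_shap": med,
            "min_abs_shap": per_split.min(axis=0),
            "max_abs_shap": per_split.max(axis=0),
        }
    )
    if ft is not None:
        post = ft[ft["condition"] == POST_DRUG]
        pre = ft[ft["condition"] == PRE_DRUG]
        shift = post[feature_names].mean(axis=0) - pre[feature_names].mean(axis=0)
        table["direction"] = np.sign(shift.to_numpy()).astype(int)
    table = table.sort_values("median_abs_shap", ascending=False, kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def model_similarity(rankings: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pearson correlation between models' median-|SHAP| importance vectors."""
    if len(rankings) < 2:
        raise ValueError("need >= 2 models")
    names = list(rankings)
    ref_features = list(rankings[names[0]].sort_values("feature")["feature"])
    vectors = []
    for name in names:
        table = rankings[name].sort_values("feature")
        if list(table["feature"]) != ref_features:
            raise ValueError(f"model {name!r} has a mismatched feature set")
        vectors.append(table["median_abs_shap"].to_numpy(dtype=float))
    corr = np.corrcoef(np.stack(vectors))
    return pd.DataFrame(corr, index=names, columns=names)
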