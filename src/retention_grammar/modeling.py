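"""Cost-sensitive modeling of intron fate from sequence features.

The evaluation engine runs stratified k-fold cross-validation of a
cost-sensitive Random Forest (class weight = majority/minority size
ratio) and reports fold AUCs, ROC curves, and held-out permutation
importances standardized by twice their cross-fold dispersion and
asinh-transformed to a pseudo-logarithmic scale. Companion analyses:
L1-penalized logistic feature selection, Mahalanobis nearest-neighbor
length matching for confounder control, scree (top-k) performance
curves, and a correlation landscape around the selected features.
Model variants (complete, length-matched, RBP-only, repeats-only) are
column/row masks over one FeatureMatrix fed to the same engine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

DEFAULT_TREES = 1000
DEFAULT_MTRY = 100
DEFAULT_FOLDS = 5
# Probability forests grow to a minimum node size of 10 by default in
# ranger-style implementations; the smoothing matters for AUC ranking
# when positives are rare.
DEFAULT_MIN_LEAF = 10
COEF_FLOOR = 1e-5
SIGMA_EPS = 1e-12

VARIANTS = (
    "complete",
    "length_matched",
    "rbp_only",
    "repeats_only",
    "repeats_only_length_matched",
)


def class_weights(labels) -> dict[int, float]:
    """Cost-sensitive weights: minority class weighted by the size ratio.

    The minority class gets ``n_majority / n_minority``; the majority
    class gets 1. Requires both classes present.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to define weights")
    if classes.size > 2:
        raise ValueError("binary labels expected")
    minority = classes[counts.argmin()]
    majority = classes[counts.argmax()]
    if counts[0] == counts[1]:
        return {int(classes[0]): 1.0, int(classes[1]): 1.0}
    ratio = counts.max() / counts.min()
    return {int(majority): 1.0, int(minority): float(ratio)}


@dataclass
class ModelReport:
    """Cross-validated performance and importance summary."""

    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    roc_curves: list[tuple[np.ndarray, np.ndarray]]
    importance: pd.DataFrame | None = None  # raw, sigma, transformed per feature
    extra: dict = field(default_factory=dict)

    def top_features(self, n: int = 10) -> list[str]:
        if self.importance is None:
            raise ValueError("report carries no importance table")
        return (
            self.importance.sort_values("transformed", ascending=False)
            .head(n)
            .index.tolist()
        )


def transform_importance(raw: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """asinh(raw / 2 sigma): pseudo-log scale defined for any sign.

    Zero dispersion is floored at a tiny epsilon so constant-importance
    features stay finite (and huge, as they should look).
    """
    raw = np.asarray(raw, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    denom = 2.0 * np.where(sigma > 0, sigma, SIGMA_EPS / 2.0)
    if (sigma <= 0).any() and (raw != 0).any():
        logger.debug("zero importance dispersion floored at %g", SIGMA_EPS)
    return np.arcsinh(raw / denom)


def cv_random_forest(
    X: pd.DataFrame,
    y: pd.Series,
    trees: int = DEFAULT_TREES,
    mtry: int = DEFAULT_MTRY,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    compute_importance: bool = True,
    importance_repeats: int = 5,
    min_samples_leaf: int = DEFAULT_MIN_LEAF,
    groups=None,
) -> ModelReport:
    """Stratified k-fold CV of a cost-sensitive Random Forest.

    Per fold: fit with the class-weight ratio, score the held-out
    fold's AUC, and (optionally) compute permutation importance on the
    held-out data. Raw importance per feature is the cross-fold mean;
    its dispersion (for the 2-sigma standardization) is the cross-fold
    standard deviation.

    *groups* (optional, one label per row) keeps rows of the same group
    in one fold; used for length-matched subsets, where a case and its
    matched controls must not straddle the train/test boundary.
    """
    y = np.asarray(y)
    weights = class_weights(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"minority class has {counts.min()} samples < {folds} folds; "
            "reduce folds or adjust the catalog/seed"
        )
    if groups is None:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = skf.split(X, y)
    else:
        sgkf = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = sgkf.split(X, y, groups=np.asarray(groups))
    max_feat = min(mtry, X.shape[1])
    fold_aucs, rocs, fold_imps = [], [], []
    for fold_i, (tr, te) in enumerate(splits):
        if len(np.unique(y[te])) < 2:
            raise ValueError(
                f"fold {fold_i} holds a single class; change seed or folds"
            )
        rf = RandomForestClassifier(
            n_estimators=trees,
            max_features=max_feat,
            class_weight=weights,
            min_samples_leaf=min_samples_leaf,
            random_state=seed + fold_i,
            n_jobs=1,
        )
        rf.fit(X.iloc[tr], y[tr])
        proba = rf.predict_proba(X.iloc[te])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[te], proba)))
        fpr, tpr, _ = roc_curve(y[te], proba)
        rocs.append((fpr, tpr))
        if compute_importance:
            pi = permutation_importance(
                rf, X.iloc[te], y[te],
                scoring="roc_auc",
                n_repeats=importance_repeats,
                random_state=seed + fold_i,
                n_jobs=1,
            )
            fold_imps.append(pi.importances_mean)
    importance = None
    if compute_importance:
        imp = np.vstack(fold_imps)
        raw = imp.mean(axis=0)
        sigma = imp.std(axis=0, ddof=1)
        importance = pd.DataFrame(
            {
                "raw": raw,
                "sigma": sigma,
                "transformed": transform_importance(raw, sigma),
            },
            index=X.columns,
        )
    return ModelReport(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        sd_auc=float(np.std(fold_aucs, ddof=1)),
        roc_curves=rocs,
        importance=importance,
    )


def lasso_select(
    X: pd.DataFrame,
    y: pd.Series,
    coef_floor: float = COEF_FLOOR,
    seed: int = 0,
    cv: int = 10,
    Cs: int = 10,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """L1-penalized logistic selection with a conservative coefficient floor.

    Columns are standardized; the penalty is chosen by internal
    cross-validated deviance; observations carry the cost-sensitive
    class weights. Features with |coefficient| below *coef_floor* (on
    the standardized scale) are dropped; survivors are returned ranked
    by |coefficient|. Constant columns are removed up front.
    """
    y = np.asarray(y)
    keep = X.std(axis=0) > 0
    Xv = X.loc[:, keep]
    scaler = StandardScaler()
    Z = scaler.fit_transform(Xv)
    n_min = np.unique(y, return_counts=True)[1].min()
    cv_eff = int(min(cv, n_min))
    model = LogisticRegressionCV(
        penalty="l1",
        solver="liblinear",
        Cs=Cs,
        cv=StratifiedKFold(cv_eff, shuffle=True, random_state=seed),
        scoring="neg_log_loss",
        class_weight=class_weights(y),
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Z, y)
    coefs = pd.Series(model.coef_.ravel(), index=Xv.columns)
    selected = coefs[coefs.abs() >= coef_floor]
    if selected.empty:
        logger.warning("no feature survives the LASSO coefficient floor")
    out = pd.DataFrame({"coef": selected})
    out["abs_coef"] = out["coef"].abs()
    return out.sort_values("abs_coef", ascending=False).drop(columns="abs_coef")


@dataclass
class MatchResult:
    """Matched subset: row index, balance report, and case clusters."""

    index: pd.Index
    balance: pd.DataFrame
    clusters: pd.Series  # row id -> case id of its matched cluster


def mahalanobis_match(
    lengths: pd.DataFrame,
    labels,
    ratio: int = 20,
) -> MatchResult:
    """Greedy Mahalanobis nearest-neighbor matching of controls to cases.

    *lengths* holds the three length covariates (upstream exon, intron,
    downstream exon); cases are label 1 (RI), controls label 0 (CI).
    The covariance is estimated on the pooled table. Each case receives
    *ratio* nearest unused controls (without replacement), in case
    order. Returns the matched row index (all cases + selected
    controls), a balance table of standardized mean differences, and
    the cluster assignment (each control mapped to its case) used to
    keep matched groups intact across CV folds.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    y = np.asarray(labels)
    case_idx = lengths.index[y == 1]
    ctrl_idx = lengths.index[y == 0]
    n_cases, n_ctrl = len(case_idx), len(ctrl_idx)
    if n_ctrl < ratio * n_cases:
        achievable = n_ctrl // max(n_cases, 1)
        raise ValueError(
            f"insufficient controls: {n_ctrl} for {n_cases} cases at "
            f"{ratio}:1 (achievable ratio {achievable}:1)"
        )
    cov = np.cov(lengths.to_numpy(dtype=float), rowvar=False)
    cov = np.atleast_2d(cov)
    VI = np.linalg.pinv(cov)
    D = cdist(
        lengths.loc[case_idx].to_numpy(dtype=float),
        lengths.loc[ctrl_idx].to_numpy(dtype=float),
        metric="mahalanobis", VI=VI,
    )
    used = np.zeros(n_ctrl, dtype=bool)
    chosen: list = []
    cluster_of: dict = {}
    for i in range(n_cases):
        cluster_of[case_idx[i]] = case_idx[i]
        order = np.argsort(D[i], kind="stable")
        picked = 0
        for j in order:
            if not used[j]:
                used[j] = True
                chosen.append(ctrl_idx[j])
                cluster_of[ctrl_idx[j]] = case_idx[i]
                picked += 1
                if picked == ratio:
                    break
    matched = case_idx.append(pd.Index(chosen))
    balance = _balance_table(lengths, y, matched)
    clusters = pd.Series({k: cluster_of[k] for k in matched}, name="cluster")
    return MatchResult(index=matched, balance=balance, clusters=clusters)


def _balance_table(covars: pd.DataFrame, y: np.ndarray, matched: pd.Index) -> pd.DataFrame:
    sub = covars.loc[matched]
    ymap = pd.Series(y, index=covars.index).loc[matched].to_numpy()
    rows = {}
    for col in covars.columns:
        a = sub.loc[ymap == 1, col].to_numpy(dtype=float)
        b = sub.loc[ymap == 0, col].to_numpy(dtype=float)
        var_a = a.var(ddof=1) if a.size > 1 else 0.0
        var_b = b.var(ddof=1) if b.size > 1 else 0.0
        pooled = np.sqrt((var_a + var_b) / 2)
        smd = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        rows[col] = {"mean_case": a.mean(), "mean_control": b.mean(), "smd": smd}
    return pd.DataFrame(rows).T


def scree_auc(
    X: pd.DataFrame,
    y: pd.Series,
    ranking: list[str],
    ks: list[int],
    seed: int = 0,
    trees: int = DEFAULT_TREES,
    mtry: int = DEFAULT_MTRY,
    folds: int = DEFAULT_FOLDS,
) -> pd.DataFrame:
    """Mean AUC as a function of the number of top-ranked features kept."""
    out = []
    for k in ks:
        if k > len(ranking) or k > X.shape[1]:
            raise ValueError(f"k={k} exceeds available features ({len(ranking)})")
        cols = ranking[:k]
        rep = cv_random_forest(
            X[cols], y, trees=trees, mtry=min(mtry, k), folds=folds,
            seed=seed, compute_importance=False,
        )
        out.append({"k": k, "mean_auc": rep.mean_auc, "sd_auc": rep.sd_auc})
    return pd.DataFrame(out).set_index("k")


def correlation_landscape(
    selected: list[str],
    X: pd.DataFrame,
    method: str = "spearman",
    floor: float = 0.8,
) -> pd.DataFrame:
    """Strongest correlates of each selected feature among all others.

    For each selected feature, every other non-constant column is
    correlated (Spearman by default, Pearson available); the max-|r|
    partner is always reported and all partners with |r| >= *floor* are
    listed. Constant columns are skipped with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr_fn = spearmanr if method == "spearman" else pearsonr
    stds = X.std(axis=0)
    usable = [c for c in X.columns if stds[c] > 0]
    dropped = set(X.columns) - set(usable)
    if dropped:
        logger.warning("skipping %d constant columns in correlation landscape", len(dropped))
    rows = []
    for feat in selected:
        if feat not in usable:
            logger.warning("selected feature %s constant or absent; skipped", feat)
            continue
        best = (None, 0.0)
        for other in usable:
            if other == feat:
                continue
            r = float(corr_fn(X[feat], X[other]).statistic)
            if np.isnan(r):
                continue
            if abs(r) > abs(best[1]):
                best = (other, r)
            if abs(r) >= floor:
                rows.append({"selected": feat, "partner": other, "r": r, "is_max": False})
        if best[0] is not None:
            rows.append({"selected": feat, "partner": best[0], "r": best[1], "is_max": True})
    return pd.DataFrame(rows, columns=["selected", "partner", "r", "is_max"])


def run_variant(
    fm,
    variant: str,
    seed: int = 0,
    trees: int = DEFAULT_TREES,
    mtry: int = DEFAULT_MTRY,
    folds: int = DEFAULT_FOLDS,
    match_ratio: int = 20,
    compute_importance: bool = True,
    importance_repeats: int = 5,
) -> ModelReport:
    """Run one named model variant over a FeatureMatrix.

    Variants select columns (rbp_only, repeats_only) and/or rows
    (length-matched subsets built once on the full catalog, then
    cross-validated).
    """
    from .feature_matrix import RBP_GROUP, REPEAT_GROUP, FeatureMatrix  # noqa: F401

    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {', '.join(VARIANTS)}")
    X, y = fm.X, fm.y
    extra: dict = {}
    groups = None
    if variant in ("length_matched", "repeats_only_length_matched"):
        lengths = X[["len_up", "len_intron", "len_down"]]
        match = mahalanobis_match(lengths, y, ratio=match_ratio)
        X, y = X.loc[match.index], y.loc[match.index]
        groups = match.clusters.loc[match.index]
        extra["balance"] = match.balance
        extra["matched_n"] = len(match.index)
    if variant == "rbp_only":
        X = X[fm.columns_for(RBP_GROUP)]
    elif variant in ("repeats_only", "repeats_only_length_matched"):
        X = X[fm.columns_for(REPEAT_GROUP)]
    report = cv_random_forest(
        X, y, trees=trees, mtry=mtry, folds=folds, seed=seed,
        compute_importance=compute_importance,
        importance_repeats=importance_repeats, groups=groups,
    )
    report.extra.update(extra)
    report.extra["variant"] = variant
    report.extra["n_features"] = X.shape[1]
    report.extra["n_samples"] = X.shape[0]
    return report
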