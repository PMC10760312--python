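"""Burden-based phenotype prediction.

A logistic model of a binary phenotype contrast on context-level
homozygosity burdens. Predictors are chosen by backward stepwise
selection on the Akaike information criterion: starting from the
saturated model, the removal that lowers AIC most is accepted at each
iteration until no removal improves AIC. The participant's sex, when
used, enters only *after* selection, to form the final model. Internal
validation uses a stratified 80/20 split, 10-fold cross-validation on
the training portion, and ROC/AUC plus accuracy (threshold 0.5) on the
held-out 20%.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .burden import select_group
from .io_model import MALE, SampleRecord

logger = logging.getLogger(__name__)

RIDGE_LAMBDA = 1e-6  # fallback penalty when the ML fit separates/diverges
SEX_COLUMN = "sex_male"


@dataclass
class FittedLogit:
    """A fitted logistic model: coefficients (incl. intercept), log
    likelihood, AIC, and whether the ridge fallback was used."""

    params: pd.Series
    llf: float
    aic: float
    penalized: bool = False

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.params.index if c != "const"]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xd = sm.add_constant(X[self.predictors], has_constant="add")
        eta = Xd.to_numpy(dtype=float) @ self.params.reindex(Xd.columns).to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logit(X: pd.DataFrame, y) -> FittedLogit:
    """Maximum-likelihood logistic fit; on perfect separation or
    non-convergence, refit with a small ridge penalty and flag it."""
    y = np.asarray(y, dtype=float)
    Xd = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", False):
            raise PerfectSeparationError("logit did not converge")
        return FittedLogit(res.params, float(res.llf), float(res.aic), False)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        logger.warning("separation/divergence in logistic fit; ridge fallback "
                       "(lambda=%.0e)", RIDGE_LAMBDA)
        return _ridge_fit(X, y)


def _ridge_fit(X: pd.DataFrame, y: np.ndarray) -> FittedLogit:
    clf = LogisticRegression(C=1.0 / RIDGE_LAMBDA, max_iter=10_000)
    if X.shape[1] == 0:
        # intercept-only: closed form
        p = np.clip(np.mean(y), 1e-12, 1 - 1e-12)
        params = pd.Series({"const": float(np.log(p / (1 - p)))})
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return FittedLogit(params, llf, 2 * 1 - 2 * llf, True)
    clf.fit(X.to_numpy(dtype=float), y)
    params = pd.Series(
        {"const": float(clf.intercept_[0]),
         **{c: float(b) for c, b in zip(X.columns, clf.coef_[0])}}
    )
    eta = clf.decision_function(X.to_numpy(dtype=float))
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    k = X.shape[1] + 1
    return FittedLogit(params, llf, 2 * k - 2 * llf, True)


def stepwise_backward_aic(
    X: pd.DataFrame, y, candidates: list[str] | None = None
) -> tuple[list[str], list[float]]:
    """Backward stepwise selection by AIC on a logistic model.

    Returns the selected predictor list (possibly empty = intercept-only)
    and the AIC path (saturated model first, then each accepted step).
    Deterministic: removal candidates are scanned in predictor name
    order, so AIC ties break toward the alphabetically first removal.
    Rows with missing predictor values are dropped (logged).
    """
    cols = sorted(candidates) if candidates is not None else sorted(X.columns)
    if not cols:
        raise ValueError("candidate set is empty")
    data = X[cols].astype(float)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    keep_rows = ~data.isna().any(axis=1)
    if not keep_rows.all():
        logger.info("dropping %d rows with missing predictors", int((~keep_rows).sum()))
        data, y = data[keep_rows], y[keep_rows]
    if len(data) <= len(cols) + 2:
        raise ValueError("need n > predictors + 2")

    current = list(cols)
    current_aic = fit_logit(data[current], y).aic
    aic_path = [current_aic]
    while current:
        trials = [(fit_logit(data[[c for c in current if c != drop]], y).aic, drop)
                  for drop in current]
        best_aic, best_drop = min(trials, key=lambda t: t[0])
        if best_aic < current_aic:
            current.remove(best_drop)
            current_aic = best_aic
            aic_path.append(best_aic)
        else:
            break
    return current, aic_path


def fit_final(
    selected: list[str], include_sex: bool, X: pd.DataFrame, y
) -> FittedLogit:
    """Final model on the selected burdens, with sex appended post-selection
    when requested (never offered to the selection step)."""
    cols = list(selected)
    if include_sex:
        if SEX_COLUMN not in X.columns:
            raise ValueError(f"include_sex requires a {SEX_COLUMN!r} column")
        cols = cols + [SEX_COLUMN]
    return fit_logit(X[cols], np.asarray(y, dtype=float))


@dataclass
class ModelReport:
    outcome: str
    selected: list[str]
    include_sex: bool
    coefficients: dict
    aic_path: list[float]
    accuracy: float
    auc: float
    cv_accuracy: float
    roc_points: pd.DataFrame
    penalized: bool
    seed: int
    n_train: int
    n_test: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["roc_points"] = self.roc_points.to_dict(orient="list")
        return d


def roc_auc(y_true, scores) -> tuple[pd.DataFrame, float]:
    """ROC points and trapezoidal AUC over score thresholds."""
    fpr, tpr, thr = roc_curve(np.asarray(y_true), np.asarray(scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), float(sk_auc(fpr, tpr))


def validate(
    X: pd.DataFrame,
    y,
    outcome: str,
    include_sex: bool,
    seed: int,
    candidates: list[str] | None = None,
    select_on: str = "train",
) -> ModelReport:
    """Stratified 80/20 split, stepwise selection, 10-fold CV on the
    training portion, and held-out accuracy/ROC/AUC.

    ``select_on="full"`` runs selection on all data before splitting (a
    documented alternative); the default selects on the training split
    only. Headline accuracy and AUC come from the 20% hold-out; the CV
    fold-mean accuracy is reported alongside.
    """
    y = pd.Series(np.asarray(y, dtype=int), index=X.index)
    if len(X) < 50:
        raise ValueError("validation needs n >= 50")
    if candidates is None:
        candidates = sorted(c for c in X.columns if c != SEX_COLUMN)
    flags: list[str] = []

    idx_train, idx_test = train_test_split(
        X.index, test_size=0.2, stratify=y, random_state=seed
    )
    X_train, y_train = X.loc[idx_train], y.loc[idx_train]
    X_test, y_test = X.loc[idx_test], y.loc[idx_test]

    sel_X, sel_y = (X, y) if select_on == "full" else (X_train, y_train)
    selected, aic_path = stepwise_backward_aic(sel_X, sel_y, candidates)

    n_splits = min(10, int(y_train.value_counts().min()))
    if n_splits < 10:
        flags.append(f"cv_folds_reduced_to_{n_splits}")
        logger.warning("training split supports only %d stratified folds", n_splits)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_acc = []
    for tr, te in skf.split(X_train, y_train):
        model = fit_final(selected, include_sex, X_train.iloc[tr], y_train.iloc[tr])
        proba = model.predict_proba(X_train.iloc[te])
        fold_acc.append(float(np.mean((proba >= 0.5) == y_train.iloc[te].to_numpy())))

    final = fit_final(selected, include_sex, X_train, y_train)
    proba_test = final.predict_proba(X_test)
    accuracy = float(np.mean((proba_test >= 0.5) == y_test.to_numpy()))
    roc_points, auc_value = roc_auc(y_test.to_numpy(), proba_test)
    if final.penalized:
        flags.append("ridge_fallback")

    return ModelReport(
        outcome=outcome,
        selected=selected,
        include_sex=include_sex,
        coefficients={k: float(v) for k, v in final.params.items()},
        aic_path=[float(a) for a in aic_path],
        accuracy=accuracy,
        auc=auc_value,
        cv_accuracy=float(np.mean(fold_acc)),
        roc_points=roc_points,
        penalized=final.penalized,
        seed=seed,
        n_train=len(idx_train),
        n_test=len(idx_test),
        flags=flags,
    )


def burden_design(
    profiles: pd.DataFrame,
    records: list[SampleRecord],
    case_label: str,
    comparison_label: str,
    contexts: list[str],
    stratum: str,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictor table (one burden column per context, plus sex indicator)
    and binary outcome for a two-group contrast."""
    case_ids = select_group(records, case_label)
    comp_ids = select_group(records, comparison_label)
    ids = case_ids + comp_ids
    sub = profiles[
        profiles["stratum"].eq(stratum)
        & profiles["context"].isin(contexts)
        & profiles["sample_id"].isin(set(ids))
    ]
    X = sub.pivot(index="sample_id", columns="context", values="rate").reindex(ids)
    X = X[contexts]
    y = pd.Series([1] * len(case_ids) + [0] * len(comp_ids), index=ids, name="outcome")
    # samples without profiled burdens (e.g. removed during QC) are dropped
    keep = X.notna().all(axis=1)
    if not keep.all():
        logger.info("dropping %d samples without complete burden profiles",
                    int((~keep).sum()))
        X, y = X[keep], y[keep]
    sex = {r.id: 1.0 if r.sex == MALE else 0.0 for r in records}
    X[SEX_COLUMN] = [sex[i] for i in X.index]
    return X, y
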