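"""Epigenetic biomarker models for insulin-resistance outcome.

Candidate CpGs are selected by rank-sum tests with Benjamini–Hochberg
correction; logistic models (single-feature, or greedy forward-AIC
stepwise) predict the IR state.  For a single-CpG model the decision
boundary in β units is the value where the fitted probability is 0.5,
cutoff = −b0/b1; with a negative coefficient the rule reads
"β < cutoff ⇒ IR".  AUC is computed in-sample from the fitted
probabilities.  Perfect separation — likely at cohort sizes of a few
dozen — triggers a declared ridge-penalized refit with a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix

logger = logging.getLogger(__name__)

#: |coefficient| beyond this is treated as a separation blow-up.
_SEPARATION_COEF = 50.0
#: Inverse ridge strength for the separation fallback.  Deliberately weak:
#: it only needs to keep the MLE finite, and a strong penalty would drag the
#: probability-0.5 point (the β cutoff) outside the observed feature range.
_RIDGE_C = 25.0


@dataclass
class LogisticModel:
    """A fitted biomarker model.

    ``beta_cutoff`` and the per-class accuracies are populated only for
    single-feature models (via :func:`beta_cutoff`).
    """

    name: str
    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    auc: float
    n_used: int
    sample_index: pd.Index
    separation_flag: bool = False
    log_likelihood: float = float("nan")
    aic: float = float("nan")
    beta_cutoff: float | None = None
    accuracy_ir: float | None = None
    accuracy_is: float | None = None
    extras: dict = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        Xa = X[self.feature_names].to_numpy(dtype=float) if self.feature_names else np.zeros(
            (len(X), 0)
        )
        return self.intercept + Xa @ self.coefficients

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


def _as_outcome(y) -> pd.Series:
    """Coerce IR indicators: accepts {0,1}, booleans or {IS, IR} labels."""
    s = pd.Series(y)
    if s.dtype == object:
        mapping = {"IR": 1, "IS": 0}
        bad = set(s.dropna().unique()) - set(mapping)
        if bad:
            raise ValueError(f"outcome labels must be IS/IR or 0/1; got {sorted(bad)}")
        s = s.map(mapping)
    return s.astype(int)


def select_candidates(
    beta: BetaMatrix | pd.DataFrame,
    groups,
    probes=None,
    q_threshold: float = 0.01,
) -> list[str]:
    """Rank-sum candidate screen over DML probes.

    Each probe's IS vs IR β values are compared by a Wilcoxon rank-sum
    (Mann-Whitney) test; Benjamini–Hochberg-adjusted p-values below
    ``q_threshold`` select the probe.  ``q_threshold >= 1`` disables the
    screen (all probes pass).
    """
    from .stats import mann_whitney  # local import avoids a cycle

    values = beta.values if isinstance(beta, BetaMatrix) else beta
    if probes is not None:
        values = values.loc[list(probes)]
    groups = pd.Series(groups).reindex(values.columns)
    is_cols = groups[groups == "IS"].index
    ir_cols = groups[groups == "IR"].index
    pvals = []
    for _, row in values.iterrows():
        x = row[is_cols].dropna().to_numpy()
        y = row[ir_cols].dropna().to_numpy()
        pvals.append(mann_whitney(x, y)[1])
    if q_threshold >= 1.0:
        return values.index.tolist()
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    selected = values.index[np.asarray(qvals) < q_threshold].tolist()
    logger.info("candidate screen: %d of %d probes at q<%g", len(selected), len(values), q_threshold)
    return selected


def fit_logistic(
    X: pd.DataFrame,
    y,
    name: str | None = None,
    penalty: str = "none",
) -> LogisticModel:
    """Maximum-likelihood logistic fit with a declared ridge fallback.

    On perfect separation (or a divergent MLE) the model is refit with a
    small L2 penalty and flagged.  AUC is in-sample, from fitted
    probabilities.
    """
    X = pd.DataFrame(X).astype(float)
    yv = _as_outcome(y)
    if len(X) != len(yv):
        raise ValueError("X and y lengths differ")
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("features must be finite")
    if (yv == 1).sum() < 3 or (yv == 0).sum() < 3:
        raise ValueError("need >= 3 samples per class")
    const = X.nunique() <= 1
    if const.any():
        raise ValueError(f"constant feature(s): {X.columns[const].tolist()}")

    features = X.columns.tolist()
    separated = penalty == "ridge"
    params = None
    if penalty == "none":
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")  # separation handled below
                res = sm.Logit(yv.to_numpy(), sm.add_constant(X, has_constant="add")).fit(
                    disp=0, maxiter=200, warn_convergence=False
                )
            params = np.asarray(res.params, dtype=float)
            if (not res.mle_retvals.get("converged", False)) or (
                np.abs(params).max() > _SEPARATION_COEF
            ):
                separated = True
        except Exception:  # PerfectSeparationError, LinAlgError, ...
            separated = True
    if separated or params is None:
        clf = LogisticRegression(C=_RIDGE_C, solver="lbfgs", max_iter=2000)
        clf.fit(X.to_numpy(), yv.to_numpy())
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        if penalty == "none":
            logger.info("separation detected for %s; ridge fallback used", features)

    intercept = float(params[0])
    coefs = np.asarray(params[1:], dtype=float)
    eta = intercept + X.to_numpy() @ coefs
    prob = 1.0 / (1.0 + np.exp(-eta))
    prob_c = np.clip(prob, 1e-12, 1 - 1e-12)
    ll = float(np.sum(yv * np.log(prob_c) + (1 - yv) * np.log(1 - prob_c)))
    k = len(coefs) + 1
    auc = float(roc_auc_score(yv, prob)) if len(np.unique(prob)) > 1 else 0.5
    return LogisticModel(
        name=name or "+".join(features),
        feature_names=features,
        intercept=intercept,
        coefficients=coefs,
        auc=auc,
        n_used=len(yv),
        sample_index=X.index,
        separation_flag=separated and penalty == "none",
        log_likelihood=ll,
        aic=2 * k - 2 * ll,
    )


def _intercept_only_model(y: pd.Series, index: pd.Index) -> LogisticModel:
    p = float(y.mean())
    p = min(max(p, 1e-12), 1 - 1e-12)
    ll = float(y.sum() * np.log(p) + (len(y) - y.sum()) * np.log(1 - p))
    return LogisticModel(
        name="intercept_only",
        feature_names=[],
        intercept=float(np.log(p / (1 - p))),
        coefficients=np.zeros(0),
        auc=0.5,
        n_used=len(y),
        sample_index=index,
        log_likelihood=ll,
        aic=2 - 2 * ll,
    )


def stepwise_select(
    X: pd.DataFrame,
    y,
    criterion: str = "aic",
    direction: str = "forward",
) -> LogisticModel:
    """Greedy forward selection by AIC over candidate features.

    Starts from the intercept-only model and adds, one at a time, the
    feature that most lowers the AIC; stops when no addition improves it
    (so an exact collinear copy of an already-included feature never
    enters).  May legitimately return a single-feature model — at small
    cohort sizes with collinear predictors that is the usual outcome.
    """
    if criterion != "aic" or direction != "forward":
        raise NotImplementedError("only forward-AIC selection is implemented")
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 candidate features")
    yv = _as_outcome(y)
    current: list[str] = []
    best = _intercept_only_model(yv, X.index)
    path = [("<intercept>", best.aic)]
    improved = True
    while improved and len(current) < X.shape[1]:
        improved = False
        trial_best = None
        for feat in X.columns.difference(current):
            try:
                m = fit_logistic(X[current + [feat]], yv)
            except ValueError:
                continue
            if trial_best is None or m.aic < trial_best.aic:
                trial_best = m
        if trial_best is not None and trial_best.aic < best.aic - 1e-9:
            best = trial_best
            current = list(best.feature_names)
            path.append((current[-1], best.aic))
            improved = True
    best.extras["stepwise_path"] = path
    logger.info("stepwise path: %s", path)
    return best


@dataclass
class CutoffResult:
    cutoff: float
    rule: str
    accuracy_ir: float
    accuracy_is: float


def beta_cutoff(model: LogisticModel, X: pd.DataFrame, y) -> CutoffResult:
    """β decision threshold of a single-feature model and per-class accuracy.

    The cutoff is the feature value with fitted probability 0.5,
    −b0/b1.  The IR side of the cutoff follows the coefficient sign
    (b1 < 0 ⇒ "β < cutoff ⇒ IR"); a value exactly at the cutoff is called
    IS.  Accuracies are per-class fractions: correctly called IR / n_IR and
    correctly called IS / n_IS.  Updates the model in place and returns the
    result.
    """
    if len(model.feature_names) != 1:
        raise ValueError("beta_cutoff requires a single-feature model")
    b1 = float(model.coefficients[0])
    if b1 == 0:
        raise ValueError("zero coefficient: no cutoff")
    b0 = model.intercept
    cutoff = -b0 / b1
    yv = _as_outcome(y)
    x = pd.DataFrame(X)[model.feature_names[0]].astype(float).to_numpy()
    pred_ir = (x < cutoff) if b1 < 0 else (x > cutoff)
    rule = f"beta {'<' if b1 < 0 else '>'} {cutoff:.4f} => IR"
    acc_ir = float(pred_ir[yv == 1].mean())
    acc_is = float((~pred_ir[yv == 0]).mean())
    model.beta_cutoff = float(cutoff)
    model.accuracy_ir = acc_ir
    model.accuracy_is = acc_is
    return CutoffResult(float(cutoff), rule, acc_ir, acc_is)


def compare_models(models: list[LogisticModel]) -> pd.DataFrame:
    """Rank fitted models by in-sample AUC (ties → fewer features).

    All models must have been fit on the same samples.
    """
    if len(models) < 2:
        raise ValueError("need >= 2 models to compare")
    ref = frozenset(models[0].sample_index)
    for m in models[1:]:
        if frozenset(m.sample_index) != ref:
            raise ValueError(f"model {m.name!r} was fit on a different sample set")
    rows = [
        {
            "model": m.name,
            "auc": m.auc,
            "n_features": len(m.feature_names),
            "n": m.n_used,
            "separation_flag": m.separation_flag,
            "beta_cutoff": m.beta_cutoff,
            "accuracy_ir": m.accuracy_ir,
            "accuracy_is": m.accuracy_is,
        }
        for m in models
    ]
    out = pd.DataFrame(rows).sort_values(
        ["auc", "n_features", "model"], ascending=[False, True, True]
    )
    return out.reset_index(drop=True)


def single_cpg_models(
    beta: BetaMatrix,
    groups,
    probes,
    with_cutoffs: bool = True,
) -> list[LogisticModel]:
    """One simple logistic model per CpG, optionally with β cutoffs."""
    groups = pd.Series(groups).reindex(beta.sample_ids)
    y = _as_outcome(groups)
    models = []
    for p in probes:
        X = beta.values.loc[[p]].T
        X.columns = [p]
        m = fit_logistic(X, y, name=p)
        if with_cutoffs:
            beta_cutoff(m, X, y)
        models.append(m)
    return models
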