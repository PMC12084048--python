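"""Comparison arms: threshold clinical scores and reference classifiers.

The clinical instruments are consumed as already-computed numeric inputs
(PPOSSUM predicted risk, ASA grade, DASI score, V̇O₂/kg at the anaerobic
threshold) and turned into binary predictions by fixed thresholds with a
clinically forced direction:

* PPOSSUM risk >= 0.30        -> high risk
* ASA grade >= 2 (inclusive)  -> high risk (ordinal 1-5, higher = sicker)
* DASI < 34                   -> high risk (lower functional capacity)
* AT < 11 ml O₂/kg/min        -> high risk (lower fitness)

Reference machine-learning arms are deliberately thin adapters over
scikit-learn, LightGBM and XGBoost — the contribution here is the shared
comparison protocol, not the learners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import Partition, grid_search_cv

__all__ = [
    "ClinicalScoreRule",
    "CLINICAL_SCORE_RULES",
    "score_predict",
    "at_logistic_baseline",
    "reference_classifiers",
    "classifier_factory",
    "DEFAULT_GRIDS",
    "SCORE_FEATURES",
]


@dataclass(frozen=True)
class ClinicalScoreRule:
    name: str
    threshold: float
    direction: str                  # "higher-is-risk" | "lower-is-risk"
    inclusive: bool = True          # boundary value counts as high risk

    def __post_init__(self):
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.direction not in ("higher-is-risk", "lower-is-risk"):
            raise ValueError(f"unknown direction {self.direction!r}")


CLINICAL_SCORE_RULES = {
    "PPOSSUM": ClinicalScoreRule("PPOSSUM", 0.30, "higher-is-risk"),
    "ASA": ClinicalScoreRule("ASA", 2, "higher-is-risk"),
    "DASI": ClinicalScoreRule("DASI", 34, "lower-is-risk", inclusive=False),
    "AT": ClinicalScoreRule("AT", 11, "lower-is-risk", inclusive=False),
}

# cohort feature column backing each score rule
SCORE_FEATURES = {"PPOSSUM": "ppossum_risk", "ASA": "asa",
                  "DASI": "dasi", "AT": "vo2_kg_at"}


def score_predict(rule: ClinicalScoreRule | str, value) -> np.ndarray | int:
    """Binary class from a threshold rule; a step function of the value."""
    if isinstance(rule, str):
        try:
            rule = CLINICAL_SCORE_RULES[rule]
        except KeyError:
            raise ValueError(f"unknown score name {rule!r}") from None
    v = np.asarray(value, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("score value must be finite")
    if rule.direction == "higher-is-risk":
        hit = v >= rule.threshold if rule.inclusive else v > rule.threshold
    else:
        hit = v <= rule.threshold if rule.inclusive else v < rule.threshold
    out = hit.astype(int)
    return int(out) if out.ndim == 0 else out


def at_logistic_baseline(train: Partition, test: Partition,
                         at_feature: str = "vo2_kg_at"):
    """Single-covariate logistic regression on the anaerobic threshold.

    Maximum-likelihood fit (no penalty); returns per-test-row probabilities
    and the fitted (intercept, slope).
    """
    from sklearn.linear_model import LogisticRegression
    if at_feature not in train.X.columns:
        raise ValueError(f"AT feature {at_feature!r} missing")
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000,
                               tol=1e-12)
    model.fit(train.X[[at_feature]], np.asarray(train.y).astype(int))
    probs = model.predict_proba(test.X[[at_feature]])[:, 1]
    return probs, (float(model.intercept_[0]), float(model.coef_[0, 0]))


def classifier_factory(name: str, seed: int = 0):
    """Factory of estimator constructors keyed by arm name."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.tree import DecisionTreeClassifier
    from sklearn.ensemble import RandomForestClassifier

    def lr(**params):
        return LogisticRegression(max_iter=2000, random_state=seed, **params)

    def dt(**params):
        return DecisionTreeClassifier(random_state=seed, **params)

    def rf(**params):
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)

    def lgbm(**params):
        import lightgbm
        return lightgbm.LGBMClassifier(random_state=seed, n_jobs=1,
                                       verbose=-1, **params)

    def xgb(**params):
        import xgboost
        return xgboost.XGBClassifier(random_state=seed, n_jobs=1,
                                     eval_metric="logloss", **params)

    try:
        return {"lr": lr, "dt": dt, "rf": rf, "lgbm": lgbm, "xgb": xgb}[name]
    except KeyError:
        raise ValueError(f"unknown classifier arm {name!r}") from None


DEFAULT_GRIDS: dict[str, list[dict]] = {
    "lr": [{"C": 1.0}, {"C": 0.1}, {"C": 10.0}],
    "dt": [{"max_depth": 3}, {"max_depth": 5}, {"max_depth": None}],
    "rf": [{"n_estimators": 100, "max_depth": None},
           {"n_estimators": 100, "max_depth": 5}],
    "lgbm": [{"n_estimators": 100, "num_leaves": 31},
             {"n_estimators": 100, "num_leaves": 15}],
    "xgb": [{"n_estimators": 100, "max_depth": 3},
            {"n_estimators": 100, "max_depth": 6}],
}


def reference_classifiers(train: Partition, test: Partition,
                          grids: dict[str, list[dict]] | None = None,
                          folds: int = 10, seed: int = 0):
    """Tune each arm by the shared CV grid-search harness; refit on the full
    training partition; return per-arm test probabilities and logs.

    Returns ``{arm: {"probabilities", "best_params", "cv_table"}}``.
    """
    grids = grids if grids is not None else DEFAULT_GRIDS
    out = {}
    for arm, grid in grids.items():
        factory = classifier_factory(arm, seed=seed)
        best, table = grid_search_cv(factory, grid, train, folds=folds,
                                     seed=seed)
        est = factory(**best).fit(train.X, np.asarray(train.y).astype(int))
        probs = np.asarray(est.predict_proba(test.X))[:, 1]
        out[arm] = {"probabilities": probs, "best_params": best,
                    "cv_table": table, "estimator": est}
    return out
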