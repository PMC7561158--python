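"""Survey-weighted classifier fitting and selection.

Implements the two prediction stages of the methodology:

* an intendedness classifier f on the maternal survey — the probability
  that a live birth resulted from an unintended pregnancy given covariates
  observed on both the survey and the birth-record file; and
* a live-birth classifier g on pregnancy histories — the probability that
  a pregnancy ends in a live birth given covariates and intendedness.

Candidate families (logistic regression, random forest, gradient boosting,
multilayer perceptron, linear SGD classifier) are compared by mean held-out
survey-weighted c-statistic over stratified K folds; the winner is refit on
all rows.  The weighted c-statistic is the probability that a randomly
drawn positive outranks a randomly drawn negative, with pair weight equal
to the product of the observation weights and ties counting one half.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from . import schema
from .errors import (
    InvalidArgumentError,
    UndefinedMetricError,
    UnsupportedOperationError,
)

# Fixed family precedence used to break c-statistic ties (simpler families
# win); within a family, earlier grid entries win.
FAMILY_ORDER = ["logistic", "random_forest", "gradient_boosting", "neural_net", "linear_sgd"]

# Default candidate grid: the five families, each with a small fixed grid.
DEFAULT_CANDIDATE_GRID = [
    {"family": "logistic", "params": {"C": 1.0}},
    {"family": "random_forest", "params": {"n_estimators": 200, "min_samples_leaf": 10}},
    {"family": "random_forest", "params": {"n_estimators": 200, "min_samples_leaf": 25}},
    {"family": "gradient_boosting", "params": {"n_estimators": 150, "max_depth": 3}},
    {"family": "neural_net", "params": {"hidden_layer_sizes": (32,), "max_iter": 300}},
    {"family": "linear_sgd", "params": {"alpha": 1e-4}},
]


# ---------------------------------------------------------------------------
# outcome coding


def code_intendedness(raw_response: str, coding_scheme: str = schema.DEFAULT_CODING_SCHEME):
    """Binary-code one five-category intendedness response.

    "later" and "never" responses are always unintended (1); "sooner" and
    "then" always not (0).  The "unsure" response is scheme-dependent: not
    unintended (default, the literature's convention), unintended, or
    excluded (returns None).
    """
    if coding_scheme not in schema.CODING_SCHEMES:
        raise InvalidArgumentError(f"unknown coding_scheme {coding_scheme!r}")
    response = schema.SHORT_RESPONSES.get(raw_response, raw_response)
    if response not in schema.RESPONSES:
        raise InvalidArgumentError(f"unknown intendedness response {raw_response!r}")
    if response in (schema.RESPONSE_LATER, schema.RESPONSE_NEVER):
        return 1
    if response == schema.RESPONSE_UNSURE:
        if coding_scheme == "drop_unsure":
            return None
        return 1 if coding_scheme == "unsure_as_unintended" else 0
    return 0


def code_intendedness_series(responses: pd.Series, coding_scheme: str = schema.DEFAULT_CODING_SCHEME) -> pd.Series:
    """Vectorized coding; excluded rows come back as NaN (caller drops them)."""
    coded = responses.map(lambda r: code_intendedness(r, coding_scheme))
    return coded.astype("float64")


# ---------------------------------------------------------------------------
# imputation


class MissingIndicatorImputer:
    """Zero/median imputation with per-feature missingness indicators.

    Missing binary values become 0; missing continuous values become the
    median observed in the fitting table (frozen at fit time so the same
    medians are applied to the birth-record file).  Every feature gets a
    companion ``<name>_mi`` indicator, 1 where the value was imputed.  If an
    indicator column already exists on the input it is OR-combined with the
    new missingness mask, which makes the transform idempotent.
    """

    def __init__(self, continuous: Sequence[str], binary: Sequence[str]):
        self.continuous = list(continuous)
        self.binary = list(binary)
        self.medians_: Optional[dict] = None

    @property
    def feature_names(self) -> list[str]:
        base = self.continuous + self.binary
        return base + [f"{c}_mi" for c in base]

    def fit(self, frame: pd.DataFrame) -> "MissingIndicatorImputer":
        medians = {}
        for col in self.continuous:
            observed = frame[col].dropna()
            if observed.empty:
                raise InvalidArgumentError(f"continuous feature {col!r} has no observed values")
            medians[col] = float(observed.median())
        self.medians_ = medians
        return self

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise InvalidArgumentError("imputer not fitted")
        out = frame.copy()
        for col in self.continuous + self.binary:
            missing = out[col].isna().to_numpy()
            ind = f"{col}_mi"
            prior = out[ind].to_numpy(dtype=float) if ind in out.columns else 0.0
            out[ind] = np.maximum(prior, missing.astype(float))
            fill = self.medians_[col] if col in self.medians_ else 0.0
            out[col] = out[col].fillna(fill)
        return out

    def fit_transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        return self.fit(frame).transform(frame)


# ---------------------------------------------------------------------------
# weighted c-statistic


def weighted_cstat(scores, labels, weights=None) -> float:
    """Survey-weighted c-statistic (area under the ROC curve).

    Probability that a random positive outscores a random negative, with
    pair weight w_i * w_j and tied scores counting one half.  Computed in
    O(n log n) by sweeping the scores in increasing order and accumulating,
    for each tie group, the negative weight strictly below plus half the
    negative weight inside the group.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    w = np.ones_like(s) if weights is None else np.asarray(weights, dtype=float)
    if not (len(s) == len(y) == len(w)):
        raise InvalidArgumentError("scores, labels, weights must have equal length")
    if np.any(w <= 0):
        raise InvalidArgumentError("weights must be positive")
    pos = y == 1
    w_pos_total = w[pos].sum()
    w_neg_total = w[~pos].sum()
    if w_pos_total == 0 or w_neg_total == 0:
        raise UndefinedMetricError("both outcome classes must be present")

    order = np.argsort(s, kind="mergesort")
    s, y, w = s[order], y[order], w[order]
    wins = 0.0
    cum_neg = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        grp = slice(i, j)
        w_pos_grp = w[grp][y[grp] == 1].sum()
        w_neg_grp = w[grp][y[grp] != 1].sum()
        wins += w_pos_grp * (cum_neg + 0.5 * w_neg_grp)
        cum_neg += w_neg_grp
        i = j
    return float(wins / (w_pos_total * w_neg_total))


# ---------------------------------------------------------------------------
# fitted-model container


@dataclass
class FittedModel:
    """A fitted classifier with its frozen imputation state and CV metadata."""

    family: str
    params: dict
    estimator: object
    feature_names: list
    imputer: Optional[MissingIndicatorImputer] = None
    cv_cstat: Optional[float] = None
    cv_table: Optional[pd.DataFrame] = None
    seed: int = 0

    def _matrix(self, frame: pd.DataFrame) -> np.ndarray:
        if self.imputer is not None:
            frame = self.imputer.transform(frame)
        missing = [c for c in self.feature_names if c not in frame.columns]
        if missing:
            from .errors import SchemaError

            raise SchemaError([f"missing feature column: {c}" for c in missing])
        return frame[self.feature_names].to_numpy(dtype=float)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Predicted probability of the positive class, in [0, 1]."""
        proba = self.estimator.predict_proba(self._matrix(frame))
        idx = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, idx]

    @property
    def feature_importances(self) -> dict:
        est = self.estimator
        if not hasattr(est, "feature_importances_"):
            raise UnsupportedOperationError(
                f"family {self.family!r} does not expose impurity-based importances"
            )
        imp = np.asarray(est.feature_importances_, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        return dict(zip(self.feature_names, imp))


class ConstantModel:
    """Predicts a fixed probability for every row; useful for limit checks."""

    def __init__(self, value: float, feature_names=()):
        self.value = float(value)
        self.feature_names = list(feature_names)
        self.family = "constant"
        self.imputer = None

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return np.full(len(frame), self.value)


# ---------------------------------------------------------------------------
# candidate fitting


def _build_estimator(family: str, params: dict, seed: int):
    params = dict(params)
    if family == "logistic":
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", LogisticRegression(max_iter=2000, **params))]
        )
    if family == "random_forest":
        params.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "neural_net":
        params.setdefault("hidden_layer_sizes", (32,))
        params.setdefault("max_iter", 300)
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", MLPClassifier(random_state=seed, **params))]
        )
    if family == "linear_sgd":
        return Pipeline(
            [("scale", StandardScaler()),
             ("clf", SGDClassifier(loss="log_loss", random_state=seed, **params))]
        )
    raise InvalidArgumentError(f"unknown model family {family!r}")


def fit_candidate(
    table: pd.DataFrame,
    outcome,
    weights,
    family: str,
    hyperparameters: Optional[dict] = None,
    seed: int = 0,
    feature_names: Optional[list] = None,
) -> FittedModel:
    """Fit one candidate family on an already-imputed feature table.

    Observation weights enter the fitting criterion exactly for families
    that accept sample weights; the multilayer perceptron (which does not)
    is fitted on a seeded weight-proportional bootstrap of the rows.
    """
    y = np.asarray(outcome, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise InvalidArgumentError("weights must be positive")
    if len(np.unique(y)) < 2:
        raise InvalidArgumentError("outcome has a single class")
    feature_names = list(feature_names) if feature_names is not None else list(table.columns)
    X = table[feature_names].to_numpy(dtype=float)

    est = _build_estimator(family, hyperparameters or {}, seed)
    if family == "neural_net":
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(y), size=len(y), p=w / w.sum())
        est.fit(X[idx], y[idx])
    elif isinstance(est, Pipeline):
        # weight the standardization too, so doubling a weight and
        # duplicating the row are exactly equivalent
        est.fit(X, y, scale__sample_weight=w, clf__sample_weight=w)
    else:
        est.fit(X, y, sample_weight=w)
    return FittedModel(family=family, params=dict(hyperparameters or {}),
                       estimator=est, feature_names=feature_names, seed=seed)


def select_model(
    table: pd.DataFrame,
    outcome,
    weights,
    candidate_grid: Optional[list] = None,
    k_folds: int = 5,
    seed: int = 0,
    feature_names: Optional[list] = None,
) -> FittedModel:
    """K-fold weighted-c-statistic model selection over a candidate grid.

    Folds are stratified by outcome and seeded.  The candidate with the
    highest mean held-out weighted c-statistic wins; ties break by the
    documented family precedence and then by grid position.  The winner is
    refit on all rows and carries its CV mean and the full CV table.
    """
    if k_folds < 2:
        raise InvalidArgumentError("k_folds must be >= 2")
    grid = candidate_grid if candidate_grid is not None else DEFAULT_CANDIDATE_GRID
    if not grid:
        raise InvalidArgumentError("candidate grid is empty")
    y = np.asarray(outcome, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    feature_names = list(feature_names) if feature_names is not None else list(table.columns)

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    records = []
    for ci, cand in enumerate(grid):
        for fold, (tr, te) in enumerate(skf.split(table[feature_names], y)):
            model = fit_candidate(
                table.iloc[tr], y[tr], w[tr], cand["family"],
                cand.get("params"), seed=seed, feature_names=feature_names,
            )
            scores = model.predict(table.iloc[te])
            records.append(
                {"candidate": ci, "family": cand["family"],
                 "params": repr(cand.get("params", {})), "fold": fold,
                 "cstat": weighted_cstat(scores, y[te], w[te])}
            )
    cv_table = pd.DataFrame(records)
    means = cv_table.groupby("candidate")["cstat"].mean()

    def sort_key(ci):
        fam = grid[ci]["family"]
        return (-means[ci], FAMILY_ORDER.index(fam) if fam in FAMILY_ORDER else len(FAMILY_ORDER), ci)

    best = min(means.index, key=sort_key)
    winner = fit_candidate(table, y, w, grid[best]["family"], grid[best].get("params"),
                           seed=seed, feature_names=feature_names)
    winner.cv_cstat = float(means[best])
    winner.cv_table = cv_table
    return winner


# ---------------------------------------------------------------------------
# importance and margins


def importance_report(model: FittedModel, top_k: int = 5) -> dict:
    """Normalized impurity importances, ranked, with the cumulative top-k share.

    The companion missingness indicators are folded into their parent
    feature before ranking so the report speaks in terms of the documented
    covariates.
    """
    raw = model.feature_importances  # raises for families without importances
    merged: dict[str, float] = {}
    for name, share in raw.items():
        base = name[:-3] if name.endswith("_mi") else name
        merged[base] = merged.get(base, 0.0) + float(share)
    ranked = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    top_k = min(top_k, len(ranked))
    return {
        "ranked": ranked,
        "top_k": top_k,
        "top_k_share": float(sum(share for _, share in ranked[:top_k])),
    }


@dataclass
class MarginSummary:
    """Distribution of predictions with one covariate forced to a level.

    All values are percentages.  The box is the 25th/50th/75th percentiles
    of the row-level predictions; the adjacent values are p25 - 1.5 IQR and
    p75 + 1.5 IQR clipped to the observed minimum/maximum.
    """

    feature: str
    level: object
    mean: float
    p25: float
    p50: float
    p75: float
    lower_adjacent: float
    upper_adjacent: float


def predictive_margins(model, table: pd.DataFrame, feature: str, levels: Sequence) -> list[MarginSummary]:
    """Predictive margins (partial dependence) of one covariate.

    For each level, the covariate is forced to that level for every row of
    the table, the model re-predicts, and the distribution of row-level
    predictions is summarized.  Averaging over the remaining covariates'
    empirical joint distribution is what distinguishes this from a simple
    stratified mean.
    """
    if feature not in table.columns:
        raise InvalidArgumentError(f"feature {feature!r} not in table")
    out = []
    for level in levels:
        forced = table.copy()
        forced[feature] = level
        preds = 100.0 * np.asarray(model.predict(forced), dtype=float)
        p25, p50, p75 = np.percentile(preds, [25, 50, 75])
        iqr = p75 - p25
        out.append(
            MarginSummary(
                feature=feature,
                level=level,
                mean=float(preds.mean()),
                p25=float(p25),
                p50=float(p50),
                p75=float(p75),
                lower_adjacent=float(max(preds.min(), p25 - 1.5 * iqr)),
                upper_adjacent=float(min(preds.max(), p75 + 1.5 * iqr)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# stage-level drivers


def fit_intendedness_model(
    survey: pd.DataFrame,
    coding_scheme: str = schema.DEFAULT_CODING_SCHEME,
    k_folds: int = 5,
    seed: int = 0,
    candidate_grid: Optional[list] = None,
) -> FittedModel:
    """Fit f: code the response, freeze imputation on the survey, select a model."""
    coded = code_intendedness_series(survey["intendedness_response"], coding_scheme)
    keep = coded.notna()
    rows = survey.loc[keep].reset_index(drop=True)
    y = coded[keep].to_numpy()
    w = rows["survey_weight"].to_numpy(dtype=float)

    imputer = MissingIndicatorImputer(schema.CONTINUOUS_F, schema.BINARY_F)
    imputed = imputer.fit_transform(rows)
    model = select_model(imputed, y, w, candidate_grid, k_folds, seed,
                         feature_names=imputer.feature_names)
    model.imputer = imputer
    return model


def fit_livebirth_model(
    pregnancies: pd.DataFrame,
    k_folds: int = 5,
    seed: int = 0,
    candidate_grid: Optional[list] = None,
) -> FittedModel:
    """Fit g: live-birth probability given covariates and intendedness."""
    y = pregnancies["live_birth"].to_numpy(dtype=float)
    w = pregnancies["survey_weight"].to_numpy(dtype=float)
    imputer = MissingIndicatorImputer(schema.CONTINUOUS_G, schema.BINARY_G + ["unintended"])
    imputed = imputer.fit_transform(pregnancies)
    model = select_model(imputed, y, w, candidate_grid, k_folds, seed,
                         feature_names=imputer.feature_names)
    model.imputer = imputer
    return model
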