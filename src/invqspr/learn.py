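"""Regression models, evaluation protocols, and descriptor selection.

Implements ordinary least squares (MLR), the coefficient of determination,
leave-one-out validation (LOOV) and repeated k-fold cross validation,
greedy forward stepwise descriptor selection (FSP), LASSO-based selection,
and the named prediction strategies that wire these together:

========== ========================= ================== =================
strategy    selection                 predictor          evaluation
========== ========================= ================== =================
MLR         none                      MLR                10 x 5-fold CV
MLR-LOO     none                      MLR                LOOV
FSP-MLR     FSP scored by 5-fold CV   MLR on selection   10 x 5-fold CV
FSP-MLR-LOO FSP scored by 5-fold CV   MLR on selection   LOOV
FSP-LOO-MLR FSP scored by LOOV        MLR on selection   LOOV
LLR-LLR     LASSO                     LASSO              10 x 5-fold CV
========== ========================= ================== =================

The repeated k-fold score is the median of the per-test-fold R^2 values.
LOOV-based strategies are intended for small samples (n <= 150 by
default); unregularized LOOV R^2 on wide matrices can be hugely negative,
which is a legal output, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, LinearRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

__all__ = [
    "LinearModel",
    "EvalProtocol",
    "EvaluationReport",
    "SelectionResult",
    "fit_mlr",
    "r_squared",
    "evaluate",
    "fsp_select",
    "lasso_select",
    "run_strategy",
    "STRATEGIES",
]

STRATEGIES = ("MLR", "MLR-LOO", "FSP-MLR", "FSP-MLR-LOO", "FSP-LOO-MLR", "LLR-LLR")


@dataclass
class LinearModel:
    """Prediction function eta(f(C)) = intercept + sum_d w_d * f_d(C)."""

    names: list[str]
    weights: dict[str, float]
    intercept: float

    def predict_vector(self, vec: dict[str, float]) -> float:
        return self.intercept + sum(w * vec.get(n, 0.0) for n, w in self.weights.items())

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept, dtype=float)
        for n, w in self.weights.items():
            out += w * X[n].to_numpy(dtype=float)
        return out

    def to_json(self) -> dict:
        return {"names": self.names, "weights": self.weights, "intercept": self.intercept}

    @classmethod
    def from_json(cls, obj: dict) -> "LinearModel":
        return cls(list(obj["names"]), dict(obj["weights"]), float(obj["intercept"]))


@dataclass
class EvalProtocol:
    mode: str = "KFOLD"  # or "LOOV"
    k: int = 5
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("LOOV", "KFOLD"):
            raise ValueError(f"unknown evaluation mode {self.mode!r}")
        if self.mode == "KFOLD" and (self.k < 2 or self.repeats < 1):
            raise ValueError("k-fold protocol needs k >= 2 and repeats >= 1")


@dataclass
class EvaluationReport:
    protocol: EvalProtocol
    score: float
    fold_scores: list[float] = field(default_factory=list)


@dataclass
class SelectionResult:
    names: list[str]
    trajectory: list[float]
    final_score: float


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def fit_mlr(X, y) -> LinearModel:
    """Ordinary least squares; rank-deficient designs get the minimum-norm
    coefficient vector (via SVD-based lstsq inside scikit-learn)."""
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(Xf) == 0 or Xf.shape[1] == 0:
        raise ValueError("empty design matrix")
    if len(Xf) != len(y) or len(y) < 2:
        raise ValueError("need matching X rows and y of length >= 2")
    reg = LinearRegression().fit(Xf.to_numpy(dtype=float), y)
    names = list(Xf.columns)
    return LinearModel(names, dict(zip(names, map(float, reg.coef_))), float(reg.intercept_))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 - SSres/SStot (may be very negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    if sstot == 0.0:
        raise ValueError("zero variance in y_true; R^2 undefined")
    ssres = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ssres / sstot


def _default_fitter(Xtr, ytr):
    return fit_mlr(Xtr, ytr)


def evaluate(X, y, protocol: EvalProtocol, fitter=_default_fitter) -> EvaluationReport:
    """LOOV: single R^2 over the n held-out predictions (seed-independent).
    KFOLD: median R^2 over repeats x k test folds, folds seeded from
    ``protocol.seed + repeat``."""
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(Xf)
    if protocol.mode == "LOOV":
        preds = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = fitter(Xf.iloc[mask], y[mask])
            preds[i] = model.predict(Xf.iloc[[i]])[0]
        return EvaluationReport(protocol, r_squared(y, preds))
    if protocol.k > n:
        raise ValueError(f"k={protocol.k} exceeds sample size n={n}")
    scores: list[float] = []
    for rep in range(protocol.repeats):
        kf = KFold(n_splits=protocol.k, shuffle=True, random_state=protocol.seed + rep)
        for tr, te in kf.split(Xf):
            model = fitter(Xf.iloc[tr], y[tr])
            scores.append(r_squared(y[te], model.predict(Xf.iloc[te])))
    return EvaluationReport(protocol, float(np.median(scores)), scores)


def fsp_select(
    X,
    y,
    max_k: int,
    protocol: EvalProtocol | None = None,
    tol: float = 1e-4,
) -> SelectionResult:
    """Greedy forward stepwise selection.

    At each iteration every unselected column is scored by ``evaluate`` on
    MLR over (selected + candidate) using the same protocol (hence the same
    folds within an iteration); the best is added.  Stops after ``max_k``
    additions or when the best one-step improvement falls below ``tol``.
    Ties break toward the earlier schema column.  Returns the prefix of the
    trajectory attaining the best score.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    protocol = protocol or EvalProtocol(mode="KFOLD", k=5, repeats=1)
    if max_k > Xf.shape[1]:
        raise ValueError("max_k exceeds number of descriptors")
    selected: list[str] = []
    trajectory: list[float] = []
    remaining = list(Xf.columns)
    best_prev = -np.inf
    while len(selected) < max_k and remaining:
        best_name, best_score = None, -np.inf
        for name in remaining:
            score = evaluate(Xf[selected + [name]], y, protocol).score
            if score > best_score:
                best_name, best_score = name, score
        if best_score <= best_prev + tol and selected:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        trajectory.append(best_score)
        best_prev = best_score
    # best prefix of the trajectory
    cut = int(np.argmax(trajectory)) + 1 if trajectory else 0
    return SelectionResult(selected[:cut], trajectory[:cut], trajectory[cut - 1] if cut else -np.inf)


def lasso_select(X, y, lam: float | None = None, seed: int = 0) -> SelectionResult:
    """Descriptors with nonzero coefficients under L1-penalized least
    squares on standardized columns; lam chosen by CV grid when omitted."""
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    scaler = StandardScaler()
    Xs = scaler.fit_transform(Xf.to_numpy(dtype=float))
    if lam is None:
        cv = KFold(5, shuffle=True, random_state=seed)
        reg = LassoCV(cv=cv, max_iter=50_000).fit(Xs, y)
        lam = float(reg.alpha_)
    elif lam == 0.0:
        model = fit_mlr(Xf, y)
        names = [n for n in Xf.columns if abs(model.weights[n]) > 1e-12]
        return SelectionResult(names, [], np.nan)
    reg = Lasso(alpha=lam, max_iter=50_000).fit(Xs, y)
    names = [n for n, c in zip(Xf.columns, reg.coef_) if abs(c) > 1e-10]
    return SelectionResult(names, [], np.nan)


def _lasso_fitter(seed: int, lam: float | None):
    """LASSO-as-predictor fitter (for the LLR-LLR strategy), expressed as a
    LinearModel on the original scale."""

    def fit(Xtr, ytr) -> LinearModel:
        Xf = _as_frame(Xtr)
        arr = Xf.to_numpy(dtype=float)
        mean, std = arr.mean(axis=0), arr.std(axis=0)
        std[std == 0] = 1.0
        Xs = (arr - mean) / std
        ytr = np.asarray(ytr, dtype=float)
        if lam is None:
            cv = KFold(min(5, len(Xf)), shuffle=True, random_state=seed)
            reg = LassoCV(cv=cv, max_iter=50_000).fit(Xs, ytr)
        else:
            reg = Lasso(alpha=lam, max_iter=50_000).fit(Xs, ytr)
        coef = reg.coef_ / std
        intercept = float(reg.intercept_ - np.dot(coef, mean))
        names = list(Xf.columns)
        return LinearModel(names, dict(zip(names, map(float, coef))), intercept)

    return fit


@dataclass
class StrategyConfig:
    max_k: int = 10
    fsp_tol: float = 1e-4
    seed: int = 0
    lam: float | None = None
    loov_limit: int = 150
    allow_large_loov: bool = False


def run_strategy(
    name: str, X, y, config: StrategyConfig | None = None
) -> tuple[LinearModel, EvaluationReport, SelectionResult | None]:
    """Run one named prediction strategy end to end.

    Returns the model fitted on all data over the selected descriptors, the
    evaluation report under the strategy's protocol, and the selection
    result (None for MLR / MLR-LOO).
    """
    if name not in STRATEGIES:
        raise ValueError(f"unknown strategy {name!r}; choose from {STRATEGIES}")
    config = config or StrategyConfig()
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if len(Xf) != len(y) or len(y) < 3:
        raise ValueError("dataset too small for strategy evaluation")

    loov = EvalProtocol(mode="LOOV")
    cv5 = EvalProtocol(mode="KFOLD", k=5, repeats=1, seed=config.seed)
    cv10x5 = EvalProtocol(mode="KFOLD", k=5, repeats=10, seed=config.seed)
    if name.endswith("LOO") or name == "FSP-LOO-MLR":
        if len(Xf) > config.loov_limit and not config.allow_large_loov:
            raise ValueError(
                f"LOOV strategies are restricted to n <= {config.loov_limit}; "
                "set allow_large_loov to override"
            )

    selection: SelectionResult | None = None
    if name in ("FSP-MLR", "FSP-MLR-LOO"):
        selection = fsp_select(Xf, y, config.max_k, cv5, config.fsp_tol)
    elif name == "FSP-LOO-MLR":
        selection = fsp_select(Xf, y, config.max_k, loov, config.fsp_tol)
    elif name == "LLR-LLR":
        selection = lasso_select(Xf, y, config.lam, config.seed)

    cols = selection.names if selection is not None else list(Xf.columns)
    if not cols:
        raise ValueError(f"strategy {name}: selection produced no descriptors")
    Xsel = Xf[cols]

    if name == "LLR-LLR":
        fitter = _lasso_fitter(config.seed, config.lam)
        report = evaluate(Xsel, y, cv10x5, fitter)
        model = fitter(Xsel, y)
    else:
        protocol = {
            "MLR": cv10x5,
            "FSP-MLR": cv10x5,
            "MLR-LOO": loov,
            "FSP-MLR-LOO": loov,
            "FSP-LOO-MLR": loov,
        }[name]
        report = evaluate(Xsel, y, protocol)
        model = fit_mlr(Xsel, y)
    return model, report, selection
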