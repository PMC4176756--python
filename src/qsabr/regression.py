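"""Linear modelling: OLS, leave-one-out validation, stepwise selection.

The modelling protocol is the classical QSPR one: prune near-collinear
descriptors, run a greedy forward-backward stepwise search driven by
partial-F tests, and validate with leave-one-out cross-validation
(PRESS / Q2) and, when a held-out test set exists, external predictivity
R2_pred computed against the *training* mean.

Definitions (y = experimental barrier, yhat = fitted, y_(i) = prediction
for object i from the model refit without it, ybar = training mean):

    R2      = 1 - sum (y - yhat)^2  / sum (y - ybar)^2
    PRESS   = sum (y - y_(i))^2          with  y - y_(i) = e_i / (1 - h_ii)
    Q2_loo  = 1 - PRESS / sum (y - ybar)^2
    R2_pred = 1 - sum (y_test - yhat_test)^2 / sum (y_test - ybar_train)^2

Ordinary-least-squares fitting, coefficient standard errors and hat
diagonals are delegated to statsmodels; the validation statistics and the
stepwise search are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class SingularDesignError(ValueError):
    """The design matrix (with intercept) is rank deficient."""


class UndefinedLOOError(ValueError):
    """A leverage of 1 makes the leave-one-out residual undefined."""


@dataclass
class LinearModel:
    """A fitted (or bundled) linear barrier model.

    Coefficients are kcal/mol per descriptor unit; ``names`` fixes the
    descriptor order used by :meth:`predict`.
    """

    intercept: float
    intercept_se: Optional[float]
    names: Tuple[str, ...]
    coef: Dict[str, float]
    coef_se: Dict[str, Optional[float]]
    n_obs: Optional[int] = None
    r2: Optional[float] = None
    f_stat: Optional[float] = None
    se_reg: Optional[float] = None
    press: Optional[float] = None
    q2_loo: Optional[float] = None
    r2_pred: Optional[float] = None
    y_train_mean: Optional[float] = None

    def predict(self, data: Union[pd.DataFrame, "np.ndarray", dict]) -> np.ndarray:
        """Predict barriers: intercept + sum(coef * descriptor).

        ``data`` may be a DataFrame (columns looked up by name), a mapping
        of name -> value, or a plain array whose columns follow ``names``.
        """
        if isinstance(data, dict):
            missing = [n for n in self.names if n not in data]
            if missing:
                raise KeyError(f"missing descriptor(s): {missing}")
            x = np.array([[data[n] for n in self.names]], dtype=float)
        elif isinstance(data, pd.DataFrame):
            missing = [n for n in self.names if n not in data.columns]
            if missing:
                raise KeyError(f"missing descriptor(s): {missing}")
            x = data.loc[:, list(self.names)].to_numpy(dtype=float)
        else:
            x = np.atleast_2d(np.asarray(data, dtype=float))
            if x.shape[1] != len(self.names):
                raise ValueError(
                    f"expected {len(self.names)} descriptor columns, got {x.shape[1]}"
                )
        beta = np.array([self.coef[n] for n in self.names])
        return self.intercept + x @ beta

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "names": list(self.names),
            "coef": self.coef,
            "coef_se": self.coef_se,
            "n_obs": self.n_obs,
            "r2": self.r2,
            "f_stat": self.f_stat,
            "se_reg": self.se_reg,
            "press": self.press,
            "q2_loo": self.q2_loo,
            "r2_pred": self.r2_pred,
            "y_train_mean": self.y_train_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            intercept=d["intercept"],
            intercept_se=d.get("intercept_se"),
            names=tuple(d["names"]),
            coef=dict(d["coef"]),
            coef_se=dict(d.get("coef_se") or {n: None for n in d["names"]}),
            n_obs=d.get("n_obs"),
            r2=d.get("r2"),
            f_stat=d.get("f_stat"),
            se_reg=d.get("se_reg"),
            press=d.get("press"),
            q2_loo=d.get("q2_loo"),
            r2_pred=d.get("r2_pred"),
            y_train_mean=d.get("y_train_mean"),
        )


@dataclass(frozen=True)
class SelectionStep:
    step: int
    action: str  # "add" | "remove"
    name: str
    partial_f: float
    p_value: float
    r2: float
    q2_loo: Optional[float] = None


@dataclass
class SelectionTrace:
    steps: List[SelectionStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": s.step,
                    "action": s.action,
                    "name": s.name,
                    "partial_f": s.partial_f,
                    "p": s.p_value,
                    "r2": s.r2,
                    "q2_loo": s.q2_loo,
                }
                for s in self.steps
            ]
        )


def _coerce(X, names) -> Tuple[np.ndarray, Tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = tuple(X.columns)
        X = X.loc[:, list(names)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if names is None:
            names = tuple(f"x{i}" for i in range(X.shape[1]))
    return X, tuple(names)


def _check_rank(Z: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # Identify columns linearly dependent on their predecessors.
        dependent = []
        r = 0
        for j in range(Z.shape[1]):
            rj = np.linalg.matrix_rank(Z[:, : j + 1])
            if rj == r:
                dependent.append("intercept" if j == 0 else names[j - 1])
            r = rj
        raise SingularDesignError(
            f"design matrix is rank deficient; dependent column(s): {dependent}"
        )


def fit_ols(
    X,
    y,
    names: Optional[Sequence[str]] = None,
    compute_loo: bool = True,
) -> LinearModel:
    """Fit an OLS barrier model with full fit and validation statistics.

    Raises :class:`SingularDesignError` on a rank-deficient design (after
    the intercept column is appended) and ``ValueError`` when there are not
    enough observations for the requested descriptor count.
    """
    X, names = _coerce(X, names)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} observations to fit {p} descriptors")
    Z = sm.add_constant(X, has_constant="add")
    _check_rank(Z, names)
    res = sm.OLS(y, Z).fit()

    model = LinearModel(
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        names=names,
        coef={nm: float(b) for nm, b in zip(names, res.params[1:])},
        coef_se={nm: float(s) for nm, s in zip(names, res.bse[1:])},
        n_obs=n,
        r2=float(res.rsquared),
        f_stat=float(res.fvalue) if p > 0 else None,
        se_reg=float(np.sqrt(res.mse_resid)),
        y_train_mean=float(y.mean()),
    )
    if compute_loo:
        model.press, model.q2_loo = loo_stats(model, X, y)
    return model


def _hat_diag(X: np.ndarray) -> np.ndarray:
    Z = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    Q, _ = np.linalg.qr(Z)
    return np.einsum("ij,ij->i", Q, Q)


def loo_stats(model: LinearModel, X, y) -> Tuple[float, float]:
    """Closed-form leave-one-out PRESS and Q2 for a fitted model.

    Uses the identity that the deleted residual equals e_i / (1 - h_ii),
    avoiding n refits.  Raises :class:`UndefinedLOOError` when some
    h_ii = 1 (the deleted fit cannot predict that object).
    """
    X, _ = _coerce(X, model.names)
    y = np.asarray(y, dtype=float).ravel()
    h = _hat_diag(X)
    bad = np.nonzero(h >= 1.0 - 1e-12)[0]
    if bad.size:
        raise UndefinedLOOError(
            f"leverage is 1 for object(s) {bad.tolist()}; LOO prediction undefined"
        )
    e = y - model.predict(X)
    press = float(np.sum((e / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedLOOError("response is constant; Q2 undefined")
    return press, 1.0 - press / tss


def r2_pred(model: LinearModel, X_test, y_test) -> float:
    """External predictivity on a held-out test set.

    The denominator centres the test responses on the *training* mean
    carried by the model, so a model no better than the training average
    scores 0.
    """
    X_test, _ = _coerce(X_test, model.names)
    y_test = np.asarray(y_test, dtype=float).ravel()
    if y_test.size == 0:
        raise ValueError("empty test set")
    if model.y_train_mean is None:
        raise ValueError("model carries no training mean; fit it first")
    denom = float(np.sum((y_test - model.y_train_mean) ** 2))
    if denom == 0.0:
        raise ValueError(
            "all test responses equal the training mean; R2_pred undefined"
        )
    num = float(np.sum((y_test - model.predict(X_test)) ** 2))
    return 1.0 - num / denom


def remove_collinear(
    X,
    names: Optional[Sequence[str]] = None,
    threshold: float = 0.99,
) -> Tuple[np.ndarray, Tuple[str, ...], List[Tuple[str, str, float]]]:
    """Greedy collinearity pre-filter.

    Scans descriptors in catalogue order and keeps each one only if its
    absolute Pearson correlation with every already-kept descriptor is at
    or below ``threshold``; the later column of an offending pair is
    dropped.  Zero-variance columns are dropped with a warning.  Returns
    the reduced matrix, the kept names, and the dropped (dropped, kept, r)
    pairs (constant columns are reported with an empty partner and r=nan).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    X, names = _coerce(X, names)
    kept: List[int] = []
    dropped: List[Tuple[str, str, float]] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.std(col) == 0.0:
            warnings.warn(f"descriptor {names[j]!r} is constant; dropped")
            dropped.append((names[j], "", float("nan")))
            continue
        clash = None
        for k in kept:
            r = float(np.corrcoef(X[:, k], col)[0, 1])
            exceeds = abs(r) > threshold or (threshold == 1.0 and np.isclose(abs(r), 1.0))
            if exceeds:
                clash = (names[j], names[k], r)
                break
        if clash is None:
            kept.append(j)
        else:
            dropped.append(clash)
    return X[:, kept], tuple(names[k] for k in kept), dropped


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    Z = sm.add_constant(X, has_constant="add") if X.size else np.ones((y.size, 1))
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return float(np.sum((y - Z @ beta) ** 2))


def stepwise_select(
    X,
    y,
    names: Optional[Sequence[str]] = None,
    alpha_enter: float = 0.25,
    alpha_remove: float = 0.25,
    criterion: str = "p",
    f_enter: float = 0.25,
    f_remove: float = 0.25,
    max_steps: int = 200,
) -> Tuple[LinearModel, SelectionTrace]:
    """Greedy forward-backward stepwise descriptor selection by partial F.

    At each forward step the candidate with the smallest partial-F p-value
    enters if p <= ``alpha_enter`` (ties broken by catalogue order); after
    every addition, included descriptors whose partial-F p exceeds
    ``alpha_remove`` are removed, largest p first.  Candidates whose
    addition would make the design rank deficient are skipped (their
    partial F is undefined).  LOO Q2 is recorded at every step for
    monitoring but never drives the search.

    ``criterion="f"`` switches to raw partial-F thresholds (enter when
    F >= ``f_enter``, remove when F < ``f_remove``) for fidelity
    experiments with stepwise dialects that threshold F itself.

    Returns the model refit on the final descriptor set (with full
    statistics) and the selection trace.  If nothing passes entry the
    result is the intercept-only model with an empty trace.
    """
    X, names = _coerce(X, names)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if criterion not in ("p", "f"):
        raise ValueError("criterion must be 'p' or 'f'")

    included: List[int] = []
    trace = SelectionTrace()
    step = 0

    # Improvements at machine-noise scale relative to the total variance are
    # treated as zero so a numerically perfect fit terminates the search
    # instead of admitting variables that "explain" rounding residue.
    tss_total = float(np.sum((y - y.mean()) ** 2))
    noise_floor = 1e-12 * tss_total

    def partial_f(rss_red: float, rss_full: float, df_full: int) -> float:
        improvement = max(rss_red - rss_full, 0.0)
        if improvement <= noise_floor:
            return 0.0
        if df_full <= 0 or rss_full <= noise_floor:
            return np.inf
        return improvement / (rss_full / df_full)

    def model_stats(idx: List[int]):
        if not idx:
            return _rss(np.empty((n, 0)), y), None
        sub = X[:, idx]
        rss = _rss(sub, y)
        return rss, sub

    while step < max_steps:
        changed = False
        rss_cur, _ = model_stats(included)
        k = len(included)

        # --- forward: best candidate by partial F ---
        # p-value ties (including underflow to 0) resolve to the larger F,
        # then to the lower catalogue index.
        best = None  # key = (p, -F, index)
        for j in range(X.shape[1]):
            if j in included:
                continue
            cand = included + [j]
            Zc = sm.add_constant(X[:, cand], has_constant="add")
            if np.linalg.matrix_rank(Zc) < Zc.shape[1]:
                continue  # partial F undefined for a dependent candidate
            df_full = n - (k + 1) - 1
            if df_full <= 0:
                continue
            rss_new = _rss(X[:, cand], y)
            F = partial_f(rss_cur, rss_new, df_full)
            p = float(stats.f.sf(F, 1, df_full)) if np.isfinite(F) else 0.0
            key = (p, -F, j)
            if best is None or key < best[0]:
                best = (key, p, j, F)
        if best is not None:
            _, p, j, F = best
            accept = (p <= alpha_enter) if criterion == "p" else (F >= f_enter)
            if accept:
                included.append(j)
                step += 1
                m_rss, _ = model_stats(included)
                tss = float(np.sum((y - y.mean()) ** 2))
                r2 = 1.0 - m_rss / tss
                q2 = _safe_q2(X[:, included], y)
                trace.steps.append(
                    SelectionStep(step, "add", names[j], float(F), p, r2, q2)
                )
                changed = True

        # --- backward: strip anything no longer significant ---
        while True:
            k = len(included)
            if k == 0:
                break
            rss_cur, _ = model_stats(included)
            df_full = n - k - 1
            worst = None  # (p, -position, F, index)
            for pos, j in enumerate(included):
                reduced = [i for i in included if i != j]
                rss_red, _ = model_stats(reduced)
                F = partial_f(rss_red, rss_cur, df_full)
                p = float(stats.f.sf(F, 1, df_full)) if np.isfinite(F) else 0.0
                if worst is None or p > worst[0]:
                    worst = (p, pos, F, j)
            p, _, F, j = worst
            remove = (p > alpha_remove) if criterion == "p" else (F < f_remove)
            if not remove:
                break
            included.remove(j)
            step += 1
            m_rss, _ = model_stats(included)
            tss = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - m_rss / tss if included else 0.0
            q2 = _safe_q2(X[:, included], y) if included else None
            trace.steps.append(
                SelectionStep(step, "remove", names[j], float(F), p, r2, q2)
            )
            changed = True

        if not changed:
            break

    if included:
        model = fit_ols(X[:, included], y, [names[j] for j in included])
    else:
        model = LinearModel(
            intercept=float(y.mean()),
            intercept_se=float(np.std(y, ddof=1) / np.sqrt(n)) if n > 1 else None,
            names=(),
            coef={},
            coef_se={},
            n_obs=n,
            r2=0.0,
            f_stat=None,
            se_reg=float(np.std(y, ddof=1)) if n > 1 else None,
            y_train_mean=float(y.mean()),
        )
    return model, trace


def _safe_q2(X: np.ndarray, y: np.ndarray) -> Optional[float]:
    try:
        m = fit_ols(X, y, compute_loo=False)
        return loo_stats(m, X, y)[1]
    except (ValueError, np.linalg.LinAlgError):
        return None
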