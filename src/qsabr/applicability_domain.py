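"""Leverage-based applicability-domain assessment (Williams plot).

A regression model is only trusted inside the descriptor-space region it
was trained on.  The leverage of an object with (intercept-augmented)
descriptor row x is h = x' (X'X)^-1 x, computed against the training
design X; objects beyond the warning leverage

    h* = 3 (n_descriptors + 1) / n_training_objects

are structural outliers, and training/test objects whose standardized
residual exceeds a cut-off (conventionally +-3) are response outliers.
Prediction-set objects without a measured barrier are assessed on leverage
alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regression import LinearModel, SingularDesignError, _coerce, _hat_diag


@dataclass(frozen=True)
class ADAssessment:
    """Domain-membership verdict for one object."""

    object_id: str
    set_label: str
    leverage: float
    h_star: float
    std_residual: Optional[float]
    leverage_outlier: bool
    residual_outlier: bool
    in_domain: bool


def _augment(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.hstack([np.ones((X.shape[0], 1)), X])


def leverages(X_train, X_query=None) -> np.ndarray:
    """Leverages h_i = x_i' (X'X)^-1 x_i against the training design.

    ``x_i`` includes the intercept element.  Without a query matrix the
    training self-leverages (hat-matrix diagonal) are returned; query
    leverages may exceed 1.
    """
    Zt = _augment(X_train)
    if np.linalg.matrix_rank(Zt) < Zt.shape[1]:
        raise SingularDesignError("training design (with intercept) is rank deficient")
    if X_query is None:
        return _hat_diag(np.atleast_2d(np.asarray(X_train, dtype=float)))
    Zq = _augment(X_query)
    gram_inv = np.linalg.inv(Zt.T @ Zt)
    return np.einsum("ij,jk,ik->i", Zq, gram_inv, Zq)


def warning_leverage(n_desc: int, n_obs: int) -> float:
    """Warning leverage h* = 3(n_desc + 1)/n_obs."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return 3.0 * (n_desc + 1) / n_obs


def standardized_residuals(
    model: LinearModel, X, y, external: bool = False
) -> np.ndarray:
    """Residuals standardized by their estimated standard deviation.

    Training objects use s*sqrt(1 - h_ii) (internally studentized);
    external objects use the regression standard error s directly.
    """
    X, _ = _coerce(X, model.names)
    y = np.asarray(y, dtype=float).ravel()
    e = y - model.predict(X)
    s = model.se_reg
    if s is None:
        raise ValueError("model carries no regression standard error")
    if s == 0.0:
        out = np.zeros_like(e)
        nonzero = e != 0.0
        out[nonzero] = np.sign(e[nonzero]) * np.inf
        return out
    if external:
        return e / s
    h = _hat_diag(X)
    denom = s * np.sqrt(np.clip(1.0 - h, 0.0, None))
    out = np.full_like(e, np.nan)
    ok = denom > 0
    out[ok] = e[ok] / denom[ok]
    return out


def williams_assessment(
    model: LinearModel,
    X_train,
    y_train,
    X_query=None,
    y_query=None,
    resid_cutoff: float = 3.0,
    train_ids: Optional[Sequence[str]] = None,
    query_ids: Optional[Sequence[str]] = None,
    query_labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Classify every object for a Williams plot.

    Returns a tidy table with columns ``id, set_label, leverage, h_star,
    std_residual, leverage_outlier, residual_outlier, in_domain`` —
    directly plottable as standardized residual vs leverage with the h*
    vertical and +-cutoff horizontal guide lines.  Query objects without
    responses get leverage flags only.
    """
    X_train, _ = _coerce(X_train, model.names)
    y_train = np.asarray(y_train, dtype=float).ravel()
    n_obs, n_desc = X_train.shape
    h_star = warning_leverage(n_desc, n_obs)

    rows = []

    h_train = leverages(X_train)
    r_train = standardized_residuals(model, X_train, y_train)
    ids = train_ids if train_ids is not None else [f"train_{i}" for i in range(n_obs)]
    for i in range(n_obs):
        lev_out = bool(h_train[i] > h_star)
        res_out = bool(np.abs(r_train[i]) > resid_cutoff)
        rows.append(
            ADAssessment(
                object_id=str(ids[i]),
                set_label="train",
                leverage=float(h_train[i]),
                h_star=h_star,
                std_residual=float(r_train[i]),
                leverage_outlier=lev_out,
                residual_outlier=res_out,
                in_domain=not (lev_out or res_out),
            )
        )

    if X_query is not None:
        X_query, _ = _coerce(X_query, model.names)
        nq = X_query.shape[0]
        h_q = leverages(X_train, X_query)
        if y_query is not None:
            y_q = np.asarray(y_query, dtype=float).ravel()
            r_q = standardized_residuals(model, X_query, y_q, external=True)
        else:
            r_q = None
        qids = query_ids if query_ids is not None else [f"query_{i}" for i in range(nq)]
        qlabels = query_labels if query_labels is not None else ["prediction"] * nq
        for i in range(nq):
            lev_out = bool(h_q[i] > h_star)
            if r_q is not None and np.isfinite(r_q[i]):
                res_out = bool(np.abs(r_q[i]) > resid_cutoff)
                sr: Optional[float] = float(r_q[i])
            else:
                res_out = False
                sr = None
            rows.append(
                ADAssessment(
                    object_id=str(qids[i]),
                    set_label=str(qlabels[i]),
                    leverage=float(h_q[i]),
                    h_star=h_star,
                    std_residual=sr,
                    leverage_outlier=lev_out,
                    residual_outlier=res_out,
                    in_domain=not (lev_out or res_out),
                )
            )

    return pd.DataFrame(
        [
            {
                "id": a.object_id,
                "set_label": a.set_label,
                "leverage": a.leverage,
                "h_star": a.h_star,
                "std_residual": a.std_residual,
                "leverage_outlier": a.leverage_outlier,
                "residual_outlier": a.residual_outlier,
                "in_domain": a.in_domain,
            }
            for a in rows
        ]
    )


def plot_williams(table: pd.DataFrame, resid_cutoff: float = 3.0, ax=None):
    """Render the Williams plot (leverage vs standardized residual)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    colors = {"train": "tab:blue", "test": "tab:red", "prediction": "tab:green"}
    for label, sub in table.groupby("set_label"):
        y = sub["std_residual"].fillna(0.0)
        ax.scatter(
            sub["leverage"], y, s=22,
            label=label, color=colors.get(label, "tab:gray"),
        )
    h_star = float(table["h_star"].iloc[0])
    ax.axvline(h_star, color="navy", lw=1, ls="--", label=f"h* = {h_star:.3f}")
    ax.axhline(resid_cutoff, color="navy", lw=1)
    ax.axhline(-resid_cutoff, color="navy", lw=1)
    ax.set_xlabel("leverage $h_i$")
    ax.set_ylabel("standardized residual")
    ax.legend(fontsize=8)
    return ax
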