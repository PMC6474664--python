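"""Partial least squares regression (PLS1) for growth-rate prediction.

Maps the 18 compendium percent-activation features to a scalar growth rate
with the NIPALS algorithm: latent components are extracted as directions of
maximal covariance between the (centered, optionally unit-variance scaled)
feature matrix and the centered response, deflating X after each component.
With as many components as the rank of centered X the fit coincides with
least squares; with fewer it regularizes the strongly collinear pathway
features.  Includes percent-error/RSS scoring and single-pass
leave-one-feature-out sensitivity pruning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLSRModel",
    "PruneResult",
    "fit",
    "predict",
    "percent_error",
    "sensitivity_prune",
]


@dataclass
class PLSRModel:
    """Fitted PLS1 model with coefficients on the original feature scale."""

    feature_names: tuple[str, ...]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    n_components: int
    weights: np.ndarray       # p x k
    x_loadings: np.ndarray    # p x k
    y_loadings: np.ndarray    # k
    coefficients: np.ndarray  # p, original X scale
    intercept: float
    scaled: bool

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "scaled": self.scaled,
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2, sort_keys=True)
            handle.write("\n")

    @classmethod
    def from_json(cls, path) -> "PLSRModel":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        return cls(
            feature_names=tuple(payload["feature_names"]),
            x_mean=np.asarray(payload["x_mean"], dtype=float),
            x_scale=np.asarray(payload["x_scale"], dtype=float),
            y_mean=float(payload["y_mean"]),
            n_components=int(payload["n_components"]),
            weights=np.asarray(payload["weights"], dtype=float),
            x_loadings=np.asarray(payload["x_loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            intercept=float(payload["intercept"]),
            scaled=bool(payload["scaled"]),
        )


def _coerce_x(X, feature_names):
    if isinstance(X, pd.DataFrame):
        if feature_names is None:
            feature_names = tuple(str(c) for c in X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    if feature_names is None:
        feature_names = tuple(f"x{j}" for j in range(X.shape[1]))
    feature_names = tuple(str(f) for f in feature_names)
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature_names length does not match X columns")
    return X, feature_names


def fit(
    X,
    y,
    n_components: int | None = None,
    feature_names: Sequence[str] | None = None,
    scale: bool = True,
) -> PLSRModel:
    """Fit a PLS1 model by NIPALS.

    ``n_components`` defaults to min(n_samples - 1, n_features) — the
    maximum; larger requests are clamped with a warning.  Features are
    mean-centered and (by default) scaled to unit variance; the response is
    centered only.  Component extraction stops early once the response
    residual is numerically exhausted.
    """
    X, feature_names = _coerce_x(X, feature_names)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"y has {y.size} values for {n} samples")
    if n < 2:
        raise ValueError("need at least 2 samples to fit")
    k_max = min(n - 1, p)
    if n_components is None:
        k = k_max
    else:
        k = int(n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k > k_max:
            warnings.warn(
                f"n_components={k} clamped to min(n-1, p)={k_max}", stacklevel=2
            )
            k = k_max

    x_mean = X.mean(axis=0)
    if scale:
        x_scale = X.std(axis=0, ddof=1)
        constant = x_scale <= 0
        if constant.any():
            warnings.warn(
                "constant feature column(s) left unscaled: "
                f"{[feature_names[j] for j in np.flatnonzero(constant)]}",
                stacklevel=2,
            )
            x_scale = np.where(constant, 1.0, x_scale)
    else:
        x_scale = np.ones(p)
    y_mean = float(y.mean())

    x_resid = (X - x_mean) / x_scale
    y_resid = y - y_mean
    y_norm0 = float(np.linalg.norm(y_resid))

    ws, ps, qs = [], [], []
    for _ in range(k):
        w = x_resid.T @ y_resid
        if np.linalg.norm(w) <= 1e-12 * max(1.0, y_norm0):
            break
        w = w / np.linalg.norm(w)
        t = x_resid @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            break
        p_load = x_resid.T @ t / tt
        q_load = float(y_resid @ t / tt)
        x_resid = x_resid - np.outer(t, p_load)
        y_resid = y_resid - q_load * t
        ws.append(w)
        ps.append(p_load)
        qs.append(q_load)

    k_eff = len(ws)
    if k_eff == 0:
        weights = np.zeros((p, 0))
        x_loadings = np.zeros((p, 0))
        y_loadings = np.zeros(0)
        beta_scaled = np.zeros(p)
    else:
        weights = np.column_stack(ws)
        x_loadings = np.column_stack(ps)
        y_loadings = np.asarray(qs)
        beta_scaled = weights @ np.linalg.solve(
            x_loadings.T @ weights, y_loadings
        )
    coefficients = beta_scaled / x_scale
    intercept = y_mean - float(x_mean @ coefficients)
    return PLSRModel(
        feature_names=feature_names,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        n_components=k_eff,
        weights=weights,
        x_loadings=x_loadings,
        y_loadings=y_loadings,
        coefficients=coefficients,
        intercept=intercept,
        scaled=scale,
    )


def predict(model: PLSRModel, X_new) -> np.ndarray:
    """Predict growth rates for new samples.

    A DataFrame input must carry exactly the training features in training
    order; a bare array is trusted to be ordered but must have the right
    width.
    """
    if isinstance(X_new, pd.DataFrame):
        columns = tuple(str(c) for c in X_new.columns)
        if columns != model.feature_names:
            raise ValueError(
                "feature name/order mismatch: model expects "
                f"{list(model.feature_names)}, got {list(columns)}"
            )
        X_new = X_new.to_numpy(dtype=float)
    else:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != len(model.feature_names):
            raise ValueError(
                f"X_new has {X_new.shape[1]} features, model expects "
                f"{len(model.feature_names)}"
            )
    return X_new @ model.coefficients + model.intercept


def percent_error(y_true, y_pred) -> tuple[np.ndarray, float]:
    """Per-sample absolute percent errors and the total residual sum of squares.

    Samples with a zero observed value get a NaN percent (flagged with a
    warning); they still contribute to the RSS.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    resid = y_pred - y_true
    rss = float(resid @ resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        percents = 100.0 * np.abs(resid) / np.abs(y_true)
    zero = y_true == 0
    if zero.any():
        warnings.warn(
            f"percent error undefined for {int(zero.sum())} zero-valued "
            "observation(s); reported as NaN",
            stacklevel=2,
        )
        percents = np.where(zero, np.nan, percents)
    return percents, rss


@dataclass
class PruneResult:
    """Outcome of single-pass leave-one-feature-out sensitivity pruning."""

    kept: tuple[str, ...]
    dropped: tuple[str, ...]
    rss_full: float
    rss_final: float
    sensitivity: pd.DataFrame  # feature, rss_without, delta_rss
    model: PLSRModel


def sensitivity_prune(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    n_components: int | None = None,
    scale: bool = True,
) -> PruneResult:
    """Drop features whose removal does not worsen the training fit.

    For each feature the model is refit without it and the training RSS
    recorded; features whose leave-one-out RSS is at or below the full
    model's (within numerical tolerance) are dropped jointly in a single
    pass, and the final model is refit on the survivors.  If every feature
    is removable the single most damaging-to-remove feature is kept with a
    warning.  Note the joint drop means mutually redundant features
    (duplicated columns) may all be removed together.
    """
    X, feature_names = _coerce_x(X, feature_names)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features to prune")
    k_req = min(n - 1, p) if n_components is None else int(n_components)

    full = fit(X, y, n_components=min(k_req, n - 1, p),
               feature_names=feature_names, scale=scale)
    _, rss_full = percent_error(y, predict(full, X))

    rss_without = np.empty(p)
    with warnings.catch_warnings():
        # the leave-one-out refits repeat the full fit's diagnostics p times
        warnings.simplefilter("ignore", UserWarning)
        for j in range(p):
            X_j = np.delete(X, j, axis=1)
            names_j = feature_names[:j] + feature_names[j + 1:]
            model_j = fit(
                X_j, y, n_components=min(k_req, n - 1, p - 1),
                feature_names=names_j, scale=scale,
            )
            _, rss_without[j] = percent_error(y, predict(model_j, X_j))

    tol = 1e-8 * (1.0 + rss_full)
    removable = rss_without <= rss_full + tol
    if removable.all():
        keep_idx = int(np.argmax(rss_without))
        removable[keep_idx] = False
        warnings.warn(
            "every feature's removal left the fit unchanged or better; "
            f"keeping only {feature_names[keep_idx]!r}",
            stacklevel=2,
        )
    kept = tuple(f for f, r in zip(feature_names, removable) if not r)
    dropped = tuple(f for f, r in zip(feature_names, removable) if r)
    keep_cols = [j for j in range(p) if not removable[j]]
    X_final = X[:, keep_cols]
    final = fit(
        X_final, y, n_components=min(k_req, n - 1, len(keep_cols)),
        feature_names=kept, scale=scale,
    )
    _, rss_final = percent_error(y, predict(final, X_final))
    sensitivity = pd.DataFrame(
        {
            "feature": list(feature_names),
            "rss_without": rss_without,
            "delta_rss": rss_without - rss_full,
            "dropped": removable,
        }
    )
    return PruneResult(
        kept=kept,
        dropped=dropped,
        rss_full=rss_full,
        rss_final=rss_final,
        sensitivity=sensitivity,
        model=final,
    )
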