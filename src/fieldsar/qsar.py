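"""Partial least squares regression on grid-field design matrices.

The regression is NIPALS PLS1 (single response) with X deflation: for
component k, ``w = X'y / ||X'y||``, ``t = Xw``, ``p = X't / t't``,
``q = y't / t't``, then ``X <- X - t p'`` and ``y <- y - q t``. For a single
response each component is a closed-form pass, so the fit is exactly
deterministic. Regression coefficients for a k-component truncation are
``B_k = W_k (P_k' W_k)^{-1} q_k`` over centered X and y.

Model quality follows the conventional QSAR panel:

* ``q²  = 1 - PRESS_cv / SS_tot`` from leave-one-out cross-validation, with
  column filtering/scaling refitted inside every fold from the n-1 retained
  molecules (no preprocessing leakage),
* ``r²  = 1 - SS_res / SS_tot`` on the non-cross-validated fit,
* ``SEE = sqrt(SS_res / (n - N - 1))`` (PRESS-based analogue for the CV
  flavour), ``F = (r²/N) / ((1-r²)/(n-N-1))``,
* external ``r²_pred = (SD - Press) / SD`` where SD sums squared deviations
  of the test activities from the *training* mean (Tropsha convention;
  configurable to the test mean).

A model is conventionally considered valid when q² > 0.5, r² > 0.9,
F > 100 and r²_pred > 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import FieldSet, DesignAssembler

logger = logging.getLogger("fieldsar.qsar")

__all__ = [
    "PLSModel", "ValidationReport", "QsarResult",
    "fit_pls", "loo_cross_validate", "loo_prediction_matrix",
    "select_components", "model_statistics", "field_contributions",
    "predict_and_validate", "scramble_q2", "build_qsar_model",
]

#: printed validity bounds for the statistics panel
VALIDITY_BOUNDS = {"q2": 0.5, "r2": 0.9, "F": 100.0, "r2_pred": 0.5}


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int, tol: float = 1e-12):
    """NIPALS PLS1 on centered data. Returns (W, P, q) with as many
    components as the data's rank supports (warns when fewer than asked)."""
    X = Xc.copy()
    y = yc.copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    k_done = 0
    for k in range(n_components):
        w = X.T @ y
        wn = np.linalg.norm(w)
        if wn <= tol:
            break
        w /= wn
        t = X @ w
        tt = float(t @ t)
        if tt <= tol:
            break
        W[:, k] = w
        P[:, k] = X.T @ t / tt
        q[k] = float(y @ t) / tt
        X -= np.outer(t, P[:, k])
        y -= q[k] * t
        k_done += 1
    if k_done < n_components:
        logger.warning("rank supports only %d of %d PLS components", k_done, n_components)
    return W[:, :k_done], P[:, :k_done], q[:k_done]


def _coef_from_decomp(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


@dataclass
class PLSModel:
    """Fitted latent-variable regression with its statistics panel."""

    n_components: int
    coef_: np.ndarray          # over kept (processed) columns, centered space
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # W (p, N)
    x_loadings: np.ndarray     # P (p, N)
    y_loadings: np.ndarray     # q (N,)
    n_samples: int
    stats: dict = dc_field(default_factory=dict)
    field_contributions: dict | None = None
    column_map: list | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef_ + self.y_mean


@dataclass
class ValidationReport:
    """External test-set validation per ``r²_pred = (SD - Press)/SD``."""

    r2_pred: float
    see_pred: float
    sd: float
    press: float
    table: pd.DataFrame        # id, experimental, predicted, residual


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 with ``n_components`` latent variables (fewer if the rank
    runs out). X is expected already column-filtered/scaled."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if len(y) != n:
        raise ValueError("X and y disagree on sample count")
    if n < n_components + 2:
        raise ValueError(f"need >= n_components + 2 = {n_components + 2} samples, got {n}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals(X - x_mean, y - y_mean, n_components)
    k = W.shape[1]
    if k == 0:
        raise ValueError("X has no usable variance; cannot fit any component")
    coef = _coef_from_decomp(W, P, q, k)
    return PLSModel(n_components=k, coef_=coef, x_mean=x_mean, y_mean=y_mean,
                    weights=W, x_loadings=P, y_loadings=q, n_samples=n)


def _identity_fold(X: np.ndarray):
    def fold(train_idx, test_idx):
        return X[train_idx], X[test_idx]
    return fold


def make_fold_preprocessor(fs: FieldSet, sigma_min: float, block_scale: bool = True):
    """Per-fold preprocessing for cross-validation: refit the electrostatic
    masking means, minimum-sigma filter and block scaling on the retained
    rows only, then transform both partitions."""
    def fold(train_idx, test_idx):
        asm = DesignAssembler(sigma_min=sigma_min, block_scale=block_scale)
        Xtr = asm.fit_transform(fs.subset(train_idx))
        Xte = asm.transform(fs.subset(test_idx))
        return Xtr, Xte
    return fold


def loo_prediction_matrix(X: np.ndarray, y: np.ndarray, max_components: int,
                          fold_preprocess=None) -> np.ndarray:
    """(n, max_components) matrix: column k-1 holds the leave-one-out
    prediction of each sample from a k-component model."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if fold_preprocess is None:
        fold_preprocess = _identity_fold(np.asarray(X, dtype=float))
    preds = np.full((n, max_components), np.nan)
    idx = np.arange(n)
    for i in range(n):
        tr = idx[idx != i]
        Xtr, Xte = fold_preprocess(tr, np.array([i]))
        ytr = y[tr]
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        W, P, q = _nipals(Xtr - x_mean, ytr - y_mean, max_components)
        k_max = W.shape[1]
        xc = Xte[0] - x_mean
        for k in range(1, max_components + 1):
            kk = min(k, k_max)
            coef = _coef_from_decomp(W, P, q, kk)
            preds[i, k - 1] = float(xc @ coef) + y_mean
    return preds


def loo_cross_validate(X: np.ndarray, y: np.ndarray, n_components: int,
                       fold_preprocess=None) -> tuple[float, float, np.ndarray]:
    """Leave-one-out q², PRESS-based SEE_cv, and per-left-out predictions."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero activity variance; q2 undefined")
    preds = loo_prediction_matrix(X, y, n_components, fold_preprocess)[:, n_components - 1]
    press = float(((y - preds) ** 2).sum())
    q2 = 1.0 - press / ss_tot
    dof = len(y) - n_components - 1
    see_cv = float(np.sqrt(press / dof)) if dof > 0 else np.nan
    return q2, see_cv, preds


def select_components(X: np.ndarray, y: np.ndarray, max_components: int,
                      fold_preprocess=None) -> tuple[int, np.ndarray]:
    """Optimal component count N = argmax of LOO q² over 1..max_components
    (ties favour the smaller N). Returns (N, q² profile)."""
    y = np.asarray(y, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero activity variance; q2 undefined")
    preds = loo_prediction_matrix(X, y, max_components, fold_preprocess)
    press = ((y[:, None] - preds) ** 2).sum(axis=0)
    q2 = 1.0 - press / ss_tot
    n_opt = int(np.argmax(q2)) + 1  # argmax returns the first maximum
    return n_opt, q2


def model_statistics(model: PLSModel, X: np.ndarray, y: np.ndarray,
                     loo_press: float | None = None) -> dict:
    """Statistics panel of the fitted model: r², SEE (both flavours when
    PRESS is supplied), F, and pass/fail flags against the conventional
    validity bounds (q² > 0.5, r² > 0.9, F > 100)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    N = model.n_components
    dof = n - N - 1
    if dof <= 0:
        raise ValueError(f"n - N - 1 = {dof} <= 0; statistics undefined")
    yhat = model.predict(X)
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero activity variance")
    r2 = 1.0 - ss_res / ss_tot
    see_ncv = float(np.sqrt(ss_res / dof))
    F = np.inf if r2 >= 1.0 else (r2 / N) / ((1.0 - r2) / dof)
    panel = {"n": n, "N": N, "r2": r2, "see_ncv": see_ncv, "F": float(F)}
    if loo_press is not None:
        panel["q2"] = 1.0 - loo_press / ss_tot
        panel["see_cv"] = float(np.sqrt(loo_press / dof))
    panel["passes"] = {
        "r2": r2 > VALIDITY_BOUNDS["r2"],
        "F": F > VALIDITY_BOUNDS["F"],
        **({"q2": panel["q2"] > VALIDITY_BOUNDS["q2"]} if loo_press is not None else {}),
    }
    model.stats.update(panel)
    return panel


def field_contributions(model: PLSModel, X: np.ndarray,
                        column_map: list[tuple[str, int]]) -> dict[str, float]:
    """Fractional contribution of each field: sum of |b_j| * sd(X_j) over
    the field's columns, normalized to 1 across all columns."""
    sd = np.asarray(X, dtype=float).std(axis=0, ddof=1)
    weight = np.abs(model.coef_) * sd
    total = float(weight.sum())
    out: dict[str, float] = {}
    for (ftype, _), w in zip(column_map, weight):
        out[ftype] = out.get(ftype, 0.0) + float(w)
    if total > 0:
        out = {k: v / total for k, v in out.items()}
    model.field_contributions = out
    return out


def predict_and_validate(model: PLSModel, X_test: np.ndarray, y_test: np.ndarray,
                         y_train_mean: float | None = None,
                         mean: str = "train",
                         ids: list[str] | None = None) -> ValidationReport:
    """External validation: ``r²_pred = (SD - Press)/SD`` with SD the sum of
    squared deviations of the test activities from the training-set mean
    (``mean="test"`` switches to the test-set mean)."""
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    yhat = model.predict(X_test)
    press = float(((y_test - yhat) ** 2).sum())
    if mean == "train":
        ref = model.y_mean if y_train_mean is None else float(y_train_mean)
    elif mean == "test":
        ref = float(y_test.mean())
    else:
        raise ValueError("mean must be 'train' or 'test'")
    sd = float(((y_test - ref) ** 2).sum())
    if sd == 0:
        raise ValueError("zero deviation sum; r2_pred undefined")
    r2_pred = (sd - press) / sd
    see_pred = float(np.sqrt(press / len(y_test)))
    table = pd.DataFrame({
        "id": ids if ids is not None else np.arange(len(y_test)),
        "experimental": y_test,
        "predicted": yhat,
        "residual": y_test - yhat,
    })
    return ValidationReport(r2_pred=r2_pred, see_pred=see_pred, sd=sd,
                            press=press, table=table)


def scramble_q2(X: np.ndarray, y: np.ndarray, n_components: int,
                n_scrambles: int = 20, seed: int = 0,
                fold_preprocess=None) -> np.ndarray:
    """y-scrambling control: LOO q² for ``n_scrambles`` random permutations
    of the activities. A real structure-activity signal should collapse to
    q² <= 0 in the median."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    out = np.empty(n_scrambles)
    for s in range(n_scrambles):
        yp = rng.permutation(y)
        q2, _, _ = loo_cross_validate(X, yp, n_components, fold_preprocess)
        out[s] = q2
    return out


@dataclass
class QsarResult:
    """Everything produced by the end-to-end field->PLS workflow."""

    model: PLSModel
    assembler: DesignAssembler
    X: np.ndarray
    column_map: list
    q2_profile: np.ndarray
    loo_predictions: np.ndarray
    stats: dict


def build_qsar_model(fs_train: FieldSet, y_train: np.ndarray,
                     sigma_min: float | None = None,
                     max_components: int | None = None,
                     refilter_folds: bool = True) -> QsarResult:
    """Fit the full pipeline on a training field set: per-fold-refitted LOO
    for component selection, then the final model with its statistics panel
    and field contributions.

    ``sigma_min`` defaults to 2.0 kcal/mol for CoMFA energies and 0.0 for
    CoMSIA similarity indices. ``max_components`` defaults to
    ``min(15, n // 5)``.
    """
    y = np.asarray(y_train, dtype=float)
    n = fs_train.n_molecules
    if sigma_min is None:
        sigma_min = 2.0 if fs_train.model_family == "CoMFA" else 0.0
    if max_components is None:
        max_components = max(1, min(15, n // 5))
    fold = make_fold_preprocessor(fs_train, sigma_min) if refilter_folds else None

    asm = DesignAssembler(sigma_min=sigma_min)
    X = asm.fit_transform(fs_train)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero activity variance; q2 undefined")
    pred_matrix = loo_prediction_matrix(X, y, max_components, fold)
    press_profile = ((y[:, None] - pred_matrix) ** 2).sum(axis=0)
    q2_profile = 1.0 - press_profile / ss_tot
    n_opt = int(np.argmax(q2_profile)) + 1
    loo_preds = pred_matrix[:, n_opt - 1]
    press = float(press_profile[n_opt - 1])

    model = fit_pls(X, y, n_opt)
    model.column_map = asm.column_map_
    stats = model_statistics(model, X, y, loo_press=press)
    contrib = field_contributions(model, X, asm.column_map_)
    stats["field_contributions"] = contrib
    return QsarResult(model=model, assembler=asm, X=X, column_map=asm.column_map_,
                      q2_profile=q2_profile, loo_predictions=loo_preds, stats=stats)
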