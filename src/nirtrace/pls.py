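"""Partial least-squares (PLS1) regression of total fat content.

A deterministic NIPALS implementation: with a single response the weight
vector of each latent variable is the (normalized) covariance direction
X'y, so there is no iteration and no random initialization — repeated fits
are bit-identical.  One pass to ``l_max`` latent variables yields the nested
regression vectors for every smaller model, which makes the leave-one-out
RMSECV curve cheap: one decomposition per left-out sample instead of one per
(sample, l) pair.

Metrics follow chemometric convention: RMSECV/RMSEP are root mean squared
leave-one-out / test-set prediction errors in fat-% units, and R^2 is the
squared Pearson correlation between predicted and reference values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectra import SpectraSet

__all__ = ["PLSModel", "LooResult", "fit_pls", "predict", "loo_cv", "score",
           "compare_preprocessing"]

_DEFLATION_TOL = 1e-12


@dataclass(frozen=True)
class PLSModel:
    """Fitted PLS1 model: prediction is ``y_mean + (x - x_mean) @ regression_vector``."""

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (l, n) unit weight vectors
    x_loadings: np.ndarray   # (l, n)
    y_loadings: np.ndarray   # (l,)
    regression_vector: np.ndarray  # (n,)
    training_grid: np.ndarray


def _nipals_path(Xc: np.ndarray, yc: np.ndarray, l_max: int):
    """Sequential-deflation PLS1 on centred data.

    Returns (W, P, q, B) where B[a] is the regression vector of the model
    with a+1 latent variables.  Stops early if y is exhausted (the remaining
    rows of B repeat the last attainable model).
    """
    m, n = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((l_max, n))
    P = np.zeros((l_max, n))
    q = np.zeros(l_max)
    scale0 = np.linalg.norm(Xc.T @ yc)
    l_eff = 0
    for a in range(l_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if not np.isfinite(nw) or nw <= _DEFLATION_TOL * max(scale0, 1.0):
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= 0:
            break
        p = X.T @ t / tt
        qa = y @ t / tt
        X -= np.outer(t, p)
        y = y - qa * t
        W[a], P[a], q[a] = w, p, qa
        l_eff = a + 1
    B = np.zeros((l_max, n))
    for a in range(l_eff):
        Wa = W[: a + 1].T            # (n, a+1)
        R = P[: a + 1] @ Wa          # (a+1, a+1), unit upper triangular
        B[a] = Wa @ np.linalg.solve(R, q[: a + 1])
    for a in range(l_eff, l_max):
        B[a] = B[l_eff - 1] if l_eff else 0.0
    return W[:l_eff], P[:l_eff], q[:l_eff], B, l_eff


def _check_xy(X: SpectraSet):
    if X.fat_pct is None or np.any(np.isnan(X.fat_pct)):
        raise ValueError("every calibration sample must carry a fat_pct reference")
    return X.absorbance, X.fat_pct


def fit_pls(X: SpectraSet, l: int) -> PLSModel:
    """Fit a PLS1 model with ``l`` latent variables on a calibration set."""
    A, y = _check_xy(X)
    m, n = A.shape
    if not 1 <= l <= min(m - 1, n):
        raise ValueError(f"l={l} outside the valid range [1, {min(m - 1, n)}]")
    x_mean = A.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, B, l_eff = _nipals_path(A - x_mean, y - y_mean, l)
    return PLSModel(
        n_latent=l_eff,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=B[l - 1],
        training_grid=X.wavelengths_nm.copy(),
    )


def predict(model: PLSModel, X: SpectraSet) -> np.ndarray:
    """Predict fat % for each sample; the grid must equal the training grid
    (no silent interpolation)."""
    g = X.wavelengths_nm
    if g.shape != model.training_grid.shape or not np.allclose(
        g, model.training_grid, rtol=0.0, atol=1e-9
    ):
        raise ValueError("wavelength grid differs from the model's training grid")
    return model.y_mean + (X.absorbance - model.x_mean) @ model.regression_vector


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out cross-validation summary."""

    l_curve: pd.DataFrame       # columns: l, rmsecv
    selected_l: int
    rmsecv: float               # at selected_l
    r2_cv: float                # squared Pearson corr. of LOO predictions at selected_l
    loo_predictions: np.ndarray  # (m,) at selected_l


def loo_cv(X: SpectraSet, l_max: Optional[int] = None) -> LooResult:
    """Leave-one-out RMSECV curve over 1..l_max latent variables.

    Selected l is the smallest l whose RMSECV is within 1e-12 of the minimum
    (parsimony tie-break).  Default ``l_max = min(15, m - 2, n)``.
    """
    A, y = _check_xy(X)
    m, n = A.shape
    if m < 3:
        raise ValueError("leave-one-out cross-validation needs at least 3 samples")
    if l_max is None:
        l_max = min(15, m - 2, n)
    if not 1 <= l_max <= min(m - 2, n):
        raise ValueError(f"l_max={l_max} outside the valid range [1, {min(m - 2, n)}]")
    preds = np.zeros((m, l_max))
    idx = np.arange(m)
    for i in range(m):
        keep = idx != i
        Ai, yi = A[keep], y[keep]
        xm = Ai.mean(axis=0)
        ym = yi.mean()
        _, _, _, B, _ = _nipals_path(Ai - xm, yi - ym, l_max)
        preds[i] = ym + (A[i] - xm) @ B.T
    rmse = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    best = rmse.min()
    selected = int(np.flatnonzero(rmse <= best + 1e-12)[0]) + 1
    curve = pd.DataFrame({"l": np.arange(1, l_max + 1), "rmsecv": rmse})
    sel_pred = preds[:, selected - 1]
    r = np.corrcoef(sel_pred, y)[0, 1] if np.std(y) > 0 else np.nan
    return LooResult(curve, selected, float(rmse[selected - 1]), float(r * r), sel_pred)


def score(predicted: Sequence[float], reference: Sequence[float]) -> dict:
    """Root mean squared error and squared Pearson correlation of predictions."""
    p = np.asarray(predicted, float)
    r = np.asarray(reference, float)
    if p.shape != r.shape or p.ndim != 1 or p.size < 2:
        raise ValueError("predicted and reference must be equal-length vectors (>= 2)")
    rmse = float(np.sqrt(np.mean((p - r) ** 2)))
    if np.std(r) == 0:
        raise ValueError("reference values have zero variance; R^2 undefined")
    corr = float(np.corrcoef(p, r)[0, 1])
    return {"rmse": rmse, "r": corr, "r2": corr * corr}


def compare_preprocessing(
    calibration: SpectraSet,
    test: SpectraSet,
    specs: Sequence,
    l_max: Optional[int] = None,
) -> pd.DataFrame:
    """Benchmark pre-treatments: for each spec run preprocess -> LOO-CV
    (selecting l) -> test prediction; rows sorted by RMSECV ascending.

    ``specs`` holds :class:`~nirtrace.preprocess.PreprocessSpec` objects or
    preset names.  Data-dependent preprocessing state (MSC reference) is
    frozen on the calibration set before the test set is transformed.
    """
    from . import preprocess as pp

    if not specs:
        raise ValueError("need at least one preprocessing spec")
    rows = []
    for spec in specs:
        spec = pp.preset(spec) if isinstance(spec, str) else spec
        spec.fit(calibration)
        cal_p = spec.apply(calibration)
        test_p = spec.apply(test)
        loo = loo_cv(cal_p, l_max)
        model = fit_pls(cal_p, loo.selected_l)
        cal_score = score(predict(model, cal_p), cal_p.fat_pct)
        test_score = score(predict(model, test_p), test_p.fat_pct)
        rows.append(
            {
                "preprocess": spec.name,
                "l": loo.selected_l,
                "RMSECV": loo.rmsecv,
                "RMSEP": test_score["rmse"],
                "R2_cal": cal_score["r2"],
                "R2_test": test_score["r2"],
            }
        )
    return (
        pd.DataFrame(rows).sort_values("RMSECV", kind="stable").reset_index(drop=True)
    )
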