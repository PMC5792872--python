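"""Ordered predictor selection (OPS) of informative wavelength regions.

OPS ranks wavelengths by the magnitude of an informative vector obtained
from a PLS fit on the full calibration set (the regression vector by
default; the per-wavelength correlation with the response, or the product of
the two, are alternatives).  Nested subsets of the ranked wavelengths are
then scored by cross-validated RMSECV at a fixed number of latent variables,
and the best-scoring subset — with the full set always in the running — is
merged into contiguous wavelength regions on the working grid.

The procedure contains no randomness: identical inputs give identical
selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pls import _check_xy, _nipals_path, fit_pls, loo_cv
from .spectra import SpectraSet, WavelengthRegions

__all__ = ["OPSConfig", "OPSResult", "informative_vector", "run_ops",
           "merge_to_regions", "expand_regions"]


@dataclass(frozen=True)
class OPSConfig:
    """OPS settings.

    informative : {"regression_vector", "correlation", "product"}.
    l_model : latent variables of the ranking fit; None (default) selects
        the LOO-CV-optimal l on the full wavelength set first, mirroring the
        practice of investigating l before building the OPS regression
        vector.
    l_eval : latent variables used when scoring each subset; None reuses
        l_model.
    window : size of the first (smallest) subset evaluated.
    increment : wavelengths added per evaluation step.
    cv_folds : None for leave-one-out (the default), else k for k-fold
        (deterministic contiguous folds, provided for speed only).
    include_full_set : keep the full wavelength set as a candidate, so the
        selected subset can never cross-validate worse than no selection.
    selection_tolerance : parsimony tie-break — the selected subset is the
        smallest one whose RMSECV is within this relative margin of the best
        (capped so it never exceeds the full-set RMSECV).  None applies a
        one-standard-error rule, 1/sqrt(2m): RMSECV differences below the
        cross-validation noise floor do not distinguish subsets.
    """

    informative: str = "regression_vector"
    l_model: Optional[int] = None
    l_eval: Optional[int] = None
    window: int = 20
    increment: int = 5
    cv_folds: Optional[int] = None
    include_full_set: bool = True
    selection_tolerance: Optional[float] = None

    def __post_init__(self):
        if self.informative not in ("regression_vector", "correlation", "product"):
            raise ValueError(f"unknown informative vector {self.informative!r}")
        if self.l_eval is not None and self.window < self.l_eval + 1:
            raise ValueError("window must be at least l_eval + 1")
        if self.increment < 1:
            raise ValueError("increment must be >= 1")

    def resolve_l(self, X) -> "OPSConfig":
        """Fill l_model/l_eval from a LOO-CV l-scan on the full set."""
        from dataclasses import replace

        if self.l_model is not None and self.l_eval is not None:
            return self
        l_best = loo_cv(X, None).selected_l
        l_model = self.l_model if self.l_model is not None else l_best
        l_eval = self.l_eval if self.l_eval is not None else l_model
        l_eval = min(l_eval, self.window - 1)
        return replace(self, l_model=l_model, l_eval=l_eval)


@dataclass(frozen=True)
class OPSResult:
    ranking: np.ndarray            # wavelength indices, most informative first
    evaluations: pd.DataFrame      # columns: n_variables, rmsecv
    selected_indices: np.ndarray   # sorted grid indices of the best subset
    selected_regions: WavelengthRegions
    rmsecv_selected: float
    rmsecv_full: float


def informative_vector(X: SpectraSet, cfg: OPSConfig = OPSConfig()) -> np.ndarray:
    """Per-wavelength importance used for ranking (always nonnegative)."""
    A, y = _check_xy(X)
    cfg = cfg.resolve_l(X)
    if cfg.informative == "regression_vector":
        return np.abs(fit_pls(X, cfg.l_model).regression_vector)
    yc = y - y.mean()
    Ac = A - A.mean(axis=0)
    denom = np.linalg.norm(Ac, axis=0) * np.linalg.norm(yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(Ac.T @ yc) / denom
    corr = np.nan_to_num(corr)
    if cfg.informative == "correlation":
        return corr
    return corr * np.abs(fit_pls(X, cfg.l_model).regression_vector)


def _cv_rmse(A: np.ndarray, y: np.ndarray, l: int, folds: Optional[int]) -> float:
    """RMSECV at exactly ``l`` latent variables (leave-one-out when
    ``folds`` is None)."""
    m = A.shape[0]
    if folds is None:
        fold_ids = np.arange(m)
        n_folds = m
    else:
        n_folds = min(folds, m)
        fold_ids = np.arange(m) % n_folds
    sq = 0.0
    for f in range(n_folds):
        test = fold_ids == f
        At, yt = A[~test], y[~test]
        xm, ym = At.mean(axis=0), yt.mean()
        _, _, _, B, _ = _nipals_path(At - xm, yt - ym, l)
        pred = ym + (A[test] - xm) @ B[l - 1]
        sq += np.sum((pred - y[test]) ** 2)
    return float(np.sqrt(sq / m))


def run_ops(X: SpectraSet, cfg: OPSConfig = OPSConfig()) -> OPSResult:
    """Rank wavelengths, score nested ranked subsets by RMSECV, return the
    best subset merged into contiguous regions."""
    A, y = _check_xy(X)
    m, n = A.shape
    if cfg.window > n:
        raise ValueError(f"window {cfg.window} exceeds {n} wavelengths")
    cfg = cfg.resolve_l(X)
    if cfg.l_eval > min(m - 2, cfg.window):
        raise ValueError("l_eval too large for the smallest evaluated subset")
    info = informative_vector(X, cfg)
    # stable sort on (-info, index): deterministic under ties
    ranking = np.lexsort((np.arange(n), -info))
    sizes = list(range(cfg.window, n + 1, cfg.increment))
    if sizes[-1] != n and cfg.include_full_set:
        sizes.append(n)
    evals = []
    for k in sizes:
        cols = np.sort(ranking[:k])
        evals.append((k, _cv_rmse(A[:, cols], y, cfg.l_eval, cfg.cv_folds)))
    table = pd.DataFrame(evals, columns=["n_variables", "rmsecv"])
    rmsecv_full = (table.rmsecv.iloc[-1] if sizes[-1] == n
                   else _cv_rmse(A, y, cfg.l_eval, cfg.cv_folds))
    best = table.rmsecv.min()
    tol = (cfg.selection_tolerance if cfg.selection_tolerance is not None
           else 1.0 / np.sqrt(2.0 * m))
    cutoff = best * (1.0 + tol)
    if cfg.include_full_set:
        cutoff = min(cutoff, rmsecv_full)  # never worse than no selection
    ok = table[table.rmsecv <= cutoff]
    best_row = ok.loc[ok.n_variables.idxmin()]
    k_best = int(best_row.n_variables)
    selected = np.sort(ranking[:k_best])
    return OPSResult(
        ranking=ranking,
        evaluations=table,
        selected_indices=selected,
        selected_regions=merge_to_regions(selected, X.wavelengths_nm),
        rmsecv_selected=float(best_row.rmsecv),
        rmsecv_full=float(rmsecv_full),
    )


def merge_to_regions(indices, grid) -> WavelengthRegions:
    """Merge grid indices into maximal runs of adjacent grid points,
    expressed as closed (start_nm, end_nm) intervals."""
    idx = np.unique(np.asarray(indices, dtype=int))
    if idx.size == 0:
        raise ValueError("cannot merge an empty index set")
    grid = np.asarray(grid, float)
    if idx[0] < 0 or idx[-1] >= grid.size:
        raise ValueError("indices outside the grid")
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return WavelengthRegions(
        [(grid[idx[a]], grid[idx[b]]) for a, b in zip(starts, ends)]
    )


def expand_regions(regions: WavelengthRegions, grid) -> np.ndarray:
    """Inverse of :func:`merge_to_regions`: grid indices covered by the
    regions."""
    return np.flatnonzero(regions.mask(grid))
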