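"""Spectral pre-treatments for NIR absorbance matrices.

Implements the standard chemometric corrections — Savitzky–Golay smoothing
and derivatives, standard normal variate (SNV), multiplicative scatter
correction (MSC) and vector normalization (VN) — plus an ordered-composition
:class:`PreprocessSpec` with named presets such as ``"SG17-SD"`` (17-point
Savitzky–Golay smoothing fused with a second derivative) and ``"SD+VN"``
(second derivative followed by vector normalization).

All transforms are per-spectrum (row-local) except MSC, whose reference
spectrum defaults to the mean of the set it is fitted on and can be frozen
from a calibration set to avoid test-set leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

__all__ = [
    "savitzky_golay",
    "snv",
    "msc",
    "vector_normalize",
    "PreprocessSpec",
    "preset",
    "PRESETS",
]


def savitzky_golay(
    s: SpectraSet, window: int, polyorder: int = 3, deriv: int = 0
) -> SpectraSet:
    """Savitzky–Golay least-squares polynomial filtering per spectrum.

    ``deriv=k`` returns the k-th derivative with respect to wavelength
    (scaled by the grid step, so units are absorbance per nm^k).  The half
    window at each edge is truncated — no polynomial extrapolation enters
    downstream models — so the returned grid shrinks by ``window - 1``
    points.  Requires a uniform grid.
    """
    n = s.n_wavelengths
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window > n:
        raise ValueError(f"window {window} exceeds {n} wavelength points")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than the window")
    if deriv not in (0, 1, 2):
        raise ValueError("deriv must be 0, 1 or 2")
    steps = np.diff(s.wavelengths_nm)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-8):
        raise ValueError("Savitzky-Golay filtering requires a uniform wavelength grid")
    delta = steps[0] if steps.size else 1.0
    out = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=delta, axis=1, mode="interp",
    )
    h = window // 2
    sl = slice(h, n - h)
    return s.with_absorbance(out[:, sl], s.wavelengths_nm[sl])


def finite_difference(s: SpectraSet, deriv: int = 1) -> SpectraSet:
    """Plain central finite-difference derivative (testing aid, not a
    production pre-treatment)."""
    ab = s.absorbance
    wl = s.wavelengths_nm
    for _ in range(deriv):
        ab = (ab[:, 2:] - ab[:, :-2]) / (wl[2:] - wl[:-2])
        wl = wl[1:-1]
        s = s.with_absorbance(ab, wl)
    return s


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre each spectrum and scale to unit
    sample (n-1) standard deviation."""
    ab = s.absorbance
    flat = np.flatnonzero(np.ptp(ab, axis=1) == 0)
    if flat.size:
        raise ValueError(f"constant spectrum for sample {s.sample_ids[flat[0]]!r}")
    mu = ab.mean(axis=1, keepdims=True)
    sd = ab.std(axis=1, ddof=1, keepdims=True)
    return s.with_absorbance((ab - mu) / sd)


def msc(s: SpectraSet, reference: Optional[np.ndarray] = None) -> SpectraSet:
    """Multiplicative scatter correction.

    Each spectrum x is regressed on the reference r by ordinary least
    squares, x ≈ a + b·r, and corrected to (x − a)/b.  ``reference`` defaults
    to the mean spectrum of ``s``; pass the calibration-set mean when
    correcting a test set.
    """
    ab = s.absorbance
    r = ab.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if r.shape != (s.n_wavelengths,):
        raise ValueError("MSC reference length must equal the number of wavelengths")
    rc = r - r.mean()
    denom = rc @ rc
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    b = (ab - ab.mean(axis=1, keepdims=True)) @ rc / denom
    zero = np.flatnonzero(b == 0)
    if zero.size:
        raise ValueError(
            f"MSC gain is zero for sample {s.sample_ids[zero[0]]!r}; "
            "spectrum is orthogonal to the reference"
        )
    a = ab.mean(axis=1) - b * r.mean()
    return s.with_absorbance((ab - a[:, None]) / b[:, None])


def vector_normalize(s: SpectraSet) -> SpectraSet:
    """Centre each spectrum, then divide by the Euclidean norm of the
    centred spectrum, so every row has vector norm 1."""
    ab = s.absorbance
    flat = np.flatnonzero(np.ptp(ab, axis=1) == 0)
    if flat.size:
        raise ValueError(f"constant spectrum for sample {s.sample_ids[flat[0]]!r}")
    centred = ab - ab.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    return s.with_absorbance(centred / norms)


@dataclass
class PreprocessSpec:
    """Ordered list of pre-treatment steps.

    Each step is ``(name, kwargs)`` with name in {"savitzky_golay", "snv",
    "msc", "vector_normalize"}.  ``fit`` freezes data-dependent state (the
    MSC reference) from a calibration set; ``apply`` then transforms any set
    with that frozen state.
    """

    steps: list
    name: str = "custom"
    _msc_reference: Optional[np.ndarray] = field(default=None, repr=False)

    def fit(self, calibration: SpectraSet) -> "PreprocessSpec":
        """Freeze the MSC reference from the calibration set (the mean of the
        calibration spectra at the point MSC runs in the chain)."""
        s = calibration
        for step_name, kw in self.steps:
            if step_name == "msc" and kw.get("reference") is None:
                self._msc_reference = s.absorbance.mean(axis=0)
            s = self._apply_step(step_name, kw, s)
        return self

    def _apply_step(self, step_name, kw, s):
        if step_name == "savitzky_golay":
            return savitzky_golay(s, **kw)
        if step_name == "snv":
            return snv(s)
        if step_name == "msc":
            ref = kw.get("reference")
            if ref is None:
                ref = self._msc_reference
            return msc(s, reference=ref)
        if step_name == "vector_normalize":
            return vector_normalize(s)
        raise ValueError(f"unknown preprocessing step {step_name!r}")

    def apply(self, s: SpectraSet) -> SpectraSet:
        for step_name, kw in self.steps:
            s = self._apply_step(step_name, kw, s)
        return s

    def __call__(self, s: SpectraSet) -> SpectraSet:
        return self.apply(s)


def _sg(window, deriv, polyorder=3):
    return ("savitzky_golay", dict(window=window, polyorder=polyorder, deriv=deriv))


#: Named pre-treatments.  Derivatives are Savitzky–Golay fused
#: smooth-and-differentiate filters (17-point window, cubic polynomial):
#: plain difference derivatives would amplify noise the smoothing is there
#: to suppress.
PRESETS = {
    "raw": [],
    "SG17-SD": [_sg(17, 2)],
    "SD+VN": [_sg(17, 2), ("vector_normalize", {})],
    "FD": [_sg(17, 1)],
    "SD": [_sg(17, 2)],
    "SNV": [("snv", {})],
    "MSC": [("msc", {"reference": None})],
    "VN": [("vector_normalize", {})],
}


def preset(name: str) -> PreprocessSpec:
    """Return a fresh :class:`PreprocessSpec` for a named pre-treatment."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PreprocessSpec([(n, dict(kw)) for n, kw in PRESETS[name]], name=name)
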