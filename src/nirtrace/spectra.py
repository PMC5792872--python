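"""Core containers and I/O for NIR absorbance spectra.

A :class:`SpectraSet` holds a sample-by-wavelength absorbance matrix together
with per-sample metadata (sample id, geographic origin, reference total fat
content in %).  Wavelength selections are expressed as
:class:`WavelengthRegions`, ordered lists of closed ``[start, end]`` nm
intervals; calibration/test partitions as a :class:`SplitPlan`.

The canonical on-disk format is a wide comma-separated table with header
``id,origin,fat_pct,<wl1>,<wl2>,...`` — one row per sample, wavelength columns
in nm.  A minimal JCAMP-DX reader is provided for single-spectrum
interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "WavelengthRegions",
    "SplitPlan",
    "read_spectra",
    "write_spectra",
    "read_jcamp",
    "restrict_to_regions",
    "make_split",
]


@dataclass(frozen=True)
class SpectraSet:
    """Absorbance matrix ``X (m x n)`` on a common wavelength grid.

    Parameters
    ----------
    wavelengths_nm : strictly increasing grid, length n.
    absorbance : (m, n) array of finite absorbance values.
    sample_ids : m unique labels.
    origin : optional m categorical origin labels.
    fat_pct : optional m reference total fat contents (%); NaN marks a
        sample without a reference value.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    sample_ids: tuple
    origin: Optional[tuple] = None
    fat_pct: Optional[np.ndarray] = None

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.ndim != 2:
            raise ValueError("absorbance must be a 2-D (samples x wavelengths) array")
        m, n = ab.shape
        if m < 1:
            raise ValueError("a SpectraSet needs at least one sample (m >= 1)")
        if wl.ndim != 1 or wl.size != n:
            raise ValueError(
                f"wavelength grid length {wl.size} does not match {n} absorbance columns"
            )
        if n > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(ab)):
            bad = np.argwhere(~np.isfinite(ab))[0]
            raise ValueError(
                f"non-finite absorbance at sample {bad[0]}, wavelength index {bad[1]}"
            )
        ids = tuple(str(s) for s in self.sample_ids)
        if len(ids) != m:
            raise ValueError(f"{len(ids)} sample ids for {m} samples")
        if len(set(ids)) != len(ids):
            dups = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.origin is not None and len(self.origin) != m:
            raise ValueError("origin labels must have one entry per sample")
        if self.fat_pct is not None:
            fp = np.asarray(self.fat_pct, dtype=float)
            if fp.shape != (m,):
                raise ValueError("fat_pct must have one entry per sample")
            object.__setattr__(self, "fat_pct", fp)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        object.__setattr__(self, "sample_ids", ids)
        if self.origin is not None:
            object.__setattr__(self, "origin", tuple(str(o) for o in self.origin))

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def with_absorbance(self, absorbance, wavelengths_nm=None) -> "SpectraSet":
        """Copy with a new absorbance matrix (and optionally a new grid)."""
        wl = self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm
        return SpectraSet(wl, absorbance, self.sample_ids, self.origin, self.fat_pct)

    def select_samples(self, ids: Sequence[str]) -> "SpectraSet":
        """Subset (and reorder) samples by id."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in ids]
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None
        return SpectraSet(
            self.wavelengths_nm,
            self.absorbance[rows],
            [self.sample_ids[i] for i in rows],
            None if self.origin is None else [self.origin[i] for i in rows],
            None if self.fat_pct is None else self.fat_pct[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: id/origin/fat_pct metadata then wavelength columns."""
        df = pd.DataFrame(self.absorbance, columns=list(self.wavelengths_nm))
        df.insert(0, "fat_pct", self.fat_pct if self.fat_pct is not None else np.nan)
        df.insert(0, "origin", self.origin if self.origin is not None else "")
        df.insert(0, "id", list(self.sample_ids))
        return df


@dataclass(frozen=True)
class WavelengthRegions:
    """Ordered, pairwise-disjoint closed wavelength intervals in nm.

    A grid point equal to a region boundary belongs to the region: region
    tables in the NIR literature list touching endpoints (e.g. 1385/1386 nm)
    and open intervals would silently drop grid points there.
    """

    regions: tuple

    def __init__(self, regions):
        regs = []
        for r in regions:
            lo, hi = float(r[0]), float(r[1])
            if lo > hi:
                raise ValueError(f"region ({lo}, {hi}) has start > end")
            regs.append((lo, hi))
        regs.sort()
        for (a_lo, a_hi), (b_lo, b_hi) in zip(regs, regs[1:]):
            if b_lo <= a_hi:
                raise ValueError(
                    f"regions ({a_lo}, {a_hi}) and ({b_lo}, {b_hi}) overlap"
                )
        object.__setattr__(self, "regions", tuple(regs))

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)

    def mask(self, wavelengths_nm) -> np.ndarray:
        """Boolean membership of each grid point in any region (closed ends)."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        m = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.regions:
            m |= (wl >= lo) & (wl <= hi)
        return m

    @property
    def first(self):
        return self.regions[0]


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint calibration/test partition of sample ids."""

    calibration_ids: tuple
    test_ids: tuple
    seed: int = 0

    def __post_init__(self):
        cal = tuple(str(s) for s in self.calibration_ids)
        tst = tuple(str(s) for s in self.test_ids)
        if set(cal) & set(tst):
            raise ValueError("calibration and test sets overlap")
        object.__setattr__(self, "calibration_ids", cal)
        object.__setattr__(self, "test_ids", tst)

    def apply(self, s: SpectraSet):
        """Return (calibration, test) SpectraSets."""
        return s.select_samples(self.calibration_ids), s.select_samples(self.test_ids)


# ---------------------------------------------------------------------------
# wide-table I/O

_META_COLS = ("id", "origin", "fat_pct")


def read_spectra(path, dialect: str = "wide_table") -> SpectraSet:
    """Read a SpectraSet from disk.

    ``wide_table``: CSV with header ``id,origin,fat_pct,<wl>...``; empty
    origin/fat fields are allowed.  ``jcamp``: single-spectrum JCAMP-DX.
    """
    if dialect == "jcamp":
        return read_jcamp(path)
    if dialect != "wide_table":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, dtype={"id": str, "origin": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing metadata columns {missing} in {path}")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as e:
        raise ValueError(f"non-numeric wavelength header in {path}: {e}") from None
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError(f"wavelength header in {path} is not strictly increasing")
    ab = df[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(ab)):
        r, c = np.argwhere(~np.isfinite(ab))[0]
        raise ValueError(
            f"non-numeric absorbance at row {df['id'].iloc[r]!r}, column {wl_cols[c]}"
        )
    origin = df["origin"].fillna("").astype(str)
    origin_t = None if (origin == "").all() else tuple(origin)
    fat = pd.to_numeric(df["fat_pct"], errors="coerce").to_numpy(dtype=float)
    fat_a = None if np.all(np.isnan(fat)) else fat
    return SpectraSet(wl, ab, tuple(df["id"]), origin_t, fat_a)


def write_spectra(s: SpectraSet, path) -> str:
    """Write a SpectraSet as a wide CSV table; round-trips through
    :func:`read_spectra` to numeric round-off (fixed ``%.12g`` formatting)."""
    df = s.to_frame()
    df.columns = [c if isinstance(c, str) else format(c, ".12g") for c in df.columns]
    df.to_csv(path, index=False, float_format="%.12g")
    return str(path)


def read_jcamp(path) -> SpectraSet:
    """Minimal JCAMP-DX reader for a single spectrum in ``(X++(Y..Y))`` form.

    Honours XFACTOR/YFACTOR and the per-line leading X value; AFFN numeric
    form only (no SQZ/DIF compression).
    """
    title, xfactor, yfactor = "spectrum", 1.0, 1.0
    firstx = lastx = npoints = None
    data_lines = []  # (x0, [y...]) per data line
    in_data = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "TITLE":
                    title = val or title
                elif key == "XFACTOR":
                    xfactor = float(val)
                elif key == "YFACTOR":
                    yfactor = float(val)
                elif key == "FIRSTX":
                    firstx = float(val)
                elif key == "LASTX":
                    lastx = float(val)
                elif key == "NPOINTS":
                    npoints = int(float(val))
                elif key == "XYDATA":
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if in_data and line:
                vals = [float(t) for t in line.replace(",", " ").split()]
                if len(vals) >= 2:
                    data_lines.append((vals[0], vals[1:]))
    if not data_lines:
        raise ValueError(f"no XYDATA found in {path}")
    ys = [y for _, yvals in data_lines for y in yvals]
    # x step: from FIRSTX/LASTX/NPOINTS when given, else from line-start x's
    if firstx is not None and lastx is not None and npoints is not None and npoints > 1:
        step = (lastx - firstx) / (npoints - 1)
        x0 = firstx / xfactor
    elif len(data_lines) > 1:
        step = (data_lines[1][0] - data_lines[0][0]) / len(data_lines[0][1])
        x0, step = data_lines[0][0], step
    else:
        raise ValueError(f"cannot infer the x grid of {path}")
    if firstx is not None and lastx is not None and npoints is not None and npoints > 1:
        wl = np.linspace(firstx, lastx, npoints)
    else:
        wl = (x0 + step * np.arange(len(ys))) * xfactor
    if wl.size != len(ys):
        raise ValueError(f"{path}: NPOINTS does not match the number of y values")
    ab = np.asarray(ys, dtype=float)[None, :] * yfactor
    order = np.argsort(wl)
    return SpectraSet(wl[order], ab[:, order], (title,))


# ---------------------------------------------------------------------------
# wavelength restriction and calibration/test splitting


def restrict_to_regions(s: SpectraSet, r: WavelengthRegions) -> SpectraSet:
    """Keep only grid points lying inside any region (closed intervals)."""
    mask = r.mask(s.wavelengths_nm)
    if not mask.any():
        raise ValueError("regions do not intersect the wavelength grid")
    return s.with_absorbance(s.absorbance[:, mask], s.wavelengths_nm[mask])


def make_split(
    s: SpectraSet,
    plan: str = "random_fraction",
    *,
    n_calibration: int = None,
    n_test_per_origin: int = None,
    seed: int = 0,
) -> SplitPlan:
    """Partition samples into calibration and test sets.

    ``random_fraction`` draws ``n_calibration`` samples uniformly without
    replacement; ``per_origin_count`` reserves exactly ``n_test_per_origin``
    test samples from every origin.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(s.sample_ids)
    if plan == "random_fraction":
        if n_calibration is None or not (0 < n_calibration < s.n_samples):
            raise ValueError("n_calibration must be in (0, n_samples)")
        cal = rng.choice(s.n_samples, size=n_calibration, replace=False)
        cal_mask = np.zeros(s.n_samples, dtype=bool)
        cal_mask[cal] = True
        return SplitPlan(tuple(ids[cal_mask]), tuple(ids[~cal_mask]), seed)
    if plan == "per_origin_count":
        if s.origin is None:
            raise ValueError("per-origin split requires origin labels")
        k = n_test_per_origin
        if k is None or k < 1:
            raise ValueError("n_test_per_origin must be >= 1")
        origins = np.array(s.origin)
        test_idx = []
        for o in sorted(set(origins)):
            members = np.flatnonzero(origins == o)
            if k >= members.size:
                raise ValueError(
                    f"origin {o!r} has only {members.size} samples; "
                    f"cannot reserve {k} for the test set"
                )
            test_idx.extend(rng.choice(members, size=k, replace=False))
        test_mask = np.zeros(s.n_samples, dtype=bool)
        test_mask[test_idx] = True
        return SplitPlan(tuple(ids[~test_mask]), tuple(ids[test_mask]), seed)
    raise ValueError(f"unknown split plan {plan!r}")
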