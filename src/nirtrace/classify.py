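"""Two-step class-modeling classifier for geographic origin of NIR spectra.

Step I is a coarse class model: PCA scores of the preprocessed calibration
spectra (PC1 excluded by default — it carries the bulk chemical signal, e.g.
fat content, rather than between-origin differences) with per-class
Mahalanobis distance.  Step II is a fine class model on different wavelength
regions and preprocessing: each spectrum is min–max anchored on the first
selected wavelength region ("scaling to the first range") and compared to
class mean spectra by Euclidean distance.

Every class carries an acceptance threshold computed from the distances of
its own calibration samples to the class centre (the "Hit" distribution):

    D_T = max(Hit) + Q * sd(Hit),      Q = 0.25 by default.

Separation of two classes is summarised by the selectivity statistic

    S = D / (D_T1 + D_T2),

where D is the distance between the class centres: S > 1 means fully
separated, S = 1 in contact, S < 1 overlapping.  Classes connected by S < 1
form ambiguity groups; samples assigned to such classes by Step I (or
falling outside every class threshold) are routed to a Step II model fitted
on the group's calibration samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import preset
from .spectra import SpectraSet, WavelengthRegions, restrict_to_regions

__all__ = [
    "PCASubspace",
    "ClassModel",
    "ClassModelSet",
    "SelectivityReport",
    "StepConfig",
    "TwoStepResult",
    "DEFAULT_STEP1_REGIONS",
    "DEFAULT_STEP2_REGIONS",
    "fit_pca",
    "hit_threshold",
    "mahalanobis_distance",
    "scale_to_first_range",
    "fit_class_models",
    "selectivity",
    "classify",
    "run_two_step",
]


def _coalesce(intervals):
    """Merge touching/overlapping closed intervals."""
    out = []
    for lo, hi in sorted((float(a), float(b)) for a, b in intervals):
        if out and lo <= out[-1][1]:
            out[-1][1] = max(out[-1][1], hi)
        else:
            out.append([lo, hi])
    return WavelengthRegions([tuple(r) for r in out])


# Built-in wavelength region sets for the two classification stages, from the
# standard NIR band assignments of the fat-sensitive functional groups (C-H
# second overtones near 1150-1250 nm, C-H combination/first overtones at
# 1280-1420 and 1620-1770 nm, O-H ~1450-1475 nm, N-H ~1530-1620 nm).  The
# Step II set trades the broad N-H stretch at 1568-1602 nm for the adjacent
# 1604-1622 nm band the Step I set does not cover.
DEFAULT_STEP1_REGIONS = _coalesce([
    (1145, 1208), (1210, 1223), (1225, 1246), (1287, 1295), (1300, 1310),
    (1321, 1346), (1352, 1364), (1368, 1378), (1381, 1385), (1391, 1393),
    (1394, 1400), (1402, 1410), (1420, 1422), (1452, 1455), (1458, 1462),
    (1464, 1473), (1532, 1538), (1540, 1566), (1568, 1602), (1624, 1645),
    (1648, 1651), (1654, 1660), (1665, 1670), (1674, 1680), (1688, 1690),
    (1698, 1700), (1712, 1734), (1740, 1750), (1750, 1758), (1760, 1770),
])

DEFAULT_STEP2_REGIONS = _coalesce([
    (1210, 1223), (1300, 1310), (1321, 1346), (1381, 1385), (1386, 1390),
    (1394, 1400), (1402, 1410), (1412, 1418), (1450, 1452), (1452, 1455),
    (1458, 1462), (1464, 1473), (1532, 1538), (1540, 1566), (1604, 1622),
    (1624, 1645), (1648, 1651), (1654, 1660), (1665, 1670), (1674, 1680),
    (1688, 1690), (1698, 1700), (1712, 1734), (1734, 1738), (1750, 1758),
])


# ---------------------------------------------------------------------------
# PCA subspace


@dataclass(frozen=True)
class PCASubspace:
    """Mean-centred PCA with a deterministic sign convention (the
    largest-magnitude element of each loading is positive)."""

    mean: np.ndarray
    loadings: np.ndarray                 # (k, n), orthonormal rows
    explained_variance_ratio: np.ndarray  # fraction of total variance, per PC
    used_components: tuple               # zero-based PC indices used as scores

    def scores(self, absorbance: np.ndarray) -> np.ndarray:
        """Scores on the used components only."""
        t = (np.atleast_2d(absorbance) - self.mean) @ self.loadings.T
        return t[:, list(self.used_components)]


def fit_pca(X: SpectraSet, used_components: Sequence[int] = (1, 2, 3)) -> PCASubspace:
    """Fit PCA on a calibration set.

    ``used_components`` are zero-based: the default ``(1, 2, 3)`` keeps
    PC2-PC4 and drops PC1.
    """
    used = tuple(int(c) for c in used_components)
    if not used:
        raise ValueError("need at least one retained component")
    A = X.absorbance
    m, n = A.shape
    k_max = min(m - 1, n)
    if max(used) >= k_max:
        raise ValueError(
            f"component index {max(used)} not available with {m} samples"
        )
    mean = A.mean(axis=0)
    U, s, Vt = np.linalg.svd(A - mean, full_matrices=False)
    k = max(used) + 1
    V = Vt[:k]
    # sign convention: largest-|loading| element positive
    for i in range(k):
        j = np.argmax(np.abs(V[i]))
        if V[i, j] < 0:
            V[i] = -V[i]
    var = s**2
    ratio = (var / var.sum())[:k]
    return PCASubspace(mean, V, ratio, used)


# ---------------------------------------------------------------------------
# class models


@dataclass(frozen=True)
class ClassModel:
    """Per-origin reference model with its acceptance threshold."""

    label: str
    centre: np.ndarray
    hits: np.ndarray          # calibration distances to the centre
    d_threshold: float        # D_T = max(Hit) + q * sd(Hit)
    q: float
    metric: str               # "mahalanobis" | "euclidean"
    covariance: Optional[np.ndarray] = None
    _cov_inv: Optional[np.ndarray] = field(default=None, repr=False)


def hit_threshold(hits, q: float = 0.25) -> float:
    """Class acceptance threshold D_T = max(Hit) + Q * sd(Hit), with the
    sample (n-1) standard deviation of the calibration Hit distances."""
    hits = np.asarray(hits, float)
    if hits.size == 0 or np.any(hits < 0):
        raise ValueError("hits must be a nonempty vector of nonnegative distances")
    sd = hits.std(ddof=1) if hits.size > 1 else 0.0
    return float(hits.max() + q * sd)


def mahalanobis_distance(score: np.ndarray, model: ClassModel) -> float:
    """Covariance-weighted distance of a score vector from the class centre."""
    if model.covariance is None:
        raise ValueError("model has no covariance; not a Mahalanobis class model")
    d = np.atleast_2d(score) - model.centre
    if d.shape[1] != model.centre.size:
        raise ValueError("score dimension does not match the class model")
    cov_inv = model._cov_inv
    if cov_inv is None:
        cov_inv = np.linalg.inv(model.covariance)
    out = np.sqrt(np.einsum("ij,jk,ik->i", d, cov_inv, d))
    return float(out[0]) if np.ndim(score) == 1 else out


def _regularized_cov(scores: np.ndarray, shrinkage: float) -> np.ndarray:
    """Sample covariance shrunk toward its own diagonal:
    (1 - lambda) * S + lambda * diag(S)."""
    S = np.cov(scores, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    out = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
    if np.linalg.matrix_rank(out) < out.shape[0]:
        raise np.linalg.LinAlgError(
            "singular class covariance; increase the shrinkage parameter"
        )
    return out


def scale_to_first_range(x, wavelengths_nm, regions: WavelengthRegions):
    """Min–max anchor a spectrum (or matrix of spectra) on the first region.

    The whole spectrum is transformed as (x - min_R1) / (max_R1 - min_R1),
    where the min/max are taken over the grid points of the first
    (lowest-wavelength) region, which therefore maps onto [0, 1].
    """
    wl = np.asarray(wavelengths_nm, float)
    first_mask = ((wl >= regions.first[0]) & (wl <= regions.first[1]))
    if first_mask.sum() < 2:
        raise ValueError("first region must contain at least two grid points")
    ab = np.atleast_2d(np.asarray(x, float))
    sub = ab[:, first_mask]
    lo = sub.min(axis=1, keepdims=True)
    hi = sub.max(axis=1, keepdims=True)
    if np.any(hi - lo <= 0):
        raise ValueError("spectrum is flat over the first region; cannot scale")
    out = (ab - lo) / (hi - lo)
    return out[0] if np.ndim(x) == 1 else out


@dataclass(frozen=True)
class ClassModelSet:
    """The fitted per-class models plus the shared space they live in."""

    models: tuple
    method: str                       # "pca_md" | "first_range"
    regions: WavelengthRegions
    pca: Optional[PCASubspace] = None

    def __iter__(self):
        return iter(self.models)

    def __len__(self):
        return len(self.models)

    @property
    def labels(self):
        return [m.label for m in self.models]

    def _embed(self, s: SpectraSet) -> np.ndarray:
        sub = restrict_to_regions(s, self.regions)
        if self.method == "pca_md":
            return self.pca.scores(sub.absorbance)
        return scale_to_first_range(sub.absorbance, sub.wavelengths_nm, self.regions)

    def distances(self, s: SpectraSet) -> np.ndarray:
        """(m_samples, n_classes) distance matrix in the model metric."""
        E = self._embed(s)
        cols = []
        for mod in self.models:
            if self.method == "pca_md":
                cols.append(mahalanobis_distance(E, mod))
            else:
                cols.append(np.linalg.norm(E - mod.centre, axis=1))
        return np.column_stack(cols)


def fit_class_models(
    X: SpectraSet,
    regions: WavelengthRegions,
    method: str = "pca_md",
    q: float = 0.25,
    pca: Optional[PCASubspace] = None,
    used_components: Sequence[int] = (1, 2, 3),
    shrinkage: float = 0.1,
) -> ClassModelSet:
    """Fit one class model per origin on a preprocessed calibration set.

    ``pca_md``: class centres and covariances of PCA scores (PCA fitted here
    on the region-restricted data unless supplied), Mahalanobis hits.
    ``first_range``: class mean of range-scaled region-restricted spectra,
    Euclidean hits.
    """
    if X.origin is None:
        raise ValueError("calibration set must carry origin labels")
    if method not in ("pca_md", "first_range"):
        raise ValueError(f"unknown class-model method {method!r}")
    sub = restrict_to_regions(X, regions)
    origins = np.asarray(X.origin)
    labels = sorted(set(X.origin))
    for o in labels:
        if (origins == o).sum() < 2:
            raise ValueError(f"origin {o!r} has fewer than 2 calibration samples")
    if method == "pca_md":
        if pca is None:
            pca = fit_pca(sub, used_components)
        E = pca.scores(sub.absorbance)
    else:
        E = scale_to_first_range(sub.absorbance, sub.wavelengths_nm, regions)
    models = []
    for o in labels:
        Eo = E[origins == o]
        centre = Eo.mean(axis=0)
        # Hits are jackknifed: each calibration sample's distance is taken to
        # a centre (and covariance) estimated without it.  In-sample
        # Mahalanobis distances are systematically deflated for small
        # classes, which would make D_T reject far too many genuine unknowns.
        n_o = Eo.shape[0]
        keep = ~np.eye(n_o, dtype=bool)
        if method == "pca_md":
            cov = _regularized_cov(Eo, shrinkage)
            cov_inv = np.linalg.inv(cov)
            hits = np.empty(n_o)
            for i in range(n_o):
                Ei = Eo[keep[i]]
                ci = Ei.mean(axis=0)
                cov_i = (_regularized_cov(Ei, shrinkage)
                         if n_o > Eo.shape[1] + 1 else cov)
                d = Eo[i] - ci
                hits[i] = np.sqrt(d @ np.linalg.solve(cov_i, d))
            models.append(ClassModel(o, centre, hits, hit_threshold(hits, q), q,
                                     "mahalanobis", cov, cov_inv))
        else:
            hits = np.array([
                np.linalg.norm(Eo[i] - Eo[keep[i]].mean(axis=0))
                for i in range(n_o)
            ])
            models.append(ClassModel(o, centre, hits, hit_threshold(hits, q), q,
                                     "euclidean"))
    return ClassModelSet(tuple(models), method, regions, pca)


# ---------------------------------------------------------------------------
# selectivity


@dataclass(frozen=True)
class SelectivityReport:
    """Pairwise separation of the fitted classes."""

    labels: tuple
    pairwise_D: np.ndarray
    pairwise_S: np.ndarray
    nearest_class: dict        # label -> (nearest label, S)
    ambiguous_groups: tuple    # frozensets of labels connected by S < 1
    step: str = ""

    def table(self) -> pd.DataFrame:
        """Per-class nearest neighbour and its S (minimum-S table)."""
        rows = [
            {"group": a, "nearest": b, "S": s}
            for a, (b, s) in self.nearest_class.items()
        ]
        return pd.DataFrame(rows)

    def group_of(self, label) -> Optional[frozenset]:
        for g in self.ambiguous_groups:
            if label in g:
                return g
        return None


def _pair_distance(a: ClassModel, b: ClassModel) -> float:
    diff = a.centre - b.centre
    if a.metric != b.metric:
        raise ValueError("class models use different metrics")
    if a.metric == "mahalanobis":
        pooled = 0.5 * (a.covariance + b.covariance)
        return float(np.sqrt(diff @ np.linalg.solve(pooled, diff)))
    return float(np.linalg.norm(diff))


def selectivity(model_set, step: str = "") -> SelectivityReport:
    """Pairwise centre distances D and selectivity S = D / (D_T1 + D_T2);
    ambiguity groups are the connected components of the S < 1 graph.

    Mahalanobis centre-to-centre distances use the average of the two class
    covariances, which keeps D (and hence S) exactly symmetric.
    """
    models = list(model_set)
    k = len(models)
    if k < 2:
        raise ValueError("selectivity needs at least two class models")
    labels = tuple(m.label for m in models)
    D = np.zeros((k, k))
    S = np.full((k, k), np.inf)
    parent = list(range(k))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            d = _pair_distance(models[i], models[j])
            s = d / (models[i].d_threshold + models[j].d_threshold)
            D[i, j] = D[j, i] = d
            S[i, j] = S[j, i] = s
            if s < 1.0:
                parent[find(i)] = find(j)
    nearest = {}
    for i in range(k):
        j = int(np.argmin(S[i]))
        nearest[labels[i]] = (labels[j], float(S[i, j]))
    comps: Dict[int, set] = {}
    for i in range(k):
        comps.setdefault(find(i), set()).add(labels[i])
    groups = tuple(frozenset(g) for g in comps.values() if len(g) > 1)
    return SelectivityReport(labels, D, S, nearest, groups, step)


# ---------------------------------------------------------------------------
# classification


def classify(
    s: SpectraSet,
    model_set: ClassModelSet,
    report: Optional[SelectivityReport] = None,
) -> pd.DataFrame:
    """Assign each (already preprocessed) spectrum to its nearest class.

    Columns: assigned (nearest class), distance (to it), within_threshold
    (distance <= that class's D_T), unknown (the distance to every class
    exceeds that class's threshold) and ambiguous (the assigned class
    belongs to an S < 1 group of ``report``).
    """
    dist = model_set.distances(s)
    labels = np.array(model_set.labels)
    thresholds = np.array([m.d_threshold for m in model_set])
    best = np.argmin(dist, axis=1)
    d_best = dist[np.arange(dist.shape[0]), best]
    unknown = np.all(dist > thresholds[None, :], axis=1)
    assigned = labels[best]
    ambiguous = np.zeros(len(assigned), dtype=bool)
    if report is not None and report.ambiguous_groups:
        in_group = {l for g in report.ambiguous_groups for l in g}
        ambiguous = np.array([a in in_group for a in assigned])
    return pd.DataFrame(
        {
            "id": list(s.sample_ids),
            "assigned": assigned,
            "distance": d_best,
            "within_threshold": d_best <= thresholds[best],
            "unknown": unknown,
            "ambiguous": ambiguous,
        }
    )


@dataclass(frozen=True)
class StepConfig:
    """Preprocessing, wavelength regions and class-model method of one step."""

    preprocess: str
    regions: WavelengthRegions
    method: str
    used_components: tuple = (1, 2, 3)
    shrinkage: float = 0.1


def default_step1() -> StepConfig:
    return StepConfig("SG17-SD", DEFAULT_STEP1_REGIONS, "pca_md")


def default_step2() -> StepConfig:
    return StepConfig("SD+VN", DEFAULT_STEP2_REGIONS, "first_range")


@dataclass(frozen=True)
class TwoStepResult:
    assignments: pd.DataFrame       # per sample: truth, step I, routing, final
    report_step1: SelectivityReport
    reports_step2: dict             # frozenset group -> SelectivityReport
    confusion: dict                 # {"calibration": DataFrame, "test": DataFrame}
    correct_rate: dict              # {"calibration": fraction, "test": fraction}
    step1_models: ClassModelSet
    step2_models: dict              # frozenset group -> ClassModelSet


def _route_group(assigned, groups):
    for g in groups:
        if assigned in g:
            return g
    return groups[0] if len(groups) == 1 else None


def run_two_step(
    cal: SpectraSet,
    test: Optional[SpectraSet] = None,
    step1: Optional[StepConfig] = None,
    step2: Optional[StepConfig] = None,
    q: float = 0.25,
) -> TwoStepResult:
    """Fit the tandem classifier on ``cal`` and classify ``cal`` (and
    optionally ``test``).

    Step I models are fitted on all calibration origins.  Samples whose
    Step I assignment lands in an S < 1 ambiguity group — or that fall
    outside every class threshold — are re-classified by a Step II model
    fitted on the calibration samples of that group's classes only.
    """
    if step1 is None:
        step1 = default_step1()
    if step2 is None:
        step2 = default_step2()
    if cal.origin is None:
        raise ValueError("calibration set must carry origin labels")

    pp1 = preset(step1.preprocess).fit(cal)
    cal1 = pp1.apply(cal)
    set1 = fit_class_models(
        cal1, step1.regions, step1.method, q,
        used_components=step1.used_components, shrinkage=step1.shrinkage,
    )
    report1 = selectivity(set1, step="I") if len(set1) > 1 else None
    groups = report1.ambiguous_groups if report1 else ()

    # Step II models, one per ambiguity group, on that group's cal samples
    set2, report2, pp2 = {}, {}, {}
    for g in groups:
        members = [i for i, o in enumerate(cal.origin) if o in g]
        sub = cal.select_samples([cal.sample_ids[i] for i in members])
        pp = preset(step2.preprocess).fit(sub)
        sub2 = pp.apply(sub)
        ms = fit_class_models(
            sub2, step2.regions, step2.method, q,
            used_components=step1.used_components, shrinkage=step1.shrinkage,
        )
        set2[g] = ms
        pp2[g] = pp
        report2[g] = selectivity(ms, step="II") if len(ms) > 1 else None

    def _classify_set(s: SpectraSet, role: str) -> pd.DataFrame:
        res1 = classify(pp1.apply(s), set1, report1)
        final = res1.assigned.to_numpy(dtype=object).copy()
        routed = (res1.ambiguous | res1.unknown).to_numpy()
        step2_assigned = np.full(len(final), "", dtype=object)
        for g in groups:
            rows = np.flatnonzero(
                routed & np.array([_route_group(a, groups) == g
                                   for a in res1.assigned])
            )
            if rows.size == 0:
                continue
            sub = s.select_samples([s.sample_ids[i] for i in rows])
            res2 = classify(pp2[g].apply(sub), set2[g], report2[g])
            lab = res2.assigned.to_numpy(dtype=object)
            lab[res2.unknown.to_numpy()] = "unknown"
            step2_assigned[rows] = lab
            final[rows] = lab
        # out-of-threshold samples that no Step II group re-classified
        unresolved = res1.unknown.to_numpy() & (step2_assigned == "")
        final[unresolved] = "unknown"
        truth = np.array(s.origin) if s.origin is not None else np.full(len(final), "")
        return pd.DataFrame(
            {
                "id": list(s.sample_ids),
                "set": role,
                "origin": truth,
                "step1_assigned": res1.assigned,
                "step1_distance": res1.distance,
                "routed": routed,
                "step2_assigned": step2_assigned,
                "final": final,
                "correct": final == truth,
            }
        )

    frames = [_classify_set(cal, "calibration")]
    if test is not None:
        frames.append(_classify_set(test, "test"))
    assignments = pd.concat(frames, ignore_index=True)

    confusion, rates = {}, {}
    for role, df in assignments.groupby("set"):
        confusion[role] = pd.crosstab(df.origin, df.final)
        rates[role] = float(df.correct.mean())
    return TwoStepResult(
        assignments, report1, report2, confusion, rates, set1, set2
    )
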