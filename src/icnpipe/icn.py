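"""Group spatial ICA, subject-specific component back-reconstruction,
template matching and voxelwise Fisher-z connectivity maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from icnpipe.errors import InvalidConfigurationError, InvalidInputError
from icnpipe.preprocess import Scan
from icnpipe.synthgen import ComponentAtlas

__all__ = [
    "GroupICAResult",
    "SubjectICN",
    "FCMap",
    "group_ica",
    "subject_icns",
    "match_templates",
    "fc_map",
]

# E[log cosh(nu)] for nu ~ N(0,1); baseline of the negentropy surrogate.
_GAUSS_LOGCOSH = 0.3745672966


@dataclass
class GroupICAResult:
    maps: np.ndarray  # (K, n_voxels), z-scored, skewness-positive
    k: int
    variance_retained: float
    seed: int
    grid_shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]


@dataclass
class SubjectICN:
    subject_id: str
    session: str
    maps: np.ndarray  # (K, n_voxels)
    timecourses: np.ndarray  # (K, n_volumes)
    mode: str  # "dual_regression" | "guided"


@dataclass
class FCMap:
    subject_id: str
    session: str
    component: int
    z_values: np.ndarray  # (n_voxels,)


def _centered_timeseries(scan: Scan) -> np.ndarray:
    ts = scan.timeseries()  # (T, V)
    return ts - ts.mean(axis=0, keepdims=True)


def _subject_pca(ts: np.ndarray, r: int) -> np.ndarray:
    """Reduce (T, V) data to its top-r temporal modes, returned as (r, V)."""
    cov = ts @ ts.T
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:r]
    return evecs[:, order].T @ ts


def group_ica(scans: list[Scan], k: int = 20, seed: int = 0) -> GroupICAResult:
    """Temporal-concatenation group PCA followed by fixed-point spatial ICA.

    Each scan is voxelwise demeaned and reduced to ``2k`` temporal modes, the
    reductions are stacked and reduced again to ``k`` modes, and a logcosh
    FastICA with symmetric decorrelation unmixes the spatial sources. Maps
    are z-scored, sign-fixed to non-negative skewness, and ordered by
    descending explained variance. Non-convergence restarts with ``seed + 1``
    (up to 5 restarts).
    """
    if len(scans) < 2:
        raise InvalidInputError(f"group ICA needs >= 2 scans; got {len(scans)}")
    grid_shape = scans[0].grid_shape
    for s in scans:
        if s.grid_shape != grid_shape:
            raise InvalidInputError("all scans must share one voxel grid")
    r1 = min(2 * k, min(s.n_volumes for s in scans))
    reduced = np.vstack([_subject_pca(_centered_timeseries(s), r1) for s in scans])
    if k > min(reduced.shape):
        raise InvalidConfigurationError(
            f"k={k} exceeds the rank of the concatenated data ({min(reduced.shape)})"
        )
    cov = reduced @ reduced.T
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[k - 1] <= 1e-12 * evals[0]:
        raise InvalidConfigurationError(f"concatenated data has rank < k={k}")
    variance_retained = float(evals[:k].sum() / evals.sum())
    nvox = reduced.shape[1]
    whitened = (evecs[:, :k] * evals[:k] ** -0.5).T @ reduced * np.sqrt(nvox)

    sources = None
    for attempt in range(6):
        ica = FastICA(
            n_components=k,
            whiten=False,
            algorithm="parallel",
            fun="logcosh",
            tol=1e-6,
            max_iter=500,
            random_state=seed + attempt,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            s_try = ica.fit_transform(whitened.T)  # (V, k)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            sources = s_try
            break
        sources = s_try  # keep last attempt as fallback
    maps = sources.T

    # z-score, fix sign by skewness, order by explained variance
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    skew = sstats.skew(maps, axis=1)
    maps *= np.where(skew < 0, -1.0, 1.0)[:, None]
    proj = reduced @ maps.T  # (rows, k)
    explained = (proj**2).sum(axis=0)
    maps = maps[np.argsort(explained)[::-1]]
    return GroupICAResult(
        maps=maps,
        k=k,
        variance_retained=variance_retained,
        seed=seed,
        grid_shape=grid_shape,
    )


def _standardize(y: np.ndarray) -> np.ndarray:
    y = y - y.mean()
    sd = y.std()
    if sd == 0:
        raise InvalidInputError("degenerate (constant) map")
    return y / sd


def _negentropy(y: np.ndarray) -> float:
    return float((np.mean(np.log(np.cosh(y))) - _GAUSS_LOGCOSH) ** 2)


def _project_to_corr(y: np.ndarray, g: np.ndarray, tau: float) -> np.ndarray:
    """Blend y toward g until corr(blend, g) >= tau (both standardized)."""
    if float(np.corrcoef(y, g)[0, 1]) >= tau:
        return y
    lo, hi = 0.0, 1.0  # alpha: weight on y; alpha=0 gives g itself
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        cand = _standardize(mid * y + (1 - mid) * g)
        if float(np.corrcoef(cand, g)[0, 1]) >= tau:
            lo = mid
        else:
            hi = mid
    return _standardize(lo * y + (1 - lo) * g)


def _guided_refine(
    y0: np.ndarray, g: np.ndarray, tau: float = 0.7, max_iter: int = 100, tol: float = 1e-5
) -> np.ndarray:
    """Negentropy ascent on a standardized map subject to corr with the group
    map >= tau. Never returns a map with lower negentropy than the start."""
    g = _standardize(g)
    y = _project_to_corr(_standardize(y0), g, tau)
    best, best_j = y, _negentropy(y)
    eta = 0.1
    for _ in range(max_iter):
        drift = np.sign(np.mean(np.log(np.cosh(best))) - _GAUSS_LOGCOSH) or 1.0
        cand = _standardize(best + eta * drift * np.tanh(best))
        cand = _project_to_corr(cand, g, tau)
        j = _negentropy(cand)
        if j > best_j + tol:
            best, best_j = cand, j
        else:
            eta *= 0.5
            if eta < 1e-6:
                break
    return best


def subject_icns(
    scan: Scan, group: GroupICAResult, mode: str = "dual_regression"
) -> SubjectICN:
    """Back-reconstruct subject-specific maps and time courses.

    ``dual_regression``: two-stage least squares against the group maps.
    ``guided``: dual-regression initialization refined by constrained
    negentropy ascent (spatial correlation with the group map kept >= 0.7).
    """
    if mode not in ("dual_regression", "guided"):
        raise InvalidConfigurationError(f"unknown mode {mode!r}")
    if scan.grid_shape != group.grid_shape:
        raise InvalidInputError(
            f"scan grid {scan.grid_shape} != group grid {group.grid_shape}"
        )
    y = _centered_timeseries(scan)  # (T, V)
    g = group.maps  # (K, V)
    tc, *_ = np.linalg.lstsq(g.T, y.T, rcond=None)  # (K, T)
    maps, *_ = np.linalg.lstsq(tc.T, y, rcond=None)  # (K, V)
    if mode == "guided":
        refined = np.empty_like(maps)
        for c in range(group.k):
            refined[c] = _guided_refine(maps[c], g[c])
        maps = refined
        tc, *_ = np.linalg.lstsq(maps.T, y.T, rcond=None)
    return SubjectICN(
        subject_id=scan.subject_id,
        session=scan.session,
        maps=maps,
        timecourses=tc,
        mode=mode,
    )


def match_templates(
    group: GroupICAResult, templates: ComponentAtlas, threshold: float = 0.3
) -> dict[int, str]:
    """Greedy one-to-one assignment of group components to template labels by
    descending absolute spatial correlation; sub-threshold components are
    labeled ``"unmatched"``."""
    if templates.k == 0:
        raise InvalidInputError("empty template set")
    if templates.n_voxels != group.n_voxels:
        raise InvalidInputError("templates and group maps are on different grids")
    corr = np.zeros((group.k, templates.k))
    for i in range(group.k):
        for j in range(templates.k):
            corr[i, j] = np.corrcoef(group.maps[i], templates.maps[j])[0, 1]
    labels = {i: "unmatched" for i in range(group.k)}
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = sorted(
        ((abs(corr[i, j]), i, j) for i in range(group.k) for j in range(templates.k)),
        reverse=True,
    )
    for r, i, j in pairs:
        if r < threshold:
            break
        if i in used_i or j in used_j:
            continue
        labels[i] = templates.labels[j]
        used_i.add(i)
        used_j.add(j)
    return labels


def fc_map(scan: Scan, timecourse: np.ndarray, clip: float = 1e-7) -> FCMap:
    """Voxelwise Pearson correlation with a component time course, Fisher
    z-transformed with |r| clipped to 1 - ``clip``."""
    tc = np.asarray(timecourse, dtype=np.float64).ravel()
    ts = scan.timeseries()  # (T, V)
    if len(tc) != ts.shape[0]:
        raise InvalidInputError(
            f"time course length {len(tc)} != scan volumes {ts.shape[0]}"
        )
    tc_sd = tc.std()
    if tc_sd == 0:
        raise InvalidInputError("zero-variance time course")
    tc_c = (tc - tc.mean()) / tc_sd
    y = ts - ts.mean(axis=0, keepdims=True)
    sd = y.std(axis=0)
    safe = sd > 0
    r = np.zeros(ts.shape[1])
    r[safe] = (tc_c @ y[:, safe]) / (len(tc) * sd[safe])
    r = np.clip(r, -1 + clip, 1 - clip)
    return FCMap(
        subject_id=scan.subject_id,
        session=scan.session,
        component=-1,
        z_values=np.arctanh(r),
    )
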