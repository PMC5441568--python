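"""Nested leave-one-out SVM ensemble over subject-specific component maps.

Outer LOO leaves one subject out for testing; within each outer fold a
forward component-selection (seeded with the a-priori anchor components,
grid-searching SVM parameters inside every evaluation) picks the most
discriminative component set by inner-LOO accuracy, and one base classifier
is fitted per inner leave-one-out training subset. Each base classifier
emits a signed probability score (s = 2p - 1, positive = patient); the
median of the base scores is the subject's aggregated score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from icnpipe.errors import InvalidInputError, UndefinedMetricError
from icnpipe.icn import SubjectICN

__all__ = [
    "SVMParams",
    "default_grid",
    "FeatureSet",
    "build_features",
    "BaseClassifier",
    "FoldModel",
    "EnsembleResult",
    "Metrics",
    "forward_select",
    "classification_score",
    "loo_ensemble",
    "evaluate",
    "score_followup",
]

PATIENT, CONTROL = 1, 0
_MAX_PCA_DIM = 50


@dataclass(frozen=True)
class SVMParams:
    kernel: str  # "linear" | "rbf"
    C: float
    gamma_scale: float | None = None  # rbf gamma = gamma_scale / n_features

    def __str__(self) -> str:
        if self.kernel == "linear":
            return f"linear(C={self.C})"
        return f"rbf(C={self.C}, gamma={self.gamma_scale}/d)"


def default_grid() -> list[SVMParams]:
    """C in {0.01, 0.1, 1, 10, 100}; linear and RBF with gamma in {1/d, 10/d}."""
    grid = []
    for c in (0.01, 0.1, 1.0, 10.0, 100.0):
        grid.append(SVMParams("linear", c))
        grid.append(SVMParams("rbf", c, 1.0))
        grid.append(SVMParams("rbf", c, 10.0))
    return grid


@dataclass
class FeatureSet:
    """Per subject/session, one z-scored flattened spatial map per component."""

    data: np.ndarray  # (n_subjects, K, n_features)
    component_labels: list[str]
    subject_ids: list[str]
    sessions: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise InvalidInputError(
                f"feature data must be (subjects, components, voxels); "
                f"got shape {self.data.shape}"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1]

    def rows_for(self, subject_ids) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            return np.array([index[s] for s in subject_ids])
        except KeyError as exc:
            raise InvalidInputError(f"unknown subject {exc.args[0]!r}") from exc


def build_features(
    icns: list[SubjectICN], mask: np.ndarray | None = None
) -> FeatureSet:
    """Stack z-scored (optionally masked) subject maps into a FeatureSet."""
    if not icns:
        raise InvalidInputError("no subject ICNs given")
    k = icns[0].maps.shape[0]
    rows = []
    for icn in icns:
        m = icn.maps[:, mask] if mask is not None else icn.maps
        sd = m.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        rows.append((m - m.mean(axis=1, keepdims=True)) / sd)
    data = np.stack(rows)
    if data.shape[1] != k:
        raise InvalidInputError("inconsistent component counts across subjects")
    return FeatureSet(
        data=data,
        component_labels=[f"IC{c}" for c in range(k)],
        subject_ids=[i.subject_id for i in icns],
        sessions=[i.session for i in icns],
    )


def as_binary_labels(labels) -> np.ndarray:
    """Map labels to {1: patient, 0: control}. Accepts ints or strings."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "iufb":
        out = arr.astype(int)
        if not set(np.unique(out)) <= {0, 1}:
            raise InvalidInputError(f"numeric labels must be 0/1; got {np.unique(out)}")
        return out
    mapping = {"patient": PATIENT, "control": CONTROL}
    try:
        return np.array([mapping[str(v)] for v in arr])
    except KeyError as exc:
        raise InvalidInputError(f"unknown label {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# fold-local feature space: per-component PCA fitted on training rows only


class _FoldSpace:
    """Per-component PCA (fit on the training rows) plus cached per-component
    linear Gram matrices over all rows, so any candidate component set's
    kernel is a cheap sum."""

    def __init__(self, features: FeatureSet, train_rows: np.ndarray, max_dim: int = _MAX_PCA_DIM):
        X = features.data  # (n, K, V)
        n, K, V = X.shape
        self.train_rows = np.asarray(train_rows)
        d = int(min(len(self.train_rows) - 1, max_dim, V))
        if d < 1:
            raise InvalidInputError("not enough training rows for PCA")
        self.d = d
        self.means = np.empty((K, V))
        self.bases = np.empty((K, V, d))
        self.F = np.empty((K, n, d))
        for c in range(K):
            tr = X[self.train_rows, c]  # (n_tr, V)
            mu = tr.mean(axis=0)
            Yc = tr - mu
            # PCA via the small Gram matrix
            gram = Yc @ Yc.T
            evals, evecs = np.linalg.eigh(gram)
            order = np.argsort(evals)[::-1][:d]
            evals = np.clip(evals[order], 1e-12, None)
            basis = (Yc.T @ evecs[:, order]) / np.sqrt(evals)  # (V, d), orthonormal
            self.means[c] = mu
            F = (X[:, c] - mu) @ basis
            # unit mean squared norm over training rows: keeps kernel entries
            # O(1) so libsvm converges in tens of iterations, and makes C
            # comparable across component-set sizes
            scale = max(np.sqrt((F[self.train_rows] ** 2).sum(axis=1).mean()), 1e-12)
            self.bases[c] = basis / scale
            # recomputed through the same arithmetic as transform(), so
            # in-sample rows and external copies of them project identically
            self.F[c] = (X[:, c] - mu) @ self.bases[c]
        self.G = np.einsum("cnd,cmd->cnm", self.F, self.F)  # (K, n, n)
        self.sq = np.einsum("cnd,cnd->cn", self.F, self.F)  # (K, n)

    def transform(self, maps: np.ndarray) -> np.ndarray:
        """Project external z-scored maps (m, K, V) into the space: (K, m, d)."""
        m = np.asarray(maps, dtype=np.float64)
        if m.ndim == 2:
            m = m[None]
        if m.shape[1:] != self.means.shape:
            raise InvalidInputError(
                f"external maps shape {m.shape[1:]} != expected {self.means.shape}"
            )
        return np.einsum("mcv,cvd->cmd", m - self.means[None], self.bases)

    def kernel_matrix(self, comps, params: SVMParams) -> np.ndarray:
        """Full (n, n) kernel over all rows for the given component set."""
        comps = list(comps)
        G = self.G[comps].sum(axis=0)
        if params.kernel == "linear":
            return G
        sq = self.sq[comps].sum(axis=0)
        dist = np.maximum(sq[:, None] + sq[None, :] - 2 * G, 0.0)
        gamma = params.gamma_scale / (2.0 * len(comps))
        return np.exp(-gamma * dist)

    def kernel_cross(self, comps, params: SVMParams, ext_F: np.ndarray) -> np.ndarray:
        """(m, n) kernel between external samples and all rows."""
        comps = list(comps)
        G = np.einsum("cmd,cnd->mn", ext_F[comps], self.F[comps])
        if params.kernel == "linear":
            return G
        sq_ext = np.einsum("cmd,cmd->m", ext_F[comps], ext_F[comps])
        sq = self.sq[comps].sum(axis=0)
        dist = np.maximum(sq_ext[:, None] + sq[None, :] - 2 * G, 0.0)
        gamma = params.gamma_scale / (2.0 * len(comps))
        return np.exp(-gamma * dist)


# ---------------------------------------------------------------------------
# SVM plumbing

# libsvm called through its cython binding for the hot inner loops: at these
# problem sizes the SVC wrapper spends ~95% of its time in validation, not in
# the solver. Falls back to the public SVC when the binding is unavailable;
# decisions are identical either way.
try:  # pragma: no cover - exercised implicitly
    from sklearn.svm import _libsvm as _libsvm_binding

    _libsvm_binding.set_verbosity_wrap(0)
except Exception:  # pragma: no cover
    _libsvm_binding = None


class _KernelSVM:
    """Binary C-SVC on a precomputed kernel; decision is patient-positive."""

    def __init__(self, C: float):
        self.C = float(C)

    def fit(self, K: np.ndarray, y: np.ndarray) -> "_KernelSVM":
        y = np.asarray(y, dtype=np.float64)
        if _libsvm_binding is not None:
            K = np.ascontiguousarray(K, dtype=np.float64)
            out = _libsvm_binding.fit(
                K, y, svm_type=0, kernel="precomputed", C=self.C, tol=1e-3
            )
            self._support = out[0].astype(int)
            self._coef = out[3].ravel()
            self._rho = float(out[4].ravel()[0])
            self._svc = None
        else:
            self._svc = SVC(C=self.C, kernel="precomputed", tol=1e-3).fit(K, y)
            self._support = self._svc.support_.astype(int)
        return self

    @property
    def support_(self) -> np.ndarray:
        return self._support

    def decision(self, K_rows: np.ndarray) -> np.ndarray:
        """Signed distances for rows of kernel values vs the training set;
        positive means the patient class."""
        if self._svc is not None:
            return self._svc.decision_function(K_rows)
        # the binding's raw decision is control-positive; SVC negates it too
        return -(K_rows[:, self._support] @ self._coef + self._rho)

    def predict(self, K_rows: np.ndarray) -> np.ndarray:
        return np.where(self.decision(K_rows) > 0, PATIENT, CONTROL)


def _fit_svc(K_tr: np.ndarray, y_tr: np.ndarray, C: float) -> _KernelSVM:
    return _KernelSVM(C).fit(K_tr, y_tr)


def _loo_accuracy(K: np.ndarray, y: np.ndarray, C: float) -> float:
    """Exact leave-one-out accuracy on a precomputed kernel.

    Non-support-vectors of the full fit satisfy the KKT margin condition, so
    removing one changes nothing and its LOO prediction equals its (correct)
    training prediction; only support vectors need refits.
    """
    n = len(y)
    full = _fit_svc(K, y, C)
    support = set(int(s) for s in full.support_)
    correct = n - len(support)
    idx = np.arange(n)
    for j in sorted(support):
        tr = idx[idx != j]
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            pred = y_tr[0]
        else:
            clf = _fit_svc(K[np.ix_(tr, tr)], y_tr, C)
            pred = clf.predict(K[j][tr][None, :])[0]
        correct += int(pred == y[j])
    return correct / n


def _platt_fit(decisions: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit P(patient | f) = sigmoid(A f + B) with Platt-regularized targets."""
    f = np.asarray(decisions, dtype=np.float64)
    y = np.asarray(y)
    n1 = int((y == PATIENT).sum())
    n0 = int((y == CONTROL).sum())
    t = np.where(y == PATIENT, (n1 + 1.0) / (n1 + 2.0), 1.0 / (n0 + 2.0))

    def nll(ab):
        a, b = ab
        z = a * f + b  # log-odds of the patient class
        # -sum t*log p + (1-t)*log(1-p), p = sigmoid(z)
        return float(np.sum(np.logaddexp(0.0, z) - t * z))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="BFGS")
    a, b = res.x
    return float(a), float(b)


def _platt_prob(decisions: np.ndarray, ab: tuple[float, float]) -> np.ndarray:
    a, b = ab
    z = np.clip(a * np.asarray(decisions) + b, -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class BaseClassifier:
    """A fitted SVM with its selected components and probability calibration."""

    selected_components: list[int]
    svm_params: SVMParams
    inner_accuracy: float
    _space: _FoldSpace
    _svc: SVC
    _train_rows: np.ndarray
    _platt: tuple[float, float]

    def score_ext(self, ext_F: np.ndarray) -> np.ndarray:
        """Signed scores for samples already projected into the fold space."""
        kc = self._space.kernel_cross(self.selected_components, self.svm_params, ext_F)
        dec = self._svc.decision(kc[:, self._train_rows])
        return 2.0 * _platt_prob(dec, self._platt) - 1.0

    def score_maps(self, maps: np.ndarray) -> np.ndarray:
        """Signed scores for external z-scored maps (m, K, V) or (K, V)."""
        return self.score_ext(self._space.transform(maps))


def _grid_eval(
    space: _FoldSpace, train: np.ndarray, y: np.ndarray, comps, grid
) -> tuple[float, SVMParams]:
    """Best inner-LOO accuracy over the grid; ties keep the earlier grid point."""
    best_acc, best_params = -1.0, None
    for params in grid:
        K = space.kernel_matrix(comps, params)[np.ix_(train, train)]
        acc = _loo_accuracy(K, y[train], params.C)
        if acc > best_acc:
            best_acc, best_params = acc, params
    return best_acc, best_params


def _select(
    space: _FoldSpace, train: np.ndarray, y: np.ndarray, anchors, grid
) -> tuple[list[int], SVMParams, float]:
    """Forward selection from the anchor set; strict improvement required;
    ties broken toward the smaller component index."""
    selected = sorted(int(a) for a in anchors)
    best_acc, best_params = _grid_eval(space, train, y, selected, grid)
    if best_acc == 1.0:
        return selected, best_params, best_acc
    candidates = [c for c in range(space.F.shape[0]) if c not in selected]
    while candidates:
        round_acc, round_c, round_params = best_acc, None, None
        for c in candidates:
            acc, params = _grid_eval(space, train, y, selected + [c], grid)
            if acc > round_acc:
                round_acc, round_c, round_params = acc, c, params
        if round_c is None:
            break
        selected.append(round_c)
        candidates.remove(round_c)
        best_acc, best_params = round_acc, round_params
        if best_acc == 1.0:
            break
    return selected, best_params, best_acc


def _fit_base(
    space: _FoldSpace, rows: np.ndarray, y: np.ndarray, sel, params, inner_acc
) -> BaseClassifier:
    K = space.kernel_matrix(sel, params)
    K_tr = K[np.ix_(rows, rows)]
    svc = _fit_svc(K_tr, y[rows], params.C)
    dec_tr = svc.decision(K_tr)
    platt = _platt_fit(dec_tr, y[rows])
    return BaseClassifier(
        selected_components=list(sel),
        svm_params=params,
        inner_accuracy=inner_acc,
        _space=space,
        _svc=svc,
        _train_rows=rows,
        _platt=platt,
    )


def forward_select(
    train: FeatureSet, labels, anchors=(0, 1), grid=None
) -> BaseClassifier:
    """Select components by anchored forward search on the whole training set
    and return one classifier fitted on all of it."""
    y = as_binary_labels(labels)
    if train.n_subjects < 4:
        raise InvalidInputError("need at least 4 training subjects")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("training set contains a single class")
    grid = list(grid) if grid is not None else default_grid()
    rows = np.arange(train.n_subjects)
    space = _FoldSpace(train, rows)
    sel, params, acc = _select(space, rows, y, anchors, grid)
    return _fit_base(space, rows, y, sel, params, acc)


def classification_score(classifier: BaseClassifier, features) -> float | np.ndarray:
    """Signed probability score s = 2p - 1 (positive = patient) for external
    features: a z-scored map stack (K, V) or a batch (m, K, V)."""
    arr = np.asarray(features, dtype=np.float64)
    out = classifier.score_maps(arr)
    return float(out[0]) if arr.ndim == 2 else out


@dataclass
class FoldModel:
    test_index: int
    selected_components: list[int]
    svm_params: SVMParams
    inner_accuracy: float


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None
    tp: int
    fn: int
    tn: int
    fp: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
        }


@dataclass
class EnsembleResult:
    subject_ids: list[str]
    labels: np.ndarray  # (n,) 1 = patient
    base_scores: np.ndarray  # (n, n_train) signed scores from each base classifier
    aggregated_scores: np.ndarray  # (n,) medians
    predicted: np.ndarray  # (n,) 1 = patient (aggregated score > 0)
    folds: list[FoldModel]
    selection_frequency: np.ndarray  # (K,)
    anchors: tuple[int, ...]
    grid: list[SVMParams] = field(repr=False)
    features: FeatureSet = field(repr=False)
    excluded_folds: list[int] = field(default_factory=list)


def _fold_base_classifiers(
    features: FeatureSet, y: np.ndarray, fold: FoldModel
) -> list[BaseClassifier]:
    """Rebuild the base classifiers of one outer fold (deterministic)."""
    n = features.n_subjects
    train = np.array([r for r in range(n) if r != fold.test_index])
    space = _FoldSpace(features, train)
    bases = []
    for j in train:
        rows = train[train != j]
        bases.append(
            _fit_base(space, rows, y, fold.selected_components, fold.svm_params,
                      fold.inner_accuracy)
        )
    return bases


def loo_ensemble(
    features: FeatureSet,
    labels,
    anchors=(0, 1),
    grid=None,
    seed: int = 0,
) -> tuple[EnsembleResult, Metrics]:
    """Outer LOO over subjects; per fold: anchored forward selection by inner
    LOO, then one base classifier per inner leave-one-out training subset,
    each scoring the held-out subject; aggregated score = median."""
    y = as_binary_labels(labels)
    n = features.n_subjects
    if n < 6:
        raise InvalidInputError(f"need >= 6 subjects; got {n}")
    if len(np.unique(y)) < 2:
        raise InvalidInputError("both classes must be present")
    grid = list(grid) if grid is not None else default_grid()
    anchors = tuple(int(a) for a in anchors)

    base_scores = np.full((n, n - 1), np.nan)
    aggregated = np.full(n, np.nan)
    folds: list[FoldModel] = []
    excluded: list[int] = []
    counts = np.zeros(features.k)
    for i in range(n):
        train = np.array([r for r in range(n) if r != i])
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {i}: training set single-class; excluded")
            excluded.append(i)
            folds.append(FoldModel(i, [], SVMParams("linear", 1.0), np.nan))
            continue
        space = _FoldSpace(features, train)
        sel, params, acc = _select(space, train, y, anchors, grid)
        fold = FoldModel(i, sel, params, acc)
        folds.append(fold)
        counts[sel] += 1
        scores = np.empty(n - 1)
        ext_i = space.transform(features.data[i])
        for pos, j in enumerate(train):
            rows = train[train != j]
            base = _fit_base(space, rows, y, sel, params, acc)
            scores[pos] = float(base.score_ext(ext_i)[0])
        base_scores[i] = scores
        aggregated[i] = np.median(scores)

    ok = np.array([i for i in range(n) if i not in excluded])
    predicted = np.where(aggregated > 0, PATIENT, CONTROL)
    result = EnsembleResult(
        subject_ids=list(features.subject_ids),
        labels=y,
        base_scores=base_scores,
        aggregated_scores=aggregated,
        predicted=predicted,
        folds=folds,
        selection_frequency=counts / max(len(ok), 1),
        anchors=anchors,
        grid=grid,
        features=features,
        excluded_folds=excluded,
    )
    metrics = evaluate(predicted[ok], y[ok], aggregated[ok])
    return result, metrics


def evaluate(predictions, labels, scores=None) -> Metrics:
    """Accuracy, patient recall (sensitivity), control recall (specificity)
    and rank-statistic AUC over aggregated scores."""
    y = as_binary_labels(labels)
    pred = as_binary_labels(predictions)
    if len(y) == 0 or len(pred) != len(y):
        raise InvalidInputError("predictions and labels must be same non-zero length")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("both classes required to evaluate metrics")
    tp = int(np.sum((pred == PATIENT) & (y == PATIENT)))
    fn = int(np.sum((pred == CONTROL) & (y == PATIENT)))
    tn = int(np.sum((pred == CONTROL) & (y == CONTROL)))
    fp = int(np.sum((pred == PATIENT) & (y == CONTROL)))
    auc = float(roc_auc_score(y, scores)) if scores is not None else None
    return Metrics(
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc,
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def score_followup(
    ensemble: EnsembleResult, followup_features: FeatureSet
) -> dict[str, tuple[float, float]]:
    """Score follow-up scans with the base classifiers of each subject's own
    outer fold (which excluded that subject at training time).

    Returns {subject_id: (baseline_score, followup_score)}.
    """
    index = {s: i for i, s in enumerate(ensemble.subject_ids)}
    out: dict[str, tuple[float, float]] = {}
    for row, sid in enumerate(followup_features.subject_ids):
        if sid not in index:
            raise InvalidInputError(f"subject {sid!r} was not in the baseline ensemble")
        i = index[sid]
        if i in ensemble.excluded_folds:
            continue
        fold = ensemble.folds[i]
        bases = _fold_base_classifiers(ensemble.features, ensemble.labels, fold)
        ext = bases[0]._space.transform(followup_features.data[row])
        scores = np.array([float(b.score_ext(ext)[0]) for b in bases])
        out[sid] = (float(ensemble.aggregated_scores[i]), float(np.median(scores)))
    return out
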