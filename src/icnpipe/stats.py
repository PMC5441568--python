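"""Permutation tests on connectivity and scores, and covariate-adjusted
association between classification scores and treatment response."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from icnpipe.errors import InvalidInputError

__all__ = [
    "PairedPermResult",
    "AssociationResult",
    "treatment_response",
    "response_table",
    "paired_perm_test",
    "perm_score_decrease",
    "residualize",
    "score_response_association",
    "detect_outliers",
]

PANSS_MEASURES = ("panss_total", "panss_pos", "panss_neg", "panss_gen")


@dataclass
class PairedPermResult:
    t_map: np.ndarray  # voxelwise paired-t statistic
    p_map: np.ndarray  # voxelwise two-sided permutation p
    mask: np.ndarray  # p <= alpha
    alpha: float
    n_permutations: int
    n_pairs: int


@dataclass
class AssociationResult:
    measure: str
    rho: float
    p_raw: float
    p_bonferroni: float
    n: int
    covariates: list[str]
    family_size: int
    outlier_indices: list[int]
    rho_no_outliers: float | None
    p_raw_no_outliers: float | None
    p_bonferroni_no_outliers: float | None


def treatment_response(pre: float, post: float) -> float:
    """(pre - post) / pre; the symptom-score reduction as a fraction of
    the baseline score."""
    pre = float(pre)
    if pre <= 0:
        raise InvalidInputError(f"baseline score must be positive; got {pre}")
    return (pre - float(post)) / pre


def response_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient normalized response for the total score and each subscale,
    built from a long phenotype table with baseline and follow-up rows."""
    base = records[records.session == "baseline"].set_index("subject_id")
    post = records[records.session == "followup"].set_index("subject_id")
    rows = {}
    for sid in post.index:
        rows[sid] = {
            m: treatment_response(base.loc[sid, m], post.loc[sid, m])
            for m in PANSS_MEASURES
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(PANSS_MEASURES)]


def _pair_maps(pre_maps, post_maps) -> np.ndarray:
    """Difference matrix (n_pairs, n_voxels) from matched FCMap lists or
    aligned arrays."""
    if hasattr(pre_maps[0], "z_values"):
        pre_by_sid = {m.subject_id: m.z_values for m in pre_maps}
        post_by_sid = {m.subject_id: m.z_values for m in post_maps}
        if set(pre_by_sid) != set(post_by_sid):
            raise InvalidInputError(
                f"unmatched subjects: {sorted(set(pre_by_sid) ^ set(post_by_sid))}"
            )
        sids = sorted(pre_by_sid)
        pre = np.stack([pre_by_sid[s] for s in sids])
        post = np.stack([post_by_sid[s] for s in sids])
    else:
        pre = np.atleast_2d(np.asarray(pre_maps, dtype=np.float64))
        post = np.atleast_2d(np.asarray(post_maps, dtype=np.float64))
        if pre.shape != post.shape:
            raise InvalidInputError(
                f"pre shape {pre.shape} != post shape {post.shape}"
            )
    return pre - post


def _sign_flips(rng, n_perm: int, n: int) -> np.ndarray:
    """Random +-1 matrices excluding the identity (all +1) pattern, which is
    already accounted for by the add-one p estimator."""
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    while True:
        ident = np.flatnonzero((signs == 1.0).all(axis=1))
        if not len(ident):
            return signs
        signs[ident] = rng.choice([-1.0, 1.0], size=(len(ident), n))


def paired_perm_test(
    pre_maps,
    post_maps,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PairedPermResult:
    """Pseudo paired t-test: voxelwise paired t on Fisher-z differences with a
    sign-flip permutation null; two-sided, add-one p estimator, mask at alpha
    uncorrected."""
    diffs = _pair_maps(pre_maps, post_maps)
    n = diffs.shape[0]
    if n < 3:
        raise InvalidInputError(f"need >= 3 pairs; got {n}")

    def paired_t(d_signed_mean: np.ndarray) -> np.ndarray:
        # second moment is sign-invariant, so only the mean varies per flip
        var = (msq - d_signed_mean**2) * n / (n - 1)
        return d_signed_mean / np.sqrt(np.maximum(var, 1e-300) / n)

    msq = (diffs**2).mean(axis=0)
    t_obs = paired_t(diffs.mean(axis=0))
    rng = np.random.default_rng(seed)
    signs = _sign_flips(rng, n_perm, n)
    perm_means = signs @ diffs / n  # (n_perm, n_voxels)
    exceed = np.zeros(diffs.shape[1])
    abs_t_obs = np.abs(t_obs)
    # chunked to bound memory on large permutation counts
    for start in range(0, n_perm, 200):
        t_perm = paired_t(perm_means[start : start + 200])
        exceed += (np.abs(t_perm) >= abs_t_obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PairedPermResult(
        t_map=t_obs,
        p_map=p,
        mask=p <= alpha,
        alpha=alpha,
        n_permutations=n_perm,
        n_pairs=n,
    )


def perm_score_decrease(
    baseline_scores,
    followup_scores,
    n_perm: int = 10000,
    seed: int = 0,
    exclude_nonpositive_baseline: bool = False,
) -> float:
    """One-tailed sign-flip permutation p for a decrease of the mean paired
    score; optionally first excludes pairs whose baseline aggregated score is
    non-positive (baseline-misclassified patients)."""
    pre = np.asarray(baseline_scores, dtype=np.float64).ravel()
    post = np.asarray(followup_scores, dtype=np.float64).ravel()
    if pre.shape != post.shape:
        raise InvalidInputError("baseline and follow-up score lengths differ")
    if exclude_nonpositive_baseline:
        keep = pre > 0
        pre, post = pre[keep], post[keep]
    n = len(pre)
    if n < 3:
        raise InvalidInputError(f"need >= 3 pairs after filtering; got {n}")
    d = pre - post
    obs = d.mean()
    rng = np.random.default_rng(seed)
    signs = _sign_flips(rng, n_perm, n)
    perm = signs @ d / n
    return float((1.0 + np.sum(perm >= obs)) / (1.0 + n_perm))


def _design(covariates) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=np.float64)
    else:
        X = np.asarray(covariates, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    return np.column_stack([np.ones(len(X)), X]), ["intercept"] + names


def residualize(y, covariates) -> np.ndarray:
    """Least-squares residuals of y on [intercept | covariates]."""
    y = np.asarray(y, dtype=np.float64).ravel()
    X, _ = _design(covariates)
    if len(y) != X.shape[0]:
        raise InvalidInputError("y and covariates lengths differ")
    if len(y) <= X.shape[1]:
        raise InvalidInputError(
            f"need n > number of covariates + 1 ({X.shape[1]}); got n={len(y)}"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidInputError("covariate design is rank-deficient")
    q, _ = np.linalg.qr(X)
    return y - q @ (q.T @ y)


def detect_outliers(x, y) -> list[int]:
    """Indices whose externally studentized residual from the least-squares
    fit of y on x falls outside the central 95% of its t reference."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(x) != len(y):
        raise InvalidInputError("x and y lengths differ")
    n = len(x)
    if n < 5:
        raise InvalidInputError(f"need >= 5 observations; got {n}")
    if np.ptp(x) == 0:
        raise InvalidInputError("x has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    scale = max(np.var(y), 1.0)
    if model.ssr < 1e-12 * n * scale:  # perfect fit: no residual to studentize
        return []
    resid = model.get_influence().resid_studentized_external
    crit = sstats.t.ppf(0.975, df=n - 3)
    return [int(i) for i in np.flatnonzero(np.abs(resid) > crit)]


def _spearman_partial_p(rho: float, n: int, n_covariates: int) -> float:
    """Two-sided p for a (partial) Spearman coefficient via the t
    approximation with n - 2 - n_covariates degrees of freedom, so the test
    stays calibrated after residualizing both variables."""
    df = n - 2 - n_covariates
    if df <= 0:
        return 1.0
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    return float(2.0 * sstats.t.sf(abs(t), df=df))


def _one_association(
    x: np.ndarray, y: np.ndarray, measure: str, cov_names, family_size: int
) -> AssociationResult:
    rho = float(sstats.spearmanr(x, y).statistic)
    p = _spearman_partial_p(rho, len(x), len(cov_names))
    try:
        out = detect_outliers(x, y)
    except InvalidInputError:
        out = []
    rho2 = p2 = pb2 = None
    if out:
        keep = np.setdiff1d(np.arange(len(x)), out)
        if len(keep) >= 5:
            rho2 = float(sstats.spearmanr(x[keep], y[keep]).statistic)
            p2 = _spearman_partial_p(rho2, len(keep), len(cov_names))
            pb2 = min(1.0, family_size * p2)
    return AssociationResult(
        measure=measure,
        rho=float(rho),
        p_raw=float(p),
        p_bonferroni=min(1.0, family_size * float(p)),
        n=len(x),
        covariates=cov_names,
        family_size=family_size,
        outlier_indices=out,
        rho_no_outliers=rho2,
        p_raw_no_outliers=p2,
        p_bonferroni_no_outliers=pb2,
    )


def score_response_association(
    scores,
    response,
    covariates=None,
    family_size: int = 4,
) -> dict[str, AssociationResult]:
    """Covariate-adjusted Spearman correlation between classification scores
    and normalized treatment response, Bonferroni-corrected across the
    symptom measures, with least-squares outlier screening and a repeat
    analysis excluding flagged observations.

    ``response`` may be a DataFrame/dict with one column per measure or a
    single vector (treated as one measure); ``covariates=None`` skips the
    adjustment."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    n = len(scores)
    if n < 5:
        raise InvalidInputError(f"need >= 5 matched patients; got {n}")
    if isinstance(response, (pd.DataFrame, dict)):
        resp = pd.DataFrame(response)
    else:
        resp = pd.DataFrame({"response": np.asarray(response, dtype=np.float64)})
    if len(resp) != n:
        raise InvalidInputError("scores and response lengths differ")
    if covariates is None:
        cov_names = []
        x = scores
        adjust = lambda v: v  # noqa: E731
    else:
        cov_names = _design(covariates)[1][1:]
        x = residualize(scores, covariates)
        adjust = lambda v: residualize(v, covariates)  # noqa: E731
    results: dict[str, AssociationResult] = {}
    for measure in resp.columns:
        yv = adjust(resp[measure].to_numpy())
        results[measure] = _one_association(x, yv, measure, cov_names, family_size)
    return results
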