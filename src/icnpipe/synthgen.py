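"""Synthetic resting-state cohorts with known ground truth.

The generative model mirrors what the downstream analysis assumes: each scan
is a mixture of smooth spatial component maps and band-limited time courses
plus Gaussian noise. Group membership perturbs the spatial maps of a
designated *affected* subset of components through per-subject loadings on
fixed deviation patterns; follow-up scans of treated patients move those
loadings back toward the control mean by a per-subject response fraction,
and symptom scores improve in proportion. All planted quantities are
recorded so parameter-recovery tests can check every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from icnpipe.errors import InvalidConfigurationError, InvalidInputError
from icnpipe.preprocess import NuisanceSet, Scan

__all__ = [
    "ComponentAtlas",
    "CohortConfig",
    "CohortTruth",
    "Cohort",
    "make_atlas",
    "simulate_time_courses",
    "simulate_cohort",
    "write_cohort",
]

# Table-1 style baseline symptom profile: total mean/SD and the relative
# weight of the positive/negative/general subscales.
PANSS_TOTAL_MEAN = 80.59
PANSS_TOTAL_SD = 7.25
PANSS_SUBSCALE_MEANS = {"pos": 26.94, "neg": 16.74, "gen": 37.00}

MAX_PAIRWISE_MAP_CORR = 0.3


@dataclass
class ComponentAtlas:
    """K dispersed smooth blobs on a 3-D grid, with anchor/affected labels."""

    grid_shape: tuple[int, int, int]
    maps: np.ndarray  # (K, n_voxels), each non-negative with max exactly 1
    labels: list[str]
    anchor_indices: dict[str, int]  # {"DMN": idx, "MTL": idx}
    affected_default: tuple[int, ...]
    seed: int

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]

    def map_volume(self, c: int) -> np.ndarray:
        return self.maps[c].reshape(self.grid_shape)

    def validate(self) -> None:
        if self.k < 2:
            raise InvalidConfigurationError("atlas needs at least 2 components")
        if np.any(self.maps < 0):
            raise InvalidConfigurationError("atlas maps must be non-negative")
        peaks = self.maps.max(axis=1)
        if not np.allclose(peaks, 1.0, atol=1e-12):
            raise InvalidConfigurationError("every atlas map must peak at exactly 1")
        corr = np.corrcoef(self.maps)
        off = corr[~np.eye(self.k, dtype=bool)]
        if np.any(np.abs(off) >= MAX_PAIRWISE_MAP_CORR):
            raise InvalidConfigurationError(
                f"atlas maps overlap too much: max |r| = {np.abs(off).max():.3f}"
            )


@dataclass
class CohortConfig:
    """Study-design parameters. Defaults reproduce the reference design:
    34 patients + 34 controls, 13 ECT + 16 medication-only follow-ups,
    240 volumes at TR 2 s, 20 components of which 6 carry group effects."""

    n_patients: int = 34
    n_controls: int = 34
    n_followup_ect: int = 13
    n_followup_med: int = 16
    n_volumes: int = 240
    tr_seconds: float = 2.0
    k_components: int = 20
    affected: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    delta: float = 2.0
    response_gain: float = 0.8
    response_couple: float = 0.3
    noise_sd: float = 0.5
    map_jitter: float = 0.02
    amp_sd: float = 0.1
    deviation_amp: float = 0.3
    affected_within_sd: float = 1.5
    affected_anticorr: float = 0.7
    affected_indep_sd: float = 0.5
    offset: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise InvalidConfigurationError("need at least one subject per group")
        if self.n_followup_ect + self.n_followup_med > self.n_patients:
            raise InvalidConfigurationError("more follow-ups than patients")
        if self.n_volumes < 30:
            raise InvalidConfigurationError("n_volumes must be >= 30")
        if self.k_components < 2:
            raise InvalidConfigurationError("k_components must be >= 2")
        if self.delta < 0:
            raise InvalidConfigurationError("delta must be >= 0")
        if len(self.affected) and (
            min(self.affected) < 0 or max(self.affected) >= self.k_components
        ):
            raise InvalidConfigurationError(
                f"affected indices {self.affected} out of range for "
                f"k={self.k_components}"
            )
        if self.noise_sd < 0:
            raise InvalidConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.affected_anticorr <= 1:
            raise InvalidConfigurationError("affected_anticorr must be in [0, 1]")


@dataclass
class CohortTruth:
    """Everything needed to recompute the planted effects."""

    signs: np.ndarray  # (K,) component effect signs (+-1); zero off affected
    deviation_maps: np.ndarray  # (K, n_voxels) unit-peak deviation patterns
    loadings_baseline: dict[str, np.ndarray]  # subject_id -> (K,)
    loadings_followup: dict[str, np.ndarray]  # follow-up subjects only
    amps: dict[str, np.ndarray]  # subject_id -> (K,) mixing amplitudes
    rho: dict[str, float]  # follow-up subjects: normalization fraction
    response: dict[str, float]  # follow-up subjects: PANSS response ratio
    affected: tuple[int, ...]
    subject_maps: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    timecourses: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)


@dataclass
class Cohort:
    atlas: ComponentAtlas
    config: CohortConfig
    scans: list[Scan]
    nuisance: dict[tuple[str, str], NuisanceSet]
    records: pd.DataFrame
    truth: CohortTruth

    def scan(self, subject_id: str, session: str = "baseline") -> Scan:
        for s in self.scans:
            if s.subject_id == subject_id and s.session == session:
                return s
        raise InvalidInputError(f"no scan for {subject_id}/{session}")

    def baseline_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.session == "baseline"]

    def followup_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.session == "followup"]

    def validate(self) -> None:
        baseline_ids = {s.subject_id for s in self.baseline_scans()}
        for s in self.followup_scans():
            if s.subject_id not in baseline_ids:
                raise InvalidInputError(
                    f"follow-up scan for {s.subject_id} has no baseline scan"
                )


def _blob(grid_shape, center, sigma):
    axes = [np.arange(n, dtype=float) for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2
    m = np.exp(-d2 / (2.0 * sigma**2))
    return (m / m.max()).ravel()


def make_atlas(
    grid_shape: tuple[int, int, int], k: int = 20, seed: int = 0
) -> ComponentAtlas:
    """Place ``k`` unit-peak Gaussian blobs on a dispersed lattice.

    Cells of the lattice are at least 4 voxels wide, guaranteeing pairwise
    spatial correlation below 0.3. Deterministic given ``seed``.
    """
    if k < 2:
        raise InvalidConfigurationError(f"k must be >= 2; got {k}")
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 1:
        raise InvalidConfigurationError(f"bad grid shape {grid_shape}")
    cell = 4
    splits = tuple(max(1, n // cell) for n in grid_shape)
    n_cells = int(np.prod(splits))
    if n_cells < k or min(grid_shape) < 2:
        raise InvalidConfigurationError(
            f"grid {grid_shape} too small to place {k} dispersed components"
        )
    rng = np.random.default_rng(seed)
    cells = rng.choice(n_cells, size=k, replace=False)
    sigma = 1.1
    maps = np.empty((k, int(np.prod(grid_shape))))
    for i, c in enumerate(cells):
        idx = np.unravel_index(c, splits)
        center = [
            (idx[a] + 0.5) * grid_shape[a] / splits[a] - 0.5 + rng.uniform(-0.5, 0.5)
            for a in range(3)
        ]
        maps[i] = _blob(grid_shape, center, sigma)
    labels = ["DMN", "MTL"] + [f"IC{i + 1:02d}" for i in range(2, k)]
    affected = tuple(range(min(6, k)))
    atlas = ComponentAtlas(
        grid_shape=grid_shape,
        maps=maps,
        labels=labels,
        anchor_indices={"DMN": 0, "MTL": 1},
        affected_default=affected,
        seed=seed,
    )
    atlas.validate()
    return atlas


def simulate_time_courses(
    k: int,
    n_volumes: int,
    tr_seconds: float = 2.0,
    seed: int = 0,
    low_hz: float = 0.012,
    high_hz: float = 0.078,
) -> np.ndarray:
    """Zero-mean, unit-variance, mutually orthogonal band-limited rows.

    Rows are built from random complex spectra supported strictly inside the
    analysis band, then symmetrically decorrelated (a linear combination of
    in-band signals stays in-band), so orthogonality is exact and >= 80% of
    each row's power lies in 0.01-0.08 Hz by construction.
    """
    if n_volumes < 30:
        raise InvalidConfigurationError(f"n_volumes must be >= 30; got {n_volumes}")
    if k < 1:
        raise InvalidConfigurationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)
    band = (freqs >= low_hz) & (freqs <= high_hz)
    n_band = int(band.sum())
    if 2 * n_band < k:
        raise InvalidConfigurationError(
            f"only {n_band} in-band frequency bins for {k} orthogonal "
            f"time courses; increase n_volumes"
        )
    spectra = np.zeros((k, len(freqs)), dtype=complex)
    spectra[:, band] = rng.normal(size=(k, n_band)) + 1j * rng.normal(size=(k, n_band))
    tc = np.fft.irfft(spectra, n=n_volumes, axis=1)
    cov = tc @ tc.T
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() <= 1e-12 * evals.max():
        raise InvalidConfigurationError("time courses degenerate; increase n_volumes")
    tc = (evecs @ np.diag(evals**-0.5) @ evecs.T) @ tc
    tc /= tc.std(axis=1, keepdims=True)
    return tc


def _random_walk(rng, n, scale):
    w = np.cumsum(rng.normal(scale=scale, size=n))
    return w - w.mean()


def _simulate_nuisance(rng, n_volumes) -> NuisanceSet:
    motion = np.column_stack([_random_walk(rng, n_volumes, 0.02) for _ in range(6)])
    wm = _random_walk(rng, n_volumes, 0.05)
    csf = _random_walk(rng, n_volumes, 0.05)
    return NuisanceSet(motion=motion, wm=wm, csf=csf)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def _panss_baseline(rng):
    total = _truncnorm(rng, PANSS_TOTAL_MEAN, PANSS_TOTAL_SD, 30.0, 210.0)
    weights = np.array(list(PANSS_SUBSCALE_MEANS.values()))
    weights = weights / weights.sum()
    jitter = rng.normal(scale=0.02, size=3)
    w = np.clip(weights + jitter, 0.05, None)
    w /= w.sum()
    pos, neg, gen = (total * w).tolist()
    return total, pos, neg, gen


def simulate_cohort(atlas: ComponentAtlas, config: CohortConfig) -> Cohort:
    """Simulate scans, phenotypes and ground truth for one cohort.

    Patients' loadings on the affected components are shifted by
    ``delta * sign_c`` (signs drawn once per component); at follow-up each
    treated patient's affected loadings move a fraction ``rho`` back toward
    the control mean of zero, and the PANSS reduction is generated as
    ``response_gain * rho`` plus noise. ``delta = 0`` makes the patient and
    control scan distributions identical.
    """
    config.validate()
    atlas.validate()
    if len(config.affected) and max(config.affected) >= atlas.k:
        raise InvalidConfigurationError(
            f"affected set {config.affected} out of range for atlas with k={atlas.k}"
        )
    if config.k_components != atlas.k:
        raise InvalidConfigurationError(
            f"config.k_components={config.k_components} != atlas k={atlas.k}"
        )
    k, nvox = atlas.k, atlas.n_voxels
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    signs = np.zeros(k)
    aff = np.asarray(config.affected, dtype=int)
    signs[aff] = rng.choice([-1.0, 1.0], size=len(aff))

    # Fixed deviation pattern per component: a displaced unit-peak blob.
    dev_maps = np.empty_like(atlas.maps)
    for c in range(k):
        vol = atlas.map_volume(c)
        peak = np.array(np.unravel_index(np.argmax(vol), atlas.grid_shape), dtype=float)
        shift = rng.normal(size=3)
        shift = 2.5 * shift / np.linalg.norm(shift)
        center = np.clip(peak + shift, 0, np.array(atlas.grid_shape) - 1)
        dev_maps[c] = _blob(atlas.grid_shape, center, 1.1)

    patients = [f"P{i + 1:03d}" for i in range(config.n_patients)]
    controls = [f"C{i + 1:03d}" for i in range(config.n_controls)]
    followup_ids = patients[: config.n_followup_ect + config.n_followup_med]
    arms = {sid: "none" for sid in patients + controls}
    for i, sid in enumerate(followup_ids):
        arms[sid] = "ECT" if i < config.n_followup_ect else "MED"

    loadings_b: dict[str, np.ndarray] = {}
    loadings_f: dict[str, np.ndarray] = {}
    amps: dict[str, np.ndarray] = {}
    # Affected-component loading noise is partially anticorrelated within a
    # subject (each series centered toward its mean across the affected set),
    # so no single component carries the whole group difference and forward
    # selection keeps improving as components are added. Identical structure
    # in both groups; only the mean shifts by delta * sign.
    patient_set = set(patients)
    for sid in patients + controls:
        b = rng.normal(size=k)
        if len(aff):
            u = rng.normal(scale=config.affected_within_sd, size=len(aff))
            e = u - config.affected_anticorr * u.mean()
            shift = config.delta if sid in patient_set else 0.0
            b[aff] = signs[aff] * (shift + e) + rng.normal(
                scale=config.affected_indep_sd, size=len(aff)
            )
        loadings_b[sid] = b
        amps[sid] = np.clip(rng.normal(1.0, config.amp_sd, size=k), 0.2, None)

    # Individual response: Beta(2,2) baseline, anti-coupled to the signed
    # deviation so patients closer to the control mean improve more.
    if len(aff):
        dev_score = {
            sid: float(np.mean(loadings_b[sid][aff] * signs[aff])) for sid in followup_ids
        }
    else:
        dev_score = {sid: 0.0 for sid in followup_ids}
    mean_dev = np.mean(list(dev_score.values())) if followup_ids else 0.0
    rho: dict[str, float] = {}
    response: dict[str, float] = {}
    for sid in followup_ids:
        u = rng.beta(2.0, 2.0)
        r = float(
            np.clip(u - config.response_couple * (dev_score[sid] - mean_dev), 0.0, 1.0)
        )
        rho[sid] = r
        response[sid] = float(
            np.clip(config.response_gain * r + rng.normal(scale=0.05), 0.0, 0.95)
        )
        b_fu = loadings_b[sid].copy()
        b_fu[aff] = b_fu[aff] * (1.0 - r)
        loadings_f[sid] = b_fu

    truth = CohortTruth(
        signs=signs,
        deviation_maps=dev_maps,
        loadings_baseline=loadings_b,
        loadings_followup=loadings_f,
        amps=amps,
        rho=rho,
        response=response,
        affected=tuple(config.affected),
    )

    scans: list[Scan] = []
    nuisance: dict[tuple[str, str], NuisanceSet] = {}
    sessions = [(sid, "baseline") for sid in patients + controls] + [
        (sid, "followup") for sid in followup_ids
    ]
    scan_seeds = ss.spawn(len(sessions) + 1)[1:]
    for (sid, session), child in zip(sessions, scan_seeds):
        srng = np.random.default_rng(child)
        tc = simulate_time_courses(
            k, config.n_volumes, config.tr_seconds, seed=srng.integers(2**31)
        )
        b = loadings_b[sid] if session == "baseline" else loadings_f[sid]
        subject_maps = (
            atlas.maps
            + config.deviation_amp * b[:, None] * dev_maps
            + config.map_jitter * srng.normal(size=(k, nvox))
        )
        signal = (amps[sid][:, None] * subject_maps).T @ tc  # (voxel, volume)
        data = (
            config.offset
            + signal
            + config.noise_sd * srng.normal(size=signal.shape)
        )
        scans.append(
            Scan(
                data=data.reshape(*atlas.grid_shape, config.n_volumes),
                tr_seconds=config.tr_seconds,
                subject_id=sid,
                session=session,
            )
        )
        nuisance[(sid, session)] = _simulate_nuisance(srng, config.n_volumes)
        truth.subject_maps[(sid, session)] = subject_maps
        truth.timecourses[(sid, session)] = tc

    rows = []
    prng = np.random.default_rng(ss.spawn(2)[1])
    for sid in patients + controls:
        group = "patient" if sid.startswith("P") else "control"
        age = _truncnorm(prng, 29.0 if group == "patient" else 28.0, 7.0, 18, 60)
        sex = int(prng.random() < 0.4)
        edu = _truncnorm(prng, 13.0 if group == "patient" else 15.0, 3.0, 6, 22)
        illness = (
            _truncnorm(prng, 6.0, 4.0, 0.2, 30.0) if group == "patient" else 0.0
        )
        if group == "patient":
            total, pos, neg, gen = _panss_baseline(prng)
        else:
            total = pos = neg = gen = np.nan
        rows.append(
            dict(
                subject_id=sid,
                group=group,
                arm=arms[sid],
                session="baseline",
                age=round(age, 1),
                sex=sex,
                education_years=round(edu, 1),
                illness_years=round(illness, 1),
                panss_total=total,
                panss_pos=pos,
                panss_neg=neg,
                panss_gen=gen,
            )
        )
        if sid in rho:
            base = rows[-1]
            sub_jit = prng.normal(scale=0.04, size=3)
            post = {}
            for name, jit in zip(("panss_pos", "panss_neg", "panss_gen"), sub_jit):
                frac = float(np.clip(response[sid] + jit, 0.0, 0.98))
                post[name] = base[name] * (1.0 - frac)
            post["panss_total"] = sum(post.values())
            rows.append(
                dict(
                    base,
                    session="followup",
                    panss_total=post["panss_total"],
                    panss_pos=post["panss_pos"],
                    panss_neg=post["panss_neg"],
                    panss_gen=post["panss_gen"],
                )
            )
            # keep truth consistent with the emitted table
            response[sid] = float(
                (base["panss_total"] - post["panss_total"]) / base["panss_total"]
            )

    records = pd.DataFrame(rows)
    cohort = Cohort(
        atlas=atlas,
        config=config,
        scans=scans,
        nuisance=nuisance,
        records=records,
        truth=truth,
    )
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, directory: str | Path) -> dict:
    """Write one NIfTI + nuisance TSV per scan, phenotype and truth CSVs, and
    a JSON manifest. Returns the manifest dict."""
    from icnpipe import io as cio

    if not cohort.scans:
        raise InvalidInputError("cohort has no scans")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for scan in cohort.scans:
        stem = f"sub-{scan.subject_id}_ses-{scan.session}"
        cio.write_scan(scan, directory / f"{stem}_bold.nii")
        cio.write_nuisance(
            cohort.nuisance[(scan.subject_id, scan.session)],
            directory / f"{stem}_nuisance.tsv",
        )
        files += [f"{stem}_bold.nii", f"{stem}_nuisance.tsv"]

    cohort.records.to_csv(directory / "phenotypes.csv", index=False)
    files.append("phenotypes.csv")

    k = cohort.atlas.k
    truth_rows = []
    for sid, b in cohort.truth.loadings_baseline.items():
        row = dict(subject_id=sid, session="baseline", rho=np.nan, response=np.nan)
        row.update({f"loading_{c}": b[c] for c in range(k)})
        truth_rows.append(row)
    for sid, b in cohort.truth.loadings_followup.items():
        row = dict(
            subject_id=sid,
            session="followup",
            rho=cohort.truth.rho[sid],
            response=cohort.truth.response[sid],
        )
        row.update({f"loading_{c}": b[c] for c in range(k)})
        truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(directory / "truth.csv", index=False)
    files.append("truth.csv")

    manifest = {
        "n_scans": len(cohort.scans),
        "grid_shape": list(cohort.atlas.grid_shape),
        "k_components": k,
        "labels": cohort.atlas.labels,
        "anchor_indices": cohort.atlas.anchor_indices,
        "affected": list(cohort.truth.affected),
        "signs": cohort.truth.signs.tolist(),
        "config": {
            f.name: (list(v) if isinstance(v := getattr(cohort.config, f.name), tuple) else v)
            for f in fields(cohort.config)
        },
        "files": files,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
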