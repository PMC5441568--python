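"""Pipeline configuration, stage orchestration and run manifests.

One global seed fans out to per-stage seeds by fixed offsets, so a single
flag reproduces the whole run. Stages hand data forward in memory inside
:func:`run_pipeline`; the CLI exposes the same stages with on-disk handoff.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from icnpipe import __version__, classify, icn, io as cio, stats, synthgen
from icnpipe.errors import InvalidConfigurationError, InvalidInputError
from icnpipe.preprocess import PreprocessParams, preprocess_scan

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "stage_preprocess",
    "stage_ica",
    "stage_classify",
    "stage_stats",
]

SEED_OFFSETS = {"synth": 0, "ica": 1, "classify": 2, "stats": 3}


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the declared analysis values
    (20 components, 0.01-0.08 Hz, 6 mm FWHM, mean 10,000, 6 dropped volumes,
    1000/10000 permutations, alpha = 0.05)."""

    out_dir: str = "icnpipe_out"
    data_dir: str | None = None  # existing cohort directory when skipping synthesis
    skip_synthesis: bool = False
    write_cohort: bool = True
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    cohort: synthgen.CohortConfig = field(default_factory=synthgen.CohortConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    ica_k: int = 20
    icn_mode: str = "dual_regression"
    anchors: tuple[str, str] = ("DMN", "MTL")
    svm_grid: list[classify.SVMParams] = field(default_factory=classify.default_grid)
    n_perm_maps: int = 1000
    n_perm_scores: int = 10000
    alpha: float = 0.05
    family_size: int = 4
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + SEED_OFFSETS[stage]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["svm_grid"] = [dataclasses.asdict(p) for p in self.svm_grid]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if isinstance(c.get("affected"), list):
                c["affected"] = tuple(c["affected"])
            d["cohort"] = synthgen.CohortConfig(**c)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessParams(**d["preprocess"])
        if "svm_grid" in d and d["svm_grid"] and isinstance(d["svm_grid"][0], dict):
            d["svm_grid"] = [classify.SVMParams(**p) for p in d["svm_grid"]]
        for key in ("grid_shape", "anchors"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: dict[str, Path] | None = None, **info):
        entry = {"stage": name, "timestamp": time.time(), **info}
        if outputs:
            entry["outputs"] = {
                key: {"path": str(p), "sha256": _hash_file(p)}
                for key, p in outputs.items()
            }
        self.stages.append(entry)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "version": self.version,
                    "seeds": self.seeds,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                default=str,
            )


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_cohort_dir(data_dir: Path):
    """Read scans, nuisance sets and phenotypes from a cohort directory."""
    if not data_dir.is_dir():
        raise InvalidInputError(f"input directory {data_dir} does not exist")
    records = cio.read_phenotypes(data_dir / "phenotypes.csv")
    scans, nuisance = [], {}
    for _, row in records.iterrows():
        stem = f"sub-{row.subject_id}_ses-{row.session}"
        scan_path = data_dir / f"{stem}_bold.nii"
        if not scan_path.exists():
            raise InvalidInputError(f"missing scan {scan_path}")
        scans.append(cio.read_scan(scan_path))
        nuis_path = data_dir / f"{stem}_nuisance.tsv"
        nuisance[(row.subject_id, row.session)] = (
            cio.read_nuisance(nuis_path) if nuis_path.exists() else None
        )
    return scans, nuisance, records


def _anchor_components(group, atlas, anchor_labels) -> tuple[int, ...]:
    """Map anchor template labels to group-ICA component indices."""
    labels = icn.match_templates(group, atlas)
    anchors = []
    for want in anchor_labels:
        hits = [c for c, lab in labels.items() if lab == want]
        if not hits:
            raise InvalidInputError(
                f"anchor template {want!r} matched no group component"
            )
        anchors.append(hits[0])
    return tuple(anchors)


# ---------------------------------------------------------------------------
# staged execution with on-disk handoff (used by the CLI stage subcommands)


def stage_preprocess(config: PipelineConfig, in_dir: Path, out_dir: Path) -> None:
    """Clean every scan of a cohort directory; write cleaned NIfTIs plus the
    phenotype table to ``out_dir``."""
    scans, nuisance, records = _load_cohort_dir(Path(in_dir))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for scan in scans:
        cleaned = preprocess_scan(
            scan, nuisance.get((scan.subject_id, scan.session)), config.preprocess
        )
        cio.write_scan(
            cleaned, out_dir / f"sub-{scan.subject_id}_ses-{scan.session}_bold.nii"
        )
    records.to_csv(out_dir / "phenotypes.csv", index=False)


def _load_preproc_dir(in_dir: Path):
    in_dir = Path(in_dir)
    records = cio.read_phenotypes(in_dir / "phenotypes.csv")
    scans = [
        cio.read_scan(in_dir / f"sub-{r.subject_id}_ses-{r.session}_bold.nii")
        for _, r in records.iterrows()
    ]
    return scans, records


def stage_ica(config: PipelineConfig, preproc_dir: Path, out_dir: Path) -> None:
    """Group ICA + subject back-reconstruction over a preprocessed cohort.

    Writes group maps (NIfTI), per-scan time courses (CSV, component x
    volume), subject maps (npz), and the anchor/template labels (JSON)."""
    scans, records = _load_preproc_dir(preproc_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    baseline = [s for s in scans if s.session == "baseline"]
    group = icn.group_ica(baseline, k=config.ica_k, seed=config.stage_seed("ica"))
    atlas = synthgen.make_atlas(
        config.grid_shape, config.cohort.k_components, seed=config.stage_seed("synth")
    )
    labels = icn.match_templates(group, atlas)
    anchors = _anchor_components(group, atlas, config.anchors)
    cio.write_scan(
        dataclasses.replace(
            baseline[0],
            data=group.maps.T.reshape(*group.grid_shape, group.k),
            subject_id="group",
            session="ica",
        ),
        out_dir / "group_maps.nii",
    )
    subject_maps = {}
    for scan in scans:
        sicn = icn.subject_icns(scan, group, mode=config.icn_mode)
        key = f"{scan.subject_id}__{scan.session}"
        subject_maps[key] = sicn.maps
        pd.DataFrame(sicn.timecourses).to_csv(
            out_dir / f"sub-{scan.subject_id}_ses-{scan.session}_timecourses.csv",
            index=False,
        )
    np.savez(out_dir / "subject_maps.npz", **subject_maps)
    with open(out_dir / "labels.json", "w") as fh:
        json.dump(
            {
                "component_labels": {str(c): lab for c, lab in labels.items()},
                "anchors": list(anchors),
                "variance_retained": group.variance_retained,
            },
            fh,
            indent=2,
        )


def _features_from_ica_dir(ica_dir: Path, records: pd.DataFrame, session: str):
    maps = np.load(Path(ica_dir) / "subject_maps.npz")
    rows = records[records.session == session]
    icns = [
        icn.SubjectICN(
            subject_id=r.subject_id,
            session=session,
            maps=maps[f"{r.subject_id}__{session}"],
            timecourses=np.empty((0, 0)),
            mode="loaded",
        )
        for _, r in rows.iterrows()
    ]
    return classify.build_features(icns) if icns else None


def _write_classify_outputs(out_dir, ensemble, metrics, pairs):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    score_rows = [
        dict(
            subject_id=sid,
            session="baseline",
            aggregated_score=ensemble.aggregated_scores[i],
            predicted_label="patient" if ensemble.predicted[i] else "control",
            n_base=int(np.sum(~np.isnan(ensemble.base_scores[i]))),
        )
        for i, sid in enumerate(ensemble.subject_ids)
    ] + [
        dict(
            subject_id=sid,
            session="followup",
            aggregated_score=fu,
            predicted_label="patient" if fu > 0 else "control",
            n_base=len(ensemble.subject_ids) - 1,
        )
        for sid, (_, fu) in pairs.items()
    ]
    pd.DataFrame(score_rows).to_csv(out_dir / "scores.csv", index=False)
    pd.DataFrame(
        {
            "component": range(len(ensemble.selection_frequency)),
            "frequency": ensemble.selection_frequency,
        }
    ).to_csv(out_dir / "selection_frequency.csv", index=False)
    pd.DataFrame(
        [
            dict(
                fold=f.test_index,
                test_subject=ensemble.subject_ids[f.test_index],
                selected_components=" ".join(map(str, f.selected_components)),
                svm_params=str(f.svm_params),
                inner_accuracy=f.inner_accuracy,
            )
            for f in ensemble.folds
        ]
    ).to_csv(out_dir / "fold_selections.csv", index=False)
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics.as_dict(), fh, indent=2)
    ok = [i for i in range(len(ensemble.subject_ids))
          if i not in ensemble.excluded_folds]
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(
        ensemble.labels[ok], ensemble.aggregated_scores[ok]
    )
    pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}).to_csv(
        out_dir / "roc.csv", index=False
    )


def stage_classify(
    config: PipelineConfig, ica_dir: Path, preproc_dir: Path, out_dir: Path
) -> dict:
    """Nested LOO ensemble over the back-reconstructed subject maps; writes
    scores, per-fold selections, metrics and ROC points."""
    ica_dir = Path(ica_dir)
    records = cio.read_phenotypes(Path(preproc_dir) / "phenotypes.csv")
    with open(ica_dir / "labels.json") as fh:
        anchors = tuple(json.load(fh)["anchors"])
    feats = _features_from_ica_dir(ica_dir, records, "baseline")
    base_records = records[records.session == "baseline"].set_index("subject_id")
    labels = [base_records.loc[s, "group"] for s in feats.subject_ids]
    ensemble, metrics = classify.loo_ensemble(
        feats, labels, anchors=anchors, grid=config.svm_grid,
        seed=config.stage_seed("classify"),
    )
    feats_fu = _features_from_ica_dir(ica_dir, records, "followup")
    pairs = classify.score_followup(ensemble, feats_fu) if feats_fu else {}
    _write_classify_outputs(out_dir, ensemble, metrics, pairs)
    return {"metrics": metrics, "ensemble": ensemble, "pairs": pairs}


def stage_stats(
    config: PipelineConfig,
    classify_dir: Path,
    preproc_dir: Path,
    ica_dir: Path,
    out_dir: Path,
) -> dict:
    """Score-decrease permutation test, FC-change maps on the anchor
    components, and the score/response association table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scores = pd.read_csv(Path(classify_dir) / "scores.csv")
    records = cio.read_phenotypes(Path(preproc_dir) / "phenotypes.csv")
    with open(Path(ica_dir) / "labels.json") as fh:
        anchors = tuple(json.load(fh)["anchors"])
    base = scores[scores.session == "baseline"].set_index("subject_id")
    fu = scores[scores.session == "followup"].set_index("subject_id")
    pairs = {
        sid: (base.loc[sid].aggregated_score, fu.loc[sid].aggregated_score)
        for sid in fu.index
    }
    out: dict = {}
    seed_stats = config.stage_seed("stats")
    if pairs:
        pre = np.array([v[0] for v in pairs.values()])
        post = np.array([v[1] for v in pairs.values()])
        if int(np.sum(pre > 0)) >= 3:
            out["score_decrease_p"] = stats.perm_score_decrease(
                pre, post, n_perm=config.n_perm_scores, seed=seed_stats,
                exclude_nonpositive_baseline=True,
            )
        scans, _ = _load_preproc_dir(preproc_dir)
        scan_by = {(s.subject_id, s.session): s for s in scans}
        for comp in anchors:
            fc_pre, fc_post = [], []
            for sid in pairs:
                for ses, dest in (("baseline", fc_pre), ("followup", fc_post)):
                    tcs = pd.read_csv(
                        Path(ica_dir) / f"sub-{sid}_ses-{ses}_timecourses.csv"
                    ).to_numpy()
                    m = icn.fc_map(scan_by[(sid, ses)], tcs[comp])
                    m.component = comp
                    dest.append(m)
            if len(fc_pre) >= 3:
                res = stats.paired_perm_test(
                    fc_pre, fc_post, n_perm=config.n_perm_maps,
                    alpha=config.alpha, seed=seed_stats + comp,
                )
                grid = scan_by[next(iter(scan_by))].grid_shape
                for name, arr in (
                    ("tmap", res.t_map),
                    ("pmap", res.p_map),
                    ("mask", res.mask.astype(float)),
                ):
                    cio.write_scan(
                        dataclasses.replace(
                            scans[0],
                            data=arr.reshape(*grid, 1),
                            subject_id="stats",
                            session=name,
                        ),
                        out_dir / f"fc_change_comp{comp}_{name}.nii",
                    )
                out[f"fc_change_component_{comp}"] = {
                    "significant_fraction": float(res.mask.mean()),
                    "n_pairs": res.n_pairs,
                }
        fu_ids = [s for s in pairs if s in set(records[records.session == "followup"].subject_id)]
        if len(fu_ids) >= 7:
            resp = stats.response_table(records).loc[fu_ids]
            base_rec = records[records.session == "baseline"].set_index("subject_id")
            cov = base_rec.loc[
                fu_ids, ["age", "sex", "education_years", "illness_years"]
            ]
            assoc = stats.score_response_association(
                np.array([pairs[s][0] for s in fu_ids]), resp, cov,
                family_size=config.family_size,
            )
            pd.DataFrame(
                [
                    dict(
                        measure=a.measure, rho=a.rho, p_raw=a.p_raw,
                        p_bonferroni=a.p_bonferroni, n=a.n,
                        outliers_removed=len(a.outlier_indices),
                        rho_no_outliers=a.rho_no_outliers,
                    )
                    for a in assoc.values()
                ]
            ).to_csv(out_dir / "associations.csv", index=False)
            out["associations"] = {m: a.rho for m, a in assoc.items()}
    with open(out_dir / "stats.json", "w") as fh:
        json.dump(out, fh, indent=2)
    return out


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute synthgen (optional) -> preprocess -> icn -> classify -> stats.

    Writes metrics JSON, score/selection/association CSVs, group maps and a
    run manifest under ``config.out_dir``; returns the manifest and a dict of
    in-memory results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seeds={s: config.stage_seed(s) for s in SEED_OFFSETS},
    )
    results: dict = {}

    # --- synthesis -----------------------------------------------------
    atlas = synthgen.make_atlas(
        config.grid_shape, config.cohort.k_components, seed=config.stage_seed("synth")
    )
    if config.skip_synthesis:
        if config.data_dir is None:
            raise InvalidConfigurationError("skip_synthesis requires data_dir")
        scans, nuisance, records = _load_cohort_dir(Path(config.data_dir))
        manifest.add_stage("load", n_scans=len(scans))
    else:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.stage_seed("synth"))
        cohort = synthgen.simulate_cohort(atlas, cohort_cfg)
        scans, nuisance, records = cohort.scans, cohort.nuisance, cohort.records
        results["cohort"] = cohort
        if config.write_cohort:
            synthgen.write_cohort(cohort, out / "cohort")
        manifest.add_stage("synthgen", n_scans=len(scans))

    # --- preprocessing -------------------------------------------------
    cleaned = [
        preprocess_scan(s, nuisance.get((s.subject_id, s.session)), config.preprocess)
        for s in scans
    ]
    manifest.add_stage("preprocess", params=dataclasses.asdict(config.preprocess))

    # --- intrinsic networks --------------------------------------------
    baseline = [s for s in cleaned if s.session == "baseline"]
    followup = [s for s in cleaned if s.session == "followup"]
    group = icn.group_ica(baseline, k=config.ica_k, seed=config.stage_seed("ica"))
    anchors = _anchor_components(group, atlas, config.anchors)
    icns_base = [icn.subject_icns(s, group, mode=config.icn_mode) for s in baseline]
    icns_fu = [icn.subject_icns(s, group, mode=config.icn_mode) for s in followup]
    results.update(group_ica=group, anchors=anchors)
    cio.write_scan(
        dataclasses.replace(
            baseline[0],
            data=group.maps.T.reshape(*group.grid_shape, group.k),
            subject_id="group",
            session="ica",
        ),
        out / "group_maps.nii",
    )
    manifest.add_stage(
        "icn",
        outputs={"group_maps": out / "group_maps.nii"},
        anchors=list(anchors),
        variance_retained=group.variance_retained,
    )

    # --- classification ------------------------------------------------
    feats = classify.build_features(icns_base)
    base_records = records[records.session == "baseline"].set_index("subject_id")
    labels = [base_records.loc[s, "group"] for s in feats.subject_ids]
    ensemble, metrics = classify.loo_ensemble(
        feats,
        labels,
        anchors=anchors,
        grid=config.svm_grid,
        seed=config.stage_seed("classify"),
    )
    results.update(ensemble=ensemble, metrics=metrics)

    pairs: dict[str, tuple[float, float]] = {}
    if icns_fu:
        feats_fu = classify.build_features(icns_fu)
        pairs = classify.score_followup(ensemble, feats_fu)
        results["score_pairs"] = pairs

    _write_classify_outputs(out, ensemble, metrics, pairs)
    manifest.add_stage(
        "classify",
        outputs={
            "scores": out / "scores.csv",
            "metrics": out / "metrics.json",
            "selection_frequency": out / "selection_frequency.csv",
        },
        accuracy=metrics.accuracy,
    )

    # --- statistics ----------------------------------------------------
    stats_out: dict = {}
    seed_stats = config.stage_seed("stats")
    if pairs:
        pre = np.array([v[0] for v in pairs.values()])
        post = np.array([v[1] for v in pairs.values()])
        if int(np.sum(pre > 0)) >= 3:
            stats_out["score_decrease_p"] = stats.perm_score_decrease(
                pre,
                post,
                n_perm=config.n_perm_scores,
                seed=seed_stats,
                exclude_nonpositive_baseline=True,
            )

        # voxelwise pre/post connectivity change on the anchor components
        fu_sids = list(pairs)
        tc_by = {(i.subject_id, i.session): i for i in icns_base + icns_fu}
        scan_by = {(s.subject_id, s.session): s for s in cleaned}
        for comp in anchors:
            fc_pre, fc_post = [], []
            for sid in fu_sids:
                for ses, dest in (("baseline", fc_pre), ("followup", fc_post)):
                    m = icn.fc_map(
                        scan_by[(sid, ses)], tc_by[(sid, ses)].timecourses[comp]
                    )
                    m.component = comp
                    dest.append(m)
            if len(fc_pre) >= 3:
                res = stats.paired_perm_test(
                    fc_pre,
                    fc_post,
                    n_perm=config.n_perm_maps,
                    alpha=config.alpha,
                    seed=seed_stats + comp,
                )
                stats_out[f"fc_change_component_{comp}"] = {
                    "significant_fraction": float(res.mask.mean()),
                    "n_pairs": res.n_pairs,
                }

        # association between baseline scores and normalized response
        fu_records = records[records.session == "followup"]
        assoc_sids = [s for s in fu_sids if s in set(fu_records.subject_id)]
        if len(assoc_sids) >= 7:
            resp = stats.response_table(records).loc[assoc_sids]
            cov = base_records.loc[
                assoc_sids, ["age", "sex", "education_years", "illness_years"]
            ]
            scores_v = np.array([pairs[s][0] for s in assoc_sids])
            assoc = stats.score_response_association(
                scores_v, resp, cov, family_size=config.family_size
            )
            results["associations"] = assoc
            pd.DataFrame(
                [
                    dict(
                        measure=a.measure,
                        rho=a.rho,
                        p_raw=a.p_raw,
                        p_bonferroni=a.p_bonferroni,
                        n=a.n,
                        outliers_removed=len(a.outlier_indices),
                        rho_no_outliers=a.rho_no_outliers,
                    )
                    for a in assoc.values()
                ]
            ).to_csv(out / "associations.csv", index=False)

    results["stats"] = stats_out
    with open(out / "stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2)
    manifest.add_stage("stats", outputs={"stats": out / "stats.json"})

    manifest.write(out / "manifest.json")
    return manifest, results
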