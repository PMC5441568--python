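"""Readers and writers for the on-disk formats the pipeline consumes:
NIfTI-1 scans, nuisance-regressor TSVs and the phenotype table."""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from icnpipe.errors import FormatError, InvalidInputError, SchemaError
from icnpipe.preprocess import NuisanceSet, Scan

__all__ = [
    "read_scan",
    "write_scan",
    "read_nuisance",
    "write_nuisance",
    "read_phenotypes",
    "PHENOTYPE_COLUMNS",
]

PHENOTYPE_COLUMNS = [
    "subject_id",
    "group",
    "arm",
    "session",
    "age",
    "sex",
    "education_years",
    "illness_years",
    "panss_total",
    "panss_pos",
    "panss_neg",
    "panss_gen",
]

_FNAME_RE = re.compile(r"sub-(?P<sid>[^_]+)_ses-(?P<ses>[^_]+)")


def write_scan(scan: Scan, path: str | Path) -> None:
    """Write a scan as uncompressed NIfTI-1; TR goes into pixdim[4]."""
    img = nib.Nifti1Image(np.asarray(scan.data, dtype=np.float64), affine=_affine(scan))
    img.header.set_zooms((*scan.voxel_size_mm, scan.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def _affine(scan: Scan) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = scan.voxel_size_mm
    return aff


def read_scan(
    path: str | Path, subject_id: str | None = None, session: str | None = None
) -> Scan:
    """Read a 4-D NIfTI-1 scan. Subject id and session default to the
    ``sub-<id>_ses-<session>`` tokens of the filename when present."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4-D data, got shape {data.shape}")
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    m = _FNAME_RE.search(path.name)
    if subject_id is None:
        subject_id = m.group("sid") if m else path.stem
    if session is None:
        session = m.group("ses") if m else "baseline"
    return Scan(
        data=data,
        tr_seconds=tr,
        subject_id=subject_id,
        session=session,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
    )


def write_nuisance(nuisance: NuisanceSet, path: str | Path) -> None:
    cols = {f"motion_{i + 1}": nuisance.motion[:, i] for i in range(6)}
    cols["wm"] = nuisance.wm
    cols["csf"] = nuisance.csf
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_nuisance(path: str | Path) -> NuisanceSet:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot read nuisance file {path}: {exc}") from exc
    motion_cols = [f"motion_{i + 1}" for i in range(6)]
    missing = [c for c in motion_cols + ["wm", "csf"] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing nuisance columns {missing}")
    return NuisanceSet(
        motion=df[motion_cols].to_numpy(),
        wm=df["wm"].to_numpy(),
        csf=df["csf"].to_numpy(),
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate the phenotype CSV.

    Enforces the column schema, the group/arm/session vocabularies and
    subject_id+session uniqueness; PANSS values may be missing for controls.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse phenotype CSV {path}: {exc}") from exc
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col, allowed in (
        ("group", {"patient", "control"}),
        ("arm", {"ECT", "MED", "none"}),
        ("session", {"baseline", "followup"}),
    ):
        bad = df.loc[~df[col].isin(allowed)]
        if len(bad):
            raise SchemaError(
                f"{path}: illegal {col} value(s) {sorted(bad[col].unique())} "
                f"in row(s) {bad.index.tolist()}; allowed: {sorted(allowed)}"
            )
    dup = df.duplicated(subset=["subject_id", "session"])
    if dup.any():
        raise SchemaError(
            f"{path}: duplicate subject_id+session in rows {df.index[dup].tolist()}"
        )
    followup = df[df.session == "followup"]
    baseline_ids = set(df.loc[df.session == "baseline", "subject_id"])
    orphans = set(followup.subject_id) - baseline_ids
    if orphans:
        raise SchemaError(f"{path}: follow-up rows without baseline: {sorted(orphans)}")
    return df


def validate_scan_matches(scan: Scan, expected_volumes: int) -> None:
    if scan.n_volumes != expected_volumes:
        raise InvalidInputError(
            f"scan {scan.subject_id}/{scan.session} has {scan.n_volumes} "
            f"volumes, expected {expected_volumes}"
        )
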