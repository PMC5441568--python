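"""Temporal and spatial cleaning of already-aligned 4-D scans.

The chain is: discard equilibration volumes, scale to a global mean,
zero-phase band-pass, nuisance + trend regression, Gaussian smoothing.
All stages operate on :class:`Scan` objects and return new scans; no
stage mutates its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from icnpipe.errors import InvalidConfigurationError, InvalidInputError

__all__ = [
    "Scan",
    "NuisanceSet",
    "PreprocessParams",
    "drop_initial_volumes",
    "intensity_scale",
    "bandpass",
    "regress_nuisance",
    "smooth",
    "preprocess_scan",
]


@dataclass
class Scan:
    """A 4-D intensity grid (x, y, z, volume) with acquisition metadata."""

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    session: str = "baseline"
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise InvalidInputError(
                f"scan data must be 4-D (x, y, z, volume); got ndim={self.data.ndim}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidInputError("scan contains non-finite values")
        if self.tr_seconds <= 0:
            raise InvalidInputError(f"tr_seconds must be positive; got {self.tr_seconds}")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def timeseries(self) -> np.ndarray:
        """Return data as (volume, voxel) with voxels flattened in C order."""
        return self.data.reshape(-1, self.n_volumes).T


@dataclass
class NuisanceSet:
    """Motion, white-matter and CSF regressor series for one scan."""

    motion: np.ndarray  # (volumes, 6)
    wm: np.ndarray  # (volumes,)
    csf: np.ndarray  # (volumes,)

    def __post_init__(self) -> None:
        self.motion = np.atleast_2d(np.asarray(self.motion, dtype=np.float64))
        if self.motion.shape[1] != 6:
            if self.motion.shape[0] == 6:
                self.motion = self.motion.T
            else:
                raise InvalidInputError(
                    f"motion must have 6 regressors; got shape {self.motion.shape}"
                )
        self.wm = np.asarray(self.wm, dtype=np.float64).ravel()
        self.csf = np.asarray(self.csf, dtype=np.float64).ravel()
        n = self.motion.shape[0]
        if len(self.wm) != n or len(self.csf) != n:
            raise InvalidInputError("motion, wm and csf series lengths differ")

    @property
    def n_volumes(self) -> int:
        return self.motion.shape[0]

    def as_matrix(self) -> np.ndarray:
        """Stack the 8 nuisance series as columns (volumes, 8)."""
        return np.column_stack([self.motion, self.wm, self.csf])

    def drop_initial(self, k: int) -> "NuisanceSet":
        return NuisanceSet(self.motion[k:], self.wm[k:], self.csf[k:])


@dataclass
class PreprocessParams:
    """Parameters for the full cleaning chain (defaults follow the pipeline
    configuration used everywhere else in the package)."""

    k_drop: int = 6
    target_mean: float = 10000.0
    low_hz: float = 0.01
    high_hz: float = 0.08
    fwhm_mm: float = 6.0
    do_drop: bool = True
    do_scale: bool = True
    do_bandpass: bool = True
    do_regress: bool = True
    do_smooth: bool = True


def drop_initial_volumes(scan: Scan, k: int = 6) -> Scan:
    """Discard the first ``k`` volumes (magnetization equilibration)."""
    if k < 0:
        raise InvalidConfigurationError(f"k must be non-negative; got {k}")
    if scan.n_volumes <= k:
        raise InvalidInputError(
            f"scan has {scan.n_volumes} volumes; cannot drop {k}"
        )
    return replace(
        scan,
        data=scan.data[..., k:].copy(),
        provenance=scan.provenance + [f"drop_initial_volumes(k={k})"],
    )


def intensity_scale(scan: Scan, target: float = 10000.0) -> Scan:
    """Rescale by one positive factor so the whole-scan mean equals ``target``."""
    mean = float(scan.data.mean())
    if mean <= 0:
        raise InvalidInputError(f"whole-scan mean must be positive; got {mean}")
    factor = target / mean
    return replace(
        scan,
        data=scan.data * factor,
        provenance=scan.provenance + [f"intensity_scale(target={target})"],
    )


def _bandpass_mask(n: int, tr: float, low: float, high: float) -> np.ndarray:
    """Frequency-domain gain for ``rfft`` bins: 1 inside [low, high], else 0.

    Binary at bin resolution, so the filter is exactly idempotent and
    zero-phase; DC is always removed.
    """
    freqs = np.fft.rfftfreq(n, d=tr)
    gain = ((freqs >= low) & (freqs <= high)).astype(float)
    gain[freqs == 0] = 0.0
    return gain


def bandpass(scan: Scan, low_hz: float = 0.01, high_hz: float = 0.08) -> Scan:
    """Zero-phase temporal band-pass via frequency-domain masking."""
    nyquist = 1.0 / (2.0 * scan.tr_seconds)
    if not (0 < low_hz < high_hz < nyquist):
        raise InvalidConfigurationError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:.4g} Hz)"
        )
    n = scan.n_volumes
    gain = _bandpass_mask(n, scan.tr_seconds, low_hz, high_hz)
    spectra = np.fft.rfft(scan.data, axis=3)
    filtered = np.fft.irfft(spectra * gain, n=n, axis=3)
    return replace(
        scan,
        data=filtered,
        provenance=scan.provenance + [f"bandpass({low_hz}, {high_hz})"],
    )


def _design_matrix(nuisance: NuisanceSet) -> np.ndarray:
    """Intercept + linear + quadratic trend + 8 nuisance series, one column
    each, as an orthonormal basis (QR) of the span."""
    n = nuisance.n_volumes
    t = np.linspace(-1.0, 1.0, n)
    design = np.column_stack([np.ones(n), t, t**2, nuisance.as_matrix()])
    q, r = np.linalg.qr(design)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def regress_nuisance(scan: Scan, nuisance: NuisanceSet) -> Scan:
    """Project out nuisance series plus intercept, linear and quadratic trends."""
    if nuisance.n_volumes != scan.n_volumes:
        raise InvalidInputError(
            f"nuisance length {nuisance.n_volumes} != scan volumes {scan.n_volumes}"
        )
    q = _design_matrix(nuisance)
    ts = scan.timeseries()  # (volumes, voxels)
    resid = ts - q @ (q.T @ ts)
    data = resid.T.reshape(scan.data.shape)
    return replace(
        scan,
        data=data,
        provenance=scan.provenance + ["regress_nuisance(trends+motion+wm+csf)"],
    )


def smooth(scan: Scan, fwhm_mm: float = 6.0) -> Scan:
    """Spatial Gaussian smoothing with the stated FWHM in millimetres.

    Edge handling is renormalized truncated-kernel convolution: the data are
    convolved with zero padding and divided by the convolved all-ones mask, so
    constants are preserved exactly and interior mass is conserved.
    """
    if fwhm_mm < 0:
        raise InvalidConfigurationError(f"fwhm_mm must be >= 0; got {fwhm_mm}")
    if fwhm_mm == 0:
        return replace(scan, provenance=scan.provenance + ["smooth(fwhm=0)"])
    sigmas = tuple(
        fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs for vs in scan.voxel_size_mm
    )
    norm = ndimage.gaussian_filter(
        np.ones(scan.grid_shape), sigma=sigmas, mode="constant", cval=0.0
    )
    out = np.empty_like(scan.data)
    for v in range(scan.n_volumes):
        out[..., v] = (
            ndimage.gaussian_filter(scan.data[..., v], sigma=sigmas, mode="constant", cval=0.0)
            / norm
        )
    return replace(
        scan, data=out, provenance=scan.provenance + [f"smooth(fwhm={fwhm_mm}mm)"]
    )


def preprocess_scan(
    scan: Scan,
    nuisance: NuisanceSet | None,
    params: PreprocessParams | None = None,
) -> Scan:
    """Apply drop -> scale -> bandpass -> regress -> smooth in order.

    ``nuisance`` series must cover the untrimmed scan; they are trimmed in
    lockstep with the volumes. Stages can be disabled individually through
    ``params``; provenance of applied steps is recorded on the result.
    """
    params = params or PreprocessParams()
    out = scan
    nuis = nuisance
    if params.do_drop and params.k_drop > 0:
        if nuis is not None:
            if nuis.n_volumes != scan.n_volumes:
                raise InvalidInputError(
                    f"nuisance length {nuis.n_volumes} != scan volumes {scan.n_volumes}"
                )
            nuis = nuis.drop_initial(params.k_drop)
        out = drop_initial_volumes(out, params.k_drop)
    if params.do_scale:
        out = intensity_scale(out, params.target_mean)
    if params.do_bandpass:
        out = bandpass(out, params.low_hz, params.high_hz)
    if params.do_regress:
        if nuis is None:
            raise InvalidInputError("nuisance regressors required when do_regress=True")
        out = regress_nuisance(out, nuis)
    if params.do_smooth:
        out = smooth(out, params.fwhm_mm)
    return out
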