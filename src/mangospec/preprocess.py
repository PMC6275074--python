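"""Spectral preprocessing: Savitzky-Golay smoothing, SNV and MSC.

All three operate row-wise on a SpectraMatrix (one spectrum per sample) and
preserve shape and sample order.  SNV and MSC both target multiplicative
scatter: SNV standardises each spectrum to zero mean and unit dispersion,
MSC regresses each spectrum onto a reference ("ideal") spectrum and inverts
the fitted affine distortion.  The MSC reference is the column-wise mean of
the calibration set, frozen at fit time so that validation spectra are
corrected without information leakage.

Conventions pinned here: SNV uses the sample standard deviation (n-1
denominator); S-G edges are handled by a polynomial fit on the truncated
window (no mirroring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .hsi_io import WavelengthGrid

__all__ = [
    "SpectraMatrix",
    "MscReference",
    "savitzky_golay",
    "snv",
    "msc_fit",
    "msc_apply",
    "apply_named",
]


@dataclass
class SpectraMatrix:
    """n x p matrix of spectra on a shared wavelength grid."""

    sample_ids: list[str]
    grid: WavelengthGrid
    values: np.ndarray
    provenance: str = "raw"

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal row count")
        if p != self.grid.count:
            raise ValueError("column count must equal grid count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, provenance: str) -> "SpectraMatrix":
        return SpectraMatrix(list(self.sample_ids), self.grid, values, provenance)

    def subset_bands(self, idx: np.ndarray) -> "SpectraMatrix":
        idx = np.asarray(idx, dtype=int)
        return SpectraMatrix(
            list(self.sample_ids),
            WavelengthGrid(self.grid.values[idx]),
            self.values[:, idx],
            provenance=self.provenance,
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.grid.values
        )
        df.index.name = "sample_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, provenance: str = "raw") -> "SpectraMatrix":
        df = pd.read_csv(path, index_col=0)
        grid = WavelengthGrid(np.array([float(c) for c in df.columns]))
        return cls(list(df.index.astype(str)), grid, df.to_numpy(float), provenance)


@dataclass
class MscReference:
    """Frozen MSC reference spectrum plus per-application fit coefficients."""

    reference: np.ndarray
    grid: WavelengthGrid
    last_fit: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.reference = np.asarray(self.reference, dtype=float).ravel()
        if self.reference.size != self.grid.count:
            raise ValueError("reference length must match grid")


def savitzky_golay(
    spectra: SpectraMatrix, window: int = 11, polyorder: int = 2
) -> SpectraMatrix:
    """Moving-window local polynomial least-squares smoothing per spectrum."""
    p = spectra.grid.count
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    if window >= p:
        raise ValueError(f"window {window} must be smaller than band count {p}")
    smoothed = savgol_filter(
        spectra.values, window_length=window, polyorder=polyorder, axis=1,
        mode="interp",
    )
    return spectra.with_values(smoothed, provenance="SG")


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: per-spectrum centering and unit scaling."""
    x = spectra.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0)
    if degenerate.size:
        names = [spectra.sample_ids[i] for i in degenerate[:5]]
        raise ValueError(f"constant spectrum cannot be SNV-scaled: {names}")
    return spectra.with_values((x - mean) / sd, provenance="SNV")


def msc_fit(training: SpectraMatrix) -> MscReference:
    """Freeze the MSC reference as the column-wise mean of the training set."""
    if training.n < 2:
        raise ValueError("MSC reference needs at least 2 training spectra")
    return MscReference(training.values.mean(axis=0), training.grid)


def msc_apply(spectra: SpectraMatrix, ref: MscReference) -> SpectraMatrix:
    """Correct each spectrum by inverting its OLS affine fit to the reference.

    For each row x, fit x ~ a + b * ref over bands and return (x - a) / b.
    """
    if ref.grid != spectra.grid:
        raise ValueError("MSC reference grid does not match spectra grid")
    r = ref.reference
    rc = r - r.mean()
    denom = float(rc @ rc)
    x = spectra.values
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < 1e-8):
        bad = [spectra.sample_ids[i] for i in np.flatnonzero(np.abs(b) < 1e-8)[:5]]
        raise ValueError(f"degenerate MSC fit (|slope| < 1e-8) for {bad}")
    a = x.mean(axis=1) - b * r.mean()
    corrected = (x - a[:, None]) / b[:, None]
    ref.last_fit = pd.DataFrame(
        {"sample_id": spectra.sample_ids, "intercept": a, "slope": b}
    )
    return spectra.with_values(corrected, provenance="MSC")


def apply_named(
    spectra: SpectraMatrix,
    method: str,
    *,
    reference: MscReference | None = None,
    window: int = 11,
    polyorder: int = 2,
) -> SpectraMatrix:
    """Dispatch a preprocessing transform by its config name.

    ``method`` is one of ``"snv"``, ``"sg"``, ``"msc"`` or ``"none"``.  MSC
    requires a frozen reference (fit it on the calibration rows only).
    """
    method = method.lower()
    if method == "none":
        return spectra
    if method == "snv":
        return snv(spectra)
    if method == "sg":
        return savitzky_golay(spectra, window=window, polyorder=polyorder)
    if method == "msc":
        if reference is None:
            raise ValueError("msc requires a fitted MscReference")
        return msc_apply(spectra, reference)
    raise ValueError(f"unknown preprocessing method {method!r}")
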