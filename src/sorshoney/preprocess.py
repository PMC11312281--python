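"""Spectral pretreatment chain.

Order of operations is fixed: crop -> modified-polynomial baseline
subtraction -> Savitzky-Golay smoothing -> SNV row normalisation ->
replicate averaging.  The chain turns raw detector counts (Raman signal
riding on a large smooth fluorescence background, with per-measurement gain
differences) into comparable per-sample spectra.

ModPoly here is the plain min-replacement variant: iteratively fit a
polynomial to the working spectrum by least squares, clip the working
spectrum to the pointwise minimum of itself and the fit, and stop when the
fitted curve changes by less than a relative tolerance.  The axis is
rescaled to [-1, 1] before fitting for numerical conditioning.

SNV uses the sample (n-1 denominator) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet

logger = logging.getLogger(__name__)

# Information-rich crop windows used in the two acquisition campaigns.
YEAR1_CROP = (337.8, 1470.9)
YEAR2_CROP = (585.0, 1550.0)


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Tunable parameters of the pretreatment chain.

    Defaults match the published pipeline where it is explicit (SG window 31,
    polynomial order 7, derivative order 0; crop window) and the common
    ModPoly defaults where it is not (degree 4, 100 iterations, tol 1e-3).
    """

    crop_lo: float = YEAR2_CROP[0]
    crop_hi: float = YEAR2_CROP[1]
    baseline_degree: int = 4
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-3
    sg_window: int = 31
    sg_polyorder: int = 7
    sg_derivorder: int = 0

    def __post_init__(self) -> None:
        if not self.crop_lo < self.crop_hi:
            raise PreprocessError("crop_lo must be < crop_hi")
        if self.baseline_degree < 1 or self.baseline_max_iter < 1 or self.baseline_tol <= 0:
            raise PreprocessError("invalid baseline parameters")
        if self.sg_window % 2 != 1:
            raise PreprocessError("sg_window must be odd")
        if not (0 <= self.sg_derivorder <= self.sg_polyorder < self.sg_window):
            raise PreprocessError("need 0 <= derivorder <= polyorder < window")


def year1_config(**overrides) -> PreprocessConfig:
    return PreprocessConfig(crop_lo=YEAR1_CROP[0], crop_hi=YEAR1_CROP[1], **overrides)


def year2_config(**overrides) -> PreprocessConfig:
    return PreprocessConfig(**overrides)


def crop_range(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep exactly the axis points in the closed interval [lo, hi]."""
    mask = (sset.axis >= lo) & (sset.axis <= hi)
    if not mask.any():
        raise PreprocessError(f"crop [{lo}, {hi}] leaves no axis points")
    return SpectraSet(sset.axis[mask], sset.intensities[:, mask], sset.meta)


def modpoly_baseline(
    spectrum: np.ndarray,
    axis: np.ndarray,
    degree: int = 4,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Modified-polynomial baseline of one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum - baseline``.
    Convergence: max relative change of the fitted curve between successive
    iterations < ``tol``, or ``max_iter`` reached.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if not np.all(np.isfinite(spectrum)):
        raise PreprocessError("non-finite values in spectrum")
    if degree + 1 >= spectrum.size:
        raise PreprocessError(f"degree {degree} too high for {spectrum.size}-point spectrum")

    # rescale axis to [-1, 1] for conditioning
    x = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
    working = spectrum.copy()
    previous_fit: np.ndarray | None = None
    for _ in range(max_iter):
        coef = np.polynomial.polynomial.polyfit(x, working, degree)
        fit = np.polynomial.polynomial.polyval(x, coef)
        if previous_fit is not None:
            scale = np.max(np.abs(fit)) or 1.0
            if np.max(np.abs(fit - previous_fit)) / scale < tol:
                previous_fit = fit
                break
        previous_fit = fit
        working = np.minimum(working, fit)
    baseline = previous_fit
    return baseline, spectrum - baseline


def baseline_correct(sset: SpectraSet, degree: int = 4, max_iter: int = 100, tol: float = 1e-3) -> SpectraSet:
    """Row-wise ModPoly baseline subtraction."""
    corrected = np.empty_like(sset.intensities)
    for i in range(sset.n_measurements):
        _, corrected[i] = modpoly_baseline(sset.intensities[i], sset.axis, degree, max_iter, tol)
    return SpectraSet(sset.axis, corrected, sset.meta)


def savgol_smooth(sset: SpectraSet, window: int = 31, polyorder: int = 7, derivorder: int = 0) -> SpectraSet:
    """Savitzky-Golay smoothing/differentiation of every row.

    Edges are handled by the polynomial fit on the one-sided window
    (``mode='interp'``), so the filter reproduces polynomials of degree
    <= polyorder exactly everywhere.
    """
    if window % 2 != 1:
        raise PreprocessError("window must be odd")
    if window > sset.axis.size:
        raise PreprocessError(f"window {window} exceeds axis length {sset.axis.size}")
    delta = float(np.mean(np.diff(sset.axis)))
    smoothed = savgol_filter(
        sset.intensities, window_length=window, polyorder=polyorder, deriv=derivorder,
        delta=delta, axis=1, mode="interp",
    )
    return SpectraSet(sset.axis, smoothed, sset.meta)


def snv_normalise(sset: SpectraSet) -> SpectraSet:
    """Standard normal variate: per row, subtract mean and divide by sd (n-1)."""
    means = sset.intensities.mean(axis=1, keepdims=True)
    sds = sset.intensities.std(axis=1, ddof=1, keepdims=True)
    # effectively-constant rows (incl. flat spectra reduced to rounding noise
    # by the baseline step) cannot be standardised
    floor = 1e-10 * np.maximum(1.0, np.abs(means))
    zero = np.where((sds < floor).ravel())[0]
    if zero.size:
        ids = sset.meta.loc[zero, "measurement_id"].tolist()
        raise PreprocessError(f"zero-variance rows cannot be SNV-normalised: {ids}")
    return SpectraSet(sset.axis, (sset.intensities - means) / sds, sset.meta)


def average_replicates(sset: SpectraSet) -> SpectraSet:
    """Collapse technical replicates: one mean spectrum per sample_id.

    Output metadata keeps one record per sample (first-appearance order)
    with ``replicate`` set to 0 and ``measurement_id`` = sample_id.
    """
    order = sset.meta["sample_id"].drop_duplicates().tolist()
    groups = {sid: np.where(sset.meta["sample_id"] == sid)[0] for sid in order}
    rows = np.vstack([sset.intensities[idx].mean(axis=0) for idx in (groups[s] for s in order)])
    meta = sset.meta.drop_duplicates(subset="sample_id", keep="first").copy()
    meta = meta.set_index("sample_id").loc[order].reset_index()
    meta["replicate"] = 0
    meta["measurement_id"] = meta["sample_id"]
    meta = meta.loc[:, list(sset.meta.columns)]
    return SpectraSet(sset.axis, rows, meta)


def preprocess_pipeline(sset: SpectraSet, cfg: PreprocessConfig | None = None) -> SpectraSet:
    """Full chain: crop -> baseline -> SG smooth -> SNV -> replicate average."""
    cfg = cfg or PreprocessConfig()
    out = crop_range(sset, cfg.crop_lo, cfg.crop_hi)
    logger.info("crop [%g, %g]: %s points kept", cfg.crop_lo, cfg.crop_hi, out.axis.size)
    out = baseline_correct(out, cfg.baseline_degree, cfg.baseline_max_iter, cfg.baseline_tol)
    logger.info("ModPoly(degree=%d) baseline subtracted", cfg.baseline_degree)
    out = savgol_smooth(out, cfg.sg_window, cfg.sg_polyorder, cfg.sg_derivorder)
    logger.info("Savitzky-Golay(%d, %d, deriv=%d) applied", cfg.sg_window, cfg.sg_polyorder, cfg.sg_derivorder)
    out = snv_normalise(out)
    out = average_replicates(out)
    logger.info("SNV + replicate averaging: %d rows x %d points", out.n_measurements, out.axis.size)
    return out
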