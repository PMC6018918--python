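"""BOLD preprocessing: trim, despike, nuisance regression, smoothing, band-pass.

The stages are applied in the fixed order

    trim -> despike -> nuisance regression -> spatial smoothing -> band-pass

which is the standard resting-state denoising order (temporal artifact
removal before spatial operations, filtering last so regression does not
reintroduce out-of-band energy). :func:`preprocess_series` runs the full
chain; each stage is also exposed on its own.

Despiking uses a per-voxel quadratic detrend and a hyperbolic-tangent
compression of large residuals measured in MAD-based robust standard
deviations: residuals below ``c1`` robust SDs pass unchanged, larger ones are
compressed toward and capped at ``c2`` robust SDs. Band-pass filtering is a
zero-phase (forward-backward) Butterworth filter of order 2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal as sps

from fcdecode.types import BoldSeries, NuisanceSet

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def trim_volumes(series: BoldSeries, n_trim: int) -> BoldSeries:
    """Drop the first ``n_trim`` volumes (T1-equilibration discard)."""
    if n_trim < 0:
        raise ValueError("n_trim must be nonnegative")
    if n_trim >= series.n_timepoints:
        raise ValueError(
            f"cannot trim {n_trim} volumes from a series of {series.n_timepoints}"
        )
    return series.with_data(series.data[..., n_trim:])


def despike(series: BoldSeries, c1: float = 2.5, c2: float = 4.0) -> BoldSeries:
    """Compress transient spikes voxelwise.

    Per voxel: fit a quadratic trend by least squares, express residuals in
    robust SDs (1.4826 x median absolute deviation), and map residual
    magnitudes s > c1 to ``c1 + (c2 - c1) * tanh((s - c1) / (c2 - c1))``,
    which caps them at ``c2``. Voxels with near-zero residual spread are
    returned untouched.
    """
    if not c2 > c1 > 0:
        raise ValueError("need 0 < c1 < c2")
    t = series.n_timepoints
    if t < 8:
        raise ValueError("despike needs at least 8 timepoints")
    flat = series.data.reshape(-1, t)
    x = np.linspace(-1.0, 1.0, t)
    design = np.column_stack([np.ones(t), x, x**2])
    coef, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    trend = (design @ coef).T
    resid = flat - trend

    mad = np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)), axis=1)
    sigma = 1.4826 * mad
    ok = sigma > 1e-12 * (np.abs(flat).max(axis=1) + 1.0)
    s = np.zeros_like(resid)
    s[ok] = resid[ok] / sigma[ok, None]

    mag = np.abs(s)
    over = mag > c1
    span = c2 - c1
    compressed = np.where(over, np.sign(s) * (c1 + span * np.tanh((mag - c1) / span)), s)
    out = np.where(ok[:, None], trend + compressed * sigma[:, None], flat)
    return series.with_data(out.reshape(series.data.shape))


def regress_nuisance(series: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Project out ventricular and motion regressors voxelwise.

    Each in-mask voxel time series is replaced by its least-squares residual
    against the design ``[intercept | ventricular | motion x 6]``; residuals
    are orthogonal to every design column.
    """
    t = series.n_timepoints
    if nuisance.n_timepoints != t:
        raise ValueError(
            f"nuisance rows ({nuisance.n_timepoints}) do not match series length ({t})"
        )
    design, names = nuisance.design_matrix()
    # rank check with column attribution via pivoted QR diagonal
    _, r_diag, piv = _qr_rank(design)
    rank = int((r_diag > 1e-10 * max(r_diag[0], 1.0)).sum())
    if rank < design.shape[1]:
        bad = [names[piv[i]] for i in range(rank, design.shape[1])]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")

    flat = series.data.reshape(-1, t)
    mask = series.brain_mask.ravel()
    y = flat[mask].T  # t x V
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = flat.copy()
    out[mask] = resid.T
    return series.with_data(out.reshape(series.data.shape))


def _qr_rank(a: np.ndarray):
    from scipy.linalg import qr

    _, r, piv = qr(a, mode="economic", pivoting=True)
    return r, np.abs(np.diag(r)), piv


def smooth_spatial(series: BoldSeries, fwhm_mm: float = 0.6) -> BoldSeries:
    """Mask-normalized Gaussian smoothing of each volume.

    The kernel width is ``sigma_mm = fwhm / (2 sqrt(2 ln 2))`` converted to
    voxel units per axis. Smoothing is normalized within the brain mask
    (numerator and denominator both masked) so out-of-mask values never bleed
    in; out-of-mask voxels are left unmodified.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return series.with_data(series.data.copy())
    sigma_vox = [
        fwhm_mm * GAUSS_FWHM_TO_SIGMA / vs for vs in series.voxel_size_mm
    ]
    mask = series.brain_mask
    maskf = mask.astype(float)
    den = ndimage.gaussian_filter(maskf, sigma=sigma_vox)
    out = series.data.copy()
    for j in range(series.n_timepoints):
        vol = series.data[..., j]
        num = ndimage.gaussian_filter(vol * maskf, sigma=sigma_vox)
        sm = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
        out[..., j] = np.where(mask, sm, vol)
    return series.with_data(out)


def bandpass_filter(
    series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 2
) -> BoldSeries:
    """Zero-phase Butterworth band-pass along the time axis (in-mask voxels)."""
    nyquist = 0.5 / series.tr_seconds
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz ({high_hz}) must be below the Nyquist frequency ({nyquist:.4f} Hz)"
        )
    fs = 1.0 / series.tr_seconds
    if low_hz > 0:
        sos = sps.butter(order, [low_hz, high_hz], btype="band", fs=fs, output="sos")
    else:
        sos = sps.butter(order, high_hz, btype="low", fs=fs, output="sos")
    flat = series.data.reshape(-1, series.n_timepoints)
    mask = series.brain_mask.ravel()
    out = flat.copy()
    out[mask] = sps.sosfiltfilt(sos, flat[mask], axis=1)
    return series.with_data(out.reshape(series.data.shape))


def fluctuation_amplitude(series: BoldSeries, roi_mask: np.ndarray) -> float:
    """Temporal SD of the ROI-mean signal (anesthesia-depth QC readout)."""
    roi = np.asarray(roi_mask, dtype=bool) & series.brain_mask
    if not roi.any():
        raise ValueError("ROI does not intersect the brain mask")
    course = series.data[roi].mean(axis=0)
    return float(course.std())


def preprocess_series(
    series: BoldSeries,
    nuisance: NuisanceSet,
    n_trim: int = 20,
    despike_c1: float = 2.5,
    despike_c2: float = 4.0,
    fwhm_mm: float = 0.6,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> BoldSeries:
    """Full preprocessing chain in the fixed pipeline order.

    The nuisance set is trimmed to match the retained volumes (its rows are
    expected to cover the raw series, one per volume).
    """
    out = trim_volumes(series, n_trim)
    nuis = nuisance.trimmed(n_trim) if nuisance.n_timepoints == series.n_timepoints else nuisance
    out = despike(out, despike_c1, despike_c2)
    out = regress_nuisance(out, nuis)
    out = smooth_spatial(out, fwhm_mm)
    out = bandpass_filter(out, low_hz, high_hz)
    return out
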