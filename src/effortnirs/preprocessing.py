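"""Continuous-wave fNIRS preprocessing stages.

The pipeline order is fixed: step-artifact removal on raw intensity, channel
quality control by scalp coupling index (SCI), conversion to optical density,
wavelet motion correction, modified Beer-Lambert conversion to hemoglobin,
wide band-pass (0.01-1.5 Hz), short-separation regression of superficial
physiology, and a final narrow band-pass (0.01-0.09 Hz). Each stage is a
plain function over arrays so it can be tested in isolation; ``run_pipeline``
composes them and records what every stage did in a QC report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from .constants import DEFAULT_DPF, extinction_matrix
from .probe_io import ProbeMontage, RawRecording, nearest_short_channel
from .series import HbSeries, ODSeries

CANONICAL_STAGES = (
    "step_removal",
    "sci_rejection",
    "optical_density",
    "wavelet_correction",
    "beer_lambert",
    "bandpass_wide",
    "short_separation_regression",
    "bandpass_narrow",
)


@dataclass
class PipelineParams:
    """Tunable parameters; defaults are the analysis' stated values."""

    k_sd: float = 2.0
    sci_threshold: float = 0.75
    sci_band: tuple = (0.5, 1.5)
    wavelet: str = "db2"
    wavelet_level: int = 5
    iqr_k: float = 0.1
    band_wide_hz: tuple = (0.01, 1.5)
    band_narrow_hz: tuple = (0.01, 0.09)
    dpf: float = DEFAULT_DPF
    stages: tuple = CANONICAL_STAGES


@dataclass
class QCReport:
    """Per-channel quality metrics and a log of every stage's actions."""

    sci: np.ndarray
    rejected: np.ndarray
    threshold: float
    channel_names: list
    zeroed_derivative_samples: np.ndarray | None = None
    wavelet_coefficients_shrunk: np.ndarray | None = None
    stage_log: list = field(default_factory=list)

    @property
    def fraction_rejected(self) -> float:
        return float(np.mean(self.rejected))

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "fraction_rejected": self.fraction_rejected,
            "channels": [
                {
                    "name": self.channel_names[i],
                    "sci": float(self.sci[i]),
                    "rejected": bool(self.rejected[i]),
                    "zeroed_derivative_samples": (
                        int(self.zeroed_derivative_samples[i].sum())
                        if self.zeroed_derivative_samples is not None
                        else None
                    ),
                    "wavelet_coefficients_shrunk": (
                        int(self.wavelet_coefficients_shrunk[i].sum())
                        if self.wavelet_coefficients_shrunk is not None
                        else None
                    ),
                }
                for i in range(len(self.channel_names))
            ],
            "stage_log": list(self.stage_log),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# stage 1: step-like noise


def remove_step_noise(intensity: np.ndarray, k_sd: float = 2.0) -> np.ndarray:
    """Zero abrupt jumps in the intensity derivative and re-integrate.

    Per series, the first difference d is computed; samples with
    |d| > mean(d) + k_sd * SD(d) are zeroed; the series is rebuilt as the
    first sample plus the cumulative sum of the modified derivative. A pure
    ramp (constant derivative, SD = 0) passes through unchanged.
    """
    x = np.asarray(intensity, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("series too short for derivative-based step removal")
    flat = x.reshape(x.shape[0], -1)
    d = np.diff(flat, axis=0)
    thr = d.mean(axis=0) + k_sd * d.std(axis=0)
    # float-equality guard: a constant derivative (SD = 0) must pass untouched
    eps = 1e-9 * np.maximum(np.abs(d).max(axis=0), 1e-300)
    zeroed = np.abs(d) > thr + eps
    d = np.where(zeroed, 0.0, d)
    out = np.concatenate([flat[:1], flat[:1] + np.cumsum(d, axis=0)], axis=0)
    return out.reshape(x.shape)


def count_zeroed_derivative(intensity: np.ndarray, k_sd: float = 2.0) -> np.ndarray:
    """Number of derivative samples the step-removal stage zeroes, per series."""
    x = np.asarray(intensity, dtype=float).reshape(intensity.shape[0], -1)
    d = np.diff(x, axis=0)
    thr = d.mean(axis=0) + k_sd * d.std(axis=0)
    eps = 1e-9 * np.maximum(np.abs(d).max(axis=0), 1e-300)
    return (np.abs(d) > thr + eps).sum(axis=0).reshape(intensity.shape[1:])


# ---------------------------------------------------------------------------
# stage 2: scalp coupling index


def _butter_bandpass(lo_hz: float, hi_hz: float, fs: float, order: int = 3):
    if not (0 < lo_hz < hi_hz < fs / 2):
        raise ValueError(f"invalid band ({lo_hz}, {hi_hz}) Hz at fs={fs} Hz")
    return signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs)


def scalp_coupling_index(
    intensity_760: np.ndarray,
    intensity_850: np.ndarray,
    fs: float,
    band: tuple = (0.5, 1.5),
) -> float:
    """Cardiac-band correlation between the two wavelengths of one channel.

    Both series are zero-phase band-pass filtered to the cardiac band and
    Pearson-correlated; a well-coupled optode sees the same heartbeat at both
    wavelengths, so SCI near 1 indicates good scalp contact.
    """
    x, y = np.asarray(intensity_760, float), np.asarray(intensity_850, float)
    if x.shape != y.shape:
        raise ValueError("wavelength series must have equal length")
    if x.shape[0] < 10 * fs:
        raise ValueError("need at least 10 s of data for a stable SCI")
    b, a = _butter_bandpass(band[0], band[1], fs)
    xf = signal.filtfilt(b, a, x)
    yf = signal.filtfilt(b, a, y)
    sx, sy = xf.std(), yf.std()
    # below numerical residue of the filter there is no cardiac content to correlate
    tiny_x = 1e-10 * max(float(np.abs(x).max()), 1e-300)
    tiny_y = 1e-10 * max(float(np.abs(y).max()), 1e-300)
    if sx <= tiny_x or sy <= tiny_y:
        warnings.warn("zero variance in cardiac band; SCI set to 0")
        return 0.0
    return float(np.corrcoef(xf, yf)[0, 1])


def reject_channels(recording: RawRecording, threshold: float = 0.75, band: tuple = (0.5, 1.5)) -> QCReport:
    """Score every channel's SCI and flag whole channels below threshold."""
    n_ch = recording.montage.n_channels
    sci = np.empty(n_ch)
    for c in range(n_ch):
        sci[c] = scalp_coupling_index(
            recording.intensity[:, c, 0], recording.intensity[:, c, 1], recording.fs, band
        )
    rejected = sci < threshold
    return QCReport(
        sci=sci,
        rejected=rejected,
        threshold=threshold,
        channel_names=[ch.name for ch in recording.montage.channels],
    )


# ---------------------------------------------------------------------------
# stage 3: optical density


def intensity_to_od(intensity: np.ndarray, fs: float | None = None, channel_names: list | None = None) -> np.ndarray:
    """OD(t) = -ln(I(t) / mean(I)) per channel x wavelength; mean OD ~ 0."""
    x = np.asarray(intensity, dtype=float)
    if np.any(x <= 0):
        bad = np.argwhere(x <= 0)[0]
        name = channel_names[bad[1]] if channel_names is not None and x.ndim > 1 else str(tuple(bad))
        raise ValueError(f"non-positive intensity sample in channel {name}")
    return -np.log(x / x.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# stage 4: wavelet motion correction


def wavelet_motion_correct(
    od: np.ndarray,
    iqr_k: float = 0.1,
    wavelet: str = "db2",
    level: int = 5,
    return_counts: bool = False,
):
    """Zero outlying wavelet detail coefficients and reconstruct.

    Per series, a multi-level discrete wavelet decomposition is taken and,
    per detail level, coefficients outside [Q1 - iqr_k*IQR, Q3 + iqr_k*IQR]
    are set to zero before reconstruction. Approximation coefficients (the
    slow trend) are untouched. ``iqr_k = inf`` is the identity up to
    reconstruction round-off.
    """
    x = np.asarray(od, dtype=float)
    shape = x.shape
    flat = x.reshape(shape[0], -1)
    n = shape[0]
    w = pywt.Wavelet(wavelet)
    if n < 2 * w.dec_len:
        warnings.warn("series shorter than one filter length; wavelet correction skipped")
        counts = np.zeros(flat.shape[1], dtype=int)
        out = flat.copy()
    else:
        max_level = pywt.dwt_max_level(n, w.dec_len)
        lvl = min(level, max_level)
        out = np.empty_like(flat)
        counts = np.zeros(flat.shape[1], dtype=int)
        for j in range(flat.shape[1]):
            coeffs = pywt.wavedec(flat[:, j], w, level=lvl)
            for k in range(1, len(coeffs)):
                c = coeffs[k]
                q1, q3 = np.percentile(c, [25, 75])
                iqr = q3 - q1
                if np.isinf(iqr_k):
                    continue
                mask = (c < q1 - iqr_k * iqr) | (c > q3 + iqr_k * iqr)
                counts[j] += int(mask.sum())
                coeffs[k] = np.where(mask, 0.0, c)
            out[:, j] = pywt.waverec(coeffs, w)[:n]
    out = out.reshape(shape)
    if return_counts:
        return out, counts.reshape(shape[1:])
    return out


# ---------------------------------------------------------------------------
# stage 5: modified Beer-Lambert law


def od_to_hemoglobin(od: np.ndarray, montage: ProbeMontage, dpf: float = DEFAULT_DPF, fs: float = 10.0) -> HbSeries:
    """Invert the two-wavelength Beer-Lambert system per channel.

    OD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d * DPF with
    concentrations in mM and the emitter-detector separation d in cm; returns
    concentration changes in µM. Linear in OD by construction.
    """
    E = extinction_matrix()
    if abs(np.linalg.det(E)) < 1e-6:
        raise ValueError("extinction matrix is singular; wavelengths degenerate")
    E_inv = np.linalg.inv(E)
    n_times, n_ch, _ = od.shape
    hbo = np.empty((n_times, n_ch))
    hbr = np.empty((n_times, n_ch))
    for ch in montage.channels:
        d = montage.separation(ch)
        conc_mm = od[:, ch.index, :] @ E_inv.T / (d * dpf)
        hbo[:, ch.index] = conc_mm[:, 0] * 1000.0
        hbr[:, ch.index] = conc_mm[:, 1] * 1000.0
    return HbSeries(hbo=hbo, hbr=hbr, fs=fs)


# ---------------------------------------------------------------------------
# stage 6/8: band-pass


def bandpass(series: np.ndarray, lo_hz: float, hi_hz: float, fs: float, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (DC fully removed)."""
    b, a = _butter_bandpass(lo_hz, hi_hz, fs, order)
    return signal.filtfilt(b, a, np.asarray(series, float), axis=0)


# ---------------------------------------------------------------------------
# stage 7: short-separation regression


def short_separation_regress(long_series: np.ndarray, short_series: np.ndarray) -> tuple[np.ndarray, float]:
    """Regress the nearest short channel out of a long channel (GLM residual).

    Fits long = intercept + beta * short by least squares and returns the
    residual, which is orthogonal to the short regressor.
    """
    y = np.asarray(long_series, float)
    s = np.asarray(short_series, float)
    X = np.column_stack([np.ones_like(s), s])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return resid, float(coef[1])


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(recording: RawRecording, params: PipelineParams | None = None) -> tuple[HbSeries, QCReport]:
    """Apply all stages in the fixed canonical order.

    Raises if ``params.stages`` departs from the canonical order (the order is
    part of the method, not a tuning knob) or if every channel fails QC.
    """
    params = params or PipelineParams()
    if tuple(params.stages) != CANONICAL_STAGES:
        raise ValueError(
            "pipeline stage order is fixed; expected "
            f"{CANONICAL_STAGES}, got {tuple(params.stages)}"
        )
    recording.validate()
    montage = recording.montage
    fs = recording.fs
    log = []

    # 1. step removal
    zeroed = count_zeroed_derivative(recording.intensity, params.k_sd)
    intensity = remove_step_noise(recording.intensity, params.k_sd)
    log.append(f"step_removal: zeroed {int(zeroed.sum())} derivative samples")

    # 2. SCI channel rejection
    cleaned = RawRecording(intensity, fs, recording.events, montage, recording.meta)
    qc = reject_channels(cleaned, params.sci_threshold, params.sci_band)
    qc.zeroed_derivative_samples = zeroed
    log.append(
        f"sci_rejection: {int(qc.rejected.sum())}/{montage.n_channels} channels below "
        f"{params.sci_threshold}"
    )
    if qc.rejected.all():
        raise ValueError("all channels rejected by SCI quality control")

    # 3. optical density
    od = intensity_to_od(intensity, channel_names=qc.channel_names)
    log.append("optical_density: converted to mean-referenced OD")

    # 4. wavelet motion correction
    od, shrunk = wavelet_motion_correct(
        od, params.iqr_k, params.wavelet, params.wavelet_level, return_counts=True
    )
    qc.wavelet_coefficients_shrunk = shrunk
    log.append(f"wavelet_correction: shrank {int(shrunk.sum())} detail coefficients")

    # 5. Beer-Lambert
    hb = od_to_hemoglobin(od, montage, params.dpf, fs)
    log.append(f"beer_lambert: DPF={params.dpf}")

    # 6. wide band-pass
    hb.hbo = bandpass(hb.hbo, *params.band_wide_hz, fs)
    hb.hbr = bandpass(hb.hbr, *params.band_wide_hz, fs)
    log.append(f"bandpass_wide: {params.band_wide_hz} Hz")

    # 7. short-separation regression
    short_ok = {c.index: not qc.rejected[c.index] for c in montage.short_channels}
    for ch in montage.long_channels:
        near = nearest_short_channel(montage, ch)
        if not short_ok[near.index]:
            fallback = [s for s in montage.short_channels if short_ok[s.index]]
            if not fallback:
                log.append(f"short_separation_regression: {ch.name} skipped (no usable short channel)")
                continue
            log.append(
                f"short_separation_regression: {ch.name} fell back from rejected "
                f"{near.name} to {fallback[0].name}"
            )
            near = fallback[0]
        hb.hbo[:, ch.index], _ = short_separation_regress(hb.hbo[:, ch.index], hb.hbo[:, near.index])
        hb.hbr[:, ch.index], _ = short_separation_regress(hb.hbr[:, ch.index], hb.hbr[:, near.index])
    log.append("short_separation_regression: done")

    # 8. narrow band-pass
    hb.hbo = bandpass(hb.hbo, *params.band_narrow_hz, fs)
    hb.hbr = bandpass(hb.hbr, *params.band_narrow_hz, fs)
    log.append(f"bandpass_narrow: {params.band_narrow_hz} Hz")

    hb.channel_mask = ~qc.rejected
    hb.stages = list(CANONICAL_STAGES)
    qc.stage_log = log
    return hb, qc
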