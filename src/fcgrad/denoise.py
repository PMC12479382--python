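"""Scan-level denoising of parcellated BOLD time series.

The recipe, applied in this fixed order:

1. spike identification from framewise displacement (FD > 0.5 mm, strict);
2. nuisance regression — Friston-24 motion expansion, principal
   components of noise channels (50%-variance rule), spike regressors,
   and optionally the global mean signal (GSR);
3. zero-phase band-pass filtering (0.008–0.09 Hz);
4. deletion of flagged frames before any correlation is computed.

Scrubbed frames participate in the regression as spike regressors and
are then removed, so they cannot leak variance into retained frames.
Continuous regressors are band-passed with the data's filter before
regression so the two steps commute (see :func:`denoise_scan`).
"""

from __future__ import annotations

import numpy as np

from .types import ConfoundSet, ParcelTimeSeries

FD_THRESHOLD_MM = 0.5
BAND_LOW_HZ = 0.008
BAND_HIGH_HZ = 0.09
ACOMPCOR_VARIANCE_FRACTION = 0.5

MOTION_LABELS = ("tx", "ty", "tz", "rx", "ry", "rz")


def friston24(motion: np.ndarray) -> ConfoundSet:
    """Expand 6 rigid-body parameters into the 24-regressor model.

    Columns: the 6 parameters, their one-frame-lagged copies (first
    frame backfilled with 0), and the squares of both sets.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be frames x 6, got shape {motion.shape}")
    lagged = np.zeros_like(motion)
    lagged[1:] = motion[:-1]
    cols = np.hstack([motion, lagged, motion**2, lagged**2])
    labels = (
        [f"m_{l}" for l in MOTION_LABELS]
        + [f"m_{l}_lag" for l in MOTION_LABELS]
        + [f"m_{l}_sq" for l in MOTION_LABELS]
        + [f"m_{l}_lag_sq" for l in MOTION_LABELS]
    )
    return ConfoundSet(cols, labels, ["motion24"] * 24)


def acompcor_components(
    noise_signals: np.ndarray,
    variance_fraction: float = ACOMPCOR_VARIANCE_FRACTION,
) -> ConfoundSet:
    """Principal components of noise channels up to a variance fraction.

    Returns the smallest number of leading components whose cumulative
    explained variance reaches ``variance_fraction`` of the total.
    """
    x = np.atleast_2d(np.asarray(noise_signals, dtype=float))
    if x.shape[1] == 0:
        raise ValueError("need at least one noise channel")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must lie in (0, 1]")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise ValueError("noise channels are constant; nothing to decompose")
    frac = np.cumsum(var) / total
    n_comp = int(np.searchsorted(frac, variance_fraction - 1e-12) + 1)
    n_comp = min(n_comp, len(s))
    comps = u[:, :n_comp] * s[:n_comp]
    labels = [f"acompcor_{i + 1:02d}" for i in range(n_comp)]
    return ConfoundSet(comps, labels, ["acompcor"] * n_comp)


def spike_regressors(
    fd: np.ndarray, threshold_mm: float = FD_THRESHOLD_MM
) -> tuple[ConfoundSet, np.ndarray]:
    """One indicator column per frame with FD strictly above threshold.

    Returns the spike confounds and the retained-frame mask (True where
    the frame survives scrubbing).
    """
    fd = np.asarray(fd, dtype=float)
    if np.any(fd < 0):
        raise ValueError("FD values must be nonnegative")
    flagged = np.flatnonzero(fd > threshold_mm)
    cols = np.zeros((len(fd), len(flagged)))
    for j, t in enumerate(flagged):
        cols[t, j] = 1.0
    labels = [f"spike_t{t:04d}" for t in flagged]
    mask = np.ones(len(fd), dtype=bool)
    mask[flagged] = False
    return ConfoundSet(cols, labels, ["spike"] * len(flagged)), mask


def regress_confounds(
    ts: ParcelTimeSeries, confounds: ConfoundSet | None, gsr: bool = False
) -> ParcelTimeSeries:
    """Least-squares residualization of every parcel against nuisances.

    The design is [intercept | confounds | global mean if gsr]; rank
    deficiency is handled by the pseudoinverse, so residuals are exactly
    orthogonal to every regressor either way.
    """
    design_cols = [np.ones((ts.n_frames, 1))]
    if confounds is not None:
        if confounds.n_frames != ts.n_frames:
            raise ValueError("confound frame count must match the scan")
        if confounds.n_columns:
            design_cols.append(confounds.regressors)
    if gsr:
        design_cols.append(ts.data.mean(axis=1, keepdims=True))
    design = np.hstack(design_cols)
    beta = np.linalg.pinv(design) @ ts.data
    residuals = ts.data - design @ beta
    return ts.replace_data(residuals)


def bandpass(
    ts: ParcelTimeSeries,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
) -> ParcelTimeSeries:
    """Zero-phase band-pass via frequency-domain masking.

    The pass band [low_hz, high_hz] has unit gain; edges roll off with a
    2-bin raised-cosine taper; the DC component is always removed.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyquist:.4f}) Hz"
        )
    n = ts.n_frames
    freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
    gain = _band_gain(freqs, low_hz, high_hz)
    spectrum = np.fft.rfft(ts.data, axis=0)
    filtered = np.fft.irfft(spectrum * gain[:, None], n=n, axis=0)
    return ts.replace_data(filtered)


def _band_gain(freqs: np.ndarray, low_hz: float, high_hz: float) -> np.ndarray:
    """Pass-band mask with 2-bin cosine tapers; DC gain forced to 0."""
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    ramp = 2.0 * df
    gain = np.zeros_like(freqs)
    inside = (freqs >= low_hz) & (freqs <= high_hz)
    gain[inside] = 1.0
    lo_ramp = (freqs >= low_hz - ramp) & (freqs < low_hz)
    gain[lo_ramp] = 0.5 * (1 + np.cos(np.pi * (low_hz - freqs[lo_ramp]) / ramp))
    hi_ramp = (freqs > high_hz) & (freqs <= high_hz + ramp)
    gain[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - high_hz) / ramp))
    gain[0] = 0.0
    return gain


def denoise_scan(
    ts: ParcelTimeSeries,
    gsr: bool = False,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
    acompcor_fraction: float = ACOMPCOR_VARIANCE_FRACTION,
) -> ParcelTimeSeries:
    """Full denoising chain for one scan.

    Confounds are assembled from whatever the scan carries (motion,
    noise channels, FD); missing pieces are simply skipped. The
    returned scan keeps all frames but its ``frame_mask`` marks the
    scrubbed ones; callers must drop them before correlating (the
    connectivity stage does this automatically).
    """
    pieces: list[ConfoundSet] = []
    if ts.motion is not None:
        pieces.append(friston24(ts.motion))
    if ts.noise_signals is not None:
        pieces.append(acompcor_components(ts.noise_signals, acompcor_fraction))
    # Continuous nuisance regressors are band-passed with the same filter
    # as the data so regression and filtering commute (a frequency
    # mismatch between regressors and filtered data would otherwise
    # reintroduce out-of-band variance); spike indicators stay impulses
    # since their frames are deleted outright.
    if gsr:
        gm = ts.data.mean(axis=1, keepdims=True)
        pieces.append(ConfoundSet(gm, ["global_signal"], ["gsr"]))
    if pieces:
        continuous = ConfoundSet.concatenate(pieces)
        filtered = _filter_columns(
            continuous.regressors, ts.tr_seconds, low_hz, high_hz
        )
        pieces = [ConfoundSet(filtered, continuous.labels, continuous.provenance)]
    mask = np.ones(ts.n_frames, dtype=bool)
    if ts.fd is not None:
        spikes, mask = spike_regressors(ts.fd, fd_threshold_mm)
        if spikes.n_columns:
            pieces.append(spikes)
    confounds = ConfoundSet.concatenate(pieces) if pieces else None
    cleaned = regress_confounds(ts, confounds, gsr=False)
    cleaned = bandpass(cleaned, low_hz, high_hz)
    cleaned.frame_mask = ts.frame_mask & mask
    return cleaned


def _filter_columns(
    x: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float
) -> np.ndarray:
    n = x.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    gain = _band_gain(freqs, low_hz, high_hz)
    return np.fft.irfft(np.fft.rfft(x, axis=0) * gain[:, None], n=n, axis=0)
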