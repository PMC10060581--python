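"""EEG alpha-desynchronization preprocessing.

Continuous scalp EEG is stripped of the 24 outer-rim electrodes,
band-passed 0.3-49 Hz (zero-phase), screened for artifactual channels
(variance / neighbor-correlation / Hurst-exponent z-scores), epoched
-1000..+1000 ms around the trial anchor, cleaned of artifact independent
components, transformed to current source density (spherical-spline
surface Laplacian), and reduced to per-trial 8-13 Hz Morlet power change
(log-ratio of post-event to pre-event power; negative values =
desynchronization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .rois import BOUNDARY_ELECTRODES, EEG_ROI_ELECTRODES, RoiMap, DEFAULT_ROI_MAP
from .schedule import CONDITIONS, EventSchedule

logger = logging.getLogger(__name__)


@dataclass
class RawEeg:
    """Continuous EEG, shape (electrodes, time), uV."""

    data: np.ndarray
    labels: tuple[str, ...]
    sampling_rate: float

    def pick(self, labels: list[str]) -> "RawEeg":
        idx = [self.labels.index(l) for l in labels]
        return RawEeg(self.data[idx], tuple(labels), self.sampling_rate)


@dataclass
class EegEpochs:
    """Epoched EEG, shape (trial, electrode, time); window in s around the
    anchor marker (start_action for ME/MO, end_speak for MI)."""

    data: np.ndarray
    labels: tuple[str, ...]
    sampling_rate: float
    window: tuple[float, float]
    info: pd.DataFrame  # condition, trial (per-condition index), onset
    rejected_channels: tuple[str, ...] = ()
    units: str = "uV"


def bandpass_eeg(raw: RawEeg, low: float = 0.3, high: float = 49.0,
                 order: int = 4) -> RawEeg:
    """Zero-phase Butterworth band-pass with the published 0.3-49 Hz band."""
    nyq = raw.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError("invalid band edges")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return replace(raw, data=signal.sosfiltfilt(sos, raw.data, axis=-1))


def drop_boundary_channels(
    raw: RawEeg, boundary_list: tuple[str, ...] = BOUNDARY_ELECTRODES
) -> RawEeg:
    """Remove the outer-rim electrodes before any further processing."""
    unknown = [l for l in boundary_list if l not in raw.labels]
    if unknown:
        warnings.warn(f"unknown boundary labels skipped: {unknown}")
    keep = [l for l in raw.labels if l not in set(boundary_list)]
    return raw.pick(keep)


def _hurst_exponent(x: np.ndarray) -> np.ndarray:
    """Hurst exponent per row via detrended fluctuation over dyadic scales."""
    n_ch, n = x.shape
    y = np.cumsum(x - x.mean(axis=1, keepdims=True), axis=1)
    scales = [s for s in (8, 16, 32, 64, 128) if s <= n // 4]
    fl = []
    for s in scales:
        nwin = n // s
        seg = y[:, : nwin * s].reshape(n_ch, nwin, s)
        t = np.arange(s, dtype=float)
        t = (t - t.mean()) / np.sqrt(((t - t.mean()) ** 2).sum())
        slope = seg @ t  # (n_ch, nwin)
        detr = seg - seg.mean(axis=2, keepdims=True) - slope[:, :, None] * t
        fl.append(np.sqrt((detr ** 2).mean(axis=(1, 2))))
    logf = np.log(np.maximum(np.array(fl), 1e-300))  # (n_scales, n_ch)
    logs = np.log(np.array(scales))
    h = np.polyfit(logs, logf, 1)[0]
    return h


def reject_bad_channels(
    raw: RawEeg, z_thresh: float = 3.0, max_fraction: float = 0.30
) -> tuple[RawEeg, tuple[str, ...]]:
    """Identify artifactual channels by z-scored quality criteria.

    Per channel: log-variance, mean correlation with the other channels, and
    Hurst-exponent deviation, each z-scored across channels; channels with
    any |z| > z_thresh are removed. Aborts if more than ``max_fraction`` of
    channels would be rejected (bad recording).
    """
    x = raw.data
    n_ch = x.shape[0]
    if n_ch < 8:
        raise ValueError("need at least 8 channels for channel rejection")
    dec = max(1, int(raw.sampling_rate // 60))
    xd = x[:, ::dec]
    log_var = np.log(np.maximum(x.var(axis=1), 1e-300))
    c = np.corrcoef(xd)
    np.fill_diagonal(c, np.nan)
    mean_corr = np.nanmean(c, axis=1)
    hurst = _hurst_exponent(xd[:, : min(xd.shape[1], 20000)])

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    zs = np.vstack([zscore(log_var), zscore(mean_corr), zscore(hurst)])
    bad = np.abs(zs).max(axis=0) > z_thresh
    if bad.mean() > max_fraction:
        raise RuntimeError(
            f"channel rejection would drop {bad.sum()}/{n_ch} channels; "
            "recording looks unusable"
        )
    rejected = tuple(l for l, b in zip(raw.labels, bad) if b)
    keep = [l for l, b in zip(raw.labels, bad) if not b]
    return raw.pick(keep), rejected


def remove_artifact_components(
    epochs: EegEpochs,
    references: np.ndarray | None = None,
    corr_thresh: float = 0.7,
    kurtosis_z_thresh: float = 5.0,
    n_components: int | None = 12,
    seed: int = 0,
    max_iter: int = 200,
) -> EegEpochs:
    """ICA-based artifact removal on concatenated epochs.

    Components whose time course correlates with a reference template above
    ``corr_thresh``, or whose topography's kurtosis z-score across
    components exceeds ``kurtosis_z_thresh``, are subtracted from the data
    (rank-1 removal per component); removing nothing returns the input
    exactly. Non-convergence of the decomposition skips the stage with a
    warning.
    """
    n_ep, n_ch, n_t = epochs.data.shape
    x = epochs.data.transpose(1, 0, 2).reshape(n_ch, n_ep * n_t)
    k = min(n_components or n_ch, n_ch)
    ica = FastICA(n_components=k, random_state=seed, max_iter=max_iter, tol=1e-3)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(x.T)  # (samples, k)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        logger.warning("ICA did not converge; artifact stage skipped")
        return epochs
    mixing = ica.mixing_  # (n_ch, k)

    remove = np.zeros(k, dtype=bool)
    if references is not None:
        refs = np.atleast_2d(np.asarray(references, dtype=float))
        for r in refs:
            cc = np.array([abs(np.corrcoef(s, r)[0, 1]) for s in sources.T])
            remove |= cc > corr_thresh
    topo = mixing / np.maximum(np.linalg.norm(mixing, axis=0, keepdims=True), 1e-300)
    from scipy.stats import kurtosis

    kur = kurtosis(topo, axis=0, fisher=True)
    sd = kur.std()
    if sd > 0:
        remove |= np.abs((kur - kur.mean()) / sd) > kurtosis_z_thresh
    if not remove.any():
        return epochs
    contribution = sources[:, remove] @ mixing[:, remove].T  # (samples, n_ch)
    cleaned = x - contribution.T
    data = cleaned.reshape(n_ch, n_ep, n_t).transpose(1, 0, 2)
    logger.info("removed %d artifact components", int(remove.sum()))
    return replace(epochs, data=data)


def epoch_eeg(
    raw: RawEeg,
    schedule: EventSchedule,
    window: tuple[float, float] = (-1.0, 1.0),
    rejected_channels: tuple[str, ...] = (),
) -> EegEpochs:
    """Cut per-trial windows of exactly ``window`` (default +/-1000 ms)
    around each trial's anchor marker; trials overlapping the recording
    edges are dropped with a log entry. Raises if any condition ends up
    with zero usable trials.
    """
    fs = raw.sampling_rate
    n_lo = int(round(window[0] * fs))
    n_hi = int(round(window[1] * fs))
    n_len = n_hi - n_lo
    n_samples = raw.data.shape[1]
    out, rows = [], []
    counters = {c: 0 for c in CONDITIONS}
    for tr in schedule.trials:
        k = counters[tr.condition]
        counters[tr.condition] += 1
        i0 = int(round(tr.onset * fs))
        lo, hi = i0 + n_lo, i0 + n_lo + n_len
        if lo < 0 or hi > n_samples:
            logger.info("dropped trial at %.1f s (outside recording)", tr.onset)
            continue
        out.append(raw.data[:, lo:hi])
        rows.append((tr.condition, k, tr.onset))
    info = pd.DataFrame(rows, columns=["condition", "trial", "onset"])
    for c in CONDITIONS:
        if not (info["condition"] == c).any():
            raise RuntimeError(f"no usable trials in condition {c}")
    return EegEpochs(
        data=np.stack(out), labels=raw.labels, sampling_rate=fs,
        window=window, info=info, rejected_channels=rejected_channels,
    )


# --------------------------------------------------------------------------
# Current source density (spherical-spline surface Laplacian)
# --------------------------------------------------------------------------

def _csd_operator(
    positions: np.ndarray,
    m: int = 4,
    regularization: float = 1e-5,
    n_legendre: int = 50,
    head_radius_cm: float = 10.0,
) -> np.ndarray:
    """Linear operator mapping scalp potentials (uV) to CSD (uV/cm^2).

    Perrin-style spherical-spline construction: interpolation kernel
    g_m(cos) and Laplacian kernel h = g_{m-1}-type series, ridge-regularized
    solve with the mean (c0) constraint removed.
    """
    pos = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    n = np.arange(1, n_legendre + 1, dtype=float)
    cg = np.zeros(n_legendre + 1)
    ch = np.zeros(n_legendre + 1)
    cg[1:] = (2 * n + 1) / (n * (n + 1)) ** m / (4 * np.pi)
    ch[1:] = (2 * n + 1) / (n * (n + 1)) ** (m - 1) / (4 * np.pi)
    from numpy.polynomial import legendre as npleg

    g = npleg.legval(cosang, cg)
    h = npleg.legval(cosang, ch)
    gs = g + regularization * np.eye(len(pos))
    ci = np.linalg.inv(gs)
    ci_one = ci @ np.ones(len(pos))
    proj = ci - np.outer(ci_one, ci_one) / ci_one.sum()
    return (h @ proj) / head_radius_cm ** 2


def csd_transform(
    epochs: EegEpochs,
    positions: dict[str, np.ndarray],
    m: int = 4,
    regularization: float = 1e-5,
    n_legendre: int = 50,
    head_radius_cm: float = 10.0,
) -> EegEpochs:
    """Surface-Laplacian (CSD) transform of epoched data, uV -> uV/cm^2.

    Requires >= 16 electrodes with distinct unit-sphere positions; a
    spatially constant potential maps to (numerically) zero CSD.
    """
    pos = np.array([positions[l] for l in epochs.labels], dtype=float)
    if len(pos) < 16:
        raise ValueError("need at least 16 electrodes for CSD")
    pn = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    d = np.linalg.norm(pn[:, None, :] - pn[None, :, :], axis=-1)
    np.fill_diagonal(d, 1.0)
    if d.min() < 1e-9:
        raise ValueError("duplicate electrode positions")
    op = _csd_operator(pos, m, regularization, n_legendre, head_radius_cm)
    data = np.einsum("ij,ejt->eit", op, epochs.data)
    return replace(epochs, data=data, units="uV/cm^2")


# --------------------------------------------------------------------------
# Morlet alpha power
# --------------------------------------------------------------------------

def alpha_power(
    epochs: EegEpochs,
    band: tuple[float, float] = (8.0, 13.0),
    n_cycles: float = 5.0,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    post_window: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Per-trial, per-electrode alpha power change after the event.

    Morlet-wavelet power averaged over ``band`` (1 Hz spacing) and over the
    post-event window, expressed as ``log(post / baseline)``; negative
    values indicate event-related desynchronization.
    """
    from mne.time_frequency import tfr_array_morlet

    fs = epochs.sampling_rate
    lo, hi = band
    epoch_len = epochs.window[1] - epochs.window[0]
    if epoch_len < n_cycles / lo:
        raise ValueError("epoch shorter than the longest wavelet")
    freqs = np.arange(lo, hi + 0.5, 1.0)
    power = tfr_array_morlet(
        epochs.data, sfreq=fs, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=True, verbose="error",
    )  # (trial, ch, freq, time)
    t = epochs.window[0] + np.arange(epochs.data.shape[-1]) / fs
    base_m = (t >= baseline_window[0]) & (t < baseline_window[1])
    post_m = (t >= post_window[0]) & (t < post_window[1])
    band_power = power.mean(axis=2)
    base = band_power[:, :, base_m].mean(axis=-1)
    post = band_power[:, :, post_m].mean(axis=-1)
    change = np.log(np.maximum(post, 1e-300) / np.maximum(base, 1e-300))
    n_ep, n_ch = change.shape
    return pd.DataFrame({
        "condition": np.repeat(epochs.info["condition"].to_numpy(), n_ch),
        "trial": np.repeat(epochs.info["trial"].to_numpy(), n_ch),
        "electrode": np.tile(np.array(epochs.labels), n_ep),
        "alpha_change": change.ravel(),
    })


def aggregate_eeg_rois(
    table: pd.DataFrame, roi_map: RoiMap = DEFAULT_ROI_MAP
) -> pd.DataFrame:
    """Mean alpha change over each scalp grouping's member electrodes.

    ROIs whose members were all rejected yield NaN for that cell."""
    t = table.copy()
    t["roi"] = t["electrode"].map(roi_map.eeg)
    t = t.dropna(subset=["roi"])
    keys = [c for c in ("participant", "condition", "trial", "roi") if c in t.columns]
    agg = t.groupby(keys, as_index=False)["alpha_change"].mean()
    return agg


# --------------------------------------------------------------------------
# Full chain
# --------------------------------------------------------------------------

@dataclass
class EegParams:
    band: tuple[float, float] = (0.3, 49.0)
    reject_z_thresh: float = 3.0
    run_ica: bool = True
    ica_n_components: int = 12
    ica_corr_thresh: float = 0.7
    ica_kurtosis_z: float = 5.0
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    csd_m: int = 4
    csd_regularization: float = 1e-5
    csd_n_legendre: int = 50
    alpha_band: tuple[float, float] = (8.0, 13.0)
    morlet_n_cycles: float = 5.0
    boundary: tuple[str, ...] = BOUNDARY_ELECTRODES


def preprocess_eeg(
    raw: RawEeg,
    schedule: EventSchedule,
    positions: dict[str, np.ndarray],
    params: EegParams = EegParams(),
    seed: int = 0,
    references: np.ndarray | None = None,
) -> tuple[pd.DataFrame, EegEpochs, tuple[str, ...]]:
    """Run the whole EEG chain on one session.

    Returns (per-trial alpha-change table, CSD epochs, rejected channels)."""
    raw = drop_boundary_channels(raw, params.boundary)
    raw = bandpass_eeg(raw, *params.band)
    raw, rejected = reject_bad_channels(raw, params.reject_z_thresh)
    epochs = epoch_eeg(raw, schedule, params.epoch_window, rejected)
    if params.run_ica:
        epochs = remove_artifact_components(
            epochs, references, params.ica_corr_thresh,
            params.ica_kurtosis_z, params.ica_n_components, seed,
        )
    epochs = csd_transform(
        epochs, positions, params.csd_m, params.csd_regularization,
        params.csd_n_legendre,
    )
    table = alpha_power(
        epochs, params.alpha_band, params.morlet_n_cycles,
    )
    return table, epochs, rejected


__all__ = [
    "RawEeg", "EegEpochs", "bandpass_eeg", "drop_boundary_channels",
    "reject_bad_channels", "remove_artifact_components", "epoch_eeg",
    "csd_transform", "alpha_power", "aggregate_eeg_rois", "EegParams",
    "preprocess_eeg", "EEG_ROI_ELECTRODES",
]
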