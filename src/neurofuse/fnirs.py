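"""fNIRS hemodynamic preprocessing chain.

Raw two-wavelength light intensities are converted to optical density,
cleaned (PCA filter, motion detection, spline + Savitzky-Golay correction,
0.01-0.50 Hz band-pass), converted to HbO/HbR concentration changes with
the modified Beer-Lambert law using an age- and wavelength-dependent
differential pathlength factor, fitted with a Gaussian-basis GLM, epoched
around trial onsets, summarized as per-trial Z-scores
(Mean_stim - Mean_baseline)/SD_baseline, and filtered by a +/-2 SD
outlier rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import binary_dilation, maximum_filter1d, minimum_filter1d

from .geometry import ProbeGeometry
from .schedule import CONDITIONS, EventSchedule

logger = logging.getLogger(__name__)

WAVELENGTHS_NM = (695.0, 830.0)


# --------------------------------------------------------------------------
# Differential pathlength factor
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DpfCoefficients:
    """Coefficients of the DPF polynomial
    ``DPF(lambda, A) = alpha + beta*A**gamma + delta*lam**3 + eps*lam**2 + zeta*lam``.

    Defaults are the published values. Note: with these defaults the DPF at
    830 nm for a 33-year-old is ~15.6, far above the 4-8 range of the
    general DPF literature (where the age coefficient is 0.05624); the
    printed value is kept deliberately and the forward simulator uses the
    same table, so analyses are self-consistent. Fully configurable.
    """

    alpha: float = 223.3
    beta: float = 0.5624
    gamma: float = 0.8493
    delta: float = -5.723e-7
    epsilon: float = 0.001245
    zeta: float = -0.9025


def dpf(wavelength_nm: float, age_years: float,
        coeffs: DpfCoefficients = DpfCoefficients()) -> float:
    """Differential pathlength factor for one wavelength (nm) and age (years)."""
    lam, a = float(wavelength_nm), float(age_years)
    return (
        coeffs.alpha
        + coeffs.beta * a ** coeffs.gamma
        + coeffs.delta * lam ** 3
        + coeffs.epsilon * lam ** 2
        + coeffs.zeta * lam
    )


# --------------------------------------------------------------------------
# Extinction coefficients
# --------------------------------------------------------------------------

#: natural-log molar extinction coefficients, 1/(uM * cm), at the two
#: laser lines. Base-10 values from the standard compiled hemoglobin
#: spectra (Gratzer/Kollias, as shipped with HOMER) scaled by ln(10).
DEFAULT_EXTINCTION: dict[float, tuple[float, float]] = {
    # wavelength: (eps_HbO, eps_HbR)
    695.0: (7.39e-4, 4.281e-3),
    830.0: (2.243e-3, 1.596e-3),
}


def extinction_matrix(
    extinction: dict[float, tuple[float, float]] | None = None,
    wavelengths: tuple[float, float] = WAVELENGTHS_NM,
) -> np.ndarray:
    """2x2 matrix E with E[i] = (eps_HbO, eps_HbR) at wavelengths[i]."""
    table = DEFAULT_EXTINCTION if extinction is None else extinction
    e = np.array([table[w] for w in wavelengths], dtype=float)
    if abs(np.linalg.det(e)) < 1e-12:
        raise ValueError("singular extinction matrix")
    return e


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class OpticalDensity:
    """Optical density, shape (channels, wavelengths, time), unitless."""

    od: np.ndarray
    sampling_rate: float
    motion_mask: np.ndarray | None = None  # (channels, time) bool
    unusable_channels: set[int] = field(default_factory=set)

    @property
    def n_channels(self) -> int:
        return self.od.shape[0]


@dataclass
class HbTimeSeries:
    """HbO/HbR concentration change, shape (channels, time), uM."""

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float


# --------------------------------------------------------------------------
# Chain steps
# --------------------------------------------------------------------------

def intensity_to_od(intensity: np.ndarray, sampling_rate: float) -> OpticalDensity:
    """Attenuated light intensity -> optical density.

    ``od(c, w, t) = -ln(I(c, w, t) / mean_t I(c, w, .))``; scale-invariant
    per channel/wavelength. Raises on non-positive intensities (corrupt
    recording).
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0) or not np.all(np.isfinite(intensity)):
        raise ValueError("non-positive or non-finite light intensity")
    mean = intensity.mean(axis=-1, keepdims=True)
    return OpticalDensity(od=-np.log(intensity / mean), sampling_rate=sampling_rate)


def pca_filter(od: OpticalDensity, variance_threshold: float = 0.9) -> OpticalDensity:
    """Remove leading principal components of the channel x time OD matrix.

    The largest set of leading components whose cumulative explained
    variance stays within ``variance_threshold`` is projected out (HOMER
    semantics: remove components explaining *up to* the threshold fraction
    of variance). Targets spatially global structure such as motion;
    a single dominant component exceeding the threshold on its own is kept
    (projecting it out would also project out the fraction of the
    evoked response lying along it, ghosting an anti-correlated copy into
    every other channel). The residual plus the temporal mean is returned.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    x = od.od
    c, w, t = x.shape
    if c * w < 2:
        warnings.warn("fewer than 2 channels: PCA filter is the identity")
        return od
    flat = x.reshape(c * w, t)
    mean = flat.mean(axis=1, keepdims=True)
    resid = flat - mean
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return replace(od, od=x.copy())
    cum = np.cumsum(var) / total
    k = int((cum <= variance_threshold + 1e-12).sum())
    if k > 0:
        resid = resid - u[:, :k] @ (u[:, :k].T @ resid)
    return replace(od, od=(resid + mean).reshape(c, w, t))


def detect_motion(
    od: OpticalDensity,
    t_motion: float = 0.5,
    t_mask: float = 1.0,
    stdev_thresh: float = 20.0,
    amp_thresh: float = 5.0,
) -> np.ndarray:
    """Flag motion artifacts per channel.

    A sample is flagged when the peak-to-peak signal change within any
    sliding window of ``t_motion`` seconds exceeds ``stdev_thresh`` times
    the channel SD or ``amp_thresh`` OD units; flags are dilated by
    ``t_mask`` seconds. Returns a (channels, time) boolean mask.
    """
    if min(t_motion, t_mask, stdev_thresh, amp_thresh) <= 0:
        raise ValueError("motion-detection parameters must be positive")
    x = od.od
    c, w, t = x.shape
    win = max(int(round(t_motion * od.sampling_rate)), 2)
    flat = x.reshape(c * w, t)
    ptp = maximum_filter1d(flat, win, axis=1) - minimum_filter1d(flat, win, axis=1)
    sd = flat.std(axis=1, keepdims=True)
    flags = (ptp > stdev_thresh * sd) | (ptp > amp_thresh)
    flags = flags.reshape(c, w, t).any(axis=1)
    dil = int(round(t_mask * od.sampling_rate))
    if dil > 0 and flags.any():
        flags = binary_dilation(flags, structure=np.ones((1, 2 * dil + 1), bool))
    return flags


def _segments(mask_row: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask_row.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))  # half-open [start, stop)


def correct_motion(
    od: OpticalDensity,
    motion_mask: np.ndarray,
    spline_p: float = 0.99,
    sg_window: int = 11,
) -> OpticalDensity:
    """Spline-subtract masked segments, then Savitzky-Golay smooth.

    Within each masked segment a smoothing spline (MATLAB-style parameter
    ``spline_p``; 1 = interpolation) is fitted and subtracted, and the
    segment is re-anchored to the level of the preceding clean samples.
    A zero-phase Savitzky-Golay filter (order 3, ``sg_window`` samples)
    is then applied to the whole series. Channels fully covered by the
    mask are marked unusable.
    """
    if sg_window < 5 or sg_window % 2 == 0:
        raise ValueError("sg_window must be odd and >= 5")
    x = od.od.copy()
    c, w, t = x.shape
    fs = od.sampling_rate
    unusable = set(od.unusable_channels)
    anchor_n = max(int(round(0.5 * fs)), 1)
    lam = max(1e-12, (1.0 - spline_p) / spline_p)
    for ch in range(c):
        row_mask = motion_mask[ch]
        if row_mask.all():
            unusable.add(ch)
            continue
        for wl in range(w):
            y = x[ch, wl]
            for start, stop in _segments(row_mask):
                seg = y[start:stop]
                if len(seg) >= 4:
                    tt = np.arange(len(seg), dtype=float)
                    spl = make_smoothing_spline(tt, seg, lam=lam)
                    seg = seg - spl(tt)
                else:
                    seg = seg - seg.mean()
                if start > 0:
                    level = y[max(0, start - anchor_n):start].mean()
                elif stop < t:
                    level = y[stop:stop + anchor_n].mean()
                else:
                    level = 0.0
                y[start:stop] = seg - seg.mean() + level
                if start > 0 and stop < t:
                    # re-anchor the remainder too: a step artifact leaves a
                    # persistent level shift after the masked interval
                    tail = y[stop:stop + anchor_n].mean()
                    seg_end = y[max(start, stop - anchor_n):stop].mean()
                    y[stop:] -= tail - seg_end
    sg = signal.savgol_filter(x, sg_window, polyorder=3, axis=-1)
    return replace(od, od=sg, motion_mask=motion_mask, unusable_channels=unusable)


def bandpass_od(od: OpticalDensity, low: float = 0.01, high: float = 0.50,
                order: int = 3) -> OpticalDensity:
    """Zero-phase Butterworth band-pass (defaults 0.01-0.50 Hz); removes DC."""
    nyq = od.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError("invalid band edges")
    sos = signal.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    return replace(od, od=signal.sosfiltfilt(sos, od.od, axis=-1))


def od_to_conc(
    od: OpticalDensity,
    geometry: ProbeGeometry,
    age_years: float,
    coeffs: DpfCoefficients = DpfCoefficients(),
    extinction: dict[float, tuple[float, float]] | None = None,
    wavelengths: tuple[float, float] = WAVELENGTHS_NM,
) -> HbTimeSeries:
    """Modified Beer-Lambert law: OD at two wavelengths -> HbO/HbR (uM).

    Per channel solves ``od(w) = (eps_HbO(w)*dHbO + eps_HbR(w)*dHbR) * d * DPF(w)``.
    """
    e = extinction_matrix(extinction, wavelengths)
    dpfs = np.array([dpf(w, age_years, coeffs) for w in wavelengths])
    dist = geometry.channel_distance
    if od.n_channels != len(dist):
        raise ValueError("channel count does not match geometry")
    # normalize away pathlength, then invert the 2x2 extinction system
    scaled = od.od / (dist[:, None, None] * dpfs[None, :, None])
    e_inv = np.linalg.inv(e)
    conc = np.einsum("kw,cwt->ckt", e_inv, scaled)
    return HbTimeSeries(hbo=conc[:, 0], hbr=conc[:, 1], sampling_rate=od.sampling_rate)


# --------------------------------------------------------------------------
# GLM HRF estimation
# --------------------------------------------------------------------------

@dataclass
class GlmResult:
    conditions: tuple[str, ...]
    time_grid: np.ndarray  # s relative to onset
    hrf: np.ndarray  # (condition, channel, len(time_grid))
    coefficients: np.ndarray  # (condition, n_basis, channel)
    r_squared: np.ndarray  # (channel,)


def gaussian_basis_design(
    schedule: EventSchedule,
    n_samples: int,
    sampling_rate: float,
    window: tuple[float, float] = (-5.0, 25.0),
    basis_sd: float = 0.5,
    basis_spacing: float = 0.5,
    conditions: tuple[str, ...] = CONDITIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix of consecutive Gaussians covering ``window`` per condition.

    Returns (design (n_samples, n_cond*n_basis), basis centers (s))."""
    centers = np.arange(window[0], window[1] + 1e-9, basis_spacing)
    t = np.arange(n_samples) / sampling_rate
    support = 4.0 * basis_sd  # a Gaussian is negligible beyond 4 SD
    cols = []
    for cond in conditions:
        block = np.zeros((n_samples, len(centers)))
        for tr in schedule.by_condition(cond):
            lo = max(0, int((tr.onset + window[0] - support) * sampling_rate))
            hi = min(n_samples,
                     int((tr.onset + window[1] + support) * sampling_rate) + 2)
            rel = t[lo:hi] - tr.onset
            block[lo:hi] += np.exp(
                -0.5 * ((rel[:, None] - centers[None, :]) / basis_sd) ** 2)
        cols.append(block)
    return np.hstack(cols), centers


def _drift_regressors(n_samples: int, order: int = 3) -> np.ndarray:
    t = np.linspace(-1, 1, n_samples)
    return np.vander(t, order + 1, increasing=True)  # includes constant


def glm_hrf(
    hb: np.ndarray,
    schedule: EventSchedule,
    sampling_rate: float,
    window: tuple[float, float] = (-5.0, 25.0),
    basis_sd: float = 0.5,
    basis_spacing: float = 0.5,
    drift_order: int = 3,
    conditions: tuple[str, ...] = CONDITIONS,
) -> GlmResult:
    """Ordinary-least-squares GLM of ``hb`` (channels x time) on a
    Gaussian-basis HRF model plus polynomial drift regressors.

    Returns the fitted HRF per condition and channel on a 0.1 s grid over
    ``window``; raises on a rank-deficient design.
    """
    hb = np.atleast_2d(np.asarray(hb, dtype=float))
    n_ch, n_samples = hb.shape
    design, centers = gaussian_basis_design(
        schedule, n_samples, sampling_rate, window, basis_sd, basis_spacing,
        conditions,
    )
    drift = _drift_regressors(n_samples, drift_order)
    full = np.hstack([design, drift])
    gram = full.T @ full
    eig = np.linalg.eigvalsh(gram)
    if eig[0] < 1e-10 * eig[-1]:
        rank = int((eig > 1e-10 * eig[-1]).sum())
        raise ValueError(
            f"rank-deficient GLM design ({rank} < {full.shape[1]}): "
            "reduce basis density or drift order"
        )
    beta = np.linalg.solve(gram, full.T @ hb.T)
    fitted = full @ beta
    resid = hb.T - fitted
    ss_res = (resid ** 2).sum(axis=0)
    ss_tot = ((hb.T - hb.T.mean(axis=0)) ** 2).sum(axis=0)
    r2 = np.where(ss_tot > 0, 1 - ss_res / np.maximum(ss_tot, 1e-300), 0.0)
    n_basis = len(centers)
    grid = np.arange(window[0], window[1] + 1e-9, 0.1)
    eval_basis = np.exp(-0.5 * ((grid[:, None] - centers[None, :]) / basis_sd) ** 2)
    hrfs = np.empty((len(conditions), n_ch, len(grid)))
    coefs = np.empty((len(conditions), n_basis, n_ch))
    for i in range(len(conditions)):
        b = beta[i * n_basis:(i + 1) * n_basis]
        coefs[i] = b
        hrfs[i] = (eval_basis @ b).T
    return GlmResult(tuple(conditions), grid, hrfs, coefs, r2)


# --------------------------------------------------------------------------
# Epoching, Z-scores, outlier rule
# --------------------------------------------------------------------------

def epoch_and_zscore(
    hb: HbTimeSeries,
    schedule: EventSchedule,
    baseline_window: tuple[float, float] = (-5.0, 0.0),
    stim_window: tuple[float, float] = (0.0, 5.0),
    epoch_window: tuple[float, float] = (-5.0, 25.0),
    unusable_channels: set[int] | frozenset[int] = frozenset(),
) -> pd.DataFrame:
    """Per-trial epochs and Z-scores for HbO and HbR.

    Windows are half-open ``[lo, hi)`` in seconds relative to the trial
    anchor. ``z = (Mean_stim - Mean_baseline) / SD_baseline``; trials with a
    degenerate (zero-SD) baseline, channels marked unusable, and trials not
    fully inside the recording are flagged ``included=False``.
    Returns a tidy frame with one row per (condition, trial, channel,
    chromophore).
    """
    fs = hb.sampling_rate
    series = {"HbO": hb.hbo, "HbR": hb.hbr}
    n_samples = hb.hbo.shape[1]
    n_ch = hb.hbo.shape[0]
    unusable = np.zeros(n_ch, dtype=bool)
    unusable[list(unusable_channels)] = True
    trial_index = {c: 0 for c in CONDITIONS}
    frames = []
    for tr in schedule.trials:
        k = trial_index[tr.condition]
        trial_index[tr.condition] += 1
        i0 = int(round(tr.onset * fs))
        lo = i0 + int(round(epoch_window[0] * fs))
        hi = i0 + int(round(epoch_window[1] * fs))
        in_bounds = lo >= 0 and hi <= n_samples
        b0, b1 = (i0 + int(round(w * fs)) for w in baseline_window)
        s0, s1 = (i0 + int(round(w * fs)) for w in stim_window)
        for chrom, data in series.items():
            if in_bounds:
                mb = data[:, b0:b1].mean(axis=1)
                sb = data[:, b0:b1].std(axis=1, ddof=1)
                ms = data[:, s0:s1].mean(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    z = np.where(sb > 0, (ms - mb) / np.where(sb > 0, sb, 1.0),
                                 np.nan)
                ok = (sb > 0) & ~unusable
            else:
                mb = sb = ms = z = np.full(n_ch, np.nan)
                ok = np.zeros(n_ch, dtype=bool)
            frames.append(pd.DataFrame({
                "condition": tr.condition, "trial": k,
                "channel": np.arange(n_ch), "chromophore": chrom,
                "mean_stim": ms, "mean_baseline": mb, "sd_baseline": sb,
                "z": z, "included": ok,
            }))
    return pd.concat(frames, ignore_index=True)


def exclude_outlier_trials(
    table: pd.DataFrame,
    n_sd: float = 2.0,
    group_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Single-pass +/-2 SD outlier rule on per-trial Z-scores.

    Within each (participant, condition, channel, chromophore) group, trials
    with ``|z - mean(z)| > n_sd * SD(z)`` are marked ``included=False``
    (sample SD over the group's currently included trials). Groups with
    fewer than 3 trials are left untouched with a warning.
    """
    out = table.copy()
    if group_cols is None:
        group_cols = tuple(
            c for c in ("participant", "condition", "channel", "chromophore")
            if c in out.columns
        )
    small = 0
    for _, idx in out.groupby(list(group_cols)).groups.items():
        sub = out.loc[idx]
        valid = sub["included"] & sub["z"].notna()
        z = sub.loc[valid, "z"]
        if len(z) < 3:
            small += 1
            continue
        mu, sd = z.mean(), z.std(ddof=1)
        if sd == 0:
            continue
        bad = z.index[np.abs(z - mu) > n_sd * sd]
        out.loc[bad, "included"] = False
    if small:
        warnings.warn(f"{small} groups had < 3 trials; no outlier exclusion applied")
    return out


# --------------------------------------------------------------------------
# Full chain
# --------------------------------------------------------------------------

@dataclass
class FnirsParams:
    """Tunable parameters of the fNIRS chain (defaults as published where
    printed; remaining values are this package's defaults)."""

    pca_variance_threshold: float | None = 0.9  # None disables the PCA filter
    t_motion: float = 0.5
    t_mask: float = 1.0
    stdev_thresh: float = 20.0
    amp_thresh: float = 5.0
    spline_p: float = 0.99
    sg_window: int = 11
    band: tuple[float, float] = (0.01, 0.50)
    baseline_window: tuple[float, float] = (-5.0, 0.0)
    stim_window: tuple[float, float] = (0.0, 5.0)
    run_glm: bool = True
    outlier_n_sd: float = 2.0


def preprocess_fnirs(
    intensity: np.ndarray,
    geometry: ProbeGeometry,
    schedule: EventSchedule,
    age_years: float,
    sampling_rate: float = 10.0,
    params: FnirsParams = FnirsParams(),
    coeffs: DpfCoefficients = DpfCoefficients(),
) -> tuple[pd.DataFrame, HbTimeSeries, GlmResult | None]:
    """Run the whole chain on one session's raw intensities.

    Returns (per-trial Z-score table, concentration series, GLM result).
    The outlier rule is applied by the caller once participant labels are
    attached (its grouping includes the participant).
    """
    od = intensity_to_od(intensity, sampling_rate)
    if params.pca_variance_threshold is not None:
        od = pca_filter(od, params.pca_variance_threshold)
    mask = detect_motion(od, params.t_motion, params.t_mask,
                         params.stdev_thresh, params.amp_thresh)
    od = correct_motion(od, mask, params.spline_p, params.sg_window)
    od = bandpass_od(od, *params.band)
    hb = od_to_conc(od, geometry, age_years, coeffs)
    glm = None
    if params.run_glm:
        glm = glm_hrf(np.vstack([hb.hbo, hb.hbr]), schedule, sampling_rate)
    table = epoch_and_zscore(
        hb, schedule, params.baseline_window, params.stim_window,
        unusable_channels=od.unusable_channels,
    )
    return table, hb, glm


__all__ = [
    "DpfCoefficients", "dpf", "DEFAULT_EXTINCTION", "extinction_matrix",
    "OpticalDensity", "HbTimeSeries", "intensity_to_od", "pca_filter",
    "detect_motion", "correct_motion", "bandpass_od", "od_to_conc",
    "GlmResult", "gaussian_basis_design", "glm_hrf", "epoch_and_zscore",
    "exclude_outlier_trials", "FnirsParams", "preprocess_fnirs",
    "WAVELENGTHS_NM",
]
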