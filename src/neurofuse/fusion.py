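"""Structured sparse multiset canonical correlation analysis (ssmCCA).

Fuses per-trial fNIRS HbO Z-scores and per-trial EEG alpha power changes,
stacked across participants, by block-coordinate ascent on a SUMCOR-style
objective: find weight vectors w_m maximizing the summed pairwise
correlations of the canonical variates u_m = X_m w_m, with an L1 (LASSO)
penalty on EEG weights and a fused-LASSO penalty (L1 + graph total
variation over spatially neighbouring channels) on fNIRS weights, so that
fNIRS weight maps are sparse AND spatially smooth. Components are
extracted by deflation, ordered by decreasing canonical correlation, and
assigned to the fNIRS ROI carrying the largest absolute weight mass;
significance is assessed by a row-permutation test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .geometry import ProbeGeometry
from .rois import DEFAULT_ROI_MAP, RoiMap

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Feature sets
# --------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Column-standardized observation x feature matrix for one modality."""

    X: np.ndarray
    modality: str  # "fnirs" | "eeg"
    feature_labels: tuple
    adjacency: tuple[tuple[int, int], ...] | None = None
    keys: pd.DataFrame | None = None  # participant / condition / trial per row
    dropped_constant: tuple = ()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _standardize_columns(x: np.ndarray, labels: list) -> tuple[np.ndarray, list, list]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 1e-12
    dropped = [l for l, k in zip(labels, keep) if not k]
    if dropped:
        logger.warning("dropping constant feature columns: %s", dropped)
    x = (x[:, keep] - mean[keep]) / sd[keep]
    return x, [l for l, k in zip(labels, keep) if k], dropped


def fnirs_adjacency(
    geometry: ProbeGeometry, radius_cm: float = 3.0
) -> tuple[tuple[int, int], ...]:
    """Channels whose midpoints lie within ``radius_cm`` are neighbours."""
    mid = geometry.channel_midpoints
    d = np.linalg.norm(mid[:, None, :] - mid[None, :, :], axis=-1)
    edges = [
        (i, j)
        for i in range(len(mid))
        for j in range(i + 1, len(mid))
        if d[i, j] <= radius_cm
    ]
    return tuple(edges)


def _within_participant_standardize(wide: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column within participant; missing cells
    (excluded trials / rejected electrodes) are imputed as 0 = the
    participant mean."""
    def _z(g: pd.DataFrame) -> pd.DataFrame:
        mu = g.mean()
        sd = g.std(ddof=0).replace(0.0, np.nan)
        return ((g - mu) / sd).fillna(0.0)

    return wide.groupby(level="participant", group_keys=False).apply(_z)


def build_feature_sets(
    hb_table: pd.DataFrame,
    alpha_table: pd.DataFrame,
    condition: str | None = None,
    mode: str = "two_set_stacked",
    chromophore: str = "HbO",
    min_trials: int = 5,
    adjacency: tuple[tuple[int, int], ...] | None = None,
) -> list[FeatureSet]:
    """Align the two tidy feature tables into ssmCCA input sets.

    ``two_set_stacked`` (default): one fNIRS set (trials x channels) and one
    EEG set (trials x electrodes), trials stacked across participants after
    within-participant standardization. Participants contributing fewer
    than ``min_trials`` shared valid trials are dropped (mirrors the
    at-least-five-valid-trials rule). ``multiset_by_participant`` yields
    one set per (participant x modality), truncated to a common trial
    count.
    """
    hb = hb_table[(hb_table["chromophore"] == chromophore) & hb_table["included"]]
    if condition is not None:
        hb = hb[hb["condition"] == condition]
        alpha = alpha_table[alpha_table["condition"] == condition]
    else:
        alpha = alpha_table
    f_wide = hb.pivot_table(index=["participant", "condition", "trial"],
                            columns="channel", values="z")
    e_wide = alpha.pivot_table(index=["participant", "condition", "trial"],
                               columns="electrode", values="alpha_change")
    # electrodes missing for any participant (rejected) are dropped entirely
    by_part = e_wide.notna().groupby(level="participant").any()
    e_wide = e_wide.loc[:, by_part.all(axis=0)]
    shared = f_wide.index.intersection(e_wide.index)
    f_wide, e_wide = f_wide.loc[shared], e_wide.loc[shared]
    counts = shared.get_level_values("participant").value_counts()
    ok_parts = counts[counts >= min_trials].index
    for p in counts[counts < min_trials].index:
        logger.info("participant %s dropped (<%d shared trials)", p, min_trials)
    keep = shared.get_level_values("participant").isin(ok_parts)
    f_wide, e_wide = f_wide[keep], e_wide[keep]
    if len(f_wide) == 0:
        raise ValueError("no shared trials left after alignment")
    f_std = _within_participant_standardize(f_wide)
    e_std = _within_participant_standardize(e_wide)
    keys = f_std.index.to_frame(index=False)

    if mode == "two_set_stacked":
        xf, lf, df_ = _standardize_columns(
            f_std.to_numpy(float), list(f_std.columns))
        xe, le, de_ = _standardize_columns(
            e_std.to_numpy(float), list(e_std.columns))
        adj = _remap_adjacency(adjacency, list(f_std.columns), lf)
        return [
            FeatureSet(xf, "fnirs", tuple(lf), adj, keys, tuple(df_)),
            FeatureSet(xe, "eeg", tuple(le), None, keys, tuple(de_)),
        ]
    if mode == "multiset_by_participant":
        parts = sorted(set(keys["participant"]))
        n_common = min(
            (keys["participant"] == p).sum() for p in parts
        )
        sets: list[FeatureSet] = []
        for p in parts:
            rows = keys.index[keys["participant"] == p][:n_common]
            for wide, modality, ad in (
                (f_std, "fnirs", adjacency), (e_std, "eeg", None)
            ):
                x, labs, dropped = _standardize_columns(
                    wide.iloc[rows].to_numpy(float), list(wide.columns))
                adj = _remap_adjacency(ad, list(wide.columns), labs)
                sets.append(FeatureSet(
                    x, modality, tuple(labs), adj,
                    keys.iloc[rows].reset_index(drop=True), tuple(dropped)))
        return sets
    raise ValueError(f"unknown mode {mode!r}")


def _remap_adjacency(adjacency, original_labels, kept_labels):
    if adjacency is None:
        return None
    pos = {l: i for i, l in enumerate(kept_labels)}
    out = []
    for a, b in adjacency:
        la, lb = original_labels[a], original_labels[b]
        if la in pos and lb in pos:
            out.append((pos[la], pos[lb]))
    return tuple(out)


# --------------------------------------------------------------------------
# Proximal operators
# --------------------------------------------------------------------------

def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise ``sign(v) * max(|v| - lam, 0)`` (LASSO prox)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def _difference_matrix(p: int, adjacency) -> np.ndarray:
    d = np.zeros((len(adjacency), p))
    for k, (a, b) in enumerate(adjacency):
        if a == b:
            raise ValueError("self-loop in adjacency")
        d[k, a], d[k, b] = 1.0, -1.0
    return d


class FusedProxSolver:
    """ADMM solver for the graph fused-LASSO prox with cached factorization
    and warm starts (the inner loop of the fNIRS weight updates)."""

    def __init__(self, p: int, adjacency, rho: float = 1.0):
        self.p = p
        self.adjacency = tuple(adjacency)
        self.rho = rho
        self.d = _difference_matrix(p, self.adjacency)
        lap = self.d.T @ self.d
        self.chol = cho_factor(np.eye(p) * (1.0 + rho) + rho * lap)
        self.state: tuple | None = None

    def solve(self, v: np.ndarray, lam1: float, lam2: float,
              tol: float = 1e-8, max_iter: int = 20000,
              warm: bool = False) -> np.ndarray:
        rho, d = self.rho, self.d
        if warm and self.state is not None:
            z1, z2, u1, u2 = self.state
        else:
            z1, z2 = v.copy(), d @ v
            u1, u2 = np.zeros(self.p), np.zeros(len(self.adjacency))
        thr1, thr2 = lam1 / rho, lam2 / rho
        r_primal = np.inf
        for _ in range(max_iter):
            w = cho_solve(self.chol, v + rho * (z1 - u1) + rho * (d.T @ (z2 - u2)))
            dw = d @ w
            z1_new = soft_threshold(w + u1, thr1)
            z2_new = soft_threshold(dw + u2, thr2)
            r_primal = max(np.abs(w - z1_new).max(), np.abs(dw - z2_new).max())
            s_dual = rho * max(
                np.abs(z1_new - z1).max(),
                np.abs(d.T @ (z2_new - z2)).max() if len(z2) else 0.0,
            )
            z1, z2 = z1_new, z2_new
            u1 += w - z1
            u2 += dw - z2
            if r_primal < tol and s_dual < tol:
                break
        else:
            logger.warning("fused_lasso_prox: ADMM hit max_iter (resid %.2e)",
                           r_primal)
        self.state = (z1, z2, u1, u2)
        return z1  # feasible sparse iterate


def fused_lasso_prox(
    v: np.ndarray,
    lam1: float,
    lam2: float,
    adjacency: tuple[tuple[int, int], ...],
    tol: float = 1e-8,
    max_iter: int = 20000,
    rho: float = 1.0,
) -> np.ndarray:
    """Proximal operator of the graph fused LASSO,

    ``argmin_w 1/2 ||w - v||^2 + lam1 ||w||_1 + lam2 sum_E |w_a - w_b|``,

    solved by ADMM on the stacked splitting z = [w; Dw] (D = signed edge
    incidence). Non-convergence at ``max_iter`` returns the best iterate
    with a logged warning.
    """
    v = np.asarray(v, dtype=float)
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be >= 0")
    if lam2 == 0 or not adjacency:
        return soft_threshold(v, lam1)
    return FusedProxSolver(v.size, adjacency, rho).solve(
        v, lam1, lam2, tol, max_iter)


# --------------------------------------------------------------------------
# Penalized regression (inner solver)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty strengths; units are per the 1/(2n)||z - Xw||^2 loss with
    standardized columns."""

    lam_lasso_eeg: float = 0.10
    lam_lasso_fnirs: float = 0.10
    lam_fused_fnirs: float = 0.05
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self):
        if min(self.lam_lasso_eeg, self.lam_lasso_fnirs, self.lam_fused_fnirs) < 0:
            raise ValueError("penalties must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def for_modality(self, modality: str) -> tuple[float, float]:
        if modality == "fnirs":
            return self.lam_lasso_fnirs, self.lam_fused_fnirs
        return self.lam_lasso_eeg, 0.0

    def zero(self) -> bool:
        return (self.lam_lasso_eeg == 0 and self.lam_lasso_fnirs == 0
                and self.lam_fused_fnirs == 0)


def _penalized_regression(
    x: np.ndarray,
    z: np.ndarray,
    lam1: float,
    lam2: float,
    adjacency,
    n_iter: int = 300,
    tol: float = 1e-10,
    w0: np.ndarray | None = None,
    prox_solver: "FusedProxSolver | None" = None,
) -> np.ndarray:
    """argmin_w 1/(2n)||z - Xw||^2 + lam1||w||_1 + lam2 TV_graph(w), FISTA
    (warm-startable; the unpenalized case is a direct least-squares solve)."""
    n = x.shape[0]
    if lam1 == 0 and (lam2 == 0 or not adjacency):
        w, *_ = np.linalg.lstsq(x, z, rcond=None)
        return w
    use_fused = lam2 > 0 and adjacency
    if use_fused and prox_solver is None:
        prox_solver = FusedProxSolver(x.shape[1], adjacency)
    gram = x.T @ x / n
    xtz = x.T @ z / n
    lip = np.linalg.eigvalsh(gram)[-1]
    step = 1.0 / max(lip, 1e-12)
    w = np.zeros(x.shape[1]) if w0 is None else w0.copy()
    y = w.copy()
    t_k = 1.0
    for _ in range(n_iter):
        v = y - step * (gram @ y - xtz)
        if use_fused:
            w_new = prox_solver.solve(v, lam1 * step, lam2 * step,
                                      tol=1e-9, max_iter=3000, warm=True)
        else:
            w_new = soft_threshold(v, lam1 * step)
        t_next = (1 + np.sqrt(1 + 4 * t_k ** 2)) / 2
        y = w_new + (t_k - 1) / t_next * (w_new - w)
        if np.abs(w_new - w).max() < tol:
            w = w_new
            break
        w, t_k = w_new, t_next
    return w


# --------------------------------------------------------------------------
# ssmCCA
# --------------------------------------------------------------------------

@dataclass
class CanonicalComponent:
    """One fused component: per-set weights, variates, canonical correlation."""

    weights: list[np.ndarray]
    variates: list[np.ndarray]
    r: float
    rank: int = 0
    p: float | None = None
    attributed_roi: str | None = None
    roi_tie: bool = False
    converged: bool = True
    n_sweeps: int = 0
    objective_history: list[float] = field(default_factory=list)


def _penalty_value(w: np.ndarray, lam1: float, lam2: float, adjacency) -> float:
    val = lam1 * np.abs(w).sum()
    if lam2 > 0 and adjacency:
        val += lam2 * sum(abs(w[a] - w[b]) for a, b in adjacency)
    return float(val)


def _mean_pairwise_corr(variates: list[np.ndarray]) -> float:
    cs = [
        float(np.corrcoef(ui, uj)[0, 1])
        for ui, uj in itertools.combinations(variates, 2)
    ]
    return float(np.mean(cs))


def _mean_pairwise_dot(us: list[np.ndarray], n: int) -> float:
    # variates are exactly mean-zero (standardized columns) and unit-SD
    # after normalization, so corr(ui, uj) = ui.uj / n
    cs = [float(ui @ uj) / n for ui, uj in itertools.combinations(us, 2)]
    return float(np.mean(cs))


def _init_weight(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # leading right singular vector; seed noise only breaks exact ties
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    w = vt[0] + 1e-9 * rng.standard_normal(x.shape[1])
    i = np.argmax(np.abs(w))
    return w * np.sign(w[i])


def _extract_component(
    xs: list[np.ndarray],
    sets: list[FeatureSet],
    penalties: PenaltyConfig,
    solvers: list["FusedProxSolver | None"],
    rng: np.random.Generator,
    max_sweeps: int,
    tol: float,
    index: int,
) -> CanonicalComponent | None:
    """One component by block-coordinate ascent; None if over-penalized."""
    n = xs[0].shape[0]
    # unpenalized updates are plain least squares: cache the
    # pseudo-inverse once per component (X fixed across sweeps)
    pinvs = [
        np.linalg.pinv(x)
        if penalties.for_modality(st.modality) == (0.0, 0.0) else None
        for x, st in zip(xs, sets)
    ]
    ws = [_init_weight(x, rng) for x in xs]
    us = []
    for x, w in zip(xs, ws):
        u = x @ w
        sd = np.sqrt(u @ u / n)  # columns are mean-zero
        if sd < 1e-12:
            logger.warning("degenerate initialization; component terminated")
            return None
        w /= sd
        us.append(x @ w)
    history: list[float] = []
    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        delta = 0.0
        for m, (x, st) in enumerate(zip(xs, sets)):
            others = [us[j] for j in range(len(xs)) if j != m]
            z = others[0] if len(others) == 1 else np.mean(others, axis=0)
            lam1, lam2 = penalties.for_modality(st.modality)
            if pinvs[m] is not None:
                w_new = pinvs[m] @ z
            else:
                w_new = _penalized_regression(
                    x, z, lam1, lam2, st.adjacency,
                    n_iter=penalties.max_iter,
                    w0=ws[m] if sweep > 0 else None,
                    prox_solver=solvers[m],
                )
            u = x @ w_new
            sd = np.sqrt(u @ u / n)
            if sd < 1e-12:
                logger.warning(
                    "all-zero weights in set %d (over-penalized); "
                    "component %d terminated", m, index + 1)
                return None
            w_new = w_new / sd
            delta = max(delta, np.abs(w_new - ws[m]).max())
            ws[m] = w_new
            us[m] = u / sd
        obj = sum(
            float(ui @ uj) / n
            for ui, uj in itertools.combinations(us, 2)
        )
        if not penalties.zero():
            obj -= sum(
                _penalty_value(
                    w, *penalties.for_modality(st.modality), st.adjacency)
                for w, st in zip(ws, sets)
            )
        history.append(obj)
        sweeps = sweep + 1
        if delta < tol:
            converged = True
            break
    return CanonicalComponent(
        weights=[w.copy() for w in ws],
        variates=[u.copy() for u in us],
        r=_mean_pairwise_dot(us, n),
        converged=converged,
        n_sweeps=sweeps,
        objective_history=history,
    )


def ssmcca_fit(
    sets: list[FeatureSet],
    penalties: PenaltyConfig = PenaltyConfig(),
    n_components: int = 3,
    seed: int = 0,
    max_sweeps: int = 500,
    tol: float = 1e-6,
    penalty_backoff: bool = False,
) -> list[CanonicalComponent]:
    """Fit K ssmCCA components by block-coordinate ascent with deflation.

    Per sweep, each set's weight vector is refit by (penalized) least
    squares of the mean of the other sets' variates on that set's columns
    — soft-thresholding for EEG sets, graph fused-LASSO prox for fNIRS
    sets — and rescaled so its variate has unit SD. After convergence the
    fitted variate is regressed out of every set (deflation) and the next
    component is extracted. Components are returned ordered by decreasing
    canonical correlation (mean pairwise variate correlation).

    An over-penalized component (all-zero weights in some set) normally
    terminates extraction; with ``penalty_backoff`` the penalties are
    halved (up to 8 times, logged) for that component so that weaker,
    later components can still be reported.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    n = sets[0].n
    if any(s.n != n for s in sets):
        raise ValueError("sets must share the observation dimension")
    if n < 3:
        raise ValueError("need at least 3 observations")
    rng = np.random.default_rng(seed)
    xs = [s.X.copy() for s in sets]
    solvers: list[FusedProxSolver | None] = []
    for s in sets:
        lam1, lam2 = penalties.for_modality(s.modality)
        if lam2 > 0 and s.adjacency:
            solvers.append(FusedProxSolver(s.p, s.adjacency))
        else:
            solvers.append(None)
    comps: list[CanonicalComponent] = []
    for _k in range(n_components):
        pen_k = penalties
        comp = _extract_component(
            xs, sets, pen_k, solvers, rng, max_sweeps, tol, _k)
        if comp is None and penalty_backoff:
            for _ in range(8):
                pen_k = PenaltyConfig(
                    lam_lasso_eeg=pen_k.lam_lasso_eeg / 2,
                    lam_lasso_fnirs=pen_k.lam_lasso_fnirs / 2,
                    lam_fused_fnirs=pen_k.lam_fused_fnirs / 2,
                    max_iter=pen_k.max_iter, tol=pen_k.tol,
                )
                logger.info("component %d: retrying with halved penalties",
                            _k + 1)
                comp = _extract_component(
                    xs, sets, pen_k, solvers, rng, max_sweeps, tol, _k)
                if comp is not None:
                    break
        if comp is None:
            break
        comps.append(comp)
        for m in range(len(xs)):
            u = comp.variates[m]
            denom = float(u @ u)
            if denom > 0:
                xs[m] = xs[m] - np.outer(u, u @ xs[m] / denom)
    return _finalize(comps)


def _finalize(comps: list[CanonicalComponent]) -> list[CanonicalComponent]:
    comps = sorted(comps, key=lambda c: -c.r)
    for i, c in enumerate(comps):
        c.rank = i + 1
    return comps


# --------------------------------------------------------------------------
# Inference and attribution
# --------------------------------------------------------------------------

def permutation_pvalue(
    sets: list[FeatureSet],
    penalties: PenaltyConfig,
    observed_r: float | None = None,
    n_perm: int = 199,
    seed: int = 0,
) -> float:
    """Permutation p-value of the first component's canonical correlation.

    Observation rows of every set except the first are permuted
    independently per permutation; the first component is refit each time;
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    if observed_r is None:
        observed_r = ssmcca_fit(sets, penalties, n_components=1, seed=seed)[0].r
    count = 0
    for _ in range(n_perm):
        permuted = [sets[0]]
        for s in sets[1:]:
            idx = rng.permutation(s.n)
            permuted.append(FeatureSet(
                s.X[idx], s.modality, s.feature_labels, s.adjacency))
        comps = ssmcca_fit(permuted, penalties, n_components=1, seed=seed)
        if comps and comps[0].r >= observed_r:
            count += 1
    return (1 + count) / (1 + n_perm)


def attribute_roi(
    weights_fnirs: np.ndarray,
    channel_labels: tuple,
    roi_map: RoiMap = DEFAULT_ROI_MAP,
) -> tuple[str, bool]:
    """ROI with the largest summed |w| over its channels.

    Ties broken by larger maximum single-channel |w|, then alphabetically;
    returns (roi, tie_flag); all-zero weights give ("none", False).
    """
    w = np.abs(np.asarray(weights_fnirs, dtype=float))
    if not np.any(w):
        return "none", False
    mass: dict[str, float] = {}
    peak: dict[str, float] = {}
    for wi, ch in zip(w, channel_labels):
        roi = roi_map.fnirs.get(int(ch))
        if roi is None:
            continue
        mass[roi] = mass.get(roi, 0.0) + float(wi)
        peak[roi] = max(peak.get(roi, 0.0), float(wi))
    if not mass:
        return "none", False
    ranked = sorted(mass, key=lambda r: (-mass[r], -peak[r], r))
    best = ranked[0]
    tie = len(ranked) > 1 and np.isclose(mass[ranked[1]], mass[best])
    return best, tie


def annotate_components(
    comps: list[CanonicalComponent],
    sets: list[FeatureSet],
    penalties: PenaltyConfig,
    roi_map: RoiMap = DEFAULT_ROI_MAP,
    n_perm: int | None = None,
    seed: int = 0,
) -> list[CanonicalComponent]:
    """Attach ROI attribution (from the fNIRS set's weights) and, when
    requested, a permutation p-value for the leading component."""
    fnirs_pos = next(i for i, s in enumerate(sets) if s.modality == "fnirs")
    for c in comps:
        roi, tie = attribute_roi(
            c.weights[fnirs_pos], sets[fnirs_pos].feature_labels, roi_map)
        c.attributed_roi, c.roi_tie = roi, tie
    if n_perm and comps:
        comps[0].p = permutation_pvalue(
            sets, penalties, observed_r=comps[0].r, n_perm=n_perm, seed=seed)
    return comps


# --------------------------------------------------------------------------
# Penalty selection
# --------------------------------------------------------------------------

def select_penalties_cv(
    sets: list[FeatureSet],
    grid: list[PenaltyConfig] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    max_sweeps: int = 150,
) -> PenaltyConfig:
    """Grid search maximizing mean held-out first-component correlation
    under k-fold row-wise cross-validation (a capped sweep budget keeps
    the search affordable; the final model is refit at full precision)."""
    if grid is None:
        grid = [
            PenaltyConfig(lam_lasso_eeg=le, lam_lasso_fnirs=lf, lam_fused_fnirs=ff)
            for le in (0.01, 0.05, 0.1)
            for lf, ff in ((0.01, 0.01), (0.05, 0.05), (0.1, 0.1))
        ]
    n = sets[0].n
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    best, best_score = grid[0], -np.inf
    for pen in grid:
        scores = []
        for f in folds:
            train = np.setdiff1d(order, f)
            tr_sets = [
                FeatureSet(s.X[train], s.modality, s.feature_labels, s.adjacency)
                for s in sets
            ]
            comps = ssmcca_fit(tr_sets, pen, n_components=1, seed=seed,
                               max_sweeps=max_sweeps)
            if not comps:
                scores.append(-np.inf)
                continue
            held = [s.X[f] @ c for s, c in zip(sets, comps[0].weights)]
            if any(h.std() < 1e-12 for h in held):
                scores.append(-np.inf)
                continue
            scores.append(_mean_pairwise_corr(held))
        score = float(np.mean(scores))
        if score > best_score:
            best, best_score = pen, score
    return best


__all__ = [
    "FeatureSet", "fnirs_adjacency", "build_feature_sets", "soft_threshold",
    "fused_lasso_prox", "PenaltyConfig", "CanonicalComponent", "ssmcca_fit",
    "permutation_pvalue", "attribute_roi", "annotate_components",
    "select_penalties_cv",
]
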