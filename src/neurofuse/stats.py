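"""Group-level comparisons of the unimodal feature tables.

Two-way repeated-measures ANOVA with within-subject factors condition
(ME, MO, MI) and region of interest, plus paired post-hoc t-tests with
Cohen's dz. Sphericity is handled by reporting the Greenhouse-Geisser
corrected p alongside the uncorrected one. pingouin does the
sums-of-squares partitioning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RmAnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    p_gg: float
    eps: float
    effect_size: float  # generalized eta-squared


def _complete_cases(
    table: pd.DataFrame, dv: str, subject: str, factors: tuple[str, str]
) -> pd.DataFrame:
    """Average replicates to cell means and drop subjects missing any cell."""
    cells = (
        table.groupby([subject, *factors], as_index=False)[dv]
        .mean()
    )
    n_cells = cells.groupby(subject).size()
    full = n_cells.max()
    keep = n_cells[n_cells == full].index
    dropped = sorted(set(n_cells.index) - set(keep))
    if dropped:
        logger.info("rm_anova: dropped incomplete subjects %s", dropped)
    return cells[cells[subject].isin(keep)]


def rm_anova(
    table: pd.DataFrame,
    dv: str = "z",
    subject: str = "participant",
    factors: tuple[str, str] = ("condition", "roi"),
) -> list[RmAnovaResult]:
    """Two-factor within-subject ANOVA on cell means.

    Replicate observations (trials) are first averaged to one value per
    (subject, condition, region) cell; subjects missing any cell are
    dropped with a log entry. Requires >= 3 complete subjects.
    """
    import pingouin as pg

    cells = _complete_cases(table, dv, subject, factors)
    n_sub = cells[subject].nunique()
    if n_sub < 3:
        raise ValueError(f"need >= 3 complete participants, got {n_sub}")
    import warnings

    with warnings.catch_warnings():
        # pingouin warns that epsilon may be approximate for >2-level
        # two-way designs; the uncorrected statistics are unaffected
        warnings.filterwarnings("ignore", message="Epsilon values")
        aov = pg.rm_anova(
            data=cells, dv=dv, within=list(factors), subject=subject,
            correction=True, effsize="ng2",
        )
    out = []
    for _, row in aov.iterrows():
        out.append(RmAnovaResult(
            effect=str(row["Source"]).replace(" * ", " x "),
            F=float(row["F"]),
            df_num=float(row["ddof1"]),
            df_den=float(row["ddof2"]),
            p=float(row["p_unc"]),
            p_gg=float(row.get("p_GG_corr", np.nan)),
            eps=float(row.get("eps", np.nan)),
            effect_size=float(row.get("ng2", np.nan)),
        ))
    return out


@dataclass(frozen=True)
class PairedTResult:
    contrast: str
    t: float
    df: int
    p: float
    cohen_dz: float
    degenerate: bool = False


def posthoc_paired_t(
    table: pd.DataFrame,
    dv: str,
    contrasts: list[tuple[dict, dict, str]],
    subject: str = "participant",
    correction: str | None = None,
) -> list[PairedTResult]:
    """Paired t-tests for named contrasts.

    Each contrast is (selector_a, selector_b, name): the selectors filter
    the table (e.g. ``{"condition": "ME", "roi": "Left AG"}``), values are
    averaged per subject, and subjects present in both cells are paired.
    ``correction`` may be "holm" (statsmodels) or None (uncorrected,
    default). Zero-variance differences are flagged degenerate.
    """
    results = []
    for sel_a, sel_b, name in contrasts:
        a = _cell_means(table, dv, subject, sel_a)
        b = _cell_means(table, dv, subject, sel_b)
        merged = a.to_frame("a").join(b.to_frame("b"), how="inner").dropna()
        if len(merged) < 3:
            raise ValueError(f"contrast {name!r}: fewer than 3 pairs")
        diff = merged["a"] - merged["b"]
        if diff.std(ddof=1) == 0:
            if (diff == 0).all():  # identical vectors: no effect at all
                results.append(PairedTResult(name, 0.0, len(diff) - 1, 1.0,
                                             0.0))
            else:  # constant nonzero difference: t undefined
                results.append(PairedTResult(name, np.nan, len(diff) - 1,
                                             np.nan, np.nan, degenerate=True))
            continue
        t, p = sps.ttest_rel(merged["a"], merged["b"])
        dz = diff.mean() / diff.std(ddof=1)
        results.append(PairedTResult(name, float(t), len(diff) - 1, float(p),
                                     float(dz)))
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        ok = [i for i, r in enumerate(results) if not r.degenerate]
        if ok:
            _, p_adj, *_ = multipletests([results[i].p for i in ok], method="holm")
            for i, pa in zip(ok, p_adj):
                r = results[i]
                results[i] = PairedTResult(r.contrast, r.t, r.df, float(pa),
                                           r.cohen_dz)
    return results


def _cell_means(table, dv, subject, selector) -> pd.Series:
    mask = np.ones(len(table), dtype=bool)
    for k, v in selector.items():
        mask &= (table[k] == v).to_numpy()
    return table[mask].groupby(subject)[dv].mean()


__all__ = ["RmAnovaResult", "rm_anova", "PairedTResult", "posthoc_paired_t"]
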