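"""Sensitivity diagnostics: heterogeneity, pleiotropic outliers, influence.

* :func:`cochran_q` — Cochran's Q about the fixed-effects IVW estimate
  (chi-square with k-1 df under homogeneity) or about the fitted Egger line
  (k-2 df), driving the fixed-vs-random IVW model choice.
* :func:`presso` — simulation-based residual-sum-of-squares outlier test:
  a global heterogeneity p-value, per-SNP outlier p-values (Bonferroni
  adjusted), an outlier-corrected estimate, and a distortion test comparing
  raw vs corrected estimates.
* :func:`leave_one_out` — re-estimates with each instrument removed in turn.
* :func:`diagnostics_tables` — plot-ready funnel and forest tables (no
  rendering here; downstream tooling draws them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    IVW_FIXED,
    PRESSO_CORRECTED,
    MREstimate,
    WaldRatios,
    Z95,
    _make_estimate,
    egger,
    ivw,
    ivw_beta_se,
    wald_ratios,
)
from .exceptions import EstimationError
from .sumstats import HarmonizedSet


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic with df and upper-tail p."""

    q: float
    df: int
    p: float


def cochran_q(data: WaldRatios | HarmonizedSet, reference: str = "ivw") -> QResult:
    """Heterogeneity of per-SNP estimates about a pooled reference.

    ``reference='ivw'`` accepts Wald ratios (or a harmonized set) and
    measures Q about the fixed-effects IVW estimate with df = k-1.
    ``reference='egger'`` requires a harmonized set, measures weighted
    residuals about the fitted Egger line with df = k-2.
    """
    if reference == "ivw":
        ratios = wald_ratios(data) if isinstance(data, HarmonizedSet) else data
        k = ratios.k
        if k < 2:
            raise EstimationError(f"cochran_q(ivw) needs k >= 2, got {k}")
        w = ratios.weight
        beta, _ = ivw_beta_se(ratios.ratio, w)
        q = float((w * (ratios.ratio - beta) ** 2).sum())
        df = k - 1
    elif reference == "egger":
        if not isinstance(data, HarmonizedSet):
            raise EstimationError("cochran_q(egger) requires a HarmonizedSet")
        k = len(data.instruments)
        if k < 3:
            raise EstimationError(f"cochran_q(egger) needs k >= 3, got {k}")
        res = egger(data)
        inst = data.instruments
        bx = inst["beta_x"].to_numpy(float).copy()
        by = inst["beta_y"].to_numpy(float).copy()
        sy = inst["se_y"].to_numpy(float)
        flip = bx < 0
        bx[flip] *= -1.0
        by[flip] *= -1.0
        resid = by - res.intercept - res.estimate.beta * bx
        q = float(((resid / sy) ** 2).sum())
        df = k - 2
    else:
        raise EstimationError(f"unknown cochran_q reference {reference!r}")

    p = float(stats.chi2.sf(q, df))
    return QResult(q=q, df=df, p=max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    """Global heterogeneity, per-SNP outlier flags, and corrected estimate."""

    global_rss_obs: float
    global_p: float
    outlier_p: dict
    outliers: list
    distortion_p: float | None
    corrected: MREstimate | None


def _loo_slopes(bx: np.ndarray, Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out weighted through-origin slopes, vectorized over rows of Y."""
    sxx = float((w * bx * bx).sum())
    sxy = (w * bx * Y).sum(axis=-1, keepdims=True)
    return (sxy - w * bx * Y) / (sxx - w * bx * bx)


def presso(
    h: HarmonizedSet,
    n_sim: int = 5000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Pleiotropy residual-sum and outlier test.

    The observed RSS sums weighted squared residuals of each beta_y about
    the leave-one-out IVW prediction.  Its null distribution is built by
    parametric simulation: beta_y_j* ~ Normal(loo_slope_j * beta_x_j,
    se_y_j), n_sim replicates.  The global p is the rank-based tail
    probability (floored at 1/(n_sim+1), never 0).  Per-SNP contributions
    yield outlier p-values, Bonferroni-adjusted across the k instruments;
    when outliers are flagged, the corrected estimate is IVW on the
    remainder and the distortion p compares the observed estimate shift to
    shifts from removing equally many instruments at random.
    """
    k = len(h.instruments)
    if k < 4:
        raise EstimationError(f"presso needs >= 4 instruments, got {k}")
    if n_sim < 1000:
        raise EstimationError(f"n_sim must be >= 1000, got {n_sim}")
    if seed is None:
        raise EstimationError("presso requires an explicit seed")

    inst = h.instruments
    ids = inst["snp_id"].to_numpy()
    bx = inst["beta_x"].to_numpy(float)
    by = inst["beta_y"].to_numpy(float)
    sy = inst["se_y"].to_numpy(float)
    w = sy ** -2.0

    slopes_obs = _loo_slopes(bx, by[None, :], w)[0]
    contrib_obs = w * (by - slopes_obs * bx) ** 2
    rss_obs = float(contrib_obs.sum())

    rng = np.random.default_rng(seed)
    Y = rng.normal(slopes_obs * bx, sy, size=(n_sim, k))
    slopes_sim = _loo_slopes(bx, Y, w)
    contrib_sim = w * (Y - slopes_sim * bx) ** 2
    rss_sim = contrib_sim.sum(axis=1)

    global_p = float((1 + (rss_sim >= rss_obs).sum()) / (n_sim + 1))

    raw_p = (1 + (contrib_sim >= contrib_obs).sum(axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * k)
    is_out = adj_p < outlier_alpha
    outliers = [str(s) for s in ids[is_out]]
    outlier_p = dict(zip(map(str, ids), adj_p.astype(float)))

    corrected = None
    distortion_p = None
    if outliers:
        keep = ~is_out
        if keep.sum() >= 1:
            r_keep = by[keep] / bx[keep]
            w_keep = (sy[keep] / np.abs(bx[keep])) ** -2.0
            beta_c, se_c = ivw_beta_se(r_keep, w_keep)
            corrected = _make_estimate(PRESSO_CORRECTED, beta_c, se_c, int(keep.sum()))

            r_all = by / bx
            w_all = (sy / np.abs(bx)) ** -2.0
            beta_all, _ = ivw_beta_se(r_all, w_all)
            d_obs = beta_c - beta_all
            n_out = int(is_out.sum())
            shifts = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(k, size=n_out, replace=False)
                m = np.ones(k, bool)
                m[drop] = False
                b_s, _ = ivw_beta_se(r_all[m], w_all[m])
                shifts[s] = b_s - beta_all
            distortion_p = float(
                (1 + (np.abs(shifts) >= abs(d_obs)).sum()) / (n_sim + 1)
            )

    return PressoResult(
        global_rss_obs=rss_obs,
        global_p=global_p,
        outlier_p=outlier_p,
        outliers=outliers,
        distortion_p=distortion_p,
        corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Leave-one-out
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LOORecord:
    """IVW estimate with one instrument removed."""

    left_out_snp: str
    estimate: MREstimate


def leave_one_out(h: HarmonizedSet) -> list[LOORecord]:
    """Re-estimate (IVW, Q-rule model choice) leaving each SNP out in turn."""
    k = len(h.instruments)
    if k < 3:
        raise EstimationError(f"leave_one_out needs >= 3 instruments, got {k}")
    records = []
    for snp in h.instruments["snp_id"]:
        sub = h.drop([snp])
        est = ivw(wald_ratios(sub), model="auto")
        records.append(LOORecord(left_out_snp=str(snp), estimate=est))
    return records


# ---------------------------------------------------------------------------
# Funnel / forest tables
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsTables:
    """Plot-ready funnel and forest tables."""

    funnel: pd.DataFrame
    funnel_references: pd.DataFrame
    forest: pd.DataFrame


def diagnostics_tables(
    h: HarmonizedSet, estimates: list[MREstimate]
) -> DiagnosticsTables:
    """Build funnel (ratio vs precision) and forest (per-SNP CI) tables.

    The funnel table pairs each instrument's Wald ratio with its precision
    1/se_ratio; reference lines mark each method's pooled beta.  The forest
    table lists per-SNP ratios with 95% CIs followed by one summary row per
    supplied method estimate.
    """
    ratios = wald_ratios(h)
    funnel = pd.DataFrame(
        {
            "snp_id": ratios.snp_ids,
            "ratio": ratios.ratio,
            "precision": 1.0 / ratios.se_ratio,
        }
    )
    funnel_refs = pd.DataFrame(
        {"method": [e.method for e in estimates], "beta": [e.beta for e in estimates]}
    )
    per_snp = pd.DataFrame(
        {
            "label": ratios.snp_ids,
            "kind": "snp",
            "beta": ratios.ratio,
            "ci_low": ratios.ratio - Z95 * ratios.se_ratio,
            "ci_high": ratios.ratio + Z95 * ratios.se_ratio,
        }
    )
    summaries = pd.DataFrame(
        {
            "label": [e.method for e in estimates],
            "kind": "summary",
            "beta": [e.beta for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )
    forest = pd.concat([per_snp, summaries], ignore_index=True)
    return DiagnosticsTables(funnel=funnel, funnel_references=funnel_refs, forest=forest)


def sensitivity_row(outcome_label: str, h: HarmonizedSet) -> dict:
    """One combined pleiotropy/heterogeneity row: Egger intercept test plus
    the paired Egger-reference and IVW-reference Q statistics."""
    egg = egger(h)
    q_egger = cochran_q(h, reference="egger")
    q_ivw = cochran_q(h, reference="ivw")
    return {
        "outcome": outcome_label,
        "egger_intercept": egg.intercept,
        "egger_intercept_se": egg.intercept_se,
        "egger_intercept_p": egg.intercept_p,
        "egger_q": q_egger.q,
        "egger_q_df": q_egger.df,
        "egger_q_p": q_egger.p,
        "ivw_q": q_ivw.q,
        "ivw_q_df": q_ivw.df,
        "ivw_q_p": q_ivw.p,
    }
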