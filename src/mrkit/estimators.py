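"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrkit.sumstats.HarmonizedSet` (or the
per-SNP Wald ratios derived from one) and return an :class:`MREstimate`
carrying the causal effect per unit log-odds of exposure on both the beta
(log-odds) and odds-ratio scales.

Implemented methods
-------------------
* inverse-variance weighted (fixed, multiplicative-random, or Q-rule auto)
* MR-Egger regression with intercept-based pleiotropy test
* weighted median (robust to <50% invalid weight), bootstrap SE
* maximum likelihood under a bivariate normal measurement model
* robust adjusted profile score (RAPS), plain or Huber loss, optional
  additive overdispersion

Confidence intervals use the 1.96 normal quantile and p-values the standard
normal reference throughout, matching symmetric 95% reporting conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
from scipy import optimize, stats

from .exceptions import ConvergenceError, EmptyInputError, EstimationError
from .sumstats import HarmonizedSet

Z95 = 1.959963984540054  # standard normal 97.5% quantile

IVW_FIXED = "ivw_fixed"
IVW_RANDOM = "ivw_random"
EGGER = "egger"
WEIGHTED_MEDIAN = "weighted_median"
MAX_LIKELIHOOD = "max_likelihood"
RAPS = "raps"
PRESSO_CORRECTED = "presso_corrected"


class WaldRatio(NamedTuple):
    """Per-SNP causal estimate beta_y / beta_x with first-order SE."""

    snp_id: str
    ratio: float
    se_ratio: float
    weight: float


@dataclass
class WaldRatios:
    """Vector of per-SNP Wald ratios, order-preserving."""

    snp_ids: np.ndarray
    ratio: np.ndarray
    se_ratio: np.ndarray

    @property
    def weight(self) -> np.ndarray:
        return self.se_ratio ** -2.0

    @property
    def k(self) -> int:
        return self.ratio.size

    def __len__(self) -> int:
        return self.ratio.size

    def __iter__(self) -> Iterator[WaldRatio]:
        for s, r, se, w in zip(self.snp_ids, self.ratio, self.se_ratio, self.weight):
            yield WaldRatio(str(s), float(r), float(se), float(w))


@dataclass(frozen=True)
class MREstimate:
    """One method's causal-effect estimate with CI on beta and OR scales."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    k: int

    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope estimate plus the intercept pleiotropy test."""

    estimate: MREstimate
    intercept: float
    intercept_se: float
    intercept_p: float


def _make_estimate(method: str, beta: float, se: float, k: int) -> MREstimate:
    if se <= 0 or not np.isfinite(se):
        raise EstimationError(f"{method}: non-positive or non-finite SE ({se})")
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        p=float(max(p, np.finfo(float).tiny)),
        k=int(k),
    )


def wald_ratios(h: HarmonizedSet) -> WaldRatios:
    """Per-SNP ratio estimates beta_y/beta_x with first-order SE se_y/|beta_x|."""
    df = h.instruments
    if df.empty:
        raise EmptyInputError("no harmonized instruments")
    bx = df["beta_x"].to_numpy(float)
    zero = bx == 0.0
    if zero.any():
        bad = df.loc[zero, "snp_id"].tolist()
        raise EstimationError(f"beta_x = 0 for {bad}; Wald ratio undefined")
    by = df["beta_y"].to_numpy(float)
    sy = df["se_y"].to_numpy(float)
    return WaldRatios(
        snp_ids=df["snp_id"].to_numpy(),
        ratio=by / bx,
        se_ratio=sy / np.abs(bx),
    )


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw_beta_se(ratio: np.ndarray, weight: np.ndarray) -> tuple[float, float]:
    """Fixed-effects inverse-variance pooled estimate and SE (array core)."""
    wsum = weight.sum()
    beta = float((weight * ratio).sum() / wsum)
    return beta, float(wsum ** -0.5)


def ivw(ratios: WaldRatios, model: str = "auto") -> MREstimate:
    """Inverse-variance-weighted pooled estimate.

    ``fixed`` assumes homogeneity; ``random`` applies multiplicative SE
    inflation max(1, sqrt(Q/(k-1))); ``auto`` picks fixed when Cochran's Q
    p >= 0.05 and random otherwise, the conventional heterogeneity rule.
    """
    if model not in ("fixed", "random", "auto"):
        raise EstimationError(f"unknown IVW model {model!r}")
    k = ratios.k
    if k == 0:
        raise EmptyInputError("ivw: empty input")
    if k < 2 and model != "fixed":
        raise EstimationError(f"ivw model={model!r} needs k >= 2, got {k}")

    w = ratios.weight
    beta, se_fixed = ivw_beta_se(ratios.ratio, w)

    if model == "fixed":
        return _make_estimate(IVW_FIXED, beta, se_fixed, k)

    q = float((w * (ratios.ratio - beta) ** 2).sum())
    q_p = float(stats.chi2.sf(q, k - 1))
    scale = max(1.0, math.sqrt(q / (k - 1)))
    if model == "random" or q_p < 0.05:
        return _make_estimate(IVW_RANDOM, beta, se_fixed * scale, k)
    return _make_estimate(IVW_FIXED, beta, se_fixed, k)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression of beta_y on beta_x with an intercept.

    Instruments are first oriented so beta_x > 0 (negating both effects
    where needed); weights are se_y^-2.  The intercept estimates the average
    directional pleiotropic effect; its test is the standard pleiotropy
    check.  SEs carry a multiplicative overdispersion scale floored at 1.
    """
    df = h.instruments
    k = len(df)
    if k < 3:
        raise EstimationError(f"egger needs >= 3 instruments, got {k}")

    bx = df["beta_x"].to_numpy(float).copy()
    by = df["beta_y"].to_numpy(float).copy()
    sy = df["se_y"].to_numpy(float)
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0

    if np.ptp(bx) == 0.0:
        raise EstimationError("egger: oriented beta_x has zero variance (collinear)")

    w = sy ** -2.0
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    coef = xtwx_inv @ (XtW @ by)
    resid = by - X @ coef
    q = float((w * resid ** 2).sum())
    scale = max(1.0, math.sqrt(q / (k - 2)))
    se = np.sqrt(np.diag(xtwx_inv)) * scale

    est = _make_estimate(EGGER, coef[1], se[1], k)
    icpt_p = 2.0 * stats.norm.sf(abs(coef[0]) / se[0])
    return EggerResult(
        estimate=est,
        intercept=float(coef[0]),
        intercept_se=float(se[0]),
        intercept_p=float(max(icpt_p, np.finfo(float).tiny)),
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------

def weighted_median_point(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median of ratio with the half-weight convention."""
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    w = weight[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, r))


def weighted_median(
    ratios: WaldRatios, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Consistent when at least half of the total weight comes from valid
    instruments.  The SE resamples each ratio from a normal centred at its
    observed value with its own se_ratio, recomputing the weighted median
    ``n_boot`` times.
    """
    k = ratios.k
    if k < 3:
        raise EstimationError(f"weighted_median needs >= 3 instruments, got {k}")
    if n_boot < 100:
        raise EstimationError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise EstimationError("weighted_median requires an explicit seed")

    w = ratios.weight
    point = weighted_median_point(ratios.ratio, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(ratios.ratio, ratios.se_ratio, size=(n_boot, k))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = weighted_median_point(draws[b], w)
    se = float(boots.std(ddof=1))
    if se == 0.0:  # degenerate all-equal-ratio input
        se = float(np.min(ratios.se_ratio)) * 1e-12 + np.finfo(float).tiny
    return _make_estimate(WEIGHTED_MEDIAN, point, se, k)


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

def _profile_negloglik(b: float, bx, by, sx2, sy2) -> float:
    # gamma_j profiled out of the bivariate normal measurement model; the
    # normalizing constants do not depend on b and are dropped
    denom = sy2 + b * b * sx2
    return float(0.5 * np.sum((by - b * bx) ** 2 / denom))


def max_likelihood(h: HarmonizedSet) -> MREstimate:
    """Maximum-likelihood causal estimate under a measurement-error model.

    Observed (beta_x_j, beta_y_j) are modelled as independent normals centred
    on (gamma_j, b * gamma_j) with known SDs (se_x_j, se_y_j); the nuisance
    gamma_j are profiled out and b maximizes the resulting profile
    likelihood.  The SE comes from the observed information (negative second
    derivative of the profile log-likelihood at the optimum).
    """
    df = h.instruments
    k = len(df)
    if k < 1:
        raise EmptyInputError("max_likelihood: no instruments")
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sx2 = df["se_x"].to_numpy(float) ** 2
    sy2 = df["se_y"].to_numpy(float) ** 2

    b0, _ = ivw_beta_se(by / bx, (sy2 / bx ** 2) ** -1.0)
    spread = 10.0 * (abs(b0) + 1.0)
    res = optimize.minimize_scalar(
        _profile_negloglik,
        bounds=(b0 - spread, b0 + spread),
        args=(bx, by, sx2, sy2),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise ConvergenceError(
            "max_likelihood failed to converge", {"scipy_message": res.message}
        )
    b_hat = float(res.x)

    step = 1e-5 * max(1.0, abs(b_hat))
    f = _profile_negloglik
    d2 = (
        f(b_hat + step, bx, by, sx2, sy2)
        - 2.0 * f(b_hat, bx, by, sx2, sy2)
        + f(b_hat - step, bx, by, sx2, sy2)
    ) / step ** 2
    if d2 <= 0:
        raise ConvergenceError(
            "max_likelihood: non-positive observed information",
            {"d2": d2, "b_hat": b_hat},
        )
    return _make_estimate(MAX_LIKELIHOOD, b_hat, d2 ** -0.5, k)


# ---------------------------------------------------------------------------
# RAPS
# ---------------------------------------------------------------------------

_HUBER_C = 1.345
# E[psi_c(Z) * Z] for standard normal Z; normalizes the overdispersion moment
_HUBER_DELTA = 2.0 * stats.norm.cdf(_HUBER_C) - 1.0
# E[psi_c(Z)^2]: truncated second moment plus the clipped tails
_HUBER_VAR = (
    2.0 * stats.norm.cdf(_HUBER_C) - 1.0
    - 2.0 * _HUBER_C * stats.norm.pdf(_HUBER_C)
    + 2.0 * _HUBER_C ** 2 * stats.norm.sf(_HUBER_C)
)


def _psi(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "plain":
        return t
    return np.clip(t, -_HUBER_C, _HUBER_C)


def _psi_prime(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "plain":
        return np.ones_like(t)
    return (np.abs(t) <= _HUBER_C).astype(float)


def _raps_score(b: float, tau2: float, bx, by, sx2, sy2, loss: str) -> float:
    s2 = sy2 + b * b * sx2 + tau2
    s = np.sqrt(s2)
    t = (by - b * bx) / s
    dt_db = -(bx / s) - t * b * sx2 / s2
    return float(np.sum(_psi(t, loss) * dt_db))


def raps(
    h: HarmonizedSet,
    overdispersion: bool = False,
    loss: str = "plain",
    max_iter: int = 200,
    tol: float = 1e-10,
) -> MREstimate:
    """Robust adjusted profile score estimator.

    Solves the profile-score estimating equation
    sum_j psi(t_j) * dt_j/db = 0 with standardized residuals
    t_j = (beta_y_j - b beta_x_j) / sqrt(se_y_j^2 + b^2 se_x_j^2 + tau^2).
    ``loss`` selects the identity score (``plain``) or Huber score with
    tuning constant 1.345; with ``overdispersion`` a systematic-pleiotropy
    variance tau^2 >= 0 is estimated jointly by moment-matching the squared
    residuals.  SE by the empirical sandwich formula.
    """
    if loss not in ("plain", "huber"):
        raise EstimationError(f"unknown raps loss {loss!r}")
    df = h.instruments
    k = len(df)
    if k < 3:
        raise EstimationError(f"raps needs >= 3 instruments, got {k}")
    bx = df["beta_x"].to_numpy(float)
    by = df["beta_y"].to_numpy(float)
    sx2 = df["se_x"].to_numpy(float) ** 2
    sy2 = df["se_y"].to_numpy(float) ** 2

    delta = 1.0 if loss == "plain" else _HUBER_DELTA

    # bracket on the natural scale of the ratios: the score decays to 0 in
    # the tails, so an over-wide bracket can trap spurious far-field roots
    ratio_scale = float(np.std(by / bx) + np.abs(by / bx).mean()) + 1e-12

    def solve_b(tau2: float, b_guess: float) -> float:
        span = 0.5 * (ratio_scale + abs(b_guess))
        lo, hi = b_guess - span, b_guess + span
        for _ in range(60):
            if _raps_score(lo, tau2, bx, by, sx2, sy2, loss) * _raps_score(
                hi, tau2, bx, by, sx2, sy2, loss
            ) <= 0:
                return float(
                    optimize.brentq(
                        _raps_score, lo, hi,
                        args=(tau2, bx, by, sx2, sy2, loss), xtol=1e-13,
                    )
                )
            span *= 2.0
            lo, hi = b_guess - span, b_guess + span
            if span > 1e6 * (ratio_scale + abs(b_guess)):
                break
        raise ConvergenceError(
            "raps: could not bracket the profile-score root",
            {"tau2": tau2, "b_guess": b_guess},
        )

    b_hat, _ = ivw_beta_se(by / bx, (sy2 / bx ** 2) ** -1.0)
    tau2 = 0.0
    for _ in range(max_iter):
        b_new = solve_b(tau2, b_hat)
        if overdispersion:
            # moment equation: mean of psi(t)*t equals its std-normal value
            def tau_moment(t2: float) -> float:
                s2 = sy2 + b_new * b_new * sx2 + t2
                t = (by - b_new * bx) / np.sqrt(s2)
                return float(np.mean(_psi(t, loss) * t) - delta)

            if tau_moment(0.0) <= 0:
                tau2_new = 0.0
            else:
                hi = float(np.var(by - b_new * bx)) + np.max(sy2)
                while tau_moment(hi) > 0:
                    hi *= 4.0
                    if hi > 1e8:
                        raise ConvergenceError(
                            "raps: overdispersion estimate diverged", {"hi": hi}
                        )
                tau2_new = float(optimize.brentq(tau_moment, 0.0, hi, xtol=1e-13))
        else:
            tau2_new = 0.0
        if abs(b_new - b_hat) < tol and abs(tau2_new - tau2) < tol:
            b_hat, tau2 = b_new, tau2_new
            break
        b_hat, tau2 = b_new, tau2_new
    else:
        raise ConvergenceError(
            "raps did not converge", {"b": b_hat, "tau2": tau2, "iters": max_iter}
        )

    # sandwich SE: Var(b) ~ B / A^2 with bread A = dS/db and meat
    # B = E[psi(T)^2] * sum (dt/db)^2, using the standard-normal moment of
    # psi^2 (the residuals are standardized to unit variance by construction)
    s2 = sy2 + b_hat * b_hat * sx2 + tau2
    s = np.sqrt(s2)
    t = (by - b_hat * bx) / s
    dt_db = -(bx / s) - t * b_hat * sx2 / s2
    var_psi = 1.0 if loss == "plain" else _HUBER_VAR
    meat = float(var_psi * np.sum(dt_db ** 2))
    step = 1e-6 * max(1.0, abs(b_hat))
    bread = (
        _raps_score(b_hat + step, tau2, bx, by, sx2, sy2, loss)
        - _raps_score(b_hat - step, tau2, bx, by, sx2, sy2, loss)
    ) / (2.0 * step)
    # the score is the gradient of a minimized objective: bread > 0 at the root
    if bread <= 0:
        raise ConvergenceError("raps: non-positive score derivative", {"bread": bread})
    se = math.sqrt(meat) / abs(bread)
    est = _make_estimate(RAPS, b_hat, se, k)
    object.__setattr__(est, "tau2", float(tau2))  # diagnostic attribute
    return est
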