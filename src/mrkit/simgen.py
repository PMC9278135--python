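"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator instantiates the standard two-sample instrumental-variable
model: each SNP j carries a true exposure effect gamma_j and a direct
(pleiotropic) outcome effect alpha_j, so the true outcome association is
beta_true * gamma_j + alpha_j.  Observed effects add sampling noise with
standard errors se = 1 / sqrt(2 * EAF * (1 - EAF) * N) — the variance of a
per-allele regression coefficient for a standardized trait, an adequate
stand-in for log-odds scale when testing estimators.

Pleiotropy modes:

* ``none`` — all alpha_j = 0 (valid instruments);
* ``balanced`` — alpha_j ~ Normal(0, pleiotropy_sd): heterogeneity without
  directional bias;
* ``directional`` — alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd):
  biases IVW, detectable by the Egger intercept.

``inside_violation`` correlates alpha_j with gamma_j (violating the InSIDE
assumption MR-Egger needs); ``pleiotropy_frac`` restricts the offsets to a
random subset of instruments (the "some invalid" regime the weighted median
tolerates).  Designated fractions of SNPs are emitted with palindromic A/T
alleles or omitted from the outcome table to exercise harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .sumstats import CANONICAL_COLUMNS, HarmonizedSet, SumstatsTable

_N_CHROM = 22
_POS_SPACING = 50_000_000  # keep synthetic loci far apart: independent by design


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic two-sample study.

    Defaults describe the regime of a well-powered binary-trait GWAS pair:
    ten independent genome-wide-significant instruments with per-allele
    effects near 0.05 log-odds, exposure N = 200,000, outcome N = 500,000,
    no pleiotropy, and a true causal effect of 0.05 log-odds per log-odds
    (odds ratio about 1.05).
    """

    k_snp: int = 10
    beta_true: float = 0.05
    gamma_mean: float = 0.05
    gamma_sd: float = 0.01
    gamma_positive: bool = True
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_exposure: int = 200_000
    n_outcome: int = 500_000
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_frac: float = 1.0
    inside_violation: float = 0.0
    palindromic_fraction: float = 0.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_snp < 1:
            raise ConfigError("k_snp must be >= 1")
        if self.gamma_sd < 0 or self.pleiotropy_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        for name in ("pleiotropy_frac", "palindromic_fraction", "missing_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0,1], got {v}")
        if not 0 < self.maf_low < self.maf_high <= 0.5:
            raise ConfigError("need 0 < maf_low < maf_high <= 0.5")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not -1 <= self.inside_violation <= 1:
            raise ConfigError("inside_violation is a correlation in [-1,1]")


@dataclass
class SimTruth:
    """Per-SNP generating values, aligned with the emitted exposure table."""

    beta_true: float
    frame: pd.DataFrame  # snp_id, gamma, alpha, palindromic, missing

    def to_tsv(self, path: str | Path) -> None:
        df = self.frame.copy()
        df.insert(0, "beta_true", self.beta_true)
        df.to_csv(path, sep="\t", index=False)


def simulate_two_sample(cfg: SimConfig) -> tuple[SumstatsTable, SumstatsTable, SimTruth]:
    """Draw one synthetic exposure/outcome summary-statistics pair.

    Fully reproducible from ``cfg.seed``; identical configs give identical
    tables.
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_snp

    eaf = rng.uniform(cfg.maf_low, cfg.maf_high, size=k)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=k)
    if cfg.gamma_positive:
        gamma = np.abs(gamma)

    alpha = np.zeros(k)
    if cfg.pleiotropy_mode != "none":
        mean = cfg.pleiotropy_mean if cfg.pleiotropy_mode == "directional" else 0.0
        z = rng.standard_normal(k)
        if cfg.inside_violation != 0.0 and cfg.gamma_sd > 0:
            zg = (gamma - gamma.mean()) / max(gamma.std(), 1e-12)
            rho = cfg.inside_violation
            z = rho * zg + np.sqrt(1.0 - rho ** 2) * z
        alpha = mean + cfg.pleiotropy_sd * z
        if cfg.pleiotropy_frac < 1.0:
            n_invalid = int(round(cfg.pleiotropy_frac * k))
            invalid = rng.choice(k, size=n_invalid, replace=False)
            mask = np.zeros(k, bool)
            mask[invalid] = True
            alpha = np.where(mask, alpha, 0.0)

    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * cfg.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.beta_true * gamma + alpha, se_y)
    p_x = 2.0 * stats.norm.sf(np.abs(beta_x) / se_x)
    p_y = 2.0 * stats.norm.sf(np.abs(beta_y) / se_y)
    np.clip(p_x, np.finfo(float).tiny, 1.0, out=p_x)
    np.clip(p_y, np.finfo(float).tiny, 1.0, out=p_y)

    n_pal = int(round(cfg.palindromic_fraction * k))
    n_miss = int(round(cfg.missing_fraction * k))
    special = rng.permutation(k)
    pal_idx = set(special[:n_pal].tolist())
    miss_idx = set(special[n_pal:n_pal + n_miss].tolist())

    snp_ids = [f"rs{i + 1}" for i in range(k)]
    chrom = [str(i % _N_CHROM + 1) for i in range(k)]
    pos = [(i // _N_CHROM + 1) * _POS_SPACING for i in range(k)]
    ea = ["A"] * k
    oa = ["T" if i in pal_idx else "G" for i in range(k)]

    exposure = pd.DataFrame(
        {
            "snp_id": snp_ids, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "eaf": eaf, "beta": beta_x, "se": se_x, "pvalue": p_x,
            "n": cfg.n_exposure,
        }
    )[CANONICAL_COLUMNS]
    keep_out = [i for i in range(k) if i not in miss_idx]
    outcome = pd.DataFrame(
        {
            "snp_id": [snp_ids[i] for i in keep_out],
            "chrom": [chrom[i] for i in keep_out],
            "pos": [pos[i] for i in keep_out],
            "effect_allele": [ea[i] for i in keep_out],
            "other_allele": [oa[i] for i in keep_out],
            "eaf": eaf[keep_out], "beta": beta_y[keep_out],
            "se": se_y[keep_out], "pvalue": p_y[keep_out],
            "n": cfg.n_outcome,
        }
    )[CANONICAL_COLUMNS]

    truth = SimTruth(
        beta_true=cfg.beta_true,
        frame=pd.DataFrame(
            {
                "snp_id": snp_ids,
                "gamma": gamma,
                "alpha": alpha,
                "palindromic": [i in pal_idx for i in range(k)],
                "missing": [i in miss_idx for i in range(k)],
            }
        ),
    )
    return (
        SumstatsTable("sim_exposure", exposure, f"simgen seed={cfg.seed}"),
        SumstatsTable("sim_outcome", outcome, f"simgen seed={cfg.seed}"),
        truth,
    )


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Copy of ``cfg`` with a new seed (convenience for replicate loops)."""
    return replace(cfg, seed=int(seed))


def inject_pleiotropic_outlier(
    h: HarmonizedSet, index: int = 0, n_se: float = 10.0
) -> HarmonizedSet:
    """Return a copy with one instrument's outcome effect shifted by
    ``n_se`` ratio-scale standard errors (an artificial pleiotropic outlier
    for detection studies)."""
    inst = h.instruments.copy()
    shift = n_se * inst.loc[index, "se_y"]
    inst.loc[index, "beta_y"] = inst.loc[index, "beta_y"] + shift
    return HarmonizedSet(h.exposure_label, h.outcome_label, inst, h.audit)
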