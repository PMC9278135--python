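"""Instrument selection: significance filter, greedy LD clumping, confounder
exclusion, and instrument-strength statistics.

Clumping follows the standard greedy rule: candidates are ranked by ascending
p-value (ties broken by chromosome then position) and a candidate is accepted
only if its r-squared with every already-accepted SNP on the same chromosome
within the physical window stays below the threshold.  An LD pair absent from
the supplied table is treated as r-squared = 0 (independent), which is the
only workable convention for sparse precomputed tables.

Strength uses the cumulative explained-variance form: per SNP,
R2_j = 2 * EAF * (1 - EAF) * (beta / SD)^2 with SD = SE * sqrt(N), and
F = R2 * (N - K - 1) / (K * (1 - R2)) over the K retained instruments;
F <= 10 flags a weak instrument set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptyInputError, EstimationError
from .sumstats import SumstatsTable

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class ClumpingParams:
    """Significance and LD-pruning thresholds for instrument selection."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ConfigError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if not 0 <= self.r2_threshold <= 1:
            raise ConfigError(f"r2_threshold must be in [0,1], got {self.r2_threshold}")
        if self.window_kb <= 0:
            raise ConfigError(f"window_kb must be > 0, got {self.window_kb}")


@dataclass
class LDTable:
    """Symmetric pairwise r-squared lookup keyed by unordered SNP pair."""

    pairs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for (a, b), r2 in self.pairs.items():
            if not 0 <= r2 <= 1:
                raise ConfigError(f"r2 for pair ({a},{b}) outside [0,1]: {r2}")
            norm[frozenset((a, b))] = float(r2)
        self.pairs = norm

    def r2(self, a: str, b: str) -> float:
        """r-squared between two SNPs; an absent pair is independent (0)."""
        if a == b:
            return 1.0
        return self.pairs.get(frozenset((a, b)), 0.0)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDTable":
        """Read a 3-column TSV (snp_a, snp_b, r2), header optional."""
        df = pd.read_csv(path, sep="\t")
        if not {"snp_a", "snp_b", "r2"} <= set(df.columns):
            df = pd.read_csv(path, sep="\t", header=None,
                             names=["snp_a", "snp_b", "r2"])
        return cls({(r.snp_a, r.snp_b): r.r2 for r in df.itertuples()})


def read_exclusion_list(path: str | Path) -> set[str]:
    """One snp_id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def select_instruments(
    exposure: SumstatsTable,
    params: ClumpingParams | None = None,
    ld: LDTable | None = None,
    exclusions: Iterable[str] = (),
) -> SumstatsTable:
    """Select independent genome-wide-significant instruments.

    Drops SNPs at or above the p-value threshold, removes listed exclusions
    (the stand-in for secondary-phenotype screening), then greedily clumps.
    Returns survivors in genomic (chrom, pos) order.
    """
    params = params or ClumpingParams()
    ld = ld or LDTable()
    exclusions = set(exclusions)

    df = exposure.frame
    sig = df[df["pvalue"] < params.p_threshold]
    if sig.empty:
        raise EmptyInputError(
            f"no SNP passes the significance threshold P < {params.p_threshold:g}"
        )
    sig = sig[~sig["snp_id"].isin(exclusions)]
    if sig.empty:
        raise EmptyInputError(
            "all significant SNPs were removed by the exclusion list"
        )

    # deterministic greedy order: ascending p, ties by (chrom, pos)
    ranked = sig.sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort"
    ).itertuples()

    window_bp = params.window_kb * 1_000.0
    accepted: list = []
    for snp in ranked:
        ok = True
        for acc in accepted:
            if acc.chrom != snp.chrom:
                continue
            if abs(acc.pos - snp.pos) > window_bp:
                continue
            if ld.r2(acc.snp_id, snp.snp_id) >= params.r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(snp)

    ids = {s.snp_id for s in accepted}
    out = df[df["snp_id"].isin(ids)].sort_values(["chrom", "pos"], kind="mergesort")
    return SumstatsTable(
        trait_label=exposure.trait_label,
        frame=out.copy(),
        provenance=f"{exposure.provenance} [clumped p<{params.p_threshold:g}, "
        f"r2<{params.r2_threshold:g}, {params.window_kb:g}kb]",
    )


@dataclass(frozen=True)
class StrengthReport:
    """Cumulative explained variance and F-statistic of an instrument set."""

    per_snp_r2: Mapping[str, float]
    r2_total: float
    k: int
    n: int
    f_stat: float

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_F_THRESHOLD


def instrument_strength(instruments: SumstatsTable, n_exposure: int | None = None) -> StrengthReport:
    """Compute per-SNP R2, cumulative R2, and the multi-SNP F-statistic.

    ``n_exposure`` defaults to the maximum per-SNP sample size in the table.
    Raises if any instrument lacks an effect-allele frequency (R2 undefined)
    or if the cumulative R2 reaches 1.
    """
    df = instruments.frame
    if df.empty:
        raise EmptyInputError("no instruments to assess")
    if df["eaf"].isna().any():
        missing = df.loc[df["eaf"].isna(), "snp_id"].tolist()
        raise EstimationError(f"eaf missing for {missing[:5]}; R2 undefined")
    n = int(n_exposure if n_exposure is not None else df["n"].max())

    eaf = df["eaf"].to_numpy(float)
    beta = df["beta"].to_numpy(float)
    se = df["se"].to_numpy(float)
    sd = se * np.sqrt(n)
    r2 = 2.0 * eaf * (1.0 - eaf) * (beta / sd) ** 2

    r2_total = float(r2.sum())
    k = len(df)
    if r2_total >= 1:
        raise EstimationError(f"cumulative R2 = {r2_total:.3f} >= 1; check inputs")
    f_stat = r2_total * (n - k - 1) / (k * (1.0 - r2_total))
    return StrengthReport(
        per_snp_r2=dict(zip(df["snp_id"], r2.astype(float))),
        r2_total=r2_total,
        k=k,
        n=n,
        f_stat=float(f_stat),
    )


def strength_from_harmonized(h, n_exposure: int) -> StrengthReport:
    """Strength on a post-harmonization instrument set (K reflects drops)."""
    df = h.instruments
    if df.empty:
        raise EmptyInputError("no instruments to assess")
    if df["eaf_x"].isna().any():
        missing = df.loc[df["eaf_x"].isna(), "snp_id"].tolist()
        raise EstimationError(f"eaf missing for {missing[:5]}; R2 undefined")
    eaf = df["eaf_x"].to_numpy(float)
    beta = df["beta_x"].to_numpy(float)
    se = df["se_x"].to_numpy(float)
    sd = se * np.sqrt(n_exposure)
    r2 = 2.0 * eaf * (1.0 - eaf) * (beta / sd) ** 2
    r2_total = float(r2.sum())
    k = len(df)
    if r2_total >= 1:
        raise EstimationError(f"cumulative R2 = {r2_total:.3f} >= 1; check inputs")
    f_stat = r2_total * (n_exposure - k - 1) / (k * (1.0 - r2_total))
    return StrengthReport(
        per_snp_r2=dict(zip(df["snp_id"], r2.astype(float))),
        r2_total=r2_total, k=k, n=n_exposure, f_stat=float(f_stat),
    )
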