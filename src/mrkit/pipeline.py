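"""Config-driven orchestration of a complete two-sample MR study.

:func:`run_mr_study` runs, for one exposure against each configured outcome:
instrument selection (significance filter, exclusion list, LD clumping),
harmonization, instrument-strength assessment, all six estimators, and the
full sensitivity suite, then labels the primary estimate by the
heterogeneity rule: if Cochran's Q has p < 0.05 the random-effects IVW is
primary, otherwise the fixed-effects IVW.  Failures are isolated per
outcome so a multi-outcome study degrades gracefully.

Every stochastic step (weighted-median bootstrap, PRESSO simulations) is
seeded from the study config, so two runs with identical configs produce
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import estimators as est
from . import robustness as rob
from .exceptions import ConfigError, MRKitError
from .instruments import (
    ClumpingParams,
    LDTable,
    StrengthReport,
    read_exclusion_list,
    select_instruments,
    strength_from_harmonized,
)
from .sumstats import ColumnMap, HarmonizedSet, SumstatsTable, harmonize, read_sumstats

log = logging.getLogger("mrkit")

ALL_METHOD_LABELS = [
    "ivw", "weighted_median", "egger", "max_likelihood", "raps", "presso",
]


@dataclass
class SourceConfig:
    path: str
    label: str
    mapping: dict = field(default_factory=dict)
    delimiter: str = "\t"
    n_override: int | None = None


@dataclass
class EstimatorSettings:
    n_boot: int = 1000
    presso_n_sim: int = 5000
    presso_outlier_alpha: float = 0.05
    raps_overdispersion: bool = False
    raps_loss: str = "plain"
    seed: int = 0


@dataclass
class StudyConfig:
    """Everything needed to run one exposure against several outcomes."""

    exposure: SourceConfig
    outcomes: list[SourceConfig]
    clumping: ClumpingParams = field(default_factory=ClumpingParams)
    ld_table_path: str | None = None
    exclusion_path: str | None = None
    settings: EstimatorSettings = field(default_factory=EstimatorSettings)
    report_precision: int = 2

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ConfigError("study needs at least one outcome")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "StudyConfig":
        base = base or Path(".")

        def src(d: dict) -> SourceConfig:
            p = Path(d["path"])
            if not p.is_absolute():
                p = base / p
            return SourceConfig(
                path=str(p),
                label=d.get("label", p.stem),
                mapping=d.get("mapping", {}),
                delimiter=d.get("delimiter", "\t"),
                n_override=d.get("n"),
            )

        def opt_path(key: str) -> str | None:
            v = raw.get(key)
            if v is None:
                return None
            p = Path(v)
            return str(p if p.is_absolute() else base / p)

        return cls(
            exposure=src(raw["exposure"]),
            outcomes=[src(d) for d in raw["outcomes"]],
            clumping=ClumpingParams(**raw.get("clumping", {})),
            ld_table_path=opt_path("ld_table"),
            exclusion_path=opt_path("exclusions"),
            settings=EstimatorSettings(**raw.get("estimators", {})),
            report_precision=int(raw.get("report", {}).get("precision", 2)),
        )


@dataclass
class OutcomeReport:
    """All results for one exposure-outcome pair (or its failure reason)."""

    outcome_label: str
    failed: bool = False
    reason: str = ""
    strength: StrengthReport | None = None
    harmonized: HarmonizedSet | None = None
    estimates: dict = field(default_factory=dict)  # label -> MREstimate
    primary_method: str = ""
    egger_result: est.EggerResult | None = None
    q_ivw: rob.QResult | None = None
    q_egger: rob.QResult | None = None
    presso: rob.PressoResult | None = None
    loo: list = field(default_factory=list)
    diagnostics: rob.DiagnosticsTables | None = None


@dataclass
class StudyReport:
    exposure_label: str
    outcomes: list[OutcomeReport]
    settings: EstimatorSettings
    n_exposure: int


def analyse_pair(
    h: HarmonizedSet,
    settings: EstimatorSettings | None = None,
    n_exposure: int | None = None,
) -> OutcomeReport:
    """Run every estimator and diagnostic on one harmonized instrument set."""
    settings = settings or EstimatorSettings()
    report = OutcomeReport(outcome_label=h.outcome_label, harmonized=h)

    ratios = est.wald_ratios(h)
    report.q_ivw = rob.cochran_q(ratios, reference="ivw")
    report.q_egger = rob.cochran_q(h, reference="egger")

    # heterogeneity rule: Q p < 0.05 -> random-effects IVW is primary
    ivw_est = est.ivw(ratios, model="auto")
    report.estimates["ivw"] = ivw_est
    report.primary_method = ivw_est.method

    report.estimates["weighted_median"] = est.weighted_median(
        ratios, n_boot=settings.n_boot, seed=settings.seed
    )
    egg = est.egger(h)
    report.egger_result = egg
    report.estimates["egger"] = egg.estimate
    report.estimates["max_likelihood"] = est.max_likelihood(h)
    report.estimates["raps"] = est.raps(
        h, overdispersion=settings.raps_overdispersion, loss=settings.raps_loss
    )

    pres = rob.presso(
        h,
        n_sim=settings.presso_n_sim,
        seed=settings.seed + 1,
        outlier_alpha=settings.presso_outlier_alpha,
    )
    report.presso = pres
    # forest-table PRESSO row: outlier-corrected when outliers were found,
    # otherwise the raw IVW estimate stands ("no outlier detected")
    report.estimates["presso"] = pres.corrected if pres.corrected else est.ivw(
        ratios, model="fixed"
    )

    report.loo = rob.leave_one_out(h)
    report.diagnostics = rob.diagnostics_tables(h, list(report.estimates.values()))

    if n_exposure is not None and not h.instruments["eaf_x"].isna().any():
        report.strength = strength_from_harmonized(h, n_exposure)
        if report.strength.weak:
            log.warning(
                "%s: weak instruments (F = %.2f <= 10)",
                h.outcome_label, report.strength.f_stat,
            )
    return report


def run_mr_study(cfg: StudyConfig) -> StudyReport:
    """End-to-end study: select, harmonize, estimate, and diagnose per outcome."""
    exposure = read_sumstats(
        cfg.exposure.path,
        ColumnMap.from_dict(cfg.exposure.mapping) if cfg.exposure.mapping else None,
        trait_label=cfg.exposure.label,
        delimiter=cfg.exposure.delimiter,
    )
    n_exposure = cfg.exposure.n_override or int(exposure.frame["n"].max())
    ld = LDTable.from_tsv(cfg.ld_table_path) if cfg.ld_table_path else LDTable()
    exclusions = (
        read_exclusion_list(cfg.exclusion_path) if cfg.exclusion_path else set()
    )

    selected = select_instruments(exposure, cfg.clumping, ld, exclusions)
    log.info("selected %d instruments for %s", len(selected), cfg.exposure.label)

    reports = []
    for oc in cfg.outcomes:
        try:
            outcome = read_sumstats(
                oc.path,
                ColumnMap.from_dict(oc.mapping) if oc.mapping else None,
                trait_label=oc.label,
                delimiter=oc.delimiter,
            )
            h = harmonize(selected, outcome)
            for snp, disp in h.audit.itertuples(index=False):
                log.info("%s: %s -> %s", oc.label, snp, disp)
            if len(h) == 0:
                raise MRKitError("no instruments survived harmonization")
            reports.append(analyse_pair(h, cfg.settings, n_exposure))
        except MRKitError as exc:
            log.error("outcome %s failed: %s", oc.label, exc)
            reports.append(
                OutcomeReport(outcome_label=oc.label, failed=True, reason=str(exc))
            )
    return StudyReport(
        exposure_label=cfg.exposure.label,
        outcomes=reports,
        settings=cfg.settings,
        n_exposure=n_exposure,
    )


# ---------------------------------------------------------------------------
# Report emission
# ---------------------------------------------------------------------------

def estimates_table(report: StudyReport) -> pd.DataFrame:
    """Per-outcome, per-method OR table (the forest-figure layout).

    A Bonferroni-adjusted p-value across outcomes is included for
    transparency but plays no part in significance labelling.
    """
    n_outcomes = sum(not r.failed for r in report.outcomes)
    rows = []
    for oc in report.outcomes:
        if oc.failed:
            continue
        for label in ALL_METHOD_LABELS:
            e = oc.estimates[label]
            rows.append(
                {
                    "outcome": oc.outcome_label,
                    "method": label,
                    "detail": e.method,
                    "primary": label == "ivw",
                    "k": e.k,
                    "beta": e.beta,
                    "se": e.se,
                    "or": e.or_point,
                    "or_ci_low": e.or_low,
                    "or_ci_high": e.or_high,
                    "p": e.p,
                    "p_bonferroni": min(1.0, e.p * max(n_outcomes, 1)),
                }
            )
    return pd.DataFrame(rows)


def sensitivity_table(report: StudyReport) -> pd.DataFrame:
    """Combined pleiotropy/heterogeneity table (intercept + paired Q)."""
    rows = []
    for oc in report.outcomes:
        if oc.failed:
            continue
        egg, qe, qi = oc.egger_result, oc.q_egger, oc.q_ivw
        rows.append(
            {
                "outcome": oc.outcome_label,
                "egger_intercept": egg.intercept,
                "egger_intercept_se": egg.intercept_se,
                "egger_intercept_p": egg.intercept_p,
                "egger_q": qe.q, "egger_q_df": qe.df, "egger_q_p": qe.p,
                "ivw_q": qi.q, "ivw_q_df": qi.df, "ivw_q_p": qi.p,
            }
        )
    return pd.DataFrame(rows)


def report_to_dict(report: StudyReport) -> dict:
    """Machine-readable study report (JSON-serializable)."""
    out = {
        "exposure": report.exposure_label,
        "n_exposure": report.n_exposure,
        "outcomes": [],
    }
    for oc in report.outcomes:
        if oc.failed:
            out["outcomes"].append(
                {"outcome": oc.outcome_label, "failed": True, "reason": oc.reason}
            )
            continue
        d = {
            "outcome": oc.outcome_label,
            "failed": False,
            "k": oc.harmonized.k,
            "primary_method": oc.primary_method,
            "estimates": {
                label: {
                    "method": e.method, "beta": e.beta, "se": e.se,
                    "ci_low": e.ci_low, "ci_high": e.ci_high, "p": e.p,
                    "or": e.or_point, "or_low": e.or_low, "or_high": e.or_high,
                    "k": e.k,
                    "significant": e.p < 0.05,
                }
                for label, e in oc.estimates.items()
            },
            "egger_intercept": {
                "intercept": oc.egger_result.intercept,
                "se": oc.egger_result.intercept_se,
                "p": oc.egger_result.intercept_p,
            },
            "heterogeneity": {
                "ivw": {"q": oc.q_ivw.q, "df": oc.q_ivw.df, "p": oc.q_ivw.p},
                "egger": {"q": oc.q_egger.q, "df": oc.q_egger.df, "p": oc.q_egger.p},
            },
            "presso": {
                "global_rss": oc.presso.global_rss_obs,
                "global_p": oc.presso.global_p,
                "outliers": oc.presso.outliers,
                "distortion_p": oc.presso.distortion_p,
            },
            "leave_one_out": [
                {"left_out": r.left_out_snp, "beta": r.estimate.beta,
                 "ci_low": r.estimate.ci_low, "ci_high": r.estimate.ci_high}
                for r in oc.loo
            ],
            "audit": {
                snp: disp for snp, disp in oc.harmonized.audit.itertuples(index=False)
            },
        }
        if oc.strength is not None:
            d["strength"] = {
                "r2_total": oc.strength.r2_total,
                "f_stat": oc.strength.f_stat,
                "k": oc.strength.k,
                "n": oc.strength.n,
                "weak": oc.strength.weak,
            }
        out["outcomes"].append(d)
    return out


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Emit the TSV tables plus one machine-readable JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    estimates_table(report).to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    sensitivity_table(report).to_csv(
        out_dir / "sensitivity.tsv", sep="\t", index=False
    )
    for oc in report.outcomes:
        if oc.failed:
            continue
        safe = oc.outcome_label.replace("/", "_").replace(" ", "_")
        oc.harmonized.to_tsv(out_dir / f"harmonized_{safe}.tsv")
        oc.diagnostics.funnel.to_csv(
            out_dir / f"funnel_{safe}.tsv", sep="\t", index=False
        )
        oc.diagnostics.forest.to_csv(
            out_dir / f"forest_{safe}.tsv", sep="\t", index=False
        )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
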