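"""GWAS summary-statistics data model, readers/writers, and harmonization.

A :class:`SumstatsTable` holds one study's per-SNP association summaries
(identifier, position, alleles, effect-allele frequency, beta, SE, p, N) as a
pandas DataFrame with canonical column names.  :func:`read_sumstats` maps an
arbitrary delimited text layout onto that canonical form via an explicit
:class:`ColumnMap` — no auto-detection, so parses are reproducible.

:func:`harmonize` aligns outcome effects to the exposure's effect allele,
sign-flipping where the outcome reports the complementary orientation,
dropping palindromic (A/T, C/G) variants whose strand cannot be resolved,
and dropping exposure variants missing from the outcome rather than proxying
them.  Every input SNP receives exactly one disposition in the audit table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptyInputError, HarmonizationError

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a SumstatsTable's frame
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: harmonization dispositions
KEPT = "kept"
FLIPPED = "flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISSING = "dropped_missing"
DROPPED_ALLELE_MISMATCH = "dropped_allele_mismatch"


@dataclass(frozen=True)
class SumstatsRecord:
    """One SNP's association summary in one GWAS.

    ``beta`` is the per-effect-allele effect on the trait (log-odds for a
    binary trait), ``se`` its standard error, ``eaf`` the effect-allele
    frequency (may be NaN when the source study does not report it).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the record is valid."""
        if self.effect_allele not in VALID_ALLELES:
            return f"effect_allele {self.effect_allele!r} not in A/C/G/T"
        if self.other_allele not in VALID_ALLELES:
            return f"other_allele {self.other_allele!r} not in A/C/G/T"
        if self.effect_allele == self.other_allele:
            return "effect_allele equals other_allele"
        if not np.isfinite(self.se) or self.se <= 0:
            return f"se must be > 0, got {self.se}"
        if not np.isnan(self.eaf) and not 0 < self.eaf < 1:
            return f"eaf must lie in (0,1), got {self.eaf}"
        if not 0 < self.pvalue <= 1:
            return f"pvalue must lie in (0,1], got {self.pvalue}"
        if self.n <= 0:
            return f"n must be positive, got {self.n}"
        return None

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SumstatsTable:
    """Ordered collection of per-SNP summaries for one trait.

    ``frame`` uses the canonical columns; ``snp_id`` is unique.  ``rejected``
    records rows dropped at read time with the reason for each.
    """

    trait_label: str
    frame: pd.DataFrame
    provenance: str = ""
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "snp_id", "reason"])
    )

    def __post_init__(self) -> None:
        dup = self.frame["snp_id"].duplicated()
        if dup.any():
            dups = self.frame.loc[dup, "snp_id"].tolist()
            raise HarmonizationError(
                f"duplicate snp_id in table {self.trait_label!r}: {dups[:5]}"
            )
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield SumstatsRecord(**row._asdict())

    def get(self, snp_id: str) -> SumstatsRecord | None:
        sub = self.frame[self.frame["snp_id"] == snp_id]
        if sub.empty:
            return None
        return SumstatsRecord(**sub.iloc[0].to_dict())

    def restrict(self, snp_ids) -> "SumstatsTable":
        """Subset to the given SNPs, preserving this table's row order."""
        keep = self.frame["snp_id"].isin(set(snp_ids))
        return SumstatsTable(self.trait_label, self.frame[keep].copy(), self.provenance)

    @classmethod
    def from_records(
        cls, trait_label: str, records, provenance: str = ""
    ) -> "SumstatsTable":
        frame = pd.DataFrame([asdict(r) for r in records], columns=CANONICAL_COLUMNS)
        return cls(trait_label, frame, provenance)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ColumnMap:
    """Source-column names for each canonical field.

    ``eaf`` may be None (declared absent); ``n`` may be None with
    ``n_constant`` supplying a study-wide sample size instead.
    """

    snp_id: str = "SNP"
    chrom: str = "CHR"
    pos: str = "POS"
    effect_allele: str = "EA"
    other_allele: str = "NEA"
    beta: str = "BETA"
    se: str = "SE"
    pvalue: str = "P"
    eaf: str | None = "EAF"
    n: str | None = "N"
    n_constant: int | None = None

    @classmethod
    def from_dict(cls, d: Mapping[str, object]) -> "ColumnMap":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown column-mapping keys: {sorted(bad)}")
        return cls(**d)  # type: ignore[arg-type]


def read_sumstats(
    path: str | Path,
    mapping: ColumnMap | Mapping[str, object] | None = None,
    trait_label: str | None = None,
    delimiter: str = "\t",
) -> SumstatsTable:
    """Read a delimited summary-statistics file into a :class:`SumstatsTable`.

    Rows violating record invariants (se <= 0, eaf outside (0,1), non-ACGT
    alleles, ...) are rejected individually and logged on the returned
    table's ``rejected`` frame; structural problems (a mapped column missing
    from the header) raise :class:`ConfigError`, and a file yielding zero
    valid rows raises :class:`EmptyInputError`.
    """
    if mapping is None:
        mapping = ColumnMap()
    elif not isinstance(mapping, ColumnMap):
        mapping = ColumnMap.from_dict(mapping)

    raw = pd.read_csv(path, sep=delimiter, dtype=str)

    required = {
        "snp_id": mapping.snp_id,
        "chrom": mapping.chrom,
        "pos": mapping.pos,
        "effect_allele": mapping.effect_allele,
        "other_allele": mapping.other_allele,
        "beta": mapping.beta,
        "se": mapping.se,
        "pvalue": mapping.pvalue,
    }
    for canon, src in required.items():
        if src is None:
            raise ConfigError(f"{canon} column missing from mapping")
        if src not in raw.columns:
            raise ConfigError(
                f"{canon} column {src!r} not found in {path} "
                f"(header: {list(raw.columns)})"
            )
    if mapping.eaf is not None and mapping.eaf not in raw.columns:
        raise ConfigError(f"eaf column {mapping.eaf!r} not found in {path}")
    if mapping.n is not None and mapping.n not in raw.columns:
        if mapping.n_constant is None:
            raise ConfigError(f"n column {mapping.n!r} not found in {path}")

    out = pd.DataFrame(
        {
            "snp_id": raw[mapping.snp_id].astype(str),
            "chrom": raw[mapping.chrom].astype(str),
            "pos": pd.to_numeric(raw[mapping.pos], errors="coerce"),
            "effect_allele": raw[mapping.effect_allele].astype(str).str.upper(),
            "other_allele": raw[mapping.other_allele].astype(str).str.upper(),
            "beta": pd.to_numeric(raw[mapping.beta], errors="coerce"),
            "se": pd.to_numeric(raw[mapping.se], errors="coerce"),
            "pvalue": pd.to_numeric(raw[mapping.pvalue], errors="coerce"),
        }
    )
    if mapping.eaf is not None:
        out["eaf"] = pd.to_numeric(raw[mapping.eaf], errors="coerce")
    else:
        out["eaf"] = np.nan
    if mapping.n is not None and mapping.n in raw.columns:
        out["n"] = pd.to_numeric(raw[mapping.n], errors="coerce")
    else:
        out["n"] = mapping.n_constant

    out = out[CANONICAL_COLUMNS]

    keep_rows, rejects = [], []
    for i, row in out.iterrows():
        reason = _row_reason(row)
        if reason is None:
            keep_rows.append(i)
        else:
            rejects.append({"row": i, "snp_id": row["snp_id"], "reason": reason})

    kept = out.loc[keep_rows].copy()
    kept["pos"] = kept["pos"].astype(int)
    kept["n"] = kept["n"].astype(int)
    if kept.empty:
        raise EmptyInputError(f"no valid summary-statistics rows in {path}")

    table = SumstatsTable(
        trait_label=trait_label or str(path),
        frame=kept,
        provenance=str(path),
    )
    table.rejected = pd.DataFrame(rejects, columns=["row", "snp_id", "reason"])
    return table


def _row_reason(row: pd.Series) -> str | None:
    for col in ("pos", "beta", "se", "pvalue", "n"):
        if pd.isna(row[col]):
            return f"{col} is missing or non-numeric"
    rec = SumstatsRecord(
        snp_id=row["snp_id"], chrom=row["chrom"], pos=int(row["pos"]),
        effect_allele=row["effect_allele"], other_allele=row["other_allele"],
        eaf=float(row["eaf"]) if pd.notna(row["eaf"]) else np.nan,
        beta=float(row["beta"]), se=float(row["se"]),
        pvalue=float(row["pvalue"]), n=int(row["n"]),
    )
    return rec.validate()


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedSet:
    """Exposure/outcome-aligned instruments plus a per-input-SNP audit trail.

    ``instruments`` columns: snp_id, effect_allele, other_allele (exposure
    orientation), beta_x, se_x, beta_y, se_y, eaf_x.  ``audit`` columns:
    snp_id, disposition — one row per input exposure SNP.
    """

    exposure_label: str
    outcome_label: str
    instruments: pd.DataFrame
    audit: pd.DataFrame

    INSTRUMENT_COLUMNS = [
        "snp_id", "effect_allele", "other_allele",
        "beta_x", "se_x", "beta_y", "se_y", "eaf_x",
    ]

    def __len__(self) -> int:
        return len(self.instruments)

    @property
    def k(self) -> int:
        return len(self.instruments)

    def drop(self, snp_ids) -> "HarmonizedSet":
        """Return a copy without the named instruments (audit untouched)."""
        gone = set(snp_ids)
        keep = ~self.instruments["snp_id"].isin(gone)
        return HarmonizedSet(
            self.exposure_label,
            self.outcome_label,
            self.instruments[keep].reset_index(drop=True),
            self.audit,
        )

    def to_tsv(self, path: str | Path) -> None:
        """One row per input SNP: disposition plus aligned effects where kept."""
        merged = self.audit.merge(
            self.instruments, on="snp_id", how="left"
        )
        merged.to_csv(path, sep="\t", index=False)


def harmonize(exposure: SumstatsTable, outcome: SumstatsTable) -> HarmonizedSet:
    """Align outcome effect sizes to the exposure's effect alleles.

    For each exposure SNP, in exposure order:

    * missing from the outcome -> ``dropped_missing`` (no proxies);
    * palindromic alleles (A/T or C/G) -> ``dropped_palindromic``;
    * outcome effect allele matches the exposure effect allele, directly or
      after complementing both outcome alleles -> ``kept``;
    * outcome effect allele matches the exposure *other* allele, directly or
      after complementing -> ``flipped`` (beta_y negated);
    * anything else -> ``dropped_allele_mismatch``.
    """
    if len(exposure) == 0:
        raise EmptyInputError("exposure instrument set is empty")
    # duplicate ids are rejected at table construction; re-check defensively
    for tab in (exposure, outcome):
        if tab.frame["snp_id"].duplicated().any():
            raise HarmonizationError(f"duplicate snp_id in {tab.trait_label!r}")

    outcome_by_id = outcome.frame.set_index("snp_id")

    inst_rows, audit_rows = [], []
    for exp in exposure:
        if exp.snp_id not in outcome_by_id.index:
            audit_rows.append((exp.snp_id, DROPPED_MISSING))
            continue
        if exp.is_palindromic:
            audit_rows.append((exp.snp_id, DROPPED_PALINDROMIC))
            continue
        out = outcome_by_id.loc[exp.snp_id]
        disposition, beta_y = _align(
            exp.effect_allele, exp.other_allele,
            out["effect_allele"], out["other_allele"], float(out["beta"]),
        )
        audit_rows.append((exp.snp_id, disposition))
        if disposition in (KEPT, FLIPPED):
            inst_rows.append(
                {
                    "snp_id": exp.snp_id,
                    "effect_allele": exp.effect_allele,
                    "other_allele": exp.other_allele,
                    "beta_x": exp.beta,
                    "se_x": exp.se,
                    "beta_y": beta_y,
                    "se_y": float(out["se"]),
                    "eaf_x": exp.eaf,
                }
            )

    instruments = pd.DataFrame(inst_rows, columns=HarmonizedSet.INSTRUMENT_COLUMNS)
    audit = pd.DataFrame(audit_rows, columns=["snp_id", "disposition"])
    return HarmonizedSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        instruments=instruments,
        audit=audit,
    )


def _align(exp_ea, exp_oa, out_ea, out_oa, beta_y):
    """Match outcome alleles to the exposure pair; return (disposition, beta_y).

    Exact match is tried first, then whole-variant strand complement; a
    variant matching under neither (or ambiguously) is dropped.
    """
    comp_ea, comp_oa = COMPLEMENT.get(out_ea, "?"), COMPLEMENT.get(out_oa, "?")
    same = (out_ea == exp_ea and out_oa == exp_oa) or (
        comp_ea == exp_ea and comp_oa == exp_oa
    )
    swapped = (out_ea == exp_oa and out_oa == exp_ea) or (
        comp_ea == exp_oa and comp_oa == exp_ea
    )
    if same and not swapped:
        return KEPT, beta_y
    if swapped and not same:
        return FLIPPED, -beta_y
    return DROPPED_ALLELE_MISMATCH, np.nan


def harmonized_from_arrays(
    beta_x, se_x, beta_y, se_y,
    snp_ids=None, eaf_x=None,
    exposure_label: str = "exposure", outcome_label: str = "outcome",
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays.

    Convenience constructor for simulation studies and tests where allele
    bookkeeping has already been resolved; alleles are set to A/G.
    """
    beta_x = np.asarray(beta_x, dtype=float)
    k = beta_x.size
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(k)]
    instruments = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_x": beta_x,
            "se_x": np.asarray(se_x, dtype=float),
            "beta_y": np.asarray(beta_y, dtype=float),
            "se_y": np.asarray(se_y, dtype=float),
            "eaf_x": np.full(k, np.nan) if eaf_x is None else np.asarray(eaf_x, float),
        }
    )
    audit = pd.DataFrame({"snp_id": snp_ids, "disposition": KEPT})
    return HarmonizedSet(exposure_label, outcome_label, instruments, audit)
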