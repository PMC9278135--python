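"""Genome-wide-significant SNP selection with LD clumping and strength.

A toy five-SNP panel: two SNPs are in strong LD 500 kb apart (only the more
significant survives), one fails the significance threshold, one sits on the
exclusion list (a proxy for confounder-associated variants), one is
independent.  The F-statistic then quantifies instrument strength.
"""

import pandas as pd

from mrkit import ClumpingParams, LDTable, select_instruments, instrument_strength
from mrkit.sumstats import CANONICAL_COLUMNS, SumstatsTable

panel = pd.DataFrame(
    [
        ("rs1", "1", 10_000_000, "A", "G", 0.30, 0.12, 0.010, 1e-12, 200_000),
        ("rs2", "1", 10_500_000, "A", "G", 0.31, 0.11, 0.010, 1e-10, 200_000),  # LD with rs1
        ("rs3", "2", 5_000_000, "C", "T", 0.45, 0.08, 0.011, 6e-8, 200_000),   # not significant
        ("rs4", "3", 8_000_000, "A", "C", 0.20, 0.10, 0.012, 1e-9, 200_000),   # excluded
        ("rs5", "4", 2_000_000, "G", "T", 0.25, 0.09, 0.011, 1e-9, 200_000),
    ],
    columns=CANONICAL_COLUMNS,
)
table = SumstatsTable("exposure", panel)
ld = LDTable({("rs1", "rs2"): 0.85})

kept = select_instruments(
    table, ClumpingParams(), ld, exclusions={"rs4"}
)
print("selected instruments:", kept.frame["snp_id"].tolist())

strength = instrument_strength(kept, n_exposure=200_000)
for snp, r2 in strength.per_snp_r2.items():
    print(f"  {snp}: R2 = {r2:.5f}")
print(f"cumulative R2 = {strength.r2_total:.5f}, "
      f"F = {strength.f_stat:.1f} over K = {strength.k} SNPs "
      f"({'weak' if strength.weak else 'strong'} instruments)")
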