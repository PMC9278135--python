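"""Reader and harmonization behaviour of the summary-statistics layer."""

import numpy as np
import pandas as pd
import pytest

from mrkit import (
    ColumnMap,
    ConfigError,
    EmptyInputError,
    HarmonizationError,
    harmonize,
    read_sumstats,
)
from mrkit.sumstats import (
    DROPPED_ALLELE_MISMATCH,
    DROPPED_MISSING,
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
    SumstatsTable,
)

HEADER = "SNP\tCHR\tPOS\tEA\tNEA\tEAF\tBETA\tSE\tP\tN"


def write_file(tmp_path, rows, header=HEADER, name="ss.tsv"):
    path = tmp_path / name
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestReadSumstats:
    def test_identity_mapping_parses_all_rows(self, tmp_path):
        path = write_file(
            tmp_path,
            [
                "rs1\t1\t100\ta\tg\t0.2\t0.10\t0.01\t1e-9\t5000",
                "rs2\t1\t200\tC\tT\t0.3\t-0.05\t0.02\t1e-8\t5000",
                "rs3\t2\t300\tG\tA\t0.4\t0.08\t0.015\t1e-10\t5000",
            ],
        )
        table = read_sumstats(path)
        assert len(table) == 3
        # alleles are uppercase-normalized
        assert table.frame["effect_allele"].tolist() == ["A", "C", "G"]
        assert table.rejected.empty

    def test_missing_se_column_is_a_config_error(self, tmp_path):
        path = write_file(
            tmp_path,
            ["rs1\t1\t100\tA\tG\t0.2\t0.10\t1e-9\t5000"],
            header="SNP\tCHR\tPOS\tEA\tNEA\tEAF\tBETA\tP\tN",
        )
        with pytest.raises(ConfigError, match="se"):
            read_sumstats(path)

    def test_invalid_row_rejected_and_logged_others_kept(self, tmp_path):
        path = write_file(
            tmp_path,
            [
                "rs1\t1\t100\tA\tG\t1.2\t0.10\t0.01\t1e-9\t5000",  # eaf out of range
                "rs2\t1\t200\tC\tT\t0.3\t-0.05\t0.02\t1e-8\t5000",
            ],
        )
        table = read_sumstats(path)
        assert len(table) == 1
        assert table.frame["snp_id"].tolist() == ["rs2"]
        assert table.rejected["snp_id"].tolist() == ["rs1"]
        assert "eaf" in table.rejected["reason"].iloc[0]

    @pytest.mark.parametrize(
        "bad_row,reason_word",
        [
            ("rs9\t1\t9\tA\tA\t0.2\t0.1\t0.01\t1e-9\t5000", "other_allele"),
            ("rs9\t1\t9\tA\tG\t0.2\t0.1\t-0.01\t1e-9\t5000", "se"),
            ("rs9\t1\t9\tN\tG\t0.2\t0.1\t0.01\t1e-9\t5000", "allele"),
            ("rs9\t1\t9\tA\tG\t0.2\t0.1\t0.01\t2.0\t5000", "pvalue"),
        ],
    )
    def test_invariant_violations_each_logged(self, tmp_path, bad_row, reason_word):
        path = write_file(
            tmp_path, [bad_row, "rs2\t1\t200\tC\tT\t0.3\t-0.05\t0.02\t1e-8\t5000"]
        )
        table = read_sumstats(path)
        assert len(table) == 1
        assert reason_word.lower() in table.rejected["reason"].iloc[0].lower()

    def test_all_rows_invalid_raises_empty_input(self, tmp_path):
        path = write_file(tmp_path, ["rs1\t1\t100\tA\tG\t1.2\t0.1\t0\t1e-9\t5000"])
        with pytest.raises(EmptyInputError):
            read_sumstats(path)

    def test_constant_n_and_absent_eaf(self, tmp_path):
        path = write_file(
            tmp_path,
            ["rs1\t1\t100\tA\tG\t0.10\t0.01\t1e-9"],
            header="SNP\tCHR\tPOS\tEA\tNEA\tBETA\tSE\tP",
        )
        mapping = ColumnMap(eaf=None, n=None, n_constant=7000)
        table = read_sumstats(path, mapping)
        assert table.frame["n"].iloc[0] == 7000
        assert np.isnan(table.frame["eaf"].iloc[0])


def table_from(rows):
    frame = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele",
                 "eaf", "beta", "se", "pvalue", "n"],
    )
    return SumstatsTable("t", frame)


EXPOSURE_ROWS = [
    ("rs1", "1", 100, "A", "G", 0.2, 0.10, 0.01, 1e-9, 5000),
    ("rs2", "1", 200, "A", "T", 0.3, 0.12, 0.01, 1e-9, 5000),  # palindromic
    ("rs3", "2", 300, "C", "T", 0.4, 0.08, 0.01, 1e-9, 5000),
    ("rs4", "2", 400, "A", "G", 0.4, 0.09, 0.01, 1e-9, 5000),  # missing in outcome
    ("rs5", "3", 500, "A", "G", 0.4, 0.07, 0.01, 1e-9, 5000),  # mismatching alleles
]
OUTCOME_ROWS = [
    ("rs1", "1", 100, "G", "A", 0.2, -0.05, 0.02, 0.5, 9000),   # swapped -> flip
    ("rs2", "1", 200, "A", "T", 0.3, 0.02, 0.02, 0.5, 9000),
    ("rs3", "2", 300, "G", "A", 0.4, 0.03, 0.02, 0.5, 9000),    # complement match
    ("rs5", "3", 500, "A", "C", 0.4, 0.01, 0.02, 0.5, 9000),
]


class TestHarmonize:
    def test_dispositions_and_sign_flip(self):
        h = harmonize(table_from(EXPOSURE_ROWS), table_from(OUTCOME_ROWS))
        audit = dict(h.audit.itertuples(index=False))
        assert audit == {
            "rs1": FLIPPED,
            "rs2": DROPPED_PALINDROMIC,
            "rs3": KEPT,
            "rs4": DROPPED_MISSING,
            "rs5": DROPPED_ALLELE_MISMATCH,
        }
        inst = h.instruments.set_index("snp_id")
        # outcome reported the swapped orientation: beta_y negated
        assert inst.loc["rs1", "beta_y"] == pytest.approx(0.05)
        # complement G/A matches exposure C/T effect allele: unchanged
        assert inst.loc["rs3", "beta_y"] == pytest.approx(0.03)
        # kept/flipped carry exposure alleles and eaf
        assert inst.loc["rs1", "effect_allele"] == "A"
        assert inst.loc["rs1", "eaf_x"] == pytest.approx(0.2)

    def test_instrument_order_follows_exposure_order(self):
        h = harmonize(table_from(EXPOSURE_ROWS), table_from(OUTCOME_ROWS))
        assert h.instruments["snp_id"].tolist() == ["rs1", "rs3"]

    def test_audit_covers_every_input_exactly_once(self):
        h = harmonize(table_from(EXPOSURE_ROWS), table_from(OUTCOME_ROWS))
        assert sorted(h.audit["snp_id"]) == sorted(r[0] for r in EXPOSURE_ROWS)
        n_dropped = h.audit["disposition"].str.startswith("dropped").sum()
        assert len(h.instruments) + n_dropped == len(EXPOSURE_ROWS)

    def test_idempotent_on_own_output(self):
        h = harmonize(table_from(EXPOSURE_ROWS), table_from(OUTCOME_ROWS))
        exp2 = table_from(
            [r for r in EXPOSURE_ROWS if r[0] in set(h.instruments["snp_id"])]
        )
        out2_rows = []
        for r in h.instruments.itertuples():
            out2_rows.append(
                (r.snp_id, "1", 0, r.effect_allele, r.other_allele,
                 r.eaf_x, r.beta_y, r.se_y, 0.5, 9000)
            )
        h2 = harmonize(exp2, table_from(out2_rows))
        assert (h2.audit["disposition"] == KEPT).all()
        np.testing.assert_allclose(
            h2.instruments["beta_y"], h.instruments["beta_y"]
        )

    def test_sign_flip_involution(self):
        """Complement-swapping outcome alleles and negating beta_y is a no-op."""
        from mrkit.sumstats import COMPLEMENT

        h1 = harmonize(table_from(EXPOSURE_ROWS), table_from(OUTCOME_ROWS))
        transformed = [
            (sid, c, p, COMPLEMENT[oa], COMPLEMENT[ea], eaf, -b, se, pv, n)
            for sid, c, p, ea, oa, eaf, b, se, pv, n in OUTCOME_ROWS
        ]
        h2 = harmonize(table_from(EXPOSURE_ROWS), table_from(transformed))
        pd.testing.assert_frame_equal(h1.instruments, h2.instruments)
        # kept/flipped labels swap with the orientation; drops are identical
        dropped1 = h1.audit[h1.audit["disposition"].str.startswith("dropped")]
        dropped2 = h2.audit[h2.audit["disposition"].str.startswith("dropped")]
        pd.testing.assert_frame_equal(dropped1, dropped2)

    def test_empty_exposure_raises(self):
        with pytest.raises(EmptyInputError):
            harmonize(
                table_from(EXPOSURE_ROWS).restrict([]), table_from(OUTCOME_ROWS)
            )

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(HarmonizationError):
            table_from([EXPOSURE_ROWS[0], EXPOSURE_ROWS[0]])

    def test_roundtrip_tsv(self, tmp_path):
        h = harmonize(table_from(EXPOSURE_ROWS), table_from(OUTCOME_ROWS))
        out = tmp_path / "harm.tsv"
        h.to_tsv(out)
        back = pd.read_csv(out, sep="\t")
        assert len(back) == len(EXPOSURE_ROWS)  # one row per input SNP
        assert set(back["disposition"]) == {
            FLIPPED, KEPT, DROPPED_PALINDROMIC, DROPPED_MISSING,
            DROPPED_ALLELE_MISMATCH,
        }
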