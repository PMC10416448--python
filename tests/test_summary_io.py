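"""Reading/validation of summary-statistics tables and allele harmonization."""
import logging

import pytest

from mrkit.estimators import ivw
from mrkit.summary_io import (
    ACTION_DROPPED_INCOMPATIBLE,
    ACTION_DROPPED_PALINDROMIC,
    ACTION_FLIPPED,
    ACTION_KEPT,
    GwasRecord,
    harmonize,
    read_gwas,
    usable,
    write_gwas,
)

from .conftest import make_record

HEADER = "rsid\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn"


def write_table(path, rows):
    path.write_text("\n".join([HEADER] + rows) + "\n")


class TestReadGwas:
    def test_valid_rows_read_in_order(self, tmp_path, caplog):
        f = tmp_path / "gwas.tsv"
        write_table(
            f,
            [
                "rs1\t1\t100\tA\tG\t0.3\t0.10\t0.02\t5e-7\t18000",
                "rs2\tX\t200\tC\tT\t0.5\t-0.05\t0.02\t0.012\t18000",
                "rs3\t22\t300\tG\tC\t0.1\t0.00\t0.02\t1.0\t18000",
            ],
        )
        with caplog.at_level(logging.WARNING):
            records = read_gwas(f)
        assert [r.rsid for r in records] == ["rs1", "rs2", "rs3"]
        assert records[1].chrom == 23  # X recoded
        assert not caplog.records

    @pytest.mark.parametrize(
        "bad_row",
        [
            "rs9\t1\t100\tA\tG\t1.2\t0.1\t0.02\t1e-6\t18000",  # eaf out of range
            "rs9\t1\t100\tAT\tA\t0.3\t0.1\t0.02\t1e-6\t18000",  # indel alleles
            "rs9\t1\t100\tA\tA\t0.3\t0.1\t0.02\t1e-6\t18000",  # identical alleles
            "rs9\t1\t100\tA\tG\t0.3\t0.1\t0.00\t1e-6\t18000",  # non-positive se
            "rs9\t1\t100\tA\tG\t0.3\t0.1\t0.02\t0.0\t18000",  # p out of range
        ],
    )
    def test_invalid_row_dropped_with_warning(self, tmp_path, caplog, bad_row):
        f = tmp_path / "gwas.tsv"
        write_table(f, ["rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t5e-7\t18000", bad_row])
        with caplog.at_level(logging.WARNING):
            records = read_gwas(f)
        assert [r.rsid for r in records] == ["rs1"]
        assert any("dropped 1 invalid row" in m for m in caplog.messages)

    def test_missing_column_fatal(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        f.write_text("rsid\tbeta\nrs1\t0.1\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            read_gwas(f)

    def test_empty_file_fatal(self, tmp_path):
        f = tmp_path / "gwas.tsv"
        f.write_text(HEADER + "\n")
        with pytest.raises(ValueError, match="empty"):
            read_gwas(f)

    def test_column_map_and_gzip_roundtrip(self, tmp_path):
        records = [make_record("rs1"), make_record("rs2", pos=2000, beta=-0.2)]
        f = tmp_path / "gwas.tsv.gz"
        write_gwas(records, f)
        assert read_gwas(f) == records

    def test_inconsistent_pvalue_warns_not_drops(self, tmp_path, caplog):
        f = tmp_path / "gwas.tsv"
        # |z| = 5 implies p ~ 6e-7, but 0.5 is reported
        write_table(f, ["rs1\t1\t100\tA\tG\t0.3\t0.10\t0.02\t0.5\t18000"])
        with caplog.at_level(logging.WARNING):
            records = read_gwas(f)
        assert len(records) == 1
        assert any("inconsistent" in m for m in caplog.messages)


class TestHarmonize:
    def test_identical_alleles_kept(self):
        e = make_record(beta=0.1)
        o = make_record(beta=0.05)
        (v,) = harmonize([e], [o])
        assert v.action_taken == ACTION_KEPT
        assert v.beta_out == 0.05

    def test_swapped_alleles_flipped(self):
        e = make_record(effect_allele="A", other_allele="G", beta=0.1, eaf=0.3)
        o = make_record(effect_allele="G", other_allele="A", beta=0.05, eaf=0.7)
        (v,) = harmonize([e], [o])
        assert v.action_taken == ACTION_FLIPPED
        assert v.beta_out == pytest.approx(-0.05)
        assert v.eaf_out == pytest.approx(0.3)

    def test_ambiguous_palindromic_dropped(self):
        e = make_record(effect_allele="A", other_allele="T", eaf=0.50)
        o = make_record(effect_allele="A", other_allele="T", eaf=0.50)
        (v,) = harmonize([e], [o])
        assert v.action_taken == ACTION_DROPPED_PALINDROMIC
        assert v.palindromic

    def test_palindromic_outside_window_aligned_by_frequency(self):
        e = make_record(effect_allele="C", other_allele="G", eaf=0.2, beta=0.1)
        # outcome frequency on the other strand orientation
        o = make_record(effect_allele="C", other_allele="G", eaf=0.8, beta=0.05)
        (v,) = harmonize([e], [o])
        assert v.action_taken == ACTION_FLIPPED
        assert v.beta_out == pytest.approx(-0.05)
        o2 = make_record(effect_allele="G", other_allele="C", eaf=0.21, beta=0.05)
        (v2,) = harmonize([e], [o2])
        assert v2.action_taken == ACTION_KEPT

    def test_incompatible_alleles_dropped(self):
        e = make_record(effect_allele="A", other_allele="G")
        o = make_record(effect_allele="A", other_allele="C")
        (v,) = harmonize([e], [o])
        assert v.action_taken == ACTION_DROPPED_INCOMPATIBLE

    def test_duplicate_rsid_fatal(self):
        with pytest.raises(ValueError, match="rs1"):
            harmonize([make_record("rs1"), make_record("rs1")], [make_record("rs1")])

    def test_count_conservation(self):
        exposure = [
            make_record("rs1"),
            make_record("rs2", effect_allele="A", other_allele="T", eaf=0.5),
            make_record("rs3", effect_allele="C", other_allele="G", eaf=0.2),
            make_record("rs4"),
            make_record("rs5"),  # not shared
        ]
        outcome = [
            make_record("rs1"),
            make_record("rs2", effect_allele="A", other_allele="T", eaf=0.5),
            make_record("rs3", effect_allele="C", other_allele="G", eaf=0.9),
            make_record("rs4", effect_allele="T", other_allele="C"),
            make_record("rs6"),
        ]
        result = harmonize(exposure, outcome)
        shared = {"rs1", "rs2", "rs3", "rs4"}
        assert {v.rsid for v in result} == shared
        assert len(result) == len(shared)

    def test_idempotent_on_harmonized_pairs(self):
        exposure = [make_record("rs1"), make_record("rs2", beta=-0.2, eaf=0.6)]
        outcome = [
            make_record("rs1", effect_allele="G", other_allele="A", beta=0.05, eaf=0.7),
            make_record("rs2", beta=0.02),
        ]
        first = usable(harmonize(exposure, outcome))
        # rebuild outcome records on the aligned allele and re-harmonize
        realigned = [
            GwasRecord(v.rsid, e.chrom, e.pos, e.effect_allele, e.other_allele,
                       v.eaf_out, v.beta_out, v.se_out, 0.5, 18000)
            for v, e in zip(first, exposure)
        ]
        second = usable(harmonize(exposure, realigned))
        assert [(v.rsid, v.beta_out, v.eaf_out) for v in second] == [
            (v.rsid, v.beta_out, v.eaf_out) for v in first
        ]
        assert all(v.action_taken == ACTION_KEPT for v in second)

    def test_allele_relabel_leaves_estimates_unchanged(self):
        """Relabeling the effect allele in both tables at once must not move
        the causal estimate."""
        exposure = [
            make_record("rs1", beta=0.1, eaf=0.3),
            make_record("rs2", pos=2000, beta=-0.15, eaf=0.6),
            make_record("rs3", pos=3000, beta=0.2, eaf=0.2),
        ]
        outcome = [
            make_record("rs1", beta=0.04, se=0.03),
            make_record("rs2", pos=2000, beta=-0.05, se=0.03),
            make_record("rs3", pos=3000, beta=0.07, se=0.03),
        ]

        def relabel(rec):
            return GwasRecord(
                rec.rsid, rec.chrom, rec.pos, rec.other_allele, rec.effect_allele,
                1.0 - rec.eaf, -rec.beta, rec.se, rec.pvalue, rec.n,
            )

        base = ivw(usable(harmonize(exposure, outcome)), "fixed")
        flipped = ivw(
            usable(harmonize([relabel(r) for r in exposure],
                             [relabel(r) for r in outcome])),
            "fixed",
        )
        assert flipped.beta == pytest.approx(base.beta, rel=1e-12)
        assert flipped.se == pytest.approx(base.se, rel=1e-12)
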