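"""Catalog loading, inclusion criteria, grouping and poison-exon flagging."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from pexsplice.catalog import (
    CatalogError,
    ExonRecord,
    PERecord,
    assign_group,
    flag_poison_exon,
    load_catalog,
    summarize_catalog,
)
from pexsplice.hgvs import parse_hgvs

HEADER = (
    "pe_id\tchrom\tstart\tend\tstrand\tmechanism\tvariants\tvariant_class"
    "\tphenotype\tptc_offset\tconservation_mean"
)


def _write_catalog(tmp_path, rows, name="cat.tsv"):
    p = tmp_path / name
    p.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return p


class TestLoadCatalog:
    def test_row_without_variant_rejected_with_reason(self, tmp_path):
        """A PE without an activating genomic variant is not included."""
        p = _write_catalog(
            tmp_path,
            ["PE1\tchr1\t100\t150\t+\tnew_ss\t\tsnv\tBMD\t\t"],
        )
        records, rejected = load_catalog(p)
        assert records == []
        assert len(rejected) == 1 and "criterion 4" in rejected[0].reason

    def test_pe_overlapping_ce_rejected(self, tmp_path):
        p = _write_catalog(
            tmp_path,
            ["PE1\tchr1\t100\t150\t+\tnew_ss\tg.120A>G\tsnv\tBMD\t\t"],
        )
        records, rejected = load_catalog(p, ce_intervals=[("chr1", 100, 150)])
        assert records == []
        assert "criterion 2" in rejected[0].reason

    def test_minus_strand_sequences_are_reverse_complemented(self, tmp_path):
        plus = "ACGTACGTTTACGGGTACGT"
        fasta = {"chr1": "N" * 0 + plus + "A" * 30}
        rows = [
            f"PE{i}\tchr1\t{s}\t{e}\t-\tnew_ss\tg.{s + 1}{plus[s]}>"
            f"{'G' if plus[s] != 'G' else 'C'}\tsnv\tBMD\t\t"
            for i, (s, e) in enumerate([(0, 6), (6, 12), (12, 18)], start=1)
        ]
        p = _write_catalog(tmp_path, rows)
        records, rejected = load_catalog(p, fasta=fasta)
        assert not rejected
        for rec, (s, e) in zip(records, [(0, 6), (6, 12), (12, 18)]):
            assert rec.exon.seq == reverse_complement(plus[s:e])

    def test_malformed_row_names_location(self, tmp_path):
        p = _write_catalog(
            tmp_path, ["PE1\tchr1\tnot_an_int\t150\t+\tnew_ss\tg.1A>G\tsnv\tx\t\t"]
        )
        with pytest.raises(CatalogError, match="start/end"):
            load_catalog(p)

    def test_crlf_rejected(self, tmp_path):
        p = tmp_path / "crlf.tsv"
        p.write_bytes((HEADER + "\r\n").encode())
        with pytest.raises(CatalogError, match="CRLF"):
            load_catalog(p)

    def test_unknown_column_warns_but_loads(self, tmp_path):
        p = tmp_path / "extra.tsv"
        p.write_text(
            HEADER + "\textra_col\n"
            "PE1\tchr1\t100\t150\t+\tnew_ss\tg.120A>G\tsnv\tBMD\t\t\tzzz\n"
        )
        with pytest.warns(UserWarning, match="unknown columns"):
            records, _ = load_catalog(p)
        assert len(records) == 1


class TestGrouping:
    def _pe(self, mechanism):
        exon = ExonRecord(id="PE1", role="PE", chrom="c", start=0, end=30)
        return PERecord(
            exon=exon, variants=[parse_hgvs("g.10A>G")], mechanism=mechanism
        )

    def test_splice_site_mechanisms(self):
        assert assign_group(self._pe({"new_ss"})) == "splice_site"
        assert assign_group(self._pe({"strengthen_cryptic_ss"})) == "splice_site"

    def test_sre_mechanisms(self):
        assert assign_group(self._pe({"new_ESE", "disrupt_ESS"})) == "SRE"

    def test_mixed_mechanisms_take_splice_site_precedence(self):
        assert assign_group(self._pe({"new_ss", "new_ESE"})) == "splice_site"

    def test_empty_mechanism_errors(self):
        with pytest.raises(CatalogError):
            assign_group(self._pe(set()))


class TestPoisonFlag:
    def _exon(self, seq, cons_mean):
        return ExonRecord(
            id="PE1", role="PE", chrom="c", start=0, end=len(seq), seq=seq,
            conservation=np.full(len(seq), cons_mean),
        )

    def test_in_frame_stop_with_high_conservation(self):
        exon = self._exon("ATGTAACCC", cons_mean=3.0)
        flag, off = flag_poison_exon(exon, 0, "ATGATGATG", cons_threshold=2.0)
        assert flag is True and off == 3

    def test_low_conservation_gates_the_flag_but_reports_offset(self):
        exon = self._exon("ATGTAACCC", cons_mean=0.5)
        flag, off = flag_poison_exon(exon, 0, "ATGATGATG", cons_threshold=2.0)
        assert flag is False and off == 3

    def test_frameshift_stop_found_in_downstream_cds(self):
        """A PE of length 3k+1 shifts the frame: the stop emerges downstream.

        Independent codon-walk oracle: concatenate and scan triplets."""
        pe_seq = "A" * 7  # 3k+1, no stop inside
        downstream = "ATTAAGGG"
        exon = self._exon(pe_seq, cons_mean=3.0)
        flag, off = flag_poison_exon(exon, 0, downstream, cons_threshold=2.0)
        combined = pe_seq + downstream
        oracle = next(
            i for i in range(0, len(combined) - 2, 3)
            if combined[i : i + 3] in {"TAA", "TAG", "TGA"}
        )
        assert off == oracle and off >= len(pe_seq)
        assert flag is True

    def test_phase_offsets_shift_codon_register(self):
        # with phase 2, the first full codon starts at offset 1
        exon = self._exon("ATAAGGGCC", cons_mean=3.0)
        _, off = flag_poison_exon(exon, 2, "", cons_threshold=2.0)
        assert off == 1

    def test_missing_conservation_with_threshold_errors(self):
        exon = ExonRecord(id="x", role="PE", chrom="c", start=0, end=9, seq="ATGTAACCC")
        with pytest.raises(CatalogError, match="conservation"):
            flag_poison_exon(exon, 0, "", cons_threshold=2.0)


class TestSummaries:
    def _records(self, n_snv, n_other):
        out = []
        for i in range(n_snv + n_other):
            exon = ExonRecord(id=f"PE{i}", role="PE", chrom="c", start=0, end=30)
            out.append(
                PERecord(
                    exon=exon, variants=[parse_hgvs("g.10A>G")],
                    mechanism={"new_ss"},
                    variant_class="snv" if i < n_snv else "large_rearrangement",
                )
            )
        return out

    def test_three_snv_one_rearrangement(self):
        s = summarize_catalog(self._records(3, 1))
        assert (s.pct_snv, s.pct_other) == (75.0, 25.0)

    def test_single_snv_is_100(self):
        s = summarize_catalog(self._records(1, 0))
        assert s.pct_snv == 100.0

    def test_empty_catalog_reports_absent_percentages(self):
        s = summarize_catalog([])
        assert s.n_total == 0 and s.pct_snv is None and s.pct_other is None

    def test_percentages_sum_to_100(self):
        s = summarize_catalog(self._records(5, 3))
        assert abs(s.pct_snv + s.pct_other - 100.0) < 0.011
        assert s.n_snv_activated + s.n_rearrangement_or_small == s.n_total


class TestExonRecord:
    def test_invalid_interval_rejected(self):
        with pytest.raises(CatalogError):
            ExonRecord(id="x", role="CE", chrom="c", start=10, end=10)

    def test_sequence_length_must_match_interval(self):
        with pytest.raises(CatalogError):
            ExonRecord(id="x", role="CE", chrom="c", start=0, end=5, seq="ACG")

    def test_double_reverse_complement_is_identity(self, locus):
        for rec in locus.pe_records[:3]:
            assert (
                reverse_complement(reverse_complement(rec.exon.seq)) == rec.exon.seq
            )
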