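"""SRE motif resources, match counting, densities and flanking windows."""

import numpy as np
import pytest

from pexsplice.catalog import ExonRecord
from pexsplice.sre_scan import (
    MotifResource,
    ResourceError,
    count_matches,
    count_scored_matches,
    exonic_sre_profile,
    flanking_windows,
    intronic_sre_profile,
    load_motif_resource,
)

BASES = "ACGT"


def _list_resource(motifs, cls="ESE", name="r"):
    return MotifResource(name=name, cls=cls, kind="list", motifs=frozenset(motifs))


class TestLoading:
    def test_hexamer_list(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("ACGTAC\nTTTGGG\n")
        r = load_motif_resource(p, "toy", "list", "ESE")
        assert r.k == 6 and len(r.motifs) == 2

    def test_pssm_without_threshold_errors(self, tmp_path):
        p = tmp_path / "m.tsv"
        rows = ["\t".join("1" for _ in range(6)) for _ in range(4)]
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(ResourceError, match="threshold"):
            load_motif_resource(p, "toy", "pssm", "ESE")

    def test_width_inconsistency_errors(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("ACGTAC\nTTTT\n")
        with pytest.raises(ResourceError, match="width"):
            load_motif_resource(p, "toy", "list", "ESE")

    def test_non_acgt_symbol_errors(self, tmp_path):
        p = tmp_path / "l.txt"
        p.write_text("ACGUAC\n")
        with pytest.raises(ResourceError, match="non-ACGT"):
            load_motif_resource(p, "toy", "list", "ESE")

    def test_scored_table_with_both_signs_loads(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("TTAGGG\t5.0\tfA\nGGGAAA\t-2.0\tfB\n")
        r = load_motif_resource(p, "toy", "scored_table", "intron_scored")
        signs = sorted(np.sign(v) for _, v in r.scored_entries)
        assert signs == [-1.0, 1.0]

    def test_zero_score_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("TTAGGG\t0\tfA\n")
        with pytest.raises(ResourceError, match="zero"):
            load_motif_resource(p, "toy", "scored_table", "intron_scored")


class TestCounting:
    def test_overlapping_convention(self):
        assert count_matches(_list_resource({"AAAAAA"}), "AAAAAAA") == 2

    def test_non_overlapping_option(self):
        assert (
            count_matches(_list_resource({"AAAAAA"}), "A" * 12, overlapping=False)
            == 2
        )

    def test_sequence_shorter_than_k_is_zero(self):
        assert count_matches(_list_resource({"AAAAAA"}), "AAAAA") == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_naive_positionwise_scan(self, seed):
        rng = np.random.default_rng(seed)
        motifs = {"".join(rng.choice(list("AC"), 6)) for _ in range(2)}
        seq = "".join(rng.choice(list("AC"), 60))
        r = _list_resource(motifs)
        oracle = sum(1 for i in range(len(seq) - 5) if seq[i : i + 6] in motifs)
        assert count_matches(r, seq) == oracle

    def test_pssm_counting_equals_naive_threshold_scan(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(size=(4, 5))
        r = MotifResource(
            name="p", cls="ESE", kind="pssm", matrix=mat,
            threshold=float(mat.max(axis=0).sum() * 0.5),
        )
        seq = "".join(rng.choice(list(BASES), 80))
        idx = {b: i for i, b in enumerate(BASES)}
        oracle = sum(
            1
            for i in range(len(seq) - 4)
            if sum(mat[idx[b], j] for j, b in enumerate(seq[i : i + 5]))
            >= r.threshold
        )
        assert count_matches(r, seq) == oracle

    def test_sign_partition(self):
        r = MotifResource(
            name="s", cls="intron_scored", kind="scored_table",
            scored_entries=(("TTAGGG", 5.0), ("GGGAAA", -2.0), ("AAATTT", 1.0)),
        )
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list(BASES), 300))
        pos, neg = count_scored_matches(r, seq)
        assert pos + neg == count_matches(r, seq)


class TestExonicProfile:
    def test_density_from_planted_matches(self):
        seq = "AAAAAA" + "C" * 6 + "AAAAAA" + "G" * 6 + "CCCCAA"
        r = _list_resource({"AAAAAA"})
        prof = exonic_sre_profile(seq, [r])
        assert len(seq) == 30
        # planted: two isolated AAAAAA runs -> 2 starts, plus none elsewhere
        assert prof.counts["r"] == 2
        assert prof.densities["r"] == pytest.approx(2 / 30)

    def test_ratio(self):
        seqs = "AAAAAA" * 2 + "TTTTTT"
        ese = _list_resource({"AAAAAA"}, cls="ESE", name="e")
        ess = _list_resource({"TTTTTT"}, cls="ESS", name="s")
        prof = exonic_sre_profile(seqs, [ese, ess])
        # overlapping starts: AAAAAA x7, TTTTTT x1
        assert prof.total_ese_count == 7 and prof.total_ess_count == 1
        assert prof.ese_ess_ratio == pytest.approx(7.0)

    def test_no_matches_leaves_ratio_absent(self):
        prof = exonic_sre_profile("ACGT" * 10, [_list_resource({"AAAAAA"})])
        assert prof.total_ese_density == 0.0
        assert prof.ese_ess_ratio is None

    def test_density_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list(BASES), 40))
            prof = exonic_sre_profile(seq, [_list_resource({"ACGTAC", "TTTTTT"})])
            assert 0.0 <= prof.densities["r"] <= 1.0


class TestFlankingWindows:
    def _exon(self, start, end, prev_end, next_start, strand="+"):
        return ExonRecord(
            id="x", role="PE", chrom="c", start=start, end=end, strand=strand,
            prev_ce_end=prev_end, next_ce_start=next_start,
        )

    def test_long_introns_give_full_windows(self):
        up, down = flanking_windows(self._exon(1000, 1100, 0, 3000), w=300)
        assert up == (700, 1000) and down == (1100, 1400)

    def test_short_upstream_intron_truncates(self):
        up, down = flanking_windows(self._exon(1000, 1100, 900, 3000), w=300)
        assert up == (900, 1000)  # only 100 bp available

    def test_truncation_law_on_synthetic_annotations(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            gap_up = int(rng.integers(0, 600))
            gap_down = int(rng.integers(0, 600))
            e = self._exon(5000, 5100, 5000 - gap_up, 5100 + gap_down)
            up, down = flanking_windows(e, w=300)
            assert up[1] - up[0] == min(300, gap_up)
            assert down[1] - down[0] == min(300, gap_down)

    def test_zero_length_intron_gives_empty_window(self):
        up, _ = flanking_windows(self._exon(1000, 1100, 1000, 3000), w=300)
        assert up == (1000, 1000)

    def test_terminus_side_is_absent(self):
        up, down = flanking_windows(self._exon(1000, 1100, None, 3000), w=300)
        assert up is None and down is not None

    def test_minus_strand_swaps_sides(self):
        up, down = flanking_windows(
            self._exon(1000, 1100, 0, 3000, strand="-"), w=300
        )
        assert up == (1100, 1400) and down == (700, 1000)

    def test_negative_intron_errors(self):
        with pytest.raises(ResourceError, match="negative"):
            flanking_windows(self._exon(1000, 1100, 1050, 3000))


class TestIntronicProfile:
    RES = MotifResource(
        name="sa", cls="intron_scored", kind="scored_table",
        scored_entries=(("TTAGGG", 5.0), ("GGGAAA", -2.0)),
    )

    def test_one_occurrence_of_each_sign(self):
        window = "C" * 10 + "TTAGGG" + "C" * 10 + "GGGAAA" + "C" * 10
        prof = intronic_sre_profile(window, None, self.RES)
        L = len(window)
        assert prof.iss_density_3p == pytest.approx(1 / L)
        assert prof.ise_density_3p == pytest.approx(1 / L)
        assert prof.iss_ise_ratio == pytest.approx(1.0)

    def test_empty_windows_leave_everything_absent(self):
        prof = intronic_sre_profile("", None, self.RES)
        assert prof.iss_density_3p is None and prof.iss_ise_ratio is None

    def test_all_positive_entries_give_zero_ise(self):
        res = MotifResource(
            name="p", cls="intron_scored", kind="scored_table",
            scored_entries=(("TTAGGG", 5.0),),
        )
        prof = intronic_sre_profile("TTAGGGCCC", "CCCTTAGGG", res)
        assert prof.ise_density_3p == 0.0 and prof.ise_density_5p == 0.0
        assert prof.iss_ise_ratio is None  # no ISE matches -> ratio absent

    def test_wrong_class_rejected(self):
        with pytest.raises(ResourceError):
            intronic_sre_profile("ACGT", None, _list_resource({"ACGTAA"}))
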