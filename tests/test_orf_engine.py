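"""ORF scanning and ortholog disruption assessment against a translation
oracle built on Bio.Seq."""

import numpy as np
import pytest
from Bio.Seq import Seq

from denovoscan.orf_engine import assess_ortholog, scan_orf, translate_from
from denovoscan.trio_model import Thresholds

from conftest import make_trio, random_nt


def oracle_translate(seq: str, start: int):
    """Independent translation oracle: Bio.Seq over the trimmed frame."""
    frame = seq[start : start + 3 * ((len(seq) - start) // 3)]
    if not frame:
        return "", False
    aa = str(Seq(frame).translate())
    if "*" in aa:
        return aa.split("*")[0], True
    return aa, False


def oracle_best_orf(seq: str):
    """Longest protein over every ATG position; ties to the 5'-most."""
    best = ("", False, None)
    for i in range(len(seq) - 2):
        if seq[i : i + 3] == "ATG":
            prot, complete = oracle_translate(seq, i)
            if len(prot) > len(best[0]):
                best = (prot, complete, i)
    return best


class TestTranslateFrom:
    @pytest.mark.parametrize(
        "seq,start,protein,complete,stop_pos",
        [
            ("ATGAAATAA", 0, "MK", True, 6),
            ("ATGTAA", 0, "M", True, 3),
            ("ATGAAA", 0, "MK", False, None),
            ("CCCATGAAATAG", 3, "MK", True, 9),
        ],
    )
    def test_examples(self, seq, start, protein, complete, stop_pos):
        rep = translate_from(seq, start)
        assert (rep.protein, rep.complete, rep.stop_pos) == (protein, complete, stop_pos)

    def test_n_codon_is_x_and_never_a_stop(self):
        rep = translate_from("ATGTNAAAATAA", 0)
        assert rep.protein == "MXK" and rep.complete

    def test_start_beyond_end_rejected(self):
        with pytest.raises(ValueError, match="beyond sequence end"):
            translate_from("ATG", 7)


class TestScanOrf:
    def test_rescue_finds_downstream_start(self):
        rep = scan_orf("CCCATGAAATAA", policy="rescue", human_protein_len=2)
        assert rep.start_pos == 3 and rep.protein == "MK"
        assert rep.length_fraction == 1.0

    def test_no_atg_under_rescue(self):
        rep = scan_orf("CCCCCC", policy="rescue")
        assert rep.start_pos is None and not rep.complete

    def test_anchored_requires_atg_at_anchor(self):
        rep = scan_orf("CCCATGAAATAA", anchor=0, policy="anchored")
        assert rep.start_pos is None and not rep.complete

    def test_rescue_matches_exhaustive_atg_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            seq = random_nt(rng, 300)
            rep = scan_orf(seq, policy="rescue")
            prot, complete, start = oracle_best_orf(seq)
            assert len(rep.protein) == len(prot)
            if start is not None:
                assert rep.complete == complete
                # ties go to the 5'-most start of maximal length
                firsts = [
                    i
                    for i in range(len(seq) - 2)
                    if seq[i : i + 3] == "ATG"
                    and len(oracle_translate(seq, i)[0]) == len(prot)
                ]
                assert rep.start_pos == firsts[0]


class TestAssessOrtholog:
    def _long_trio(self, n=150, mutate=None):
        """Identity trio with an n-codon human ORF; ``mutate`` edits the
        outgroup rows (maps nt offset -> base)."""
        rng = np.random.default_rng(5)
        body = []
        aa_codons = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in {"TAA", "TAG", "TGA", "ATG"}
        ]
        prev = ""
        for _ in range(n - 1):
            while True:
                cand = aa_codons[rng.integers(len(aa_codons))]
                if "ATG" not in prev[-2:] + cand:
                    break
            body.append(cand)
            prev = cand
        human = "ATG" + "".join(body) + "TAA"
        other = human
        if mutate:
            other = list(other)
            for off, base in mutate.items():
                other[off] = base
            other = "".join(other)
        return make_trio(
            human=human, chimp=other, orang=other, start_col=0, stop_col=3 * n
        )

    def test_identical_row_is_intact(self):
        trio = self._long_trio()
        st = assess_ortholog(trio, "chimp")
        assert st.status == "intact" and not st.events
        assert st.orf.length_fraction == 1.0

    def test_premature_stop_at_codon_30_disrupts(self):
        # plant TAA at codon 30 of a 150-codon ORF
        trio = self._long_trio(mutate=None)
        human = trio.rows["human"]
        other = human[: 3 * 30] + "TAA" + human[3 * 30 + 3 :]
        trio = make_trio(human=human, chimp=other, orang=other, stop_col=450)
        st = assess_ortholog(trio, "chimp")
        prot, complete = oracle_translate(other, 0)
        assert complete and len(prot) == 30
        assert st.status == "disrupted"
        assert st.orf.length_fraction == pytest.approx(30 / 150)
        assert any(e.kind == "premature_stop" for e in st.events)

    def test_stop_at_85_percent_is_intact_enough(self):
        trio = self._long_trio()
        human = trio.rows["human"]
        k = 128  # 128/150 ~ 0.853 >= 0.80
        other = human[: 3 * k] + "TGA" + human[3 * k + 3 :]
        trio = make_trio(human=human, chimp=other, orang=other, stop_col=450)
        st = assess_ortholog(trio, "chimp")
        assert st.orf.complete and st.orf.length_fraction >= 0.80
        assert st.status == "intact_enough"

    def test_boundary_fraction_exactly_080_counts_intact_enough(self):
        trio = self._long_trio()
        human = trio.rows["human"]
        k = 120  # 120/150 = 0.80 exactly
        other = human[: 3 * k] + "TGA" + human[3 * k + 3 :]
        trio = make_trio(human=human, chimp=other, orang=other, stop_col=450)
        st = assess_ortholog(trio, "chimp")
        assert st.orf.length_fraction == pytest.approx(0.80)
        assert st.status == "intact_enough"

    def test_missing_start_without_rescue_is_disrupted(self):
        trio = self._long_trio()
        human = trio.rows["human"]
        other = "ATA" + human[3:]
        trio = make_trio(human=human, chimp=other, orang=other, stop_col=450)
        st = assess_ortholog(trio, "chimp")
        assert st.status == "disrupted"
        assert any(e.kind == "missing_start" for e in st.events)

    def test_compensated_double_indel_keeps_orf_complete(self):
        """+1 then -1 indel restores frame: translation decides the status."""
        trio = self._long_trio()
        human = trio.rows["human"]
        # choose an out-of-frame window free of stops in the shifted frame:
        # insert 'C' before codon 10, delete first base of codon 12
        ins_at, del_at = 30, 36
        other = human[:ins_at] + "C" + human[ins_at:del_at] + human[del_at + 1 :]
        # verify via the oracle that the compensated ortholog still reaches
        # the annotated stop
        prot, complete = oracle_translate(other, 0)
        aligned_h = human[:ins_at] + "-" + human[ins_at:]
        aligned_o = other[: del_at + 1] + "-" + other[del_at + 1 :]
        assert len(aligned_h) == len(aligned_o)
        trio2 = make_trio(human=aligned_h, chimp=aligned_o, orang=aligned_o, stop_col=451)
        st = assess_ortholog(trio2, "chimp")
        assert st.orf.complete == complete
        assert len(st.orf.protein) == len(prot)
        # two frameshift events annotated, but the verdict follows translation
        assert sum(e.kind == "frameshift_indel" for e in st.events) == 2
        expected = "disrupted" if st.orf.length_fraction < 0.80 else "intact_enough"
        assert st.status == expected

    def test_entirely_gapped_ortholog_errors(self):
        human = "ATGAAATAA"
        gone = "---------"
        with pytest.raises(ValueError, match="ortholog region absent"):
            assess_ortholog(
                make_trio(human=human, chimp=gone, orang=human), "chimp"
            )

    def test_earlier_stop_never_increases_length_fraction(self):
        trio = self._long_trio()
        human = trio.rows["human"]
        fractions = []
        for k in (120, 80, 40, 10):
            other = human[: 3 * k] + "TAA" + human[3 * k + 3 :]
            t = make_trio(human=human, chimp=other, orang=other, stop_col=450)
            fractions.append(assess_ortholog(t, "chimp").orf.length_fraction)
        assert fractions == sorted(fractions, reverse=True)

    def test_assessment_is_deterministic(self):
        trio = self._long_trio(mutate={92: "T"})
        a = assess_ortholog(trio, "orang")
        b = assess_ortholog(trio, "orang")
        assert a == b
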