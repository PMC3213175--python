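"""Polarization of enabling mutations and the 7-stage candidate verdict."""

import pytest

from denovoscan.orf_engine import scan_orf
from denovoscan.polarity import (
    STAGES,
    classify_candidate,
    find_enabling_mutations,
)
from denovoscan.synthetic_data import (
    SCENARIO_KINDS,
    ScenarioSpec,
    generate_trio_scenario,
)
from denovoscan.trio_model import Thresholds, ungapped_map

from conftest import make_evidence, make_trio


def counterfactual_disrupted_oracle(trio, mut, th=None):
    """Re-derive the counterfactual verdict independently: apply the
    ancestral state to the human row and translate with the ORF scanner."""
    th = th or Thresholds()
    human = trio.rows["human"]
    cf = human[: mut.column] + mut.ancestral_state + human[mut.end_column :]
    seq = cf.replace("-", "")
    m = ungapped_map(cf)
    anchor = m.to_pos(trio.human_start_col)
    hlen = trio.human_protein_len()
    if anchor is not None and seq[anchor : anchor + 3] == "ATG":
        rep = scan_orf(seq, anchor=anchor, policy="anchored", human_protein_len=hlen)
    else:
        rep = scan_orf(seq, policy="rescue", human_protein_len=hlen)
    return (not rep.complete) or rep.length_fraction < th.intact_fraction


class TestFindEnablingMutations:
    def test_stop_removal_detected_and_classified(self):
        trio, _, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_stop_removal", n_codons=120, seed=3)
        )
        muts = find_enabling_mutations(trio)
        assert len(muts) == 1
        assert muts[0].effect == "stop_removal"
        assert trio.rows["chimp"][muts[0].column] == trio.rows["orang"][muts[0].column]
        assert counterfactual_disrupted_oracle(trio, muts[0])

    def test_start_creation_detected(self):
        trio, _, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_start_creation", n_codons=120, seed=3)
        )
        muts = find_enabling_mutations(trio)
        assert len(muts) == 1 and muts[0].effect == "start_creation"
        assert trio.human_start_col <= muts[0].column < trio.human_start_col + 3

    def test_frameshifting_insertion_reversion(self):
        trio, _, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_frame_completion", n_codons=120, seed=3)
        )
        muts = find_enabling_mutations(trio)
        assert len(muts) == 1 and muts[0].effect == "frame_completion"
        assert muts[0].human_state == "-" and muts[0].ancestral_state == "T"
        assert counterfactual_disrupted_oracle(trio, muts[0])

    def test_outgroup_disagreement_is_unpolarizable(self):
        trio, _, _ = generate_trio_scenario(
            ScenarioSpec(kind="parallel_loss", n_codons=120, seed=3)
        )
        assert find_enabling_mutations(trio) == []

    def test_n_in_outgroup_disqualifies_column(self):
        trio, _, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_stop_removal", n_codons=120, seed=5)
        )
        col = find_enabling_mutations(trio)[0].column
        chimp = trio.rows["chimp"]
        noisy = trio.with_human_row(trio.rows["human"])  # copy
        rows = dict(trio.rows)
        rows["chimp"] = chimp[:col] + "N" + chimp[col + 1 :]
        from denovoscan.trio_model import CodingTrioAlignment

        trio2 = CodingTrioAlignment(
            gene_id=trio.gene_id,
            rows=rows,
            human_start_col=trio.human_start_col,
            human_stop_col=trio.human_stop_col,
        )
        assert find_enabling_mutations(trio2) == []

    def test_incomplete_human_orf_rejected(self):
        trio = make_trio(human="ATGAAATAA")  # complete, fine
        broken = trio.with_human_row("ATGAAAAAA")
        with pytest.raises(ValueError, match="human ORF not complete"):
            find_enabling_mutations(broken)


class TestClassifyCandidate:
    def test_de_novo_scenario_all_pass(self):
        trio, ev, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_stop_removal", n_codons=150, seed=7)
        )
        v = classify_candidate(trio, ev)
        assert v.verdict == "de_novo"
        assert [e.result for e in v.ledger] == ["pass"] * 7

    def test_ledger_has_fixed_stage_order(self):
        for kind in SCENARIO_KINDS:
            trio, ev, _ = generate_trio_scenario(
                ScenarioSpec(kind=kind, n_codons=120, seed=1)
            )
            v = classify_candidate(trio, ev)
            assert tuple(e.stage for e in v.ledger) == STAGES

    def test_parallel_loss_rejected_at_polarization(self):
        trio, ev, _ = generate_trio_scenario(
            ScenarioSpec(kind="parallel_loss", n_codons=150, seed=7)
        )
        v = classify_candidate(trio, ev)
        assert v.verdict == "rejected"
        assert v.failing_stage() == "enabling_mutation"
        entry = next(e for e in v.ledger if e.stage == "enabling_mutation")
        assert "no polarizable" in entry.reason

    def test_missing_peptide_rejected_at_translation(self):
        trio, ev, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_stop_removal", n_codons=150, seed=7)
        )
        v = classify_candidate(trio, make_evidence(trio.gene_id, has_peptide=False))
        assert v.verdict == "rejected" and v.failing_stage() == "translation"

    def test_missing_transcription_rejected(self):
        trio, ev, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_stop_removal", n_codons=150, seed=7)
        )
        v = classify_candidate(
            trio, make_evidence(trio.gene_id, has_mrna=False, has_est=False)
        )
        assert v.failing_stage() == "transcription"

    def test_duplicate_gene_rejected_at_single_copy(self):
        trio, ev, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_stop_removal", n_codons=150, seed=7)
        )
        v = classify_candidate(
            trio, make_evidence(trio.gene_id, single_copy_human=False)
        )
        assert v.failing_stage() == "single_copy"

    def test_short_protein_rejected_at_min_length(self):
        trio = make_trio()  # 2-aa protein
        v = classify_candidate(trio, make_evidence("g1"))
        assert v.failing_stage() == "min_length"

    def test_disrupting_snp_noted_but_not_rejecting(self):
        trio, ev, _ = generate_trio_scenario(
            ScenarioSpec(kind="de_novo_stop_removal", n_codons=150, seed=9)
        )
        v = classify_candidate(
            trio, make_evidence(trio.gene_id, disrupting_snp=True)
        )
        assert v.verdict == "de_novo"
        assert "not be fixed" in v.fixation_note

    def test_shared_human_chimp_gain_never_de_novo(self):
        for seed in range(10):
            trio, ev, _ = generate_trio_scenario(
                ScenarioSpec(kind="shared_human_chimp_gain", n_codons=120, seed=seed)
            )
            v = classify_candidate(trio, ev)
            assert v.verdict == "rejected"
            assert v.failing_stage() == "outgroups_disrupted"


class TestCounterfactualSoundness:
    def test_every_reported_mutation_reverts_to_disrupted(self):
        for kind in ("de_novo_stop_removal", "de_novo_start_creation", "de_novo_frame_completion"):
            for seed in range(5):
                trio, _, _ = generate_trio_scenario(
                    ScenarioSpec(kind=kind, n_codons=130, seed=seed)
                )
                for mut in find_enabling_mutations(trio):
                    assert counterfactual_disrupted_oracle(trio, mut), (kind, seed)
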