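"""Polarization of human-specific ORF-enabling mutations and the per-gene
de novo verdict.

A candidate is accepted as de novo only when at least one human-specific
change is *singly sufficient*: reverting the human state to the ancestral
state shared by chimpanzee AND orangutan (parsimony by identity) leaves the
human reading frame disrupted.  Columns where the two outgroups disagree are
unpolarizable and are skipped — this is what protects against parallel loss,
where an ancestrally intact gene was independently disrupted on both
outgroup lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .orf_engine import assess_ortholog, scan_orf
from .trio_model import (
    CodingTrioAlignment,
    EvidenceRecord,
    Thresholds,
    ungapped_map,
)

Effect = Literal["start_creation", "stop_removal", "frame_completion"]

STAGES = (
    "human_orf",
    "min_length",
    "single_copy",
    "outgroups_disrupted",
    "enabling_mutation",
    "transcription",
    "translation",
)


@dataclass(frozen=True)
class EnablingMutation:
    """A human-specific change whose reversion disrupts the human ORF."""

    column: int
    end_column: int  # half-open; column+1 for substitutions
    human_state: str
    ancestral_state: str
    effect: Effect


@dataclass(frozen=True)
class LedgerEntry:
    stage: str
    result: Literal["pass", "fail", "skipped"]
    reason: str


@dataclass(frozen=True)
class CandidateVerdict:
    gene_id: str
    verdict: Literal["de_novo", "rejected"]
    ledger: tuple[LedgerEntry, ...]
    enabling: tuple[EnablingMutation, ...]
    statuses: tuple  # OrthologStatus for chimp, orang
    fixation_note: str = ""

    def failing_stage(self) -> str | None:
        for entry in self.ledger:
            if entry.result == "fail":
                return entry.stage
        return None


def _human_anchored_report(trio: CodingTrioAlignment, row: str | None = None):
    """Anchored ORF report for the (possibly counterfactual) human row,
    with rescue fallback when the anchored ATG is absent."""
    human = row if row is not None else trio.rows["human"]
    seq = human.replace("-", "")
    hmap = ungapped_map(human) if any(c != "-" for c in human) else None
    human_len = trio.human_protein_len()
    anchor = hmap.to_pos(trio.human_start_col) if hmap else None
    rep = None
    if anchor is not None:
        rep = scan_orf(seq, anchor=anchor, policy="anchored", human_protein_len=human_len)
    if rep is None or rep.start_pos is None:
        rep = scan_orf(seq, policy="rescue", human_protein_len=human_len)
    return rep


def _counterfactual_disrupted(
    trio: CodingTrioAlignment, row: str, th: Thresholds
) -> bool:
    rep = _human_anchored_report(trio, row)
    return (not rep.complete) or rep.length_fraction < th.intact_fraction


def _classify_effect(
    trio: CodingTrioAlignment, row: str, indel_len: int | None, th: Thresholds
) -> Effect:
    if indel_len is not None and indel_len % 3 != 0:
        return "frame_completion"
    hmap = ungapped_map(row) if any(c != "-" for c in row) else None
    anchor = hmap.to_pos(trio.human_start_col) if hmap else None
    seq = row.replace("-", "")
    if anchor is None or seq[anchor : anchor + 3] != "ATG":
        return "start_creation"
    # frame intact, start intact: the reversion must have (re)introduced a
    # premature stop or destroyed the terminal stop — either way the human
    # change acted on a stop codon
    return "stop_removal"


def find_enabling_mutations(
    trio: CodingTrioAlignment, th: Thresholds | None = None
) -> list[EnablingMutation]:
    """Counterfactual scan for singly-sufficient human-specific mutations.

    For every alignment column (and every contiguous indel run) where the
    two outgroups share a state that differs from human, the ancestral state
    is substituted into the human row and the human ORF re-assessed; the
    mutation is enabling when the counterfactual ORF is disrupted under the
    intact-fraction rule.  'N' in either outgroup disqualifies a column;
    gap runs that only partially coincide between the outgroups are
    unpolarizable and skipped.
    """
    th = th or Thresholds()
    human = trio.rows["human"]
    chimp = trio.rows["chimp"]
    orang = trio.rows["orang"]
    base_rep = _human_anchored_report(trio)
    if not base_rep.complete:
        raise ValueError(f"{trio.gene_id}: human ORF not complete")

    out: list[EnablingMutation] = []
    n = trio.n_cols

    # substitution columns: all three bases present, outgroups identical
    for col in range(n):
        h, c, o = human[col], chimp[col], orang[col]
        if "-" in (h, c, o):
            continue
        if c != o or c == h or c == "N":
            continue
        cf_row = human[:col] + c + human[col + 1 :]
        if _counterfactual_disrupted(trio, cf_row, th):
            out.append(
                EnablingMutation(
                    column=col,
                    end_column=col + 1,
                    human_state=h,
                    ancestral_state=c,
                    effect=_classify_effect(trio, cf_row, None, th),
                )
            )

    # human-specific insertions: maximal runs gapped in BOTH outgroups; the
    # run must be a complete gap run in each outgroup (no partial overlap)
    col = 0
    while col < n:
        if chimp[col] == "-" and orang[col] == "-" and human[col] != "-":
            a = col
            while col < n and chimp[col] == "-" and orang[col] == "-" and human[col] != "-":
                col += 1
            b = col
            clean = (a == 0 or (chimp[a - 1] != "-" and orang[a - 1] != "-")) and (
                b == n or (chimp[b] != "-" and orang[b] != "-")
            )
            if clean:
                cf_row = human[:a] + "-" * (b - a) + human[b:]
                if _counterfactual_disrupted(trio, cf_row, th):
                    out.append(
                        EnablingMutation(
                            column=a,
                            end_column=b,
                            human_state=human[a:b],
                            ancestral_state="-" * (b - a),
                            effect=_classify_effect(trio, cf_row, b - a, th),
                        )
                    )
        else:
            col += 1

    # human-specific deletions: maximal human gap runs where both outgroups
    # carry identical ungapped bases across the entire run
    col = 0
    while col < n:
        if human[col] == "-":
            a = col
            while col < n and human[col] == "-":
                col += 1
            b = col
            anc_c = chimp[a:b]
            anc_o = orang[a:b]
            if "-" in anc_c or "-" in anc_o or anc_c != anc_o or "N" in anc_c:
                continue
            cf_row = human[:a] + anc_c + human[b:]
            if _counterfactual_disrupted(trio, cf_row, th):
                out.append(
                    EnablingMutation(
                        column=a,
                        end_column=b,
                        human_state="-" * (b - a),
                        ancestral_state=anc_c,
                        effect=_classify_effect(trio, cf_row, b - a, th),
                    )
                )
        else:
            col += 1

    out.sort(key=lambda m: (m.column, m.end_column))
    return out


def classify_candidate(
    trio: CodingTrioAlignment,
    ev: EvidenceRecord,
    th: Thresholds | None = None,
) -> CandidateVerdict:
    """Render the per-gene verdict through the fixed 7-stage ledger.

    Stages, in order: (1) complete anchored human ORF; (2) protein length
    at least min_protein_aa; (3) single copy in human and outgroups;
    (4) both outgroup orthologs disrupted; (5) at least one polarizable
    enabling mutation; (6) transcription evidence (mRNA or EST);
    (7) peptide evidence.  Evaluation short-circuits: stages after the
    first failure are recorded as skipped.  A disrupting SNP is noted
    (fixation caveat) but does not reject.
    """
    th = th or Thresholds()
    ledger: list[LedgerEntry] = []
    enabling: tuple[EnablingMutation, ...] = ()
    statuses: tuple = ()
    failed = False

    def record(stage: str, ok: bool, reason: str) -> bool:
        nonlocal failed
        if failed:
            ledger.append(LedgerEntry(stage, "skipped", "not evaluated"))
            return False
        ledger.append(LedgerEntry(stage, "pass" if ok else "fail", reason))
        if not ok:
            failed = True
        return ok

    rep = _human_anchored_report(trio)
    hmap = trio.human_map()
    annotated_stop = hmap.to_pos(trio.human_stop_col)
    ok = rep.complete and rep.stop_pos == annotated_stop
    record(
        "human_orf",
        ok,
        "complete ORF from annotated ATG to annotated stop"
        if ok
        else "human ORF not complete at the annotated anchors",
    )

    plen = trio.human_protein_len()
    record(
        "min_length",
        plen >= th.min_protein_aa,
        f"protein {plen} aa vs minimum {th.min_protein_aa}",
    )

    record(
        "single_copy",
        ev.single_copy_human and ev.single_copy_outgroups,
        "single copy in human and outgroups"
        if ev.single_copy_human and ev.single_copy_outgroups
        else "duplicated in human or outgroups",
    )

    if not failed:
        statuses = tuple(assess_ortholog(trio, t, th) for t in ("chimp", "orang"))
        both = all(s.status == "disrupted" for s in statuses)
        detail = ", ".join(f"{s.taxon}={s.status}" for s in statuses)
        record("outgroups_disrupted", both, detail)
    else:
        record("outgroups_disrupted", True, "")

    if not failed:
        enabling = tuple(find_enabling_mutations(trio, th))
        record(
            "enabling_mutation",
            len(enabling) > 0,
            f"{len(enabling)} singly-sufficient human-specific mutation(s)"
            if enabling
            else "no polarizable enabling mutation",
        )
    else:
        record("enabling_mutation", True, "")

    record(
        "transcription",
        ev.has_mrna or ev.has_est,
        "mRNA or EST hit" if (ev.has_mrna or ev.has_est) else "no mRNA/EST evidence",
    )
    record(
        "translation",
        ev.has_peptide,
        "peptide hit" if ev.has_peptide else "no supporting peptide evidence",
    )

    verdict = "rejected" if failed else "de_novo"
    note = (
        "segregating disrupting SNP: gene may not be fixed in the population"
        if ev.disrupting_snp
        else ""
    )
    return CandidateVerdict(
        gene_id=trio.gene_id,
        verdict=verdict,
        ledger=tuple(ledger),
        enabling=enabling,
        statuses=statuses,
        fixation_note=note,
    )
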