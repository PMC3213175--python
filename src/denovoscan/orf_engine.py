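"""Translation, ORF scanning, alternative-start rescue, and per-taxon
disruption assessment.

The authoritative disruption test is translation of the ortholog's own
ungapped sequence: an ortholog is *disrupted* when no acceptable start
yields a complete ORF, or when the completed ORF encodes less than the
intact fraction (default 80%) of the human protein.  Disruption *events*
(premature stops, frameshifting indels, missing start) are explanatory
annotations collected by comparing the ortholog to the human row in the
human codon frame; they never override the translation verdict.  This
unifies the three disruption kinds and resolves compensated-indel cases:
a +1/-1 indel pair that restores the frame without introducing a stop
leaves the ORF complete, and only the length fraction decides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from Bio.Seq import Seq

from .trio_model import (
    CodingTrioAlignment,
    STOP_CODONS,
    Thresholds,
    normalize_taxon,
    ungapped_map,
)

DisruptionKind = Literal["premature_stop", "frameshift_indel", "missing_start", "no_stop"]


@dataclass(frozen=True)
class OrfReport:
    """Outcome of translating one sequence from one (or the best) start."""

    start_pos: int | None
    stop_pos: int | None
    protein: str
    complete: bool
    length_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.complete:
            assert self.start_pos is not None and self.stop_pos is not None
            assert (self.stop_pos - self.start_pos) % 3 == 0
        assert "*" not in self.protein


@dataclass(frozen=True)
class DisruptionEvent:
    kind: DisruptionKind
    column: int
    detail: str = ""


@dataclass(frozen=True)
class OrthologStatus:
    taxon: str
    status: Literal["intact", "intact_enough", "disrupted"]
    events: tuple[DisruptionEvent, ...]
    orf: OrfReport


def _codon_to_aa(codon: str) -> str:
    """Translate one codon; any codon containing N yields 'X' and never
    counts as a stop."""
    if "N" in codon:
        return "X"
    if codon in STOP_CODONS:
        return "*"
    return str(Seq(codon).translate())


def translate_from(seq: str, start: int, human_protein_len: int | None = None) -> OrfReport:
    """Read codons from ``start`` until the first stop or the sequence end.

    ``complete`` is False when no stop codon is reached.  The length
    fraction is filled in when the human protein length is given.
    """
    if start > len(seq):
        raise ValueError(f"start {start} beyond sequence end {len(seq)}")
    aas: list[str] = []
    stop_pos: int | None = None
    for i in range(start, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aa = _codon_to_aa(codon)
        if aa == "*":
            stop_pos = i
            break
        aas.append(aa)
    protein = "".join(aas)
    complete = stop_pos is not None
    frac = 0.0
    if human_protein_len:
        frac = len(protein) / human_protein_len
    return OrfReport(
        start_pos=start,
        stop_pos=stop_pos,
        protein=protein,
        complete=complete,
        length_fraction=frac,
    )


def scan_orf(
    seq: str,
    anchor: int | None = None,
    policy: Literal["anchored", "rescue"] = "anchored",
    human_protein_len: int | None = None,
) -> OrfReport:
    """Find the ORF under the given start policy.

    anchored
        Translate from ``anchor`` only, and only if the sequence spells
        ATG there; otherwise the start is absent.
    rescue
        Alternative-start search over the whole provided region: among
        every ATG position (any frame, upstream or downstream), return
        the report maximizing protein length, ties to the 5'-most start.
    """
    if policy == "anchored":
        if anchor is None:
            raise ValueError("anchored policy requires an anchor")
        if seq[anchor : anchor + 3] == "ATG":
            return translate_from(seq, anchor, human_protein_len)
        frac = 0.0
        return OrfReport(start_pos=None, stop_pos=None, protein="", complete=False,
                         length_fraction=frac)
    best: OrfReport | None = None
    pos = seq.find("ATG")
    while pos != -1:
        rep = translate_from(seq, pos, human_protein_len)
        if best is None or len(rep.protein) > len(best.protein):
            best = rep
        pos = seq.find("ATG", pos + 1)
    if best is None:
        return OrfReport(start_pos=None, stop_pos=None, protein="", complete=False)
    return best


def _collect_events(
    trio: CodingTrioAlignment, taxon: str, orf: OrfReport
) -> list[DisruptionEvent]:
    """Annotate differences from the human row inside the human CDS span,
    read in the human codon frame."""
    human = trio.rows["human"]
    other = trio.rows[taxon]
    span_start, span_end = trio.human_cds_col_span()
    events: list[DisruptionEvent] = []

    # missing start: the taxon bases at the human start-codon columns
    start_cols = [
        c for c in range(trio.human_start_col, trio.n_cols) if human[c] != "-"
    ][:3]
    taxon_start = "".join(other[c] for c in start_cols)
    if taxon_start != "ATG":
        events.append(
            DisruptionEvent(
                kind="missing_start",
                column=trio.human_start_col,
                detail=f"taxon spells {taxon_start!r} at human start",
            )
        )

    # premature stops in the human codon frame
    cds_cols = [c for c in range(span_start, span_end) if human[c] != "-"]
    n_codons = len(cds_cols) // 3
    for k in range(n_codons - 1):  # exclude the human stop codon itself
        cols = cds_cols[3 * k : 3 * k + 3]
        codon = "".join(other[c] for c in cols)
        if codon in STOP_CODONS and "".join(human[c] for c in cols) not in STOP_CODONS:
            events.append(
                DisruptionEvent(
                    kind="premature_stop",
                    column=cols[0],
                    detail=f"codon {codon} at human codon {k}",
                )
            )

    # indels inside the CDS span with length not divisible by 3
    for gap_row, base_row, sign in ((other, human, "deletion"), (human, other, "insertion")):
        col = span_start
        while col < span_end:
            if gap_row[col] == "-" and base_row[col] != "-":
                run_start = col
                while col < span_end and gap_row[col] == "-" and base_row[col] != "-":
                    col += 1
                run_len = col - run_start
                if run_len % 3 != 0:
                    events.append(
                        DisruptionEvent(
                            kind="frameshift_indel",
                            column=run_start,
                            detail=f"{run_len}-nt {sign} in taxon",
                        )
                    )
            else:
                col += 1

    if orf.start_pos is not None and not orf.complete:
        events.append(
            DisruptionEvent(
                kind="no_stop",
                column=span_end - 1,
                detail="ORF runs off the provided region",
            )
        )
    events.sort(key=lambda e: (e.column, e.kind))
    return events


def assess_ortholog(
    trio: CodingTrioAlignment, taxon: str, th: Thresholds | None = None
) -> OrthologStatus:
    """Assess whether one outgroup ortholog is disrupted.

    Translation is anchored at the column-mapped human start; when the
    ortholog lacks an ATG there, the alternative-start rescue searches the
    entire provided region.  The final status follows the ORF report:
    disrupted iff the ORF is incomplete or encodes < intact_fraction of the
    human protein; a complete ORF at or above the fraction with recorded
    events is intact_enough (such genes are later discarded as candidates);
    intact otherwise.
    """
    th = th or Thresholds()
    taxon = normalize_taxon(taxon)
    if taxon == "human":
        raise ValueError("assess_ortholog applies to the outgroup taxa only")
    row = trio.rows[taxon]
    span_start, span_end = trio.human_cds_col_span()
    if all(c == "-" for c in row[span_start:span_end]):
        raise ValueError(f"{trio.gene_id}/{taxon}: ortholog region absent")

    seq = row.replace("-", "")
    tmap = ungapped_map(row)
    human_len = trio.human_protein_len()

    anchor = tmap.to_pos(trio.human_start_col)
    orf: OrfReport | None = None
    if anchor is not None:
        orf = scan_orf(seq, anchor=anchor, policy="anchored", human_protein_len=human_len)
    if orf is None or orf.start_pos is None:
        orf = scan_orf(seq, policy="rescue", human_protein_len=human_len)

    events = tuple(_collect_events(trio, taxon, orf))
    if not orf.complete or orf.length_fraction < th.intact_fraction:
        status = "disrupted"
    elif events:
        status = "intact_enough"
    else:
        status = "intact"
    return OrthologStatus(taxon=taxon, status=status, events=events, orf=orf)
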