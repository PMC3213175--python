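"""Batch screen orchestration, the stage-count ledger report, and the
birth-rate arithmetic.

The screen applies the 7-stage candidate classifier to every trio and
aggregates a per-stage filter ledger (entered/passed/failed, where a
stage's entered count equals the previous stage's passed count).  The
birth-rate helper turns a count of fixed de novo genes and a divergence
window into genes-per-million-years and per-gene rates, at the printed
precision conventions (3 significant figures per lineage, 2 per gene).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .polarity import STAGES, CandidateVerdict, classify_candidate
from .trio_model import CodingTrioAlignment, EvidenceRecord, Thresholds


@dataclass(frozen=True)
class StageCount:
    entered: int
    passed: int
    failed: int


@dataclass(frozen=True)
class ScreenReport:
    stage_counts: Mapping[str, StageCount]
    verdicts: tuple[CandidateVerdict, ...]
    thresholds: Thresholds
    input_digest: str

    @property
    def n_de_novo(self) -> int:
        return sum(v.verdict == "de_novo" for v in self.verdicts)


def _digest(trios: Sequence[CodingTrioAlignment], evidence: Mapping[str, EvidenceRecord]) -> str:
    h = hashlib.sha256()
    for trio in sorted(trios, key=lambda t: t.gene_id):
        h.update(trio.gene_id.encode())
        for taxon in ("human", "chimp", "orang"):
            h.update(trio.rows[taxon].encode())
        h.update(f"{trio.human_start_col},{trio.human_stop_col}".encode())
        ev = evidence[trio.gene_id]
        h.update(repr(ev).encode())
    return h.hexdigest()


def run_candidate_screen(
    trios: Sequence[CodingTrioAlignment],
    evidence: Mapping[str, EvidenceRecord] | Sequence[EvidenceRecord],
    th: Thresholds | None = None,
) -> ScreenReport:
    """Classify every gene and aggregate the per-stage filter ledger.

    Output ordering is deterministic (by gene_id).  Trio/evidence key
    mismatches are listed exhaustively before aborting.
    """
    th = th or Thresholds()
    if not isinstance(evidence, Mapping):
        evidence = {e.gene_id: e for e in evidence}
    trio_ids = {t.gene_id for t in trios}
    missing_ev = sorted(trio_ids - set(evidence))
    orphan_ev = sorted(set(evidence) - trio_ids)
    if missing_ev or orphan_ev:
        raise KeyError(
            "trio/evidence mismatch: "
            f"trios without evidence: {missing_ev}; "
            f"evidence without trios: {orphan_ev}"
        )
    verdicts = tuple(
        classify_candidate(trio, evidence[trio.gene_id], th)
        for trio in sorted(trios, key=lambda t: t.gene_id)
    )
    counts: dict[str, StageCount] = {}
    for stage in STAGES:
        entered = passed = failed = 0
        for v in verdicts:
            entry = next(e for e in v.ledger if e.stage == stage)
            if entry.result == "skipped":
                continue
            entered += 1
            if entry.result == "pass":
                passed += 1
            else:
                failed += 1
        counts[stage] = StageCount(entered=entered, passed=passed, failed=failed)
    return ScreenReport(
        stage_counts=counts,
        verdicts=verdicts,
        thresholds=th,
        input_digest=_digest(trios, evidence),
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def compute_birth_rate(
    n_fixed_genes: int,
    t_low: float,
    t_high: float,
    n_genome_genes: int | None = None,
) -> tuple[float, float, float | None, float | None]:
    """De novo gene birth rate from a fixed-gene count and divergence window.

    With ``n`` fixed genes born since a split ``t_low``–``t_high`` million
    years ago, the lineage rate range is (n/t_high, n/t_low) genes/Myr,
    reported to 3 significant figures.  Dividing by the genome gene count
    gives the per-gene rate, reported to 2 significant figures.
    """
    if n_fixed_genes < 0:
        raise ValueError("n_fixed_genes must be >= 0")
    if not 0 < t_low <= t_high:
        raise ValueError("need 0 < t_low <= t_high")
    rate_low = _round_sig(n_fixed_genes / t_high, 3)
    rate_high = _round_sig(n_fixed_genes / t_low, 3)
    per_low = per_high = None
    if n_genome_genes is not None:
        if n_genome_genes <= 0:
            raise ValueError("n_genome_genes must be positive")
        per_low = _round_sig(n_fixed_genes / (t_high * n_genome_genes), 2)
        per_high = _round_sig(n_fixed_genes / (t_low * n_genome_genes), 2)
    return rate_low, rate_high, per_low, per_high


# -- serialization -----------------------------------------------------------


def verdict_to_dict(v: CandidateVerdict) -> dict:
    return {
        "gene_id": v.gene_id,
        "verdict": v.verdict,
        "ledger": [
            {"stage": e.stage, "result": e.result, "reason": e.reason} for e in v.ledger
        ],
        "enabling_mutations": [
            {
                "column": m.column,
                "end_column": m.end_column,
                "human_state": m.human_state,
                "ancestral_state": m.ancestral_state,
                "effect": m.effect,
            }
            for m in v.enabling
        ],
        "ortholog_status": {s.taxon: s.status for s in v.statuses},
        "fixation_note": v.fixation_note,
    }


def report_to_json(report: ScreenReport) -> str:
    """Byte-stable JSON serialization of a screen report."""
    payload = {
        "stage_counts": {
            s: {"entered": c.entered, "passed": c.passed, "failed": c.failed}
            for s, c in report.stage_counts.items()
        },
        "n_de_novo": report.n_de_novo,
        "genes": [verdict_to_dict(v) for v in report.verdicts],
        "thresholds": {
            k: getattr(report.thresholds, k)
            for k in (
                "min_protein_aa",
                "intact_fraction",
                "qc_window_aa",
                "qc_max_similarity",
                "max_lineage_rate",
                "norm_scale",
                "divergence_my_low",
                "divergence_my_high",
            )
        },
        "input_digest": report.input_digest,
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"


def write_report_tsv(report: ScreenReport, path) -> None:
    """Flat per-gene summary: gene_id, verdict, failing stage, mutations."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "verdict", "failing_stage", "n_enabling", "effects"])
        for v in report.verdicts:
            w.writerow(
                [
                    v.gene_id,
                    v.verdict,
                    v.failing_stage() or "",
                    len(v.enabling),
                    ",".join(m.effect for m in v.enabling),
                ]
            )
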