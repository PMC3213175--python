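"""Ortholog-pair prefilters and the sliding-window alignment quality filter.

Badly aligned or non-orthologous regions inflate apparent divergence, so
ortholog pairs are screened before rate estimation: ambiguous residues and
short alignments are dropped, and a 5-aa sliding window (step one codon)
discards pairs containing any window with identity at or below 20%.
"Similarity" here is exact amino-acid identity — no substitution matrix —
and gaps inside a window count as mismatches.

A small global aligner with affine gap costs (Gotoh dynamic programming,
deterministic tie-breaking) is included for desk-scale pairwise alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .trio_model import Thresholds


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0  # cost of a length-1 gap
    gap_extend: float = -1.0  # each additional gapped position


@dataclass(frozen=True)
class AlignedPair:
    a: str
    b: str
    score: float


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reason: str = ""
    failing_window: int | None = None


# DP state indices; the order encodes the tie-break priority:
# diagonal (match/mismatch) beats a gap in b, which beats a gap in a.
_M, _X, _Y = 0, 1, 2


def align_pair(a: str, b: str, scoring: Scoring | None = None) -> AlignedPair:
    """Optimal global alignment of ``a`` and ``b`` with affine gap costs.

    Gotoh three-state dynamic programming.  A gap of length L costs
    ``gap_open + (L-1) * gap_extend``.  Ties are broken deterministically:
    prefer a match/mismatch step over opening a gap, and a gap in ``b``
    (consuming a base of ``a``) over a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("align_pair requires nonempty sequences")
    sc = scoring or Scoring()
    n, m = len(a), len(b)
    NEG = -np.inf
    # S[state, i, j]: best score of aligning a[:i], b[:j] ending in state
    S = np.full((3, n + 1, m + 1), NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)  # previous state
    S[_M, 0, 0] = 0.0
    for i in range(1, n + 1):
        S[_X, i, 0] = sc.gap_open + (i - 1) * sc.gap_extend
        ptr[_X, i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        S[_Y, 0, j] = sc.gap_open + (j - 1) * sc.gap_extend
        ptr[_Y, 0, j] = _Y if j > 1 else _M

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = sc.match if ai == b[j - 1] else sc.mismatch
            # diagonal: from any state at (i-1, j-1); tie-break by state order
            cand = S[:, i - 1, j - 1]
            k = int(np.argmax(cand))  # argmax returns first max: M > X > Y
            S[_M, i, j] = cand[k] + sub
            ptr[_M, i, j] = k
            # gap in b (consume a[i-1]): extend X or open from M/Y at (i-1, j)
            open_from = S[[_M, _Y], i - 1, j] + sc.gap_open
            ext = S[_X, i - 1, j] + sc.gap_extend
            choices = np.array([open_from[0], ext, open_from[1]])  # M, X, Y order
            k = int(np.argmax(choices))
            S[_X, i, j] = choices[k]
            ptr[_X, i, j] = (_M, _X, _Y)[k]
            # gap in a (consume b[j-1])
            open_from = S[[_M, _X], i, j - 1] + sc.gap_open
            ext = S[_Y, i, j - 1] + sc.gap_extend
            choices = np.array([open_from[0], open_from[1], ext])
            k = int(np.argmax(choices))
            S[_Y, i, j] = choices[k]
            ptr[_Y, i, j] = (_M, _X, _Y)[k]

    final = S[:, n, m]
    state = int(np.argmax(final))
    score = float(final[state])
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == _M:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == _X:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        state = prev
    return AlignedPair(a="".join(reversed(out_a)), b="".join(reversed(out_b)), score=score)


def window_similarity_filter(
    pa: str, pb: str, th: Thresholds | None = None
) -> QCResult:
    """Scan aligned protein strings with a fixed-width identity window.

    Windows run over aligned columns with step 1; identity is the fraction
    of positions with identical amino acids (a gap against anything is
    non-identical).  The pair fails at the first window whose identity is
    at or below ``qc_max_similarity``.
    """
    th = th or Thresholds()
    w = th.qc_window_aa
    if len(pa) != len(pb):
        raise ValueError("aligned protein strings must have equal length")
    if len(pa) < w:
        raise ValueError(f"alignment shorter than the {w}-aa window")
    ident = np.fromiter(
        (x == y and x != "-" for x, y in zip(pa, pb)), dtype=float, count=len(pa)
    )
    kernel = np.ones(w)
    sims = np.convolve(ident, kernel, mode="valid") / w
    failing = np.nonzero(sims <= th.qc_max_similarity + 1e-12)[0]
    if failing.size:
        k = int(failing[0])
        return QCResult(
            passed=False,
            reason=f"window identity {sims[k]:.2f} <= {th.qc_max_similarity:.2f}",
            failing_window=k,
        )
    return QCResult(passed=True)


@dataclass(frozen=True)
class IsoformRecord:
    """One isoform's aligned ortholog pair, as metadata for prefiltering."""

    gene_id: str
    isoform_id: str
    protein_a: str
    protein_b: str
    alignment_len: int  # aligned length in aa


def prefilter_ortholog_pair(
    records: Sequence[IsoformRecord], th: Thresholds | None = None
) -> dict[str, QCResult]:
    """Per-gene isoform prefilters applied before the window scan.

    Pairs whose proteins contain 'X' are excluded; among a gene's surviving
    isoforms only the longest alignment is retained (ties to the first in
    input order); retained alignments shorter than ``min_protein_aa`` are
    dropped.
    """
    th = th or Thresholds()
    results: dict[str, QCResult] = {}
    survivors: dict[str, list[IsoformRecord]] = {}
    for rec in records:
        if "X" in rec.protein_a or "X" in rec.protein_b:
            results[rec.isoform_id] = QCResult(passed=False, reason="ambiguous residue")
        else:
            survivors.setdefault(rec.gene_id, []).append(rec)
    for gene, recs in survivors.items():
        best = max(recs, key=lambda r: r.alignment_len)
        for rec in recs:
            if rec is not best:
                results[rec.isoform_id] = QCResult(
                    passed=False, reason="superseded by longer isoform alignment"
                )
            elif rec.alignment_len < th.min_protein_aa:
                results[rec.isoform_id] = QCResult(
                    passed=False, reason=f"alignment <{th.min_protein_aa} aa"
                )
            else:
                results[rec.isoform_id] = QCResult(passed=True)
    return results


def write_qc_report(results: dict[str, dict[str, QCResult]], path) -> None:
    """QC report TSV: gene_id, stage, passed, reason, failing_window."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "stage", "passed", "reason", "failing_window"])
        for gene_id, stages in sorted(results.items()):
            for stage, res in stages.items():
                w.writerow(
                    [
                        gene_id,
                        stage,
                        int(res.passed),
                        res.reason,
                        "" if res.failing_window is None else res.failing_window,
                    ]
                )
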