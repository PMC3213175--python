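"""Synthetic inputs with known ground truth.

Three generators cover everything the screen consumes:

* labeled trio scenarios — alignments with planted disabling/enabling
  mutations of each class (stop removal, start creation, frame completion)
  and the confounds the polarization step must reject (parallel loss,
  ancestrally intact orthologs, alternative-start rescue, an 85%-length
  truncation, a gain shared by human and chimp);
* HKY85-evolved trio alignments with known branch lengths, kappa, base
  frequencies and optional indels (true alignment retained);
* Poisson read counts per gene x tissue with tissue-specific means and
  library sizes, optionally rendered as BED-like unique-read placements.

All generators are pure functions of (spec, seed): a single explicitly
seeded pseudo-random stream per call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lineage_rates import hky_rate_matrix
from .trio_model import (
    CodingTrioAlignment,
    EvidenceRecord,
    STOP_CODONS,
    Thresholds,
)

#: The 11-tissue panel used throughout the fixtures.
TISSUES = (
    "adipose",
    "whole_brain",
    "cerebral_cortex",
    "breast",
    "colon",
    "heart",
    "liver",
    "lymph_node",
    "skeletal_muscle",
    "lung",
    "testes",
)

SCENARIO_KINDS = (
    "de_novo_stop_removal",
    "de_novo_start_creation",
    "de_novo_frame_completion",
    "parallel_loss",
    "ancestrally_intact",
    "alt_start_rescue",
    "intact_enough_85pct",
    "shared_human_chimp_gain",
)

_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)


class ScenarioError(ValueError):
    """The requested scenario cannot be satisfied at the given size."""


@dataclass(frozen=True)
class ScenarioLabel:
    verdict: str  # de_novo | rejected
    failing_stage: str | None  # None for de_novo


@dataclass(frozen=True)
class ScenarioSpec:
    kind: str
    n_codons: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ScenarioError(f"unknown scenario kind {self.kind!r}")
        if self.n_codons < 20:
            raise ScenarioError("n_codons must be >= 20")


def _atg_free(seq: str) -> bool:
    return "ATG" not in seq


def _random_codon_seq(rng: np.random.Generator, n_codons: int, forced: Mapping[int, str]) -> list[str]:
    """Sample non-stop, non-ATG codons, rejecting any that create an ATG
    substring across a codon junction; ``forced`` pins specific codons.

    The virtual tail before the first codon is 'A': the start codon's last
    base may mutate to A in a scenario, and the body must stay ATG-free
    under that change too.
    """
    codons: list[str] = []
    for k in range(n_codons):
        if k in forced:
            codons.append(forced[k])
            continue
        prev_tail = codons[-1][-2:] if codons else "A"
        next_head = forced[k + 1][:2] if (k + 1) in forced else ""
        for _ in range(200):
            cand = _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
            if _atg_free(prev_tail + cand + next_head):
                codons.append(cand)
                break
        else:  # pragma: no cover - 61-codon alphabet cannot exhaust
            raise ScenarioError("could not sample an ATG-free codon")
    return codons


def _random_flank(rng: np.random.Generator, n: int, right_of: str = "") -> str:
    """ATG-free flank that also keeps the junction with ``right_of`` clean."""
    out = ""
    for _ in range(n):
        for _ in range(100):
            b = _BASES[rng.integers(4)]
            if _atg_free((right_of + out + b)[-3:]):
                out += b
                break
    return out


def generate_trio_scenario(
    spec: ScenarioSpec, th: Thresholds | None = None, self_check: bool = True
) -> tuple[CodingTrioAlignment, EvidenceRecord, ScenarioLabel]:
    """Construct one labeled trio scenario.

    An ancestral coding sequence is built (ATG start, non-stop ATG-free
    body, TAA stop, short ATG-free flanks), the scenario's defining
    mutations are planted, and evidence flags are set favorably so the
    sequence stages alone decide the verdict.  The emitted trio is run
    through the classifier and must reproduce its label (hard failure
    otherwise).
    """
    from .polarity import classify_candidate  # deferred: avoids import cycle

    th = th or Thresholds()
    n = spec.n_codons
    if n < th.min_protein_aa:
        raise ScenarioError(
            f"scenario kinds are labeled beyond the length stage; need "
            f"n_codons >= {th.min_protein_aa}, got {n}"
        )
    rng = np.random.default_rng(spec.seed)
    kind = spec.kind

    # codon index for an early disruption: fraction k/n safely below 0.80
    k_early = int(rng.integers(max(1, n // 6), max(2, int(0.70 * n))))
    forced: dict[int, str] = {k_early: "TGG"}
    insert_at = None
    alt_start_at = None
    k_late = None
    k_early2 = None

    if kind == "de_novo_frame_completion":
        insert_at = int(rng.integers(max(1, n // 6), max(2, int(0.70 * n))))
        forced[insert_at] = "AAA"  # a 'T' inserted before it spells TAA in the shifted frame
    elif kind == "alt_start_rescue":
        alt_start_at = max(1, int(0.10 * n))
        forced[alt_start_at] = "ATG"
    elif kind == "intact_enough_85pct":
        k_late = min(n - 1, int(round(0.85 * n)))
        if k_late / n < th.intact_fraction:
            raise ScenarioError("80% boundary placement impossible at this n_codons")
        forced[k_late] = "TGG"
    elif kind == "parallel_loss":
        k_early2 = int(rng.integers(max(2, int(0.70 * n)), max(3, int(0.78 * n))))
        if k_early2 <= k_early:
            k_early2 = k_early + 1
        forced[k_early2] = "CAA"

    body = _random_codon_seq(rng, n - 1, {k - 1: v for k, v in forced.items() if k >= 1})
    cds = "ATG" + "".join(body) + "TAA"
    left = _random_flank(rng, 9)
    right = _random_flank(rng, 9, right_of=cds[-2:])
    human = left + cds + right
    start_col = len(left)
    stop_col = len(left) + 3 * n

    def at_codon(k: int) -> int:  # column of the first base of codon k
        return start_col + 3 * k

    chimp = human
    orang = human

    def subst(row: str, col: int, base: str) -> str:
        return row[: col] + base + row[col + 1 :]

    if kind == "de_novo_stop_removal":
        col = at_codon(k_early) + 2  # TGG -> TGA
        chimp = subst(chimp, col, "A")
        orang = subst(orang, col, "A")
        label = ScenarioLabel("de_novo", None)
    elif kind == "de_novo_start_creation":
        col = start_col + 2  # ATG -> ATA
        chimp = subst(chimp, col, "A")
        orang = subst(orang, col, "A")
        label = ScenarioLabel("de_novo", None)
    elif kind == "de_novo_frame_completion":
        col = at_codon(insert_at)  # ancestral 1-nt insertion before an AAA codon
        human = human[:col] + "-" + human[col:]
        chimp = chimp[:col] + "T" + chimp[col:]
        orang = orang[:col] + "T" + orang[col:]
        stop_col += 1
        label = ScenarioLabel("de_novo", None)
    elif kind == "parallel_loss":
        chimp = subst(chimp, at_codon(k_early) + 2, "A")  # TGG -> TGA
        orang = subst(orang, at_codon(k_early2), "T")  # CAA -> TAA
        label = ScenarioLabel("rejected", "enabling_mutation")
    elif kind == "ancestrally_intact":
        label = ScenarioLabel("rejected", "outgroups_disrupted")
    elif kind == "alt_start_rescue":
        col = start_col + 2
        chimp = subst(chimp, col, "A")
        orang = subst(orang, col, "A")
        label = ScenarioLabel("rejected", "outgroups_disrupted")
    elif kind == "intact_enough_85pct":
        col = at_codon(k_late) + 2
        chimp = subst(chimp, col, "A")
        orang = subst(orang, col, "A")
        label = ScenarioLabel("rejected", "outgroups_disrupted")
    elif kind == "shared_human_chimp_gain":
        orang = subst(orang, at_codon(k_early) + 2, "A")  # only the outgroup disrupted
        label = ScenarioLabel("rejected", "outgroups_disrupted")
    else:  # pragma: no cover
        raise ScenarioError(kind)

    gene_id = f"{kind}_s{spec.seed}"
    trio = CodingTrioAlignment(
        gene_id=gene_id,
        rows={"human": human, "chimp": chimp, "orang": orang},
        human_start_col=start_col,
        human_stop_col=stop_col,
    )
    evidence = EvidenceRecord(
        gene_id=gene_id,
        has_mrna=True,
        has_est=True,
        has_peptide=True,
        single_copy_human=True,
        single_copy_outgroups=True,
        disrupting_snp=False,
    )
    if self_check:
        verdict = classify_candidate(trio, evidence, th)
        got = (verdict.verdict, verdict.failing_stage())
        want = (label.verdict, label.failing_stage)
        if got != want:
            raise ScenarioError(
                f"generator self-check failed for {gene_id}: expected {want}, got {got}"
            )
    return trio, evidence, label


# -- HKY85 forward simulation ------------------------------------------------


@dataclass(frozen=True)
class EvolveParams:
    t_human: float = 0.02
    t_chimp: float = 0.03
    t_orang: float = 0.05
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    indel_rate: float = 0.0  # events per site per lineage
    indel_len_dist: float = 0.5  # geometric parameter
    length_nt: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.t_human, self.t_chimp, self.t_orang) < 0:
            raise ValueError("branch lengths must be >= 0")
        if any(f <= 0 for f in self.base_freqs):
            raise ValueError("degenerate base frequencies (zero entry)")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.length_nt < 300:
            raise ValueError("length_nt must be >= 300")


def _evolve_branch(
    anc: np.ndarray, t: float, kappa: float, pi: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    from scipy.linalg import expm

    P = expm(hky_rate_matrix(kappa, pi) * t)
    child = np.empty_like(anc)
    for x in range(4):
        idx = np.nonzero(anc == x)[0]
        if idx.size:
            child[idx] = rng.choice(4, size=idx.size, p=P[x] / P[x].sum())
    return child


def simulate_hky85(params: EvolveParams) -> tuple[dict[str, str], dict]:
    """Evolve an ancestral sequence independently along the three branches.

    Returns the (true) gapped alignment rows and a truth record with the
    branch lengths, kappa and base frequencies used.  Indels, when enabled,
    are planted per lineage after substitution; the true alignment is kept
    by construction (inserted columns are gaps in the other rows).
    """
    rng = np.random.default_rng(params.seed)
    pi = np.asarray(params.base_freqs, dtype=float)
    anc = rng.choice(4, size=params.length_nt, p=pi)
    branches = {
        "human": params.t_human,
        "chimp": params.t_chimp,
        "orang": params.t_orang,
    }
    seqs = {
        taxon: _evolve_branch(anc, t, params.kappa, pi, rng)
        for taxon, t in branches.items()
    }
    rows = {t: "".join(_BASES[i] for i in s) for t, s in seqs.items()}

    if params.indel_rate > 0:
        cols: list[dict[str, str]] = [
            {t: rows[t][i] for t in rows} for i in range(params.length_nt)
        ]
        for taxon in branches:
            n_events = rng.poisson(params.indel_rate * params.length_nt)
            for _ in range(n_events):
                length = int(rng.geometric(params.indel_len_dist))
                pos = int(rng.integers(0, len(cols)))
                if rng.random() < 0.5:  # deletion in this lineage
                    deleted = 0
                    j = pos
                    while j < len(cols) and deleted < length:
                        if cols[j][taxon] != "-":
                            cols[j] = {**cols[j], taxon: "-"}
                            deleted += 1
                        j += 1
                else:  # insertion: new columns, gaps in the other rows
                    new = [
                        {t: ("-" if t != taxon else _BASES[rng.integers(4)]) for t in rows}
                        for _ in range(length)
                    ]
                    cols[pos:pos] = new
        rows = {t: "".join(c[t] for c in cols) for t in rows}

    truth = {
        "t_human": params.t_human,
        "t_chimp": params.t_chimp,
        "t_orang": params.t_orang,
        "kappa": params.kappa,
        "base_freqs": list(params.base_freqs),
        "length_nt": params.length_nt,
        "seed": params.seed,
    }
    return rows, truth


# -- expression counts -------------------------------------------------------


def simulate_expression(
    n_genes: int,
    tissues: Sequence[str],
    mean_matrix: np.ndarray | pd.DataFrame,
    libsizes: Mapping[str, float] | pd.Series,
    seed: int = 0,
    lengths: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Draw Poisson unique-read counts at the given per-cell means.

    Returns (counts, lengths, libsizes, truth_means) with genes named
    ``g0001`` ... in order.  Coding lengths default to 300 nt.
    """
    genes = [f"g{i+1:04d}" for i in range(n_genes)]
    means = pd.DataFrame(np.asarray(mean_matrix, dtype=float), index=genes, columns=list(tissues))
    if (means.values < 0).any():
        raise ValueError("means must be nonnegative")
    lib = pd.Series(libsizes, dtype=float).reindex(list(tissues))
    if lib.isna().any():
        raise ValueError("library size missing for some tissue")
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        rng.poisson(means.values), index=genes, columns=list(tissues)
    )
    if lengths is None:
        lens = pd.Series(300.0, index=genes)
    else:
        lens = pd.Series(lengths, dtype=float).reindex(genes)
    return counts, lens, lib, means


def expression_to_bed(
    counts: pd.Series,
    cds_intervals: Mapping[str, tuple[str, int, int]],
    seed: int = 0,
    read_len: int = 50,
    multi_fraction: float = 0.1,
) -> list:
    """Render one tissue's per-gene counts as BED-like read placements.

    Emits exactly ``counts[g]`` unique reads overlapping each gene's CDS
    plus a fraction of multi-mapped decoys that must not be counted.
    """
    from .expression_stats import ReadPlacement

    rng = np.random.default_rng(seed)
    placements = []
    for gene, c in counts.items():
        chrom, start, end = cds_intervals[gene]
        span = max(1, end - start)
        for _ in range(int(c)):
            s = int(start + rng.integers(0, span))
            placements.append(ReadPlacement(chrom, s, s + read_len, unique=True))
        for _ in range(rng.poisson(multi_fraction * max(int(c), 1))):
            s = int(start + rng.integers(0, span))
            placements.append(ReadPlacement(chrom, s, s + read_len, unique=False))
    return placements


def default_scenario_batch(
    n_per_kind: int, base_seed: int = 0, n_codons: int = 150
) -> list[tuple[CodingTrioAlignment, EvidenceRecord, ScenarioLabel]]:
    """A balanced labeled batch across all scenario kinds."""
    out = []
    for i, kind in enumerate(SCENARIO_KINDS):
        for j in range(n_per_kind):
            spec = ScenarioSpec(kind=kind, n_codons=n_codons, seed=base_seed + 1000 * i + j)
            out.append(generate_trio_scenario(spec))
    return out
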