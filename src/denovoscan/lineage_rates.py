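"""Lineage-specific substitution rates from three-taxon HKY85 fits.

For each gene the human/chimp/orangutan alignment is fit by maximum
likelihood under the HKY85 substitution model (unequal base frequencies
pi, transition/transversion rate ratio kappa) on the single unrooted
3-taxon star tree.  The three terminal branch lengths, in substitutions
per site, are the lineage-specific rates; with orangutan as outgroup,
t_human and t_chimp measure evolution since the human-chimp split (the
orangutan branch absorbs the outgroup path).

Base frequencies are empirical (counted from the alignment), not
ML-optimized.  Columns containing gaps or N in any row are excluded.
Genes with a human or chimp rate above a cutoff (default 0.1) are dropped
from summaries as likely alignment artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .trio_model import TAXA, Thresholds

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
# transitions: A<->G, C<->T
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _i, _j in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _TRANSITION[_i, _j] = True


class RateFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class RateEstimate:
    gene_id: str
    t_human: float
    t_chimp: float
    t_orang: float
    kappa: float
    base_freqs: tuple[float, float, float, float]
    loglik: float
    n_sites: int

    def __post_init__(self) -> None:
        assert min(self.t_human, self.t_chimp, self.t_orang) >= 0
        assert self.kappa > 0
        assert abs(sum(self.base_freqs) - 1.0) < 1e-9


def hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 generator scaled to one expected substitution per site per
    unit branch length."""
    Q = np.tile(pi, (4, 1)).astype(float)
    Q[_TRANSITION] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    if mu <= 0:
        raise RateFitError("degenerate base frequencies")
    return Q / mu


def _pattern_counts(rows: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """Collapse usable columns to (pattern index, count); gap/N columns drop."""
    arrs = []
    for row in rows:
        a = np.frombuffer(row.upper().encode(), dtype=np.uint8)
        code = np.full(a.shape, -1, dtype=np.int8)
        for b, i in _BASE_INDEX.items():
            code[a == ord(b)] = i
        arrs.append(code)
    mat = np.vstack(arrs)
    ok = (mat >= 0).all(axis=0)
    mat = mat[:, ok].astype(np.int64)
    idx = mat[0] * 16 + mat[1] * 4 + mat[2]
    patterns, counts = np.unique(idx, return_counts=True)
    return patterns, counts, int(ok.sum())


def _neg_loglik(
    params: np.ndarray,
    patterns: np.ndarray,
    counts: np.ndarray,
    pi: np.ndarray,
    fixed_kappa: float | None,
) -> float:
    th, tc, to = params[:3]
    kappa = fixed_kappa if fixed_kappa is not None else params[3]
    Q = hky_rate_matrix(kappa, pi)
    Ph, Pc, Po = expm(Q * th), expm(Q * tc), expm(Q * to)
    # joint[a,b,c] = sum_x pi_x Ph[x,a] Pc[x,b] Po[x,c]
    joint = np.einsum("x,xa,xb,xc->abc", pi, Ph, Pc, Po).reshape(64)
    probs = np.clip(joint[patterns], 1e-300, None)
    return -float(np.dot(counts, np.log(probs)))


def fit_hky85_trio(
    alignment: Mapping[str, str],
    init: tuple[float, float, float, float] | None = None,
    tol: float = 1e-8,
    min_sites: int = 50,
    fix_kappa: float | None = None,
    equal_freqs: bool = False,
    gene_id: str = "",
    max_iter: int = 500,
) -> RateEstimate:
    """Maximum-likelihood HKY85 fit on the unrooted 3-taxon star.

    ``alignment`` maps taxon (human/chimp/orang) to equal-length rows;
    columns with gaps or N in any row are excluded.  Optimizes
    (t_human, t_chimp, t_orang, kappa) by bounded quasi-Newton from
    t=0.01, kappa=2 with t in [0, 2] and kappa in [0.05, 100];
    ``fix_kappa`` pins kappa (e.g. 1.0 for the Jukes-Cantor limit) and
    ``equal_freqs`` forces uniform base frequencies.
    """
    rows = [alignment[t] for t in TAXA]
    if len({len(r) for r in rows}) != 1:
        raise RateFitError(f"{gene_id}: unequal alignment lengths")
    patterns, counts, n_sites = _pattern_counts(rows)
    if n_sites < min_sites:
        raise RateFitError(
            f"{gene_id}: only {n_sites} usable columns, need >= {min_sites}"
        )
    if equal_freqs:
        pi = np.full(4, 0.25)
    else:
        base_counts = np.zeros(4)
        for p, c in zip(patterns, counts):
            base_counts[p // 16] += c
            base_counts[(p // 4) % 4] += c
            base_counts[p % 4] += c
        # tiny floor keeps the generator well-defined when a base is absent
        base_counts = np.maximum(base_counts, 1e-9)
        pi = base_counts / base_counts.sum()

    x0 = np.array(init) if init is not None else np.array([0.01, 0.01, 0.01, 2.0])
    bounds = [(0.0, 2.0)] * 3 + [(0.05, 100.0)]
    if fix_kappa is not None:
        x0 = x0[:3]
        bounds = bounds[:3]
    res = minimize(
        _neg_loglik,
        x0,
        args=(patterns, counts, pi, fix_kappa),
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": tol, "maxiter": max_iter},
    )
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise RateFitError(f"{gene_id}: optimizer failed: {res.message}")
    th_, tc_, to_ = (float(v) for v in res.x[:3])
    kappa = float(fix_kappa if fix_kappa is not None else res.x[3])
    return RateEstimate(
        gene_id=gene_id,
        t_human=th_,
        t_chimp=tc_,
        t_orang=to_,
        kappa=kappa,
        base_freqs=tuple(float(v) for v in pi),
        loglik=-float(res.fun),
        n_sites=n_sites,
    )


def loglik_at(
    alignment: Mapping[str, str],
    t: tuple[float, float, float],
    kappa: float,
    equal_freqs: bool = False,
) -> float:
    """Log-likelihood at explicit parameter values (no optimization)."""
    rows = [alignment[tx] for tx in TAXA]
    patterns, counts, _ = _pattern_counts(rows)
    if equal_freqs:
        pi = np.full(4, 0.25)
    else:
        base_counts = np.zeros(4)
        for p, c in zip(patterns, counts):
            base_counts[p // 16] += c
            base_counts[(p // 4) % 4] += c
            base_counts[p % 4] += c
        base_counts = np.maximum(base_counts, 1e-9)
        pi = base_counts / base_counts.sum()
    return -_neg_loglik(np.array([*t, kappa]), patterns, counts, pi, None)


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance -(3/4) ln(1 - (4/3) p) over gap-free columns."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    pairs = [
        (x, y)
        for x, y in zip(a.upper(), b.upper())
        if x in _BASE_INDEX and y in _BASE_INDEX
    ]
    if not pairs:
        raise ValueError("no comparable columns")
    p = sum(x != y for x, y in pairs) / len(pairs)
    if p >= 0.75:
        raise ValueError(f"saturated divergence p={p:.3f} >= 0.75")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class RateSummary:
    """Per-lineage mean and SD after the max-rate filter (sample SD, ddof=1;
    SD is 0 for a single retained gene)."""

    per_lineage: pd.DataFrame  # index: lineage; columns: mean, sd, n
    n_retained: int
    n_discarded: int
    background: pd.DataFrame | None = None


def _lineage_table(estimates: Sequence[RateEstimate]) -> pd.DataFrame:
    data = {
        "human": [e.t_human for e in estimates],
        "chimp": [e.t_chimp for e in estimates],
        "orang": [e.t_orang for e in estimates],
    }
    df = pd.DataFrame(data)
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1).fillna(0.0),
            "n": len(df),
        }
    )
    out.index.name = "lineage"
    return out


def summarize_rates(
    estimates: Sequence[RateEstimate],
    th: Thresholds | None = None,
    background: Sequence[RateEstimate] | None = None,
) -> RateSummary:
    """Apply the max-rate discard rule and summarize lineage rates.

    Genes with t_human or t_chimp above ``max_lineage_rate`` are discarded;
    the retained set (and the background set, filtered the same way) is
    summarized as mean and SD per lineage.
    """
    th = th or Thresholds()
    if not estimates:
        raise ValueError("no rate estimates given")
    keep = [
        e
        for e in estimates
        if e.t_human <= th.max_lineage_rate and e.t_chimp <= th.max_lineage_rate
    ]
    if not keep:
        raise ValueError("all genes discarded by the max-rate filter")
    bg_table = None
    if background:
        bg_keep = [
            e
            for e in background
            if e.t_human <= th.max_lineage_rate and e.t_chimp <= th.max_lineage_rate
        ]
        if bg_keep:
            bg_table = _lineage_table(bg_keep)
    return RateSummary(
        per_lineage=_lineage_table(keep),
        n_retained=len(keep),
        n_discarded=len(estimates) - len(keep),
        background=bg_table,
    )


def write_rates_tsv(estimates: Sequence[RateEstimate], path, th: Thresholds | None = None) -> None:
    th = th or Thresholds()
    rows = []
    for e in estimates:
        rows.append(
            {
                "gene_id": e.gene_id,
                "t_human": e.t_human,
                "t_chimp": e.t_chimp,
                "t_orang": e.t_orang,
                "kappa": e.kappa,
                "loglik": e.loglik,
                "n_sites": e.n_sites,
                "discarded_flag": int(
                    e.t_human > th.max_lineage_rate or e.t_chimp > th.max_lineage_rate
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
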