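"""RNA-seq expression statistics over coding regions.

Because the exact transcript models of newly born genes are undefined, the
expression level of a gene in a tissue is the number of uniquely mapping
reads overlapping its coding region divided by the coding-region length
(reads/nt), optionally normalized by the tissue's total valid read count.
Normalized levels are conventionally displayed on a 1e-8 scale, i.e. the
reported number is ``(U/L)/V * 1e8``.

Summaries per tissue:

* pooled mean level  sum(U)/sum(L)  — reads over ALL coding regions divided
  by their total length (not the mean of per-gene densities, which is also
  exposed, labeled ``mean_of_gene_levels``);
* pooled normalized level  (sum(U)/sum(L))/V, on the display scale;
* proportion of genes with any reads in the tissue;
* proportion of expressed genes whose maximum normalized level falls in the
  tissue (ties broken by alphabetical tissue order);
* optional ratios of each statistic to a genome-wide background matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ReadPlacement:
    """One read placement on the genome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    unique: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )


def count_unique_reads(
    reads: Iterable[ReadPlacement], cds: tuple[str, int, int]
) -> int:
    """Count uniquely mapping reads overlapping the CDS by >= 1 nt."""
    chrom, start, end = cds
    if end <= start:
        raise ValueError(f"malformed CDS interval {chrom}:{start}-{end}")
    reads = list(reads)
    if not reads:
        return 0
    starts = np.fromiter((r.start for r in reads), dtype=np.int64, count=len(reads))
    ends = np.fromiter((r.end for r in reads), dtype=np.int64, count=len(reads))
    ok = np.fromiter(
        (r.unique and r.chrom == chrom for r in reads), dtype=bool, count=len(reads)
    )
    return int(np.sum(ok & (starts < end) & (ends > start)))


def read_bed_placements(path) -> list[ReadPlacement]:
    """Read 6-column BED plus a 7th uniqueness column (0/1).

    Falls back to a name convention when only 6 columns are present: a
    read name ending in ``/multi`` is multi-mapped, anything else unique.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        vals = tuple(row)
        if len(vals) >= 7 and pd.notna(vals[6]):
            unique = bool(int(vals[6]))
        else:
            unique = not str(vals[3]).endswith("/multi")
        out.append(ReadPlacement(str(vals[0]), int(vals[1]), int(vals[2]), unique))
    return out


@dataclass
class ExpressionMatrix:
    """Gene x tissue unique-read counts with coding lengths and library sizes."""

    counts: pd.DataFrame  # genes x tissues, nonnegative ints
    lengths: pd.Series  # per-gene coding length, nt
    libsizes: pd.Series  # per-tissue total valid reads

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.lengths = self.lengths.astype(float).reindex(self.counts.index)
        self.libsizes = self.libsizes.astype(float).reindex(self.counts.columns)
        if (self.counts.values < 0).any():
            raise ValueError("read counts must be nonnegative")
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths.isna() | (self.lengths <= 0)]
            raise ValueError(f"missing/nonpositive coding length for {list(bad)}")
        if self.libsizes.isna().any() or (self.libsizes <= 0).any():
            bad = self.libsizes.index[self.libsizes.isna() | (self.libsizes <= 0)]
            raise ValueError(f"missing/nonpositive library size for tissue(s) {list(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.counts.columns)

    def raw_levels(self) -> pd.DataFrame:
        """Per-cell read density U/L (reads per nt of coding region)."""
        return self.counts.div(self.lengths, axis=0)

    def normalized_levels(self, scale: float = 1.0) -> pd.DataFrame:
        """Per-cell (U/L)/V, multiplied by ``scale`` for display."""
        return self.raw_levels().div(self.libsizes, axis=1) * scale


def build_matrix(
    counts: pd.DataFrame | Mapping[str, Mapping[str, int]],
    lengths: Mapping[str, float] | pd.Series,
    libsizes: Mapping[str, float] | pd.Series,
) -> ExpressionMatrix:
    """Assemble and validate an :class:`ExpressionMatrix`."""
    if not isinstance(counts, pd.DataFrame):
        counts = pd.DataFrame(counts).T
    return ExpressionMatrix(
        counts=counts.copy(),
        lengths=pd.Series(lengths),
        libsizes=pd.Series(libsizes),
    )


@dataclass(frozen=True)
class TissueSummary:
    """Per-tissue summary statistics (each a Series indexed by tissue)."""

    pooled_mean_level: pd.Series  # sum(U)/sum(L)
    mean_of_gene_levels: pd.Series  # mean over genes of U/L
    pooled_normalized_level: pd.Series  # (sum(U)/sum(L))/V on display scale
    proportion_expressed: pd.Series
    proportion_highest: pd.Series
    n_genes: int
    n_expressed: int
    gene_ranks: pd.DataFrame  # per-gene tissue names for rank 1..4
    background_ratios: pd.DataFrame | None = None


def summarize_tissues(
    m: ExpressionMatrix,
    background: ExpressionMatrix | None = None,
    norm_scale: float = 1e8,
) -> TissueSummary:
    """Compute the per-tissue expression summary.

    ``proportion_expressed`` divides by all genes in the set;
    ``proportion_highest`` divides by the genes expressed in at least one
    tissue (genes with zero reads everywhere carry no ranking information).
    With a background matrix over the same tissues, each statistic is also
    reported as a ratio to its genome-wide counterpart.
    """
    if m.counts.empty:
        raise ValueError("expression matrix has no genes or no tissues")
    if background is not None and list(background.tissues) != list(m.tissues):
        raise ValueError("background tissue set does not match")

    def _stats(mat: ExpressionMatrix) -> dict[str, pd.Series]:
        pooled = mat.counts.sum(axis=0) / mat.lengths.sum()
        mean_gene = mat.raw_levels().mean(axis=0)
        pooled_norm = pooled / mat.libsizes * norm_scale
        prop_expr = (mat.counts > 0).mean(axis=0)
        norm = mat.normalized_levels()
        expressed = mat.counts.sum(axis=1) > 0
        n_expr = int(expressed.sum())
        if n_expr:
            # ties to the alphabetically first tissue
            ordered = norm.loc[expressed, sorted(mat.tissues)]
            argmax = ordered.idxmax(axis=1)
            prop_high = argmax.value_counts().reindex(mat.tissues, fill_value=0) / n_expr
        else:
            prop_high = pd.Series(0.0, index=mat.tissues)
        return {
            "pooled_mean_level": pooled,
            "mean_of_gene_levels": mean_gene,
            "pooled_normalized_level": pooled_norm,
            "proportion_expressed": prop_expr,
            "proportion_highest": prop_high.astype(float),
            "_n_expressed": n_expr,  # type: ignore[dict-item]
        }

    stats = _stats(m)

    # per-gene rank lists (which tissue holds the 1st..4th highest level)
    norm = m.normalized_levels()
    expressed = m.counts.sum(axis=1) > 0
    ranks = {}
    ordered_tissues = sorted(m.tissues)
    for gene in m.genes:
        if not expressed[gene]:
            continue
        row = norm.loc[gene, ordered_tissues]
        order = row.sort_values(ascending=False, kind="stable").index
        ranks[gene] = list(order[: min(4, len(order))])
    depth = min(4, len(m.tissues))
    gene_ranks = pd.DataFrame.from_dict(
        ranks, orient="index", columns=[f"rank{i+1}" for i in range(depth)]
    )

    bg_ratios = None
    if background is not None:
        bstats = _stats(background)
        rows = {}
        for key in (
            "pooled_mean_level",
            "pooled_normalized_level",
            "proportion_expressed",
            "proportion_highest",
        ):
            denom = bstats[key].replace(0, np.nan)
            rows[key] = stats[key] / denom
        bg_ratios = pd.DataFrame(rows)

    return TissueSummary(
        pooled_mean_level=stats["pooled_mean_level"],
        mean_of_gene_levels=stats["mean_of_gene_levels"],
        pooled_normalized_level=stats["pooled_normalized_level"],
        proportion_expressed=stats["proportion_expressed"],
        proportion_highest=stats["proportion_highest"],
        n_genes=len(m.genes),
        n_expressed=int(expressed.sum()),
        gene_ranks=gene_ranks,
        background_ratios=bg_ratios,
    )


def read_counts_tsv(counts_path, lengths_path, libsizes_path) -> ExpressionMatrix:
    """Pre-counted gene x tissue TSV plus lengths and library-size TSVs."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    libsizes = pd.read_csv(libsizes_path, sep="\t", index_col=0).iloc[:, 0]
    return build_matrix(counts, lengths, libsizes)


def write_summary(summary: TissueSummary, tsv_path, ranks_json_path=None) -> None:
    df = pd.DataFrame(
        {
            "pooled_mean_level": summary.pooled_mean_level,
            "mean_of_gene_levels": summary.mean_of_gene_levels,
            "pooled_normalized_level_x1e8": summary.pooled_normalized_level,
            "proportion_expressed": summary.proportion_expressed,
            "proportion_highest": summary.proportion_highest,
        }
    )
    df.index.name = "tissue"
    df.to_csv(tsv_path, sep="\t")
    if ranks_json_path is not None:
        import json

        with open(ranks_json_path, "w") as fh:
            json.dump(
                {g: list(r.dropna()) for g, r in summary.gene_ranks.iterrows()},
                fh,
                indent=1,
            )
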