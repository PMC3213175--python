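"""Data model and I/O for gapped human/chimp/orangutan coding alignments.

A :class:`CodingTrioAlignment` holds the three aligned rows over one
candidate coding region, already resolved to the coding strand, with the
human start and stop codons anchored by 0-based alignment columns.  All
coordinates in this package are 0-based and half-open; alignment columns
are the primary frame and conversion to ungapped sequence positions goes
through :func:`ungapped_map` only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TAXA = ("human", "chimp", "orang")

_TAXON_ALIASES = {
    "human": "human",
    "homo": "human",
    "homo_sapiens": "human",
    "hsa": "human",
    "chimp": "chimp",
    "chimpanzee": "chimp",
    "pan": "chimp",
    "pan_troglodytes": "chimp",
    "ptr": "chimp",
    "orang": "orang",
    "orangutan": "orang",
    "pongo": "orang",
    "pongo_pygmaeus": "orang",
    "ppy": "orang",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
VALID_CHARS = frozenset("ACGTN-")


class TrioValidationError(ValueError):
    """Raised when a trio alignment violates a structural invariant."""


def normalize_taxon(label: str) -> str:
    key = label.strip().lower().replace(" ", "_")
    if key not in _TAXON_ALIASES:
        raise TrioValidationError(f"unrecognized taxon label: {label!r}")
    return _TAXON_ALIASES[key]


@dataclass(frozen=True)
class Thresholds:
    """Every numeric constant used by the screen, with its default.

    min_protein_aa
        Minimum human protein length (amino acids, stop excluded).
    intact_fraction
        A complete ortholog ORF encoding at least this fraction of the
        human protein is "intact enough" and the candidate is discarded.
    qc_window_aa
        Sliding-window width (amino acids) for the alignment quality filter.
    qc_max_similarity
        A window with identity fraction at or below this fails QC.
    max_lineage_rate
        Genes whose human or chimp branch length exceeds this
        (substitutions/site) are dropped from rate summaries.
    norm_scale
        Display multiplier for normalized expression levels (the 1e-8 axis
        convention, i.e. values are reported as level * 1e8).
    divergence_my_low, divergence_my_high
        Human-chimp divergence bounds in million years.
    """

    min_protein_aa: int = 100
    intact_fraction: float = 0.80
    qc_window_aa: int = 5
    qc_max_similarity: float = 0.20
    max_lineage_rate: float = 0.1
    norm_scale: float = 1e8
    divergence_my_low: float = 5.0
    divergence_my_high: float = 6.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"threshold {f.name} must be strictly positive, got {v}")
        for name in ("intact_fraction", "qc_max_similarity"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"threshold {name} must lie in (0,1), got {v}")

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "Thresholds":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**{k: v for k, v in data.items()})  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Thresholds":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


@dataclass(frozen=True)
class EvidenceRecord:
    """Boolean evidence flags standing in for external-database lookups."""

    gene_id: str
    has_mrna: bool
    has_est: bool
    has_peptide: bool
    single_copy_human: bool
    single_copy_outgroups: bool
    disrupting_snp: bool

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "gene_id":
                continue
            v = getattr(self, f.name)
            if not isinstance(v, bool):
                raise TrioValidationError(
                    f"evidence flag {f.name} for {self.gene_id} must be boolean, got {v!r}"
                )


EVIDENCE_COLUMNS = (
    "gene_id",
    "has_mrna",
    "has_est",
    "has_peptide",
    "single_copy_human",
    "single_copy_outgroups",
    "disrupting_snp",
)


@dataclass(frozen=True)
class UngappedMap:
    """Bidirectional map between alignment columns and ungapped positions."""

    col_to_pos: Mapping[int, int]
    pos_to_col: tuple[int, ...]

    def to_pos(self, col: int) -> int | None:
        """Ungapped position at alignment column ``col``, or None at a gap."""
        return self.col_to_pos.get(col)

    def to_col(self, pos: int) -> int:
        return self.pos_to_col[pos]

    def __len__(self) -> int:
        return len(self.pos_to_col)


def ungapped_map(row: str) -> UngappedMap:
    """Map non-gap alignment columns of ``row`` to ungapped positions.

    The map covers exactly the non-gap columns; composing it with its
    inverse is the identity.
    """
    if not row:
        raise ValueError("row must be nonempty")
    cols = [i for i, c in enumerate(row) if c != "-"]
    return UngappedMap(
        col_to_pos={c: p for p, c in enumerate(cols)},
        pos_to_col=tuple(cols),
    )


@dataclass(frozen=True)
class CodingTrioAlignment:
    """Gapped trio alignment over one candidate coding region.

    ``human_start_col`` is the alignment column of the first base of the
    annotated human ATG; ``human_stop_col`` that of the first base of the
    human stop codon.  Rows are uppercase over A, C, G, T, N and '-'.
    """

    gene_id: str
    rows: Mapping[str, str]
    human_start_col: int
    human_stop_col: int
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", dict(self.rows))
        self.validate()

    def validate(self) -> None:
        missing = [t for t in TAXA if t not in self.rows]
        if missing:
            raise TrioValidationError(
                f"{self.gene_id}: missing taxon record(s): {', '.join(missing)}"
            )
        lengths = {t: len(self.rows[t]) for t in TAXA}
        if len(set(lengths.values())) != 1:
            raise TrioValidationError(
                f"{self.gene_id}: unequal alignment lengths: {lengths}"
            )
        n = lengths["human"]
        if n < 6:
            raise TrioValidationError(f"{self.gene_id}: alignment shorter than 6 columns")
        for taxon in TAXA:
            row = self.rows[taxon]
            bad = set(row) - VALID_CHARS
            if bad:
                col = next(i for i, c in enumerate(row) if c in bad)
                raise TrioValidationError(
                    f"{self.gene_id}/{taxon}: non-nucleotide character "
                    f"{row[col]!r} at column {col}"
                )
        if not 0 <= self.human_start_col < n or not 0 <= self.human_stop_col < n:
            raise TrioValidationError(
                f"{self.gene_id}: anchor columns out of range for length {n}"
            )
        human = self.rows["human"]
        start3 = human[self.human_start_col : self.human_start_col + 3]
        if "-" in start3 or len(start3) < 3:
            raise TrioValidationError(
                f"{self.gene_id}: human row gapped at start codon columns "
                f"{self.human_start_col}..{self.human_start_col + 2}"
            )
        if start3 != "ATG":
            raise TrioValidationError(
                f"{self.gene_id}: human start is not ATG (found {start3!r} at "
                f"column {self.human_start_col})"
            )
        hmap = ungapped_map(human)
        s = hmap.to_pos(self.human_start_col)
        e = hmap.to_pos(self.human_stop_col)
        if e is None:
            raise TrioValidationError(
                f"{self.gene_id}: human row gapped at stop column {self.human_stop_col}"
            )
        assert s is not None
        if e <= s or (e - s) % 3 != 0:
            raise TrioValidationError(
                f"{self.gene_id}: human CDS span {e - s} nt from start to stop "
                "is not a positive multiple of 3"
            )
        seq = human.replace("-", "")
        stop = seq[e : e + 3]
        if stop not in STOP_CODONS:
            raise TrioValidationError(
                f"{self.gene_id}: human stop codon is {stop!r}, not TAA/TAG/TGA"
            )

    # -- derived views -------------------------------------------------

    @property
    def n_cols(self) -> int:
        return len(self.rows["human"])

    def row(self, taxon: str) -> str:
        return self.rows[normalize_taxon(taxon)]

    def human_map(self) -> UngappedMap:
        return ungapped_map(self.rows["human"])

    def human_protein_len(self) -> int:
        """Length of the annotated human protein in aa (stop excluded)."""
        hmap = self.human_map()
        s = hmap.to_pos(self.human_start_col)
        e = hmap.to_pos(self.human_stop_col)
        assert s is not None and e is not None
        return (e - s) // 3

    def human_cds_col_span(self) -> tuple[int, int]:
        """Half-open alignment-column span covering the human CDS incl. stop."""
        human = self.rows["human"]
        # last stop base = 3rd non-gap column at or after human_stop_col
        seen = 0
        end = self.human_stop_col
        for i in range(self.human_stop_col, len(human)):
            if human[i] != "-":
                seen += 1
                if seen == 3:
                    end = i
                    break
        else:
            raise TrioValidationError(f"{self.gene_id}: human stop codon truncated")
        return self.human_start_col, end + 1

    def with_human_row(self, new_row: str) -> "CodingTrioAlignment":
        """Copy with the human row replaced (validation skipped: the row may
        deliberately encode a disrupted ORF, e.g. a polarization
        counterfactual)."""
        obj = object.__new__(CodingTrioAlignment)
        object.__setattr__(obj, "gene_id", self.gene_id)
        object.__setattr__(obj, "rows", {**self.rows, "human": new_row})
        object.__setattr__(obj, "human_start_col", self.human_start_col)
        object.__setattr__(obj, "human_stop_col", self.human_stop_col)
        object.__setattr__(obj, "strand", self.strand)
        return obj


# -- FASTA + anchor I/O ----------------------------------------------------


def _parse_header(description: str) -> tuple[str, str, dict[str, str]]:
    """Split ``gene|taxon key=value ...`` header into parts."""
    tokens = description.split()
    head = tokens[0]
    if "|" not in head:
        raise TrioValidationError(f"header {head!r} lacks 'gene_id|taxon' form")
    gene_id, taxon = head.split("|", 1)
    kv = {}
    for tok in tokens[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            kv[k] = v
    return gene_id, taxon, kv


def read_trio_alignment(
    path: str | Path,
    annotation: str | Path | tuple[int, int] | None = None,
) -> CodingTrioAlignment:
    """Read one gapped multi-FASTA trio with anchored human start/stop.

    Anchors come from, in order of precedence: an explicit ``(start_col,
    stop_col)`` tuple, a sidecar TSV path with columns gene_id/start_col/
    stop_col, or ``start_col=``/``stop_col=`` tokens on a FASTA header.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 3:
        raise TrioValidationError(
            f"{path}: expected exactly 3 records, found {len(records)}"
        )
    rows: dict[str, str] = {}
    gene_id = None
    header_kv: dict[str, str] = {}
    for rec in records:
        gid, taxon_label, kv = _parse_header(rec.description)
        taxon = normalize_taxon(taxon_label)
        if taxon in rows:
            raise TrioValidationError(f"{path}: duplicate taxon {taxon}")
        if gene_id is None:
            gene_id = gid
        elif gid != gene_id:
            raise TrioValidationError(
                f"{path}: mixed gene ids {gene_id!r} and {gid!r}"
            )
        rows[taxon] = str(rec.seq).upper()
        header_kv.update(kv)
    assert gene_id is not None

    if isinstance(annotation, tuple):
        start_col, stop_col = annotation
    elif annotation is not None:
        anchors = read_anchor_table(annotation)
        if gene_id not in anchors:
            raise TrioValidationError(f"no anchors for gene {gene_id} in {annotation}")
        start_col, stop_col = anchors[gene_id]
    else:
        try:
            start_col = int(header_kv["start_col"])
            stop_col = int(header_kv["stop_col"])
        except KeyError as exc:
            raise TrioValidationError(
                f"{path}: no start_col/stop_col header tokens and no sidecar given"
            ) from exc
    return CodingTrioAlignment(
        gene_id=gene_id, rows=rows, human_start_col=start_col, human_stop_col=stop_col
    )


def write_trio_alignment(trio: CodingTrioAlignment, path: str | Path) -> None:
    """Write a trio back to multi-FASTA with anchors on the human header."""
    recs = []
    for taxon in TAXA:
        desc = f"{trio.gene_id}|{taxon}"
        if taxon == "human":
            desc += f" start_col={trio.human_start_col} stop_col={trio.human_stop_col}"
        recs.append(
            SeqRecord(Seq(trio.rows[taxon]), id=f"{trio.gene_id}|{taxon}", description=desc)
        )
    # id is a prefix of description; write description only
    with open(path, "w") as fh:
        for rec in recs:
            fh.write(f">{rec.description}\n{str(rec.seq)}\n")


def read_anchor_table(path: str | Path) -> dict[str, tuple[int, int]]:
    out: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["gene_id"]] = (int(row["start_col"]), int(row["stop_col"]))
    return out


def read_evidence_table(path: str | Path) -> dict[str, EvidenceRecord]:
    """Read the per-gene evidence TSV (exact header, 0/1 flags)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if tuple(reader.fieldnames or ()) != EVIDENCE_COLUMNS:
            raise TrioValidationError(
                f"{path}: evidence header must be exactly {EVIDENCE_COLUMNS}, "
                f"found {tuple(reader.fieldnames or ())}"
            )
        out: dict[str, EvidenceRecord] = {}
        for row in reader:
            gid = row["gene_id"]
            if gid in out:
                raise TrioValidationError(f"{path}: duplicate evidence for {gid}")
            flags = {}
            for col in EVIDENCE_COLUMNS[1:]:
                v = row[col].strip()
                if v not in {"0", "1"}:
                    raise TrioValidationError(
                        f"{path}: {gid}.{col} must be 0 or 1, found {v!r}"
                    )
                flags[col] = v == "1"
            out[gid] = EvidenceRecord(gene_id=gid, **flags)
    return out


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(EVIDENCE_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.gene_id]
                + [int(getattr(rec, col)) for col in EVIDENCE_COLUMNS[1:]]
            )
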