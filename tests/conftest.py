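import numpy as np
import pytest

from denovoscan.trio_model import CodingTrioAlignment, EvidenceRecord, Thresholds


@pytest.fixture
def thresholds():
    return Thresholds()


def make_trio(
    gene_id="g1",
    human="ATGAAATAA",
    chimp=None,
    orang=None,
    start_col=0,
    stop_col=6,
):
    chimp = human if chimp is None else chimp
    orang = human if orang is None else orang
    return CodingTrioAlignment(
        gene_id=gene_id,
        rows={"human": human, "chimp": chimp, "orang": orang},
        human_start_col=start_col,
        human_stop_col=stop_col,
    )


def make_evidence(gene_id="g1", **overrides):
    flags = dict(
        has_mrna=True,
        has_est=True,
        has_peptide=True,
        single_copy_human=True,
        single_copy_outgroups=True,
        disrupting_snp=False,
    )
    flags.update(overrides)
    return EvidenceRecord(gene_id=gene_id, **flags)


def random_nt(rng: np.random.Generator, n: int, gap_frac: float = 0.0) -> str:
    alphabet = list("ACGT")
    seq = rng.choice(alphabet, size=n)
    if gap_frac > 0:
        mask = rng.random(n) < gap_frac
        seq[mask] = "-"
    return "".join(seq)
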