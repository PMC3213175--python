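# denovoscan

A tested re-implementation of a comparative-genomics screen for
protein-coding genes that originated **de novo** on the human lineage since
the split from chimpanzee (~5–6 million years ago). It is aimed at
molecular-evolution researchers who want to run, audit, or stress-test this
class of screen on their own alignments — or on synthetic data with known
ground truth.

## The method

A candidate de novo gene must satisfy, in order:

1. a complete human ORF anchored at the annotated ATG and stop;
2. protein length ≥ 100 aa;
3. single copy in human and in both outgroups (evidence flags);
4. **disrupted orthologs in both chimpanzee and orangutan** — translation of
   the ortholog's own sequence (anchored at the column-mapped human start,
   with an alternative-ATG rescue over the whole region) either fails to
   reach a stop or yields a protein < 80% of the human length. A complete
   ortholog ORF encoding ≥ 80% is "intact enough" and the candidate is
   discarded;
5. **≥ 1 polarizable enabling mutation** — an alignment column (or indel
   run) where chimpanzee and orangutan share a state that differs from
   human, and substituting that ancestral state into the human row disrupts
   the human ORF. Requiring the shared ancestral disrupting state rejects
   parallel loss (independent disruption on both outgroup lineages);
6. transcription evidence (mRNA or EST hit);
7. translation evidence (peptide hit).

Around the screen the package implements the study's quantitative analyses:

- **Expression.** The level of gene *g* in tissue *t* is
  `U(g,t) / L(g)` — uniquely mapping reads over the coding region divided
  by its length — normalized by the tissue's valid-read total `V(t)` and
  displayed on a ×10⁻⁸ scale. Per-tissue summaries include the pooled mean
  `ΣU/ΣL`, the proportion of genes expressed, and the proportion of
  expressed genes whose maximum normalized level falls in each tissue.
- **Lineage rates.** Per gene, maximum-likelihood branch lengths
  (t_human, t_chimp, t_orang) and transition/transversion ratio κ under
  HKY85 on the unrooted 3-taxon tree, with empirical base frequencies;
  genes with t_human or t_chimp > 0.1 substitutions/site are discarded
  before mean ± SD summaries.
- **Alignment QC.** A 5-aa sliding window (step one codon) over aligned
  ortholog proteins; any window with identity ≤ 20% discards the pair.
  Prefilters drop X-containing proteins, keep the longest isoform
  alignment, and require ≥ 100 aligned aa.
- **Birth rate.** With *n* fixed de novo genes over a divergence window of
  t_low–t_high Myr, the birth rate is n/t_high – n/t_low genes/Myr; divided
  by the genome gene count it gives a per-gene rate.

A first-class synthetic-data module generates every input with known truth:
labeled trio scenarios for each enabling-mutation class and each confound,
HKY85-evolved alignments with known branch lengths, and Poisson read counts
over an 11-tissue panel.

## Worked example

```python
from denovoscan import (
    ScenarioSpec, generate_trio_scenario, classify_candidate,
    assess_ortholog, find_enabling_mutations, compute_birth_rate,
)

trio, evidence, label = generate_trio_scenario(
    ScenarioSpec(kind="de_novo_stop_removal", n_codons=150, seed=7)
)
for taxon in ("chimp", "orang"):
    s = assess_ortholog(trio, taxon)
    print(f"{taxon}: {s.status}  protein={len(s.orf.protein)} aa "
          f"({s.orf.length_fraction:.2f} of human)  events={[e.kind for e in s.events]}")
for m in find_enabling_mutations(trio):
    print(f"enabling mutation at column {m.column}: human {m.human_state!r} vs "
          f"ancestral {m.ancestral_state!r} ({m.effect})")
print("verdict:", classify_candidate(trio, evidence).verdict)
print("birth rate:", compute_birth_rate(59, 5, 6, 30000))
```

prints

```
chimp: disrupted  protein=100 aa (0.67 of human)  events=['premature_stop']
orang: disrupted  protein=100 aa (0.67 of human)  events=['premature_stop']
enabling mutation at column 311: human 'G' vs ancestral 'A' (stop_removal)
verdict: de_novo
birth rate: (9.83, 11.8, 0.00033, 0.00039)
```

The generated trio carries an ancestral in-frame TGA at codon 100 of 150;
both outgroups translate to a 100-aa protein (0.67 < 0.80 of the human
length, hence disrupted), the human G at alignment column 311 removes that
stop, reverting it re-disrupts the ORF, and the gene is accepted. The
birth-rate call reproduces the headline arithmetic: 59 fixed genes over
5–6 Myr is 9.83–11.8 genes/Myr, i.e. 0.00033–0.00039 per gene per Myr
against a 30,000-gene genome.

## Command line

`denovoscan` exposes thin subcommands over the library: `classify` (trio
FASTAs + evidence TSV → verdict report), `qc` (aligned protein pairs →
window-filter report), `express` (counted gene×tissue matrix → per-tissue
summary), `rate` (3-row FASTAs → HKY85 rates TSV and summary), and
`simulate` (seeded fixture bundle + truth JSON). All thresholds can be
overridden with a YAML config whose keys mirror the `Thresholds` fields.

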