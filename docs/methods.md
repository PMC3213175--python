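# Methods

## Scope and coordinate conventions

The package operates on gapped three-row alignments (human, chimpanzee,
orangutan) over single candidate coding regions, already resolved to the
coding strand by the provider; there is no reverse-complement logic, no
splice modeling, and no genome-scale liftover. All coordinates are 0-based
and half-open. Alignment columns are the primary frame; conversion to
ungapped sequence positions goes only through the bidirectional
`ungapped_map`. The human CDS length includes the terminal stop codon for
coordinate purposes; protein lengths exclude it. Codons containing `N`
translate to `X` and never count as a start or a stop — ambiguous sequence
can therefore never create evidence for disruption or for an enabling
mutation.

## ORF disruption assessment

The authoritative disruption test is *translation of the ortholog's own
ungapped sequence*, not the list of observed differences. Translation is
anchored at the column-mapped human ATG; if the ortholog lacks ATG there,
an alternative-start rescue scans every ATG in the provided region (any
frame, upstream or downstream) and keeps the start maximizing protein
length, ties to the 5'-most. Scanning the entire provided region is the
most conservative choice against false de novo calls: any start that could
plausibly rescue the ortholog is allowed to. Alternative starts are
ATG-only; non-ATG initiation (CTG/GTG) is deliberately out of scope.

The verdict is a three-way status:

- **disrupted** — no complete ORF, or a complete ORF encoding
  < `intact_fraction` (default 0.80) of the human protein length;
- **intact_enough** — a complete ORF at ≥ `intact_fraction` but with
  observed differences (premature stop, frameshifting indel, missing
  start); such orthologs disqualify the candidate;
- **intact** — complete, full-fraction, event-free.

The boundary counts as intact_enough: a complete ortholog ORF at exactly
80% of the human protein disqualifies the candidate. The fraction is
computed on unaligned predicted protein lengths. An ORF that runs off the
provided region (no stop) is disrupted.

Difference *events* (premature stops read in the human codon frame,
indel runs with length not divisible by 3 inside the human CDS span, a
non-ATG state at the human start columns) are explanatory annotations
only. This resolves compensated-indel ambiguity cleanly: a +1/−1 indel
pair that restores the frame without introducing a stop leaves the ORF
complete, and only the encoded fraction decides the status — verified in
tests against an independent translation oracle.

## Polarization and the candidate verdict

An *enabling mutation* is a human-specific change whose reversion to the
ancestral state disrupts the human ORF. Ancestral states are assigned by
parsimony-by-identity: a column (or contiguous indel run) is polarizable
only when chimpanzee and orangutan are identical there; `N` in either
outgroup, or gap runs that only partially coincide between the outgroups,
disqualify the site. Counterfactuals are applied one mutation at a time; a
candidate needs at least one *singly sufficient* enabling mutation. Genes
whose ORF completion required two or more simultaneous human changes are
therefore missed — a documented limitation, and the conservative
direction.

Counterfactual reversion re-runs the same anchored-then-rescue translation
used for orthologs, with the same 80% rule. Effects are classified by what
the reversion breaks: loss of the start ATG → `start_creation`; a frame
shift (indel length mod 3 ≠ 0) → `frame_completion`; anything else that
kills the ORF — a premature stop re-appearing, or the terminal stop
configuration being lost — → `stop_removal`.

The per-gene verdict walks a fixed 7-stage ledger (complete human ORF;
≥ 100 aa; single-copy flags; both orthologs disrupted; ≥ 1 enabling
mutation; mRNA-or-EST; peptide). External-database stages are consumed as
boolean evidence flags so the audit trail stays complete without live
lookups. Evaluation short-circuits (later stages are recorded as skipped),
which makes the per-stage entered/passed/failed counts of a batch report
conserve exactly: stage *k*'s entered equals stage *k−1*'s passed. A
disrupting SNP segregating in the population is recorded as a fixation
caveat, not a rejection.

## Alignment QC

"Similarity" in the sliding-window filter is implemented as exact
amino-acid identity — no substitution matrix — because nothing finer is
specified by the procedure this mirrors; this is the package's documented
reading. Windows are 5 aligned columns wide, step 1; gaps count as
mismatches; a window at ≤ 20% identity (i.e. ≤ 1 of 5) discards the pair,
reported with the first failing window index. Prefilters: proteins
containing `X` are dropped; among a gene's isoforms the longest alignment
is kept (ties to input order); kept alignments must span ≥ 100 aa.

The bundled pairwise aligner is a Gotoh affine-gap global aligner with
deterministic tie-breaking (diagonal over gap-in-second-sequence over
gap-in-first). Default scoring: match +1, mismatch −1, gap open −4
(length-1 gap), gap extend −1; all configurable. It is a desk-scale
utility — tests pin its optimal scores against an independent reference
aligner on exhaustive short pairs.

## Expression statistics

Counts are uniquely mapping reads overlapping the coding region by ≥ 1 nt
(partial overlaps count; the source procedure is silent on this).
Per-tissue summaries expose both the pooled mean `ΣU/ΣL` and the mean of
per-gene densities, since published captions are ambiguous between the
two; the pooled form is the primary statistic. Normalized levels divide by
the tissue's valid-read total and are displayed ×1e8. `proportion_highest`
ranks each expressed gene's tissues by normalized level with ties broken
by alphabetical tissue order (determinism); its denominator is the genes
expressed in ≥ 1 tissue, while `proportion_expressed` divides by the full
gene set. With a background matrix over the same tissue panel, each
statistic is also emitted as a ratio to its genome-wide counterpart.

## Lineage rates

HKY85 on the single unrooted 3-taxon star — the only identifiable
parameterization with three sequences. `t_human` and `t_chimp` are the
ingroup terminal branches; the orangutan branch absorbs the outgroup path.
Base frequencies are empirical (counted from the alignment, floored at
1e-9 against absent bases), not ML-optimized; no molecular clock is
imposed. Columns containing gaps or `N` in any row are excluded; sites are
collapsed to ≤ 64 patterns before likelihood evaluation. Optimization is
bounded L-BFGS-B over t ∈ [0, 2] and κ ∈ [0.05, 100] from t = 0.01,
κ = 2, ftol 1e-8, ≤ 500 iterations; the 4×4 transition matrices are exact
matrix exponentials of the unit-mean-rate generator. κ can be pinned and
frequencies forced equal, which gives the Jukes–Cantor limit used as a
closed-form oracle in tests. Genes with t_human or t_chimp > 0.1 are
discarded before summaries; summaries report mean and sample SD (ddof 1,
0 for a single gene) per lineage, optionally next to a background set
filtered the same way.

## Birth-rate arithmetic

`compute_birth_rate(n, t_low, t_high, N)` returns (n/t_high, n/t_low)
genes/Myr at 3 significant figures and, with a genome size N, the per-gene
range at 2 significant figures. The default worked example uses n = 59
fixed genes, a 5–6 Myr divergence window, and N = 30,000 — the genome
gene count consistent with both published ranges, adopted here as the
documented default since no source value is printed.

## Synthetic data: what it emulates, and what it does not

`generate_trio_scenario` builds an ancestral coding sequence (ATG start,
stop-free ATG-free body, TAA stop, 9-nt ATG-free flanks) and plants exactly
the mutations that define each scenario kind:

- `de_novo_stop_removal` — outgroups share an in-frame TGA at a codon
  placed uniformly between ~n/6 and 0.70·n (fraction safely < 0.80); the
  human state reads TGG.
- `de_novo_start_creation` — outgroups read ATA at the start; the body
  contains no other ATG, so no rescue is possible.
- `de_novo_frame_completion` — outgroups share a 1-nt T insertion placed
  before an AAA codon, so the shifted frame stops immediately (TAA) at a
  fraction < 0.80; the human row lacks the insertion.
- `parallel_loss` — chimp and orang each carry a premature stop at
  *different* columns with non-identical states: both disrupted, nothing
  polarizable.
- `ancestrally_intact` — outgroups identical to human.
- `alt_start_rescue` — start broken in the outgroups, but a shared
  in-frame ATG at ~0.10·n rescues a ≥ 80% ORF.
- `intact_enough_85pct` — shared premature stop at ~0.85·n: complete ORF
  at ≥ 80%, candidate discarded.
- `shared_human_chimp_gain` — only orangutan disrupted; the enabling state
  is shared by human and chimp, so the gene predates the split and chimp
  is intact.

Default n_codons = 150 (a mid-sized single-exon protein; everything clears
the 100-aa stage so the labeled stage is the deciding one); scenarios are
rejected below 100 codons because the length stage would preempt the
label. Evidence flags default to all-favorable so sequence stages decide.
Every emitted scenario is re-classified and must reproduce its label
(generator self-check, hard failure otherwise).

These scenarios are deliberately *unambiguous*: outgroups differ from
human only at the planted sites, with no background divergence, no
sequencing error, no alignment error, and no polymorphism. Passing the
planted-truth suite therefore demonstrates correctness of the decision
logic, not robustness to noisy real alignments — real screens also contend
with assembly gaps, mis-annotation, and alignment uncertainty that this
generator does not model.

`simulate_hky85` evolves an ancestral sequence independently along the
three branches by exact per-site transition-matrix draws (no rate
heterogeneity, sites i.i.d.); optional indels (Poisson events per lineage,
geometric lengths) are planted with the true alignment retained. The
fitting fixtures use 50-kb alignments at t = (0.02, 0.03, 0.05), κ = 4 —
divergences of the human/chimp/orangutan order — over 50 replicates;
recovery tolerances are ±20% per replicate and 3 standard errors on the
mean. `simulate_expression` draws Poisson counts at given per-cell means
over the 11-tissue panel with library sizes of 5–20 million reads and the
default fixture size of 53 genes; the BED renderer emits exactly the
counted unique reads plus multi-mapped decoys that the counter must
ignore. Poisson counts ignore overdispersion present in real RNA-seq.

All generators take an explicit seed and are pure functions of
(spec, seed).

## Degenerate inputs and numeric choices

- Validation errors name the offending record and column (missing taxon,
  unequal lengths, non-ATG start, non-nucleotide characters, truncated
  stop).
- An ortholog entirely gapped within the human CDS span raises
  "ortholog region absent" rather than being called disrupted.
- `jc_distance` raises at p ≥ 0.75 (saturation).
- Window similarity comparisons use a 1e-12 epsilon so the exact 0.20
  boundary fails reliably in floating point.
- Likelihood evaluations clip site probabilities at 1e-300 before the log.
- Report serialization is canonical JSON (sorted keys, fixed separators),
  so identical inputs produce byte-identical reports.

## Known limitations

- Single-reversion polarization misses jointly sufficient mutation pairs.
- Parsimony-by-identity, not probabilistic ancestral reconstruction.
- ATG-only starts; no selenocysteine or readthrough.
- One orangutan row per trio; multi-copy orthologs must be resolved
  upstream.
- The scenario generator's clean alignments overstate real-data accuracy
  (see above); the expression simulator is Poisson-only.
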