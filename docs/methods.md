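# Methods

## The identification model

A tRNA-derived fragment is defined positionally, relative to a two-part
reference built per species:

* **Mature tRNA**: the tRNA gene's genomic sequence, taken on the coding
  strand (reverse-complemented for minus-strand genes), introns spliced out
  when the annotation provides them, and `CCA` appended — the 3′ `CCA` is
  added post-transcriptionally by tRNA nucleotidyltransferase and is absent
  from the genome.
* **Pre-tRNA**: the unspliced gene plus flanking sequence on both sides, in
  transcript orientation, modelling the primary transcript's 5′ leader and
  3′ trailer. No `CCA` is appended. `trailer_start` marks the first base of
  the 3′ trailer inside the entry
  (`actual_upstream + gene_length + 1`).

Fragments that survive filtering are mapped to this combined reference by
exact matching: full query length, 100 % identity, zero gaps, plus strand of
the reference only (the reference is already transcript-oriented, so
antisense fragments are intentionally invisible). If a fragment hits both
the mature and the pre entry of the same gene, only the mature hit is kept —
the pre-tRNA contains the mature sequence (except the `CCA`), so the pre hit
carries no independent evidence. Resolution is gene-local: a mature hit on
one gene never suppresses a pre hit on another.

Classification then reads off the anchor: `sstart = 1` on a mature entry →
tRF-5; `send = mature_length` → tRF-3 (the match necessarily covers the
`CCA` terminus); `sstart = trailer_start` on a pre entry → tRF-1. Everything
else — internal fragments, leader-anchored pre hits — is counted but not
classified. Only fragments of 15–28 nt are eligible.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `upstream`, `downstream` | 40 nt | pre-tRNA flank sizes; clipped at chromosome ends with the actual sizes recorded |
| `min_len`, `max_len` | 15, 28 nt | tRF length window, applied at table load and again at classification |
| `min_frag_freq` | 10 | clonal frequency for table input (encodes the strict "> 9") |
| `min_q` | 28 | FASTQ rule: a read is discarded if *any* base is below Q28 (Phred+33) |
| `fastq_max_len` | 100 nt | FASTQ reads of 15–100 nt are mapped; the 15–28 nt rule bites at classification |
| `min_read_freq` | 101 | collapsed-read frequency for FASTQ input (encodes "> 100") |

All thresholds are exposed as CLI flags; the defaults encode the strict
inequalities exactly, which the test suite pins at the boundaries (9 vs 10,
100 vs 101, one Q27 base, lengths 14/15/28/29).

## Numerical and design choices

* **Coordinates** are 1-based inclusive internally; BED input (0-based
  half-open) is converted on read. All sequences are uppercase DNA; RNA `U`
  in fragment input is mapped to `T` on ingest.
* **Exact search instead of a heuristic aligner.** The acceptance rule
  (100 % identity, 0 gaps, full query length) makes alignment scoring,
  word-size and E-value machinery irrelevant; an exact substring search is
  deterministic and dependency-free. The index seeds candidate references by
  the query's leading 10-mer and confirms all occurrences by direct string
  scan; queries shorter than the seed fall back to scanning every reference.
  Equivalence with a brute-force all-occurrences scan is asserted over
  randomized instances in the suite and the acceptance script.
* **Intron handling.** Mature entries are spliced when intron annotation
  exists (that is what "mature tRNA" means); pre entries are never spliced.
  `--no-splice` reproduces the unspliced-mature behaviour for comparison
  with pipelines that ignore introns.
* **Tie rule.** A fragment spanning an entire mature tRNA is anchored at
  both ends; it is classified tRF-5 and flagged
  (`ambiguous_full_length`) rather than dropped. This can only occur for
  mature tRNAs ≤ 28 nt, which is biologically marginal, but the case is
  defined rather than silent.
* **tRF-3 and the non-genomic CCA.** Matched `CCA` bases have no genomic
  coordinates, so `genomic_location` covers templated bases only and the
  `cca_overlap` column counts the rest. Re-extracting the located genome
  slice reproduces the templated prefix of the fragment (asserted on both
  strands).
* **tRF-1 3′ boundary.** Only the start is anchored (first trailer base);
  the end may fall anywhere inside the trailer window. No poly-U terminator
  is required — trailer length is bounded by the 40 nt flank instead.
* **Multi-locus hits** are all retained; uniqueness is resolved at catalog
  level, where *entries* are sample-level records and *unique* counts are
  distinct sequences per (species, type). The per-species summary therefore
  carries both `entries_*` and `unique_*` columns, each summing to its own
  total.
* **Highest-frequency extraction.** The per-(fragment, gene) frequencies are
  surfaced in the hits table rather than applying any additional hidden
  frequency cut during mapping; a downstream consumer can apply either a
  per-tRNA or a global top-fragment rule. The run report counts unmapped
  fragments instead.
* **Determinism.** Outputs are sorted (fragments by frequency-then-sequence,
  hits by fragment/ref/position, the catalog by species/type/sequence), so
  reruns on identical inputs are byte-identical.
* **Degenerate inputs.** Empty gene lists and empty libraries produce empty
  outputs with warnings, not errors; a run with zero classified records is a
  success with a warning. Missing files and malformed FASTQ records are hard
  errors naming the path/record.

## What the synthetic generator emulates — and what it does not

`ptrf.simulate` plants 70–90 nt intron-less tRNA genes (isotype/anticodon
pairs drawn from the standard genetic code) in a random 20 kb genome, at
least 120 nt apart and 50 nt from contig ends so flanks never clip, on both
strands. Libraries contain spiked tRF-5/tRF-3/tRF-1 fragments (15–28 nt,
frequencies 120–400, above both thresholds) and decoys per class: internal
fragments, anchors shifted by one base, frequencies exactly 9 (table) and
100 copies (FASTQ), single-substitution copies verified absent from the
reference, reverse complements, random non-tRNA sequences, and — in the
FASTQ rendering only — reads carrying one Q27 base. One `random.Random`
stream per artifact, named from the single plan seed, keeps outputs
byte-stable and insulated from plan extensions. Default sizes (10 genes,
~105 planted fragments, 20 seeds in the acceptance checks) keep the full
suite in seconds while exercising every rule; they are deliberately small.

The generator does **not** emulate sequencing error profiles, ligation or
PCR bias, realistic tRNA sequence structure (covariance-model realism,
modified-base effects), tRNA halves, or multi-copy tRNA families with
shared sequence. Passing spike-recovery therefore demonstrates that the
pipeline's rules are implemented exactly as specified — not that those rules
are robust to real-library noise, nor how multi-family read assignment
should be interpreted biologically. On real data, fragments shared by
several tRNA loci yield one record per locus by design.

Real-data corpus-scale catalog numbers are not reproducible from synthetic
fixtures, and the package makes no claim about them; every number the README
or acceptance script shows is computed at run time by the code in this
repository.

## Known limitations

* Adapter trimming is minimal (leftmost exact adapter occurrence, or an
  adapter prefix ≥ 8 nt at the read's 3′ end); error-tolerant adapter
  alignment, 5′ adapters and paired-end input are out of scope — trim
  upstream with a dedicated tool if needed.
* FASTQ qualities must be Phred+33; Phred+64 data must be converted first.
* Reads containing `N` are discarded (they can never satisfy exact
  matching).
* A mature hit spanning an intron junction lifts to the genomic span from
  first to last templated base (the span then includes the intron); the
  re-extraction identity applies only to junction-free records.
* tRNA halves (30–36 nt), internal tRFs, and target prediction are out of
  scope.
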