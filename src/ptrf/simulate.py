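"""Self-contained synthetic fixtures: toy genomes with planted tRNA genes and
small-RNA libraries with spiked tRFs and decoys.

Every generated fragment carries a ground-truth *fate* — ``kept`` (with its
intended tRF type) or ``rejected:<reason>`` — so the whole pipeline can be
scored against a known answer with no external data.  Decoy classes probe
each rule: internal and off-by-one fragments (anchoring), frequencies exactly
at the failing boundaries 9 and 100 (strict-inequality thresholds),
single-mismatch and reverse-complement copies (100 %-identity, plus-strand
mapping), random non-tRNA sequences, and sub-Q28 reads (FASTQ quality rule).

Randomness discipline: one named ``random.Random`` stream per artifact,
derived from the single plan seed, so adding a decoy kind does not shift
unrelated outputs; identical plan + seed gives byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .errors import PtrfError, ValidationError
from .fragments import SampleMeta
from .reference import TRNAGene, revcomp

DECOY_KINDS = (
    "internal", "off_by_one_5p", "off_by_one_3p", "low_freq",
    "mismatch", "revcomp", "non_trna",
)

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

# (three-letter isotype, anticodon) pairs from the standard genetic code
_ISOACCEPTORS = sorted(
    (seq3(aa), revcomp(codon))
    for codon, aa in standard_dna_table.forward_table.items()
)


@dataclass
class SpikePlan:
    """Parameters of one synthetic study: genome, genes, spikes and decoys."""

    seed: int = 1
    n_contigs: int = 1
    contig_length: int = 20_000
    n_genes: int = 10
    gene_length_range: tuple[int, int] = (70, 90)
    n_trf5: int = 20
    n_trf3: int = 15
    n_trf1: int = 10
    trf_length_range: tuple[int, int] = (15, 28)
    n_decoys: int = 56
    decoy_kinds: tuple[str, ...] = DECOY_KINDS
    freq_range: tuple[int, int] = (120, 400)
    n_low_quality: int = 4
    adapter: str = DEFAULT_ADAPTER
    species: str = "toyplant"

    def __post_init__(self) -> None:
        for name in ("n_contigs", "n_genes", "n_trf5", "n_trf3", "n_trf1",
                     "n_decoys", "n_low_quality"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("gene_length_range", "trf_length_range", "freq_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} is not well-ordered")
        if not (15 <= self.trf_length_range[0] and self.trf_length_range[1] <= 28):
            raise ValidationError("trf_length_range must lie within [15, 28]")
        unknown = set(self.decoy_kinds) - set(DECOY_KINDS)
        if unknown:
            raise ValidationError(f"unknown decoy kinds: {sorted(unknown)}")


@dataclass
class GenomeTruth:
    """Ground truth emitted by make_genome."""

    contigs: dict[str, str]
    genes: list[TRNAGene]
    mature: dict[str, str]    # gene_id -> spliced+CCA mature sequence
    trailer: dict[str, str]   # gene_id -> 40 nt 3' trailer, transcript sense

    def sample(self, species: str) -> SampleMeta:
        return SampleMeta(species=species, tissue="leaf", gsm="GSM0000001",
                          pmid="00000000")


@dataclass
class SpikeItem:
    """One planted fragment and its intended pipeline fate."""

    sequence: str
    frequency: int
    kind: str              # trf5 | trf3 | trf1 | one of DECOY_KINDS | low_quality
    fate: str              # "kept" or "rejected:<reason>"
    trf_type: str | None   # expected type when kept
    gene_id: str
    fastq_copies: int      # copies emitted in the FASTQ rendering


_GENE_MARGIN = 50   # min distance from contig ends (keeps flanks unclipped)
_GENE_GAP = 120     # min distance between genes (keeps pre windows disjoint)


def make_genome(plan: SpikePlan, out_dir: str | Path | None = None) -> GenomeTruth:
    """Random genome with non-overlapping planted tRNA genes on mixed strands.

    Writes ``genome.fa``, ``genes.bed`` and ``truth.json`` when ``out_dir``
    is given.  Deterministic for a fixed plan.
    """
    rng_genome = random.Random(f"{plan.seed}:genome")
    rng_genes = random.Random(f"{plan.seed}:genes")
    contigs = {
        f"contig{i + 1}": "".join(rng_genome.choices("ACGT", k=plan.contig_length))
        for i in range(plan.n_contigs)
    }
    names = sorted(contigs)
    placed: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    genes: list[TRNAGene] = []
    max_attempts = 200 * max(1, plan.n_genes)
    attempts = 0
    for gi in range(plan.n_genes):
        glen = rng_genes.randint(*plan.gene_length_range)
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PtrfError(
                    "could not place non-overlapping genes; "
                    "increase contig_length or reduce n_genes"
                )
            chrom = rng_genes.choice(names)
            start = rng_genes.randint(
                1 + _GENE_MARGIN, plan.contig_length - glen - _GENE_MARGIN
            )
            end = start + glen - 1
            if all(end + _GENE_GAP < a or b + _GENE_GAP < start
                   for a, b in placed[chrom]):
                placed[chrom].append((start, end))
                break
        strand = rng_genes.choice("+-")
        aa, anticodon = rng_genes.choice(_ISOACCEPTORS)
        genes.append(TRNAGene(f"trna{gi + 1}", chrom, start, end, strand,
                              aa, anticodon))
    mature: dict[str, str] = {}
    trailer: dict[str, str] = {}
    for g in genes:
        body = contigs[g.chrom][g.start - 1 : g.end]
        if g.strand == "-":
            body = revcomp(body)
            tr = revcomp(contigs[g.chrom][g.start - 41 : g.start - 1])
        else:
            tr = contigs[g.chrom][g.end : g.end + 40]
        mature[g.gene_id] = body + "CCA"
        trailer[g.gene_id] = tr
    truth = GenomeTruth(contigs, genes, mature, trailer)
    if out_dir is not None:
        _write_genome(truth, Path(out_dir))
    return truth


def _write_genome(truth: GenomeTruth, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for name in sorted(truth.contigs):
            fh.write(f">{name}\n")
            seq = truth.contigs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(out / "genes.bed", "w") as fh:
        for g in truth.genes:
            name = f"{g.gene_id}|{g.amino_acid}|{g.anticodon}"
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{name}\t0\t{g.strand}\n")
    ledger = {
        "genes": [
            {
                "gene_id": g.gene_id, "chrom": g.chrom, "start": g.start,
                "end": g.end, "strand": g.strand, "amino_acid": g.amino_acid,
                "anticodon": g.anticodon,
                "mature_seq": truth.mature[g.gene_id],
                "trailer_seq": truth.trailer[g.gene_id],
            }
            for g in truth.genes
        ]
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1)
        fh.write("\n")


def _reference_strings(truth: GenomeTruth) -> list[str]:
    """Every sequence fragments will be searched against (mature + pre)."""
    refs = []
    for g in truth.genes:
        refs.append(truth.mature[g.gene_id])
        body = truth.mature[g.gene_id][:-3]
        if g.strand == "-":
            lead = revcomp(truth.contigs[g.chrom][g.end : g.end + 40])
        else:
            lead = truth.contigs[g.chrom][g.start - 41 : g.start - 1]
        refs.append(lead + body + truth.trailer[g.gene_id])
    return refs


def make_library(
    plan: SpikePlan,
    truth: GenomeTruth,
    out_dir: str | Path | None = None,
) -> list[SpikeItem]:
    """Spiked tRF-5/3/1 fragments plus decoys, with a complete fate ledger.

    Writes ``frags.tsv``, ``reads.fastq``, ``spikes.json`` and ``samples.tsv``
    when ``out_dir`` is given.  ``low_quality`` items appear only in the FASTQ
    rendering (they are reads destined to fail the quality filter, which the
    fragment-table path never sees).
    """
    if not truth.genes:
        raise ValidationError("truth has no genes to spike from")
    rng = random.Random(f"{plan.seed}:spikes")
    rng_decoy = random.Random(f"{plan.seed}:decoys")
    refs = _reference_strings(truth)
    used: set[str] = set()
    items: list[SpikeItem] = []

    def in_refs(seq: str) -> bool:
        return any(seq in r for r in refs)

    def draw(maker, rng_, *, absent: bool = False, retries: int = 500) -> tuple[str, str]:
        for _ in range(retries):
            seq, gene_id = maker(rng_)
            if seq in used:
                continue
            if absent and in_refs(seq):
                continue
            used.add(seq)
            return seq, gene_id
        raise PtrfError("could not draw a unique spike sequence; relax the plan")

    def pick_gene(rng_) -> TRNAGene:
        return rng_.choice(truth.genes)

    def pick_len(rng_) -> int:
        return rng_.randint(*plan.trf_length_range)

    def freq(rng_) -> int:
        return rng_.randint(*plan.freq_range)

    def mk_trf5(rng_):
        g = pick_gene(rng_)
        return truth.mature[g.gene_id][: pick_len(rng_)], g.gene_id

    def mk_trf3(rng_):
        g = pick_gene(rng_)
        return truth.mature[g.gene_id][-pick_len(rng_):], g.gene_id

    def mk_trf1(rng_):
        g = pick_gene(rng_)
        length = pick_len(rng_)
        tr = truth.trailer[g.gene_id]
        if length > len(tr):
            raise PtrfError(
                f"requested tRF-1 length {length} exceeds trailer length {len(tr)}"
            )
        return tr[:length], g.gene_id

    for _ in range(plan.n_trf5):
        seq, gid = draw(mk_trf5, rng)
        f = freq(rng)
        items.append(SpikeItem(seq, f, "trf5", "kept", "tRF-5", gid, f))
    for _ in range(plan.n_trf3):
        seq, gid = draw(mk_trf3, rng)
        f = freq(rng)
        items.append(SpikeItem(seq, f, "trf3", "kept", "tRF-3", gid, f))
    for _ in range(plan.n_trf1):
        seq, gid = draw(mk_trf1, rng)
        f = freq(rng)
        items.append(SpikeItem(seq, f, "trf1", "kept", "tRF-1", gid, f))

    # --- decoys, round-robin over the requested kinds -----------------------
    def mk_internal(rng_):
        g = pick_gene(rng_)
        m = truth.mature[g.gene_id]
        length = pick_len(rng_)
        i = rng_.randint(1, len(m) - length - 4)  # 0-based: sstart>=2, send<=L-4
        return m[i : i + length], g.gene_id

    def mk_off5(rng_):
        g = pick_gene(rng_)
        return truth.mature[g.gene_id][1 : 1 + pick_len(rng_)], g.gene_id

    def mk_off3(rng_):
        g = pick_gene(rng_)
        length = pick_len(rng_)
        return truth.mature[g.gene_id][-(length + 1) : -1], g.gene_id

    def mk_mismatch(rng_):
        g = pick_gene(rng_)
        length = pick_len(rng_)
        seq = list(truth.mature[g.gene_id][:length])
        pos = rng_.randint(2, length - 3)
        seq[pos] = rng_.choice(sorted(set("ACGT") - {seq[pos]}))
        return "".join(seq), g.gene_id

    def mk_revcomp(rng_):
        g = pick_gene(rng_)
        return revcomp(truth.mature[g.gene_id][: pick_len(rng_)]), g.gene_id

    def mk_non_trna(rng_):
        return "".join(rng_.choices("ACGT", k=pick_len(rng_))), ""

    decoy_spec = {
        "internal": (mk_internal, "rejected:unanchored", False),
        "off_by_one_5p": (mk_off5, "rejected:unanchored", False),
        "off_by_one_3p": (mk_off3, "rejected:unanchored", False),
        "low_freq": (mk_trf5, "rejected:low_frequency", False),
        "mismatch": (mk_mismatch, "rejected:unmapped", True),
        "revcomp": (mk_revcomp, "rejected:unmapped", True),
        "non_trna": (mk_non_trna, "rejected:unmapped", True),
    }
    if plan.decoy_kinds:
        for i in range(plan.n_decoys):
            kind = plan.decoy_kinds[i % len(plan.decoy_kinds)]
            maker, fate, absent = decoy_spec[kind]
            seq, gid = draw(maker, rng_decoy, absent=absent)
            if kind == "low_freq":
                # boundary frequencies pin the strict inequalities: 9 on the
                # table path (>9 required), 100 on the FASTQ path (>100 required)
                items.append(SpikeItem(seq, 9, kind, fate, None, gid, 100))
            else:
                f = freq(rng_decoy)
                items.append(SpikeItem(seq, f, kind, fate, None, gid, f))

    for _ in range(plan.n_low_quality):
        seq, gid = draw(mk_trf5, rng_decoy)
        items.append(SpikeItem(seq, 150, "low_quality", "rejected:low_quality",
                               None, gid, 150))

    if out_dir is not None:
        _write_library(plan, items, Path(out_dir))
    return items


def _write_library(plan: SpikePlan, items: list[SpikeItem], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "frags.tsv", "w") as fh:
        fh.write("sequence\tcount\n")
        for it in items:
            if it.kind != "low_quality":
                fh.write(f"{it.sequence}\t{it.frequency}\n")
    rng_q = random.Random(f"{plan.seed}:fastq")
    reads: list[tuple[str, str]] = []
    for it in items:
        full = it.sequence + plan.adapter
        base_qual = "I" * len(full)  # Q40
        for _ in range(it.fastq_copies):
            if it.kind == "low_quality":
                pos = rng_q.randint(0, len(it.sequence) - 1)
                qual = base_qual[:pos] + "<" + base_qual[pos + 1 :]  # '<' = Q27
            else:
                qual = base_qual
            reads.append((full, qual))
    rng_q.shuffle(reads)
    with open(out / "reads.fastq", "w") as fh:
        for i, (seq, qual) in enumerate(reads, 1):
            fh.write(f"@read{i}\n{seq}\n+\n{qual}\n")
    with open(out / "spikes.json", "w") as fh:
        json.dump([asdict(it) for it in items], fh, indent=1)
        fh.write("\n")
    with open(out / "samples.tsv", "w") as fh:
        fh.write("species\ttissue\tgsm\tpmid\tpath\ttype\tadapter\n")
        # path is relative to this manifest's own directory
        fh.write(f"{plan.species}\tleaf\tGSM0000001\t00000000\t"
                 f"frags.tsv\ttable\t\n")


def kept_set(items: list[SpikeItem]) -> set[tuple[str, str]]:
    """The ground-truth (sequence, tRF type) pairs the pipeline must recover."""
    return {(it.sequence, it.trf_type) for it in items if it.fate == "kept"}
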