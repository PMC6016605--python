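"""Shared fixtures and tiny independent oracles used across the suite."""

from __future__ import annotations

import random

import pytest

from ptrf import Fragment, ReferenceEntry, SampleMeta, TRNAGene
from ptrf.reference import revcomp


@pytest.fixture
def sample() -> SampleMeta:
    return SampleMeta(species="toyplant", tissue="leaf", gsm="GSM0000001",
                      pmid="00000000")


def make_mature_ref(seq: str, gene_id: str = "g1", ref_id: str | None = None,
                    chrom: str = "chr1", start: int = 1001,
                    strand: str = "+") -> ReferenceEntry:
    """A mature-kind entry whose sequence is given directly (ends with CCA
    only if the caller made it so); coordinates are synthesized to match."""
    body_len = len(seq) - 3
    gene = TRNAGene(gene_id, chrom, start, start + body_len - 1, strand,
                    "Ala", "AGC")
    blocks = ((gene.start, gene.end),)
    return ReferenceEntry(
        ref_id=ref_id or f"{gene_id}_mature", kind="mature", sequence=seq,
        gene=gene, mature_length=len(seq), exon_blocks=blocks,
    )


def make_pre_ref(seq: str, trailer_start: int, gene_id: str = "g1",
                 ref_id: str | None = None, chrom: str = "chr1",
                 upstream: int = 40, strand: str = "+") -> ReferenceEntry:
    gene_len = trailer_start - 1 - upstream
    downstream = len(seq) - upstream - gene_len
    start = 2001
    gene = TRNAGene(gene_id, chrom, start, start + gene_len - 1, strand,
                    "Gly", "GCC")
    return ReferenceEntry(
        ref_id=ref_id or f"{gene_id}_pre", kind="pre", sequence=seq, gene=gene,
        trailer_start=trailer_start, upstream=upstream, downstream=downstream,
        window_start=start - (upstream if strand == "+" else downstream),
        window_end=gene.end + (downstream if strand == "+" else upstream),
    )


def make_fragment(seq: str, freq: int = 200,
                  sample: SampleMeta | None = None) -> Fragment:
    return Fragment(seq, freq, sample or SampleMeta(species="toyplant"))


def random_gene_with_genome(rng: random.Random, *, length: int | None = None,
                            strand: str | None = None,
                            n_introns: int = 0,
                            chrom_len: int = 2000) -> tuple[dict, TRNAGene]:
    """A random single-contig genome and one gene placed with full flanks."""
    genome = {"chr1": "".join(rng.choices("ACGT", k=chrom_len))}
    glen = length if length is not None else rng.randint(60, 90)
    start = rng.randint(61, chrom_len - glen - 60)
    end = start + glen - 1
    introns = []
    pos = start + 5
    for _ in range(n_introns):
        a = rng.randint(pos, min(pos + 10, end - 15))
        b = a + rng.randint(3, 10)
        if b >= end - 5:
            break
        introns.append((a, b))
        pos = b + 5
    gene = TRNAGene("g_rand", "chr1", start, end,
                    strand or rng.choice("+-"), "Ala", "AGC", tuple(introns))
    return genome, gene


def brute_force_mature(genome: dict, gene: TRNAGene, splice: bool = True) -> str:
    """Independent splice-and-append oracle, built base by base."""
    bases = []
    intron_positions = set()
    if splice:
        for a, b in gene.introns:
            intron_positions.update(range(a, b + 1))
    for pos in range(gene.start, gene.end + 1):
        if pos not in intron_positions:
            bases.append(genome[gene.chrom][pos - 1])
    seq = "".join(bases).upper()
    if gene.strand == "-":
        seq = revcomp(seq)
    return seq + "CCA"


def brute_force_occurrences(refs, queries):
    """All-positions sliding-window substring scan.

    Returns the set of (query_index, ref_id, sstart) triples, the independent
    oracle for the exact mapper.
    """
    out = set()
    for qi, q in enumerate(queries):
        for ref in refs:
            seq = ref.sequence if hasattr(ref, "sequence") else ref[1]
            rid = ref.ref_id if hasattr(ref, "ref_id") else ref[0]
            for i in range(len(seq) - len(q) + 1):
                if seq[i : i + len(q)] == q:
                    out.add((qi, rid, i + 1))
    return out
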