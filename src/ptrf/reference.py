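"""Combined mature + pre-tRNA reference construction.

Mature tRNA entries are the strand-aware, intron-spliced gene sequence with the
post-transcriptionally added ``CCA`` appended.  Pre-tRNA entries are the
unspliced gene extended by 40 nt flanks on both sides (in transcript
orientation: the upstream flank is 5' of the transcript regardless of genomic
strand), with ``trailer_start`` marking the first base of the 3' trailer.

Coordinates are 1-based inclusive everywhere internally; BED input (0-based
half-open) is converted on read.  Sequences are stored as uppercase DNA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CoordinateError, MissingSequenceError, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_FLANK = 40


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_nt(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class TRNAGene:
    """An annotated tRNA gene locus.

    ``start``/``end`` are 1-based inclusive genomic positions on the plus
    strand (start <= end regardless of transcription strand).  ``introns`` are
    1-based inclusive intervals strictly inside the gene body.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    amino_acid: str
    anticodon: str
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be '+' or '-'")
        anticodon = _normalize_nt(self.anticodon)
        if len(anticodon) != 3 or any(c not in "ACGT" for c in anticodon):
            raise ValidationError(
                f"gene {self.gene_id}: anticodon {self.anticodon!r} is not a 3-mer over ACGT/U"
            )
        object.__setattr__(self, "anticodon", anticodon)
        introns = tuple(sorted((int(a), int(b)) for a, b in self.introns))
        prev_end = None
        for a, b in introns:
            if not (self.start < a <= b < self.end):
                raise ValidationError(
                    f"gene {self.gene_id}: intron {a}-{b} not strictly inside "
                    f"{self.start}-{self.end}"
                )
            if prev_end is not None and a <= prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping introns")
            prev_end = b
        object.__setattr__(self, "introns", introns)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def spliced_length(self) -> int:
        return self.length - sum(b - a + 1 for a, b in self.introns)


@dataclass(frozen=True)
class ReferenceEntry:
    """One sequence in the combined mapping reference.

    ``exon_blocks`` (mature) are genomic (start, end) intervals in transcript
    order; ``window_start``/``window_end`` (pre) delimit the genomic window
    including flanks.  Both exist to lift reference coordinates back to the
    genome.
    """

    ref_id: str
    kind: str  # "mature" | "pre"
    sequence: str
    gene: TRNAGene
    mature_length: int | None = None
    exon_blocks: tuple[tuple[int, int], ...] = ()
    trailer_start: int | None = None
    upstream: int | None = None
    downstream: int | None = None
    window_start: int | None = None
    window_end: int | None = None

    @property
    def location(self) -> str:
        g = self.gene
        if self.kind == "pre":
            return f"{g.chrom}:{self.window_start}-{self.window_end}({g.strand})"
        return f"{g.chrom}:{g.start}-{g.end}({g.strand})"

    def header(self) -> str:
        """FASTA header: ``refid|kind|aa|anticodon|chrom:start-end(strand)``."""
        g = self.gene
        return f"{self.ref_id}|{self.kind}|{g.amino_acid}|{g.anticodon}|{self.location}"


# ---------------------------------------------------------------------------
# genome access helpers (pyfaidx.Fasta or a plain mapping of str sequences)

def _chrom_length(genome, chrom: str) -> int:
    try:
        rec = genome[chrom]
    except KeyError:
        raise MissingSequenceError(f"chromosome {chrom!r} not found in genome")
    return len(rec)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """1-based inclusive plus-strand slice."""
    rec = genome[chrom]
    if isinstance(rec, str):
        return _normalize_nt(rec[start - 1 : end])
    return _normalize_nt(str(rec[start - 1 : end]))


def _check_bounds(gene: TRNAGene, genome) -> int:
    clen = _chrom_length(genome, gene.chrom)
    if gene.end > clen:
        raise CoordinateError(
            f"gene {gene.gene_id}: interval {gene.start}-{gene.end} exceeds "
            f"{gene.chrom} length {clen}"
        )
    return clen


def _exon_blocks_genomic(gene: TRNAGene) -> list[tuple[int, int]]:
    """Exonic intervals (genomic order) left after removing introns."""
    blocks: list[tuple[int, int]] = []
    pos = gene.start
    for a, b in gene.introns:
        if a > pos:
            blocks.append((pos, a - 1))
        pos = b + 1
    if pos <= gene.end:
        blocks.append((pos, gene.end))
    return blocks


def extract_mature(gene: TRNAGene, genome, *, species: str = "", splice: bool = True) -> ReferenceEntry:
    """Build the mature tRNA entry: spliced, strand-oriented, CCA-appended."""
    _check_bounds(gene, genome)
    blocks = _exon_blocks_genomic(gene) if splice else [(gene.start, gene.end)]
    body = "".join(_fetch(genome, gene.chrom, a, b) for a, b in blocks)
    if gene.strand == "-":
        body = revcomp(body)
        blocks = blocks[::-1]  # transcript order: highest genomic coords first
    sequence = body + "CCA"
    return ReferenceEntry(
        ref_id=_ref_id(species, gene.gene_id, "mature"),
        kind="mature",
        sequence=sequence,
        gene=gene,
        mature_length=len(sequence),
        exon_blocks=tuple(blocks),
    )


def extract_pre(
    gene: TRNAGene,
    genome,
    upstream: int = DEFAULT_FLANK,
    downstream: int = DEFAULT_FLANK,
    *,
    species: str = "",
) -> ReferenceEntry:
    """Build the pre-tRNA entry: unspliced gene plus flanks, no CCA.

    Flanks are clipped at chromosome boundaries; actual flank sizes are
    recorded on the entry.  ``trailer_start`` is the 1-based position of the
    first trailer base within the entry sequence.
    """
    if upstream < 0 or downstream < 0:
        raise ValidationError("flank sizes must be >= 0")
    clen = _check_bounds(gene, genome)
    if gene.strand == "+":
        wstart = max(1, gene.start - upstream)
        wend = min(clen, gene.end + downstream)
        actual_up = gene.start - wstart
        actual_down = wend - gene.end
    else:
        wstart = max(1, gene.start - downstream)
        wend = min(clen, gene.end + upstream)
        actual_up = wend - gene.end
        actual_down = gene.start - wstart
    if actual_up < upstream or actual_down < downstream:
        logger.warning(
            "gene %s: flanks clipped at chromosome boundary (upstream %d, downstream %d)",
            gene.gene_id, actual_up, actual_down,
        )
    seq = _fetch(genome, gene.chrom, wstart, wend)
    if gene.strand == "-":
        seq = revcomp(seq)
    return ReferenceEntry(
        ref_id=_ref_id(species, gene.gene_id, "pre"),
        kind="pre",
        sequence=seq,
        gene=gene,
        trailer_start=actual_up + gene.length + 1,
        upstream=actual_up,
        downstream=actual_down,
        window_start=wstart,
        window_end=wend,
    )


def _ref_id(species: str, gene_id: str, kind: str) -> str:
    parts = [p for p in (species, gene_id, kind) if p]
    return "_".join(parts)


def build_reference(
    genes: Sequence[TRNAGene],
    genome,
    *,
    species: str = "",
    upstream: int = DEFAULT_FLANK,
    downstream: int = DEFAULT_FLANK,
    splice: bool = True,
) -> list[ReferenceEntry]:
    """Build the combined reference: one mature + one pre entry per gene.

    Output order is deterministic: input gene order, mature before pre.
    """
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    if not genes:
        logger.warning("empty gene list: building an empty reference")
    entries: list[ReferenceEntry] = []
    for g in genes:
        entries.append(extract_mature(g, genome, species=species, splice=splice))
        entries.append(extract_pre(g, genome, upstream, downstream, species=species))
    return entries


def write_reference_fasta(entries: Iterable[ReferenceEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.header()}\n{e.sequence}\n")


_MANIFEST_COLUMNS = [
    "ref_id", "kind", "gene_id", "amino_acid", "anticodon", "chrom",
    "gene_start", "gene_end", "strand", "length", "mature_length",
    "trailer_start", "upstream", "downstream", "window_start", "window_end",
    "introns", "location",
]


def write_manifest(entries: Iterable[ReferenceEntry], path) -> None:
    """TSV manifest carrying everything needed to classify hits without sequences."""
    with open(path, "w") as fh:
        fh.write("\t".join(_MANIFEST_COLUMNS) + "\n")
        for e in entries:
            g = e.gene
            introns = ",".join(f"{a}-{b}" for a, b in g.introns)
            row = [
                e.ref_id, e.kind, g.gene_id, g.amino_acid, g.anticodon, g.chrom,
                g.start, g.end, g.strand, len(e.sequence),
                e.mature_length if e.mature_length is not None else "",
                e.trailer_start if e.trailer_start is not None else "",
                e.upstream if e.upstream is not None else "",
                e.downstream if e.downstream is not None else "",
                e.window_start if e.window_start is not None else "",
                e.window_end if e.window_end is not None else "",
                introns, e.location,
            ]
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_manifest(path) -> list[ReferenceEntry]:
    """Rebuild sequence-less ReferenceEntry objects from a manifest TSV.

    The returned entries carry empty ``sequence`` strings; they are sufficient
    for classification (which uses coordinates and metadata only).
    """
    entries: list[ReferenceEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")

            def get(col: str) -> str:
                return f[idx[col]]

            introns = tuple(
                tuple(int(x) for x in iv.split("-"))
                for iv in get("introns").split(",") if iv
            )
            gene = TRNAGene(
                gene_id=get("gene_id"), chrom=get("chrom"),
                start=int(get("gene_start")), end=int(get("gene_end")),
                strand=get("strand"), amino_acid=get("amino_acid"),
                anticodon=get("anticodon"), introns=introns,
            )
            kind = get("kind")
            if kind == "mature":
                blocks = _exon_blocks_genomic(gene)
                if gene.strand == "-":
                    blocks = blocks[::-1]
                entries.append(ReferenceEntry(
                    ref_id=get("ref_id"), kind=kind, sequence="", gene=gene,
                    mature_length=int(get("mature_length")),
                    exon_blocks=tuple(blocks),
                ))
            else:
                entries.append(ReferenceEntry(
                    ref_id=get("ref_id"), kind=kind, sequence="", gene=gene,
                    trailer_start=int(get("trailer_start")),
                    upstream=int(get("upstream")), downstream=int(get("downstream")),
                    window_start=int(get("window_start")),
                    window_end=int(get("window_end")),
                ))
    return entries


# ---------------------------------------------------------------------------
# annotation readers

_TRNA_NAME_RE = re.compile(r"tRNA-([A-Za-z]{3})-([ACGTUacgtu]{3})")


def _parse_bed_name(name: str) -> tuple[str, str, str]:
    """gene_id, amino_acid, anticodon from a BED name field.

    Accepts ``id|Aa|NNN`` or GtRNAdb-style ``...tRNA-Ala-AGC...`` names.
    """
    if "|" in name:
        parts = name.split("|")
        if len(parts) != 3:
            raise ValidationError(f"BED name {name!r}: expected 'id|aa|anticodon'")
        return parts[0], parts[1], parts[2]
    m = _TRNA_NAME_RE.search(name)
    if m:
        return name, m.group(1), m.group(2)
    raise ValidationError(
        f"BED name {name!r}: cannot extract isotype/anticodon "
        "(use 'id|aa|anticodon' or a 'tRNA-Ala-AGC' style name)"
    )


def read_bed(path) -> list[TRNAGene]:
    """Read tRNA genes from BED6/BED12 (0-based half-open, converted here).

    BED12 block structure, when present, defines introns as inter-block gaps.
    """
    genes: list[TRNAGene] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValidationError(f"{path}:{ln}: BED needs >= 6 columns")
            chrom, bstart, bend, name, _score, strand = f[:6]
            start, end = int(bstart) + 1, int(bend)
            gene_id, aa, anticodon = _parse_bed_name(name)
            introns: list[tuple[int, int]] = []
            if len(f) >= 12 and int(f[9]) > 1:
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                if len(sizes) != nblocks or len(starts) != nblocks:
                    raise ValidationError(f"{path}:{ln}: malformed BED12 blocks")
                for i in range(nblocks - 1):
                    a = start + starts[i] + sizes[i]       # first intron base
                    b = start + starts[i + 1] - 1          # last intron base
                    introns.append((a, b))
            genes.append(TRNAGene(gene_id, chrom, start, end, strand, aa,
                                  anticodon, tuple(introns)))
    return genes


def read_trnascan(path) -> list[TRNAGene]:
    """Read tRNAscan-SE tabular output (``--output`` dialect).

    Minus-strand genes have begin > end; intron bounds of 0 mean no intron.
    """
    genes: list[TRNAGene] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = [x.strip() for x in line.split("\t")]
            # skip the three header lines (Sequence/Name..., tRNA#..., dashes)
            if len(f) < 8 or not f[2].lstrip("-").isdigit():
                continue
            name, num = f[0], f[1]
            begin, end_ = int(f[2]), int(f[3])
            aa, anticodon = f[4], f[5]
            ib, ie = int(f[6]), int(f[7])
            strand = "+" if begin <= end_ else "-"
            start, end = min(begin, end_), max(begin, end_)
            introns = () if ib == 0 and ie == 0 else ((min(ib, ie), max(ib, ie)),)
            genes.append(TRNAGene(f"{name}.trna{num}", name, start, end, strand,
                                  aa, anticodon, introns))
    return genes
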