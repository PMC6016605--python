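"""tRF type assignment from hit coordinates.

A 15-28 nt fragment is a tRF-5 when it starts at base 1 of a mature tRNA, a
tRF-3 when it ends at the mature 3' terminus (the appended CCA), and a tRF-1
when it starts exactly at the first base of the pre-tRNA 3' trailer.  Hits
anchored at neither end yield nothing.

Reference coordinates are lifted back to the genome strand-aware.  The CCA is
post-transcriptional and has no genomic template, so a tRF-3's genomic
location covers only templated bases; the ``cca_overlap`` field counts the
matched CCA bases.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InternalConsistencyError
from .mapping import Hit
from .reference import ReferenceEntry

logger = logging.getLogger(__name__)

TRF_TYPES = ("tRF-5", "tRF-3", "tRF-1")


@dataclass(frozen=True)
class TRFRecord:
    """A classified tRNA-derived fragment — the unit of the catalog."""

    trf_type: str
    sequence: str
    length: int
    frequency: int
    anticodon: str
    amino_acid: str
    species: str
    tissue: str
    gsm: str
    pmid: str
    genomic_location: str
    source_ref: str
    cca_overlap: int = 0
    ambiguous_full_length: bool = False

    def record_id(self) -> str:
        """Stable id: hash of sequence + type + species."""
        key = f"{self.sequence}|{self.trf_type}|{self.species}".encode()
        return hashlib.sha1(key).hexdigest()[:12]


def _lift_mature(ref: ReferenceEntry, tpos: int) -> int:
    """Genomic position of templated transcript position ``tpos`` (1-based)."""
    cum = 0
    for bs, be in ref.exon_blocks:
        blen = be - bs + 1
        if tpos <= cum + blen:
            off = tpos - cum - 1
            return bs + off if ref.gene.strand == "+" else be - off
        cum += blen
    raise InternalConsistencyError(
        f"{ref.ref_id}: transcript position {tpos} beyond templated region"
    )


def _lift_pre(ref: ReferenceEntry, tpos: int) -> int:
    if ref.gene.strand == "+":
        return ref.window_start + tpos - 1
    return ref.window_end - tpos + 1


def _genomic_location(ref: ReferenceEntry, sstart: int, send: int) -> tuple[str, int]:
    """Location string for the templated part of a hit, and the CCA overlap.

    For mature hits the last three reference bases are the non-genomic CCA;
    positions beyond ``mature_length - 3`` are excluded from the lift-over.
    """
    g = ref.gene
    if ref.kind == "mature":
        templated_end = ref.mature_length - 3
        cca_overlap = max(0, send - templated_end)
        t2 = min(send, templated_end)
        ga, gb = _lift_mature(ref, sstart), _lift_mature(ref, t2)
    else:
        cca_overlap = 0
        ga, gb = _lift_pre(ref, sstart), _lift_pre(ref, send)
    lo, hi = (ga, gb) if ga <= gb else (gb, ga)
    return f"{g.chrom}:{lo}-{hi}({g.strand})", cca_overlap


def classify_hit(hit: Hit, min_len: int = 15, max_len: int = 28) -> TRFRecord | None:
    """Assign a tRF type to one hit, or None if unanchored or out of length.

    A mature hit anchored at both ends (full-length mature tRNA, possible
    only when the mature length is within the tRF range) is classified tRF-5
    with ``ambiguous_full_length`` set.
    """
    frag, ref = hit.fragment, hit.ref
    length = len(frag.sequence)
    if not (min_len <= length <= max_len):
        return None
    ambiguous = False
    if ref.kind == "mature":
        if ref.mature_length is None:
            raise InternalConsistencyError(f"{ref.ref_id}: mature entry lacks mature_length")
        at5 = hit.sstart == 1
        at3 = hit.send == ref.mature_length
        if at5 and at3:
            trf_type, ambiguous = "tRF-5", True
            logger.warning("%s: full-length mature match %s classified tRF-5",
                           ref.ref_id, frag.sequence)
        elif at5:
            trf_type = "tRF-5"
        elif at3:
            trf_type = "tRF-3"
        else:
            return None
    elif ref.kind == "pre":
        if ref.trailer_start is None:
            raise InternalConsistencyError(f"{ref.ref_id}: pre entry lacks trailer_start")
        if hit.sstart != ref.trailer_start:
            return None
        trf_type = "tRF-1"
    else:
        raise InternalConsistencyError(f"{ref.ref_id}: unknown kind {ref.kind!r}")
    location, cca_overlap = _genomic_location(ref, hit.sstart, hit.send)
    s = frag.sample
    return TRFRecord(
        trf_type=trf_type,
        sequence=frag.sequence,
        length=length,
        frequency=frag.frequency,
        anticodon=ref.gene.anticodon,
        amino_acid=ref.gene.amino_acid,
        species=s.species,
        tissue=s.tissue,
        gsm=s.gsm,
        pmid=s.pmid,
        genomic_location=location,
        source_ref=ref.ref_id,
        cca_overlap=cca_overlap,
        ambiguous_full_length=ambiguous,
    )


def classify_all(
    hits: Sequence[Hit],
    min_len: int = 15,
    max_len: int = 28,
    *,
    stats: dict | None = None,
) -> list[TRFRecord]:
    """Classify every hit; one record per hit that anchors at a defined end.

    Hits must already have passed mature/precursor resolution.  Sample
    metadata flows from each fragment; anticodon and isotype flow from the
    reference annotation.
    """
    records: list[TRFRecord] = []
    n_unclassified = 0
    for hit in hits:
        rec = classify_hit(hit, min_len, max_len)
        if rec is None:
            n_unclassified += 1
        else:
            records.append(rec)
    if stats is not None:
        by_type = Counter(r.trf_type for r in records)
        stats.update(
            records_total=len(records),
            hits_unclassified=n_unclassified,
            **{f"records_{t}": by_type.get(t, 0) for t in TRF_TYPES},
        )
    return records


def count_unique(records: Sequence[TRFRecord]) -> dict:
    """Entries-vs-unique accounting.

    ``entries`` counts records (sample-level); ``unique`` counts distinct
    fragment sequences per (species, type).
    """
    entries_by_type = Counter(r.trf_type for r in records)
    unique: dict[tuple[str, str], set[str]] = {}
    for r in records:
        unique.setdefault((r.species, r.trf_type), set()).add(r.sequence)
    return {
        "total_entries": len(records),
        "entries_by_type": dict(entries_by_type),
        "unique_by_species_type": {k: len(v) for k, v in sorted(unique.items())},
    }


_CATALOG_COLUMNS = [
    "species", "trf_type", "sequence", "length", "anticodon", "amino_acid",
    "source_ref", "genomic_location", "cca_overlap", "frequency",
    "tissue", "gsm", "pmid",
]


def sort_records(records: Iterable[TRFRecord]) -> list[TRFRecord]:
    """Canonical catalog order for reproducible diffs."""
    return sorted(records, key=lambda r: (r.species, r.trf_type, r.sequence,
                                          r.source_ref, r.gsm, r.genomic_location))


def write_catalog_tsv(records: Iterable[TRFRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLUMNS) + "\n")
        for r in sort_records(records):
            row = [r.species, r.trf_type, r.sequence, r.length, r.anticodon,
                   r.amino_acid, r.source_ref, r.genomic_location,
                   r.cca_overlap, r.frequency, r.tissue, r.gsm, r.pmid]
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_catalog_fasta(records: Iterable[TRFRecord], path) -> None:
    """One record per unique (sequence, type, species); id is the record hash."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for r in sort_records(records):
            rid = r.record_id()
            if rid in seen:
                continue
            seen.add(rid)
            fh.write(f">{rid} {r.trf_type} {r.species}\n{r.sequence}\n")
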