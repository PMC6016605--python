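"""Exact full-length, plus-strand fragment mapping.

The mapping contract — full query length, 100 % identity, 0 gaps, plus strand
of the reference only — makes heuristic alignment unnecessary: every hit is an
exact substring occurrence.  The index is a k-mer-seeded exact search: each
reference is registered under its k-mers, a query's leading k-mer selects
candidate references, and all occurrences are confirmed with direct substring
scanning.  Queries shorter than the seed fall back to scanning every
reference.  Results are identical to a brute-force all-occurrences scan.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .fragments import Fragment
from .reference import ReferenceEntry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hit:
    """An exact, full-query-length match; 1-based inclusive coordinates."""

    fragment: Fragment
    ref: ReferenceEntry
    sstart: int
    send: int

    def validate(self) -> None:
        n = len(self.fragment.sequence)
        assert self.send - self.sstart + 1 == n
        assert 1 <= self.sstart and self.send <= len(self.ref.sequence)
        assert self.ref.sequence[self.sstart - 1 : self.send] == self.fragment.sequence


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 0-based occurrence starts of needle in haystack (overlaps allowed)."""
    out = []
    i = haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


class SubstringIndex:
    """All-occurrence exact substring lookup over a reference set."""

    def __init__(self, refs: Sequence[ReferenceEntry], k: int = 10):
        if not refs:
            raise ValidationError("cannot index an empty reference set")
        self.k = k
        # refs sorted by ref_id so per-query hit order is deterministic
        self.refs = sorted(refs, key=lambda r: r.ref_id)
        self._kmer_refs: dict[str, list[int]] = defaultdict(list)
        for i, ref in enumerate(self.refs):
            seq = ref.sequence
            seen: set[str] = set()
            for j in range(len(seq) - k + 1):
                kmer = seq[j : j + k]
                if kmer not in seen:
                    seen.add(kmer)
                    self._kmer_refs[kmer].append(i)

    def lookup(self, query: str) -> list[tuple[ReferenceEntry, int]]:
        """All (reference, 1-based start) occurrences, ordered by ref_id then start."""
        if len(query) >= self.k:
            candidates = self._kmer_refs.get(query[: self.k], ())
        else:
            candidates = range(len(self.refs))
        hits = []
        for i in candidates:
            ref = self.refs[i]
            for p in _find_all(ref.sequence, query):
                hits.append((ref, p + 1))
        return hits


def build_index(refs: Sequence[ReferenceEntry], k: int = 10) -> SubstringIndex:
    """Index the combined reference for exact substring search."""
    return SubstringIndex(refs, k=k)


def map_fragments(
    fragments: Iterable[Fragment],
    index: SubstringIndex,
    *,
    stats: dict | None = None,
) -> list[Hit]:
    """Every exact occurrence of every fragment, plus strand only.

    No reverse-complement search is performed: the reference is already in
    transcript orientation, matching the strand-aware database the mapping
    contract assumes.  Ordering: fragment input order, then ref_id, then
    sstart.  Unmapped fragments yield no hits (tallied in ``stats``).
    """
    hits: list[Hit] = []
    n_mapped = n_unmapped = 0
    for frag in fragments:
        occ = index.lookup(frag.sequence)
        if occ:
            n_mapped += 1
            for ref, sstart in occ:
                hits.append(Hit(frag, ref, sstart, sstart + len(frag.sequence) - 1))
        else:
            n_unmapped += 1
    if stats is not None:
        stats.update(fragments_mapped=n_mapped, fragments_unmapped=n_unmapped,
                     hits_total=len(hits))
    return hits


def resolve_mature_precursor(hits: Sequence[Hit], *, stats: dict | None = None) -> list[Hit]:
    """Discard pre-tRNA hits shadowed by a same-gene mature hit.

    A pre-tRNA contains its mature sequence (except the CCA), so a fragment
    matching the mature body of gene X necessarily also matches gene X's pre
    entry; only the mature hit is kept.  Resolution is gene-local: a mature
    hit on gene X never suppresses a pre hit on a different gene.  Fragments
    hitting only pre entries (e.g. trailer-derived) keep those hits.
    """
    mature_genes: dict[tuple, set[str]] = defaultdict(set)

    def key(h: Hit):
        return (h.fragment.sequence, h.fragment.sample)

    for h in hits:
        if h.ref.kind == "mature":
            mature_genes[key(h)].add(h.ref.gene.gene_id)
    resolved = [
        h for h in hits
        if not (h.ref.kind == "pre" and h.ref.gene.gene_id in mature_genes.get(key(h), ()))
    ]
    if stats is not None:
        stats.update(hits_after_resolution=len(resolved),
                     hits_shadowed_by_mature=len(hits) - len(resolved))
    return resolved


def write_hits_tsv(hits: Iterable[Hit], path) -> None:
    """Hits TSV; column order is part of the interface."""
    with open(path, "w") as fh:
        fh.write("sequence\tfrequency\tref_id\tkind\tsstart\tsend\n")
        for h in hits:
            fh.write(
                f"{h.fragment.sequence}\t{h.fragment.frequency}\t"
                f"{h.ref.ref_id}\t{h.ref.kind}\t{h.sstart}\t{h.send}\n"
            )
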