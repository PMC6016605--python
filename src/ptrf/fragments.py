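"""Small-RNA input: unique-fragment tables and raw FASTQ reads.

Two dataset shapes are supported, each with its own filter defaults:

* unique-fragment tables (``sequence<TAB>count``): keep length 15-28 nt and
  clonal frequency > 9 (i.e. >= 10);
* raw FASTQ: optional 3'-adapter trim, discard any read with a base below
  Q28 anywhere, collapse to unique sequences, keep length 15-100 nt and
  frequency > 100 (i.e. >= 101).  The tighter 15-28 nt tRF length rule is
  applied later, at classification.

Qualities are Phred+33 (Sanger / Illumina 1.8+); Phred+64 input must be
converted upstream.  Reads containing N are discarded: they can never pass the
100 %-identity mapping contract.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import FastqFormatError, ValidationError

logger = logging.getLogger(__name__)

_DNA = set("ACGT")


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one small-RNA library."""

    species: str
    tissue: str = ""
    gsm: str = ""
    pmid: str = ""

    def __post_init__(self) -> None:
        if not self.species:
            raise ValidationError("sample species must be non-empty")


@dataclass(frozen=True)
class Fragment:
    """A unique small-RNA sequence with its clonal frequency."""

    sequence: str
    frequency: int
    sample: SampleMeta

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValidationError("fragment frequency must be >= 1")
        if not self.sequence or any(c not in _DNA for c in self.sequence):
            raise ValidationError(f"fragment sequence {self.sequence!r} not over ACGT")


def _normalize(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def _sorted_fragments(counts: Counter, sample: SampleMeta) -> list[Fragment]:
    """Deterministic output: frequency descending, then sequence ascending."""
    return [
        Fragment(seq, freq, sample)
        for seq, freq in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def load_fragment_table(
    path,
    sample: SampleMeta,
    min_len: int = 15,
    max_len: int = 28,
    min_freq: int = 10,
    *,
    stats: dict | None = None,
) -> list[Fragment]:
    """Load a ``sequence<TAB>count`` table, collapse, and filter.

    Keeps fragments with min_len <= length <= max_len and frequency >=
    min_freq (the default 10 encodes clonal frequency > 9).  Rows with
    non-ACGTU characters or unparseable counts are skipped, counted and
    logged.  U is normalized to T.
    """
    counts: Counter = Counter()
    n_rows = n_bad = 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                parts = line.split()
            if len(parts) < 2:
                n_bad += 1
                logger.warning("%s:%d: cannot parse row", path, ln)
                continue
            seq, cnt = _normalize(parts[0]), parts[1].strip()
            if not cnt.isdigit():
                if ln == 1:  # header row
                    continue
                n_bad += 1
                logger.warning("%s:%d: non-integer count %r", path, ln, cnt)
                continue
            if not seq or any(c not in _DNA for c in seq):
                n_bad += 1
                logger.warning("%s:%d: non-ACGTU sequence", path, ln)
                continue
            n_rows += 1
            counts[seq] += int(cnt)
    kept = {
        s: f for s, f in counts.items()
        if min_len <= len(s) <= max_len and f >= min_freq
    }
    if stats is not None:
        stats.update(
            rows_parsed=n_rows,
            rows_rejected=n_bad,
            unique_collapsed=len(counts),
            filtered_out=len(counts) - len(kept),
            fragments_kept=len(kept),
        )
    return _sorted_fragments(Counter(kept), sample)


def trim_adapter(sequence: str, quality: str | None, adapter: str):
    """Remove a 3' adapter suffix; quality is trimmed in lockstep.

    The suffix starting at the leftmost exact occurrence of the full adapter
    is removed; failing that, an adapter *prefix* of length >= 8 anchored at
    the read's 3' end is removed.  Reads without the adapter are returned
    unchanged.
    """
    if not adapter:
        raise ValidationError("adapter must be non-empty when trimming is enabled")
    cut = sequence.find(adapter)
    if cut < 0:
        cut = len(sequence)
        for k in range(min(len(adapter) - 1, len(sequence)), 7, -1):
            if sequence.endswith(adapter[:k]):
                cut = len(sequence) - k
                break
    trimmed = sequence[:cut]
    return (trimmed, quality[:cut] if quality is not None else None)


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_fastq(
    path,
    sample: SampleMeta,
    min_q: int = 28,
    min_len: int = 15,
    max_len: int = 100,
    min_freq: int = 101,
    *,
    adapter: str | None = None,
    stats: dict | None = None,
) -> list[Fragment]:
    """Load FASTQ reads, trim, quality-filter, collapse and frequency-filter.

    A read is discarded if any base quality is below min_q (default 28,
    applied after adapter trimming) or if it contains N.  Survivors are
    collapsed to unique sequences; fragments with length in [min_len, max_len]
    and frequency >= min_freq (default 101, encoding frequency > 100) are kept.
    """
    counts: Counter = Counter()
    n_reads = n_lowq = n_with_n = 0
    with _open_text(path) as fh:
        records = SeqIO.parse(fh, "fastq")
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise FastqFormatError(f"{path}: record {index}: {exc}") from exc
            index += 1
            n_reads += 1
            seq = _normalize(str(rec.seq))
            quals = rec.letter_annotations["phred_quality"]
            if adapter:
                cut_seq, _ = trim_adapter(seq, None, adapter)
                quals = quals[: len(cut_seq)]
                seq = cut_seq
            if not seq:
                continue
            if any(q < min_q for q in quals):
                n_lowq += 1
                continue
            if any(c not in _DNA for c in seq):
                n_with_n += 1
                continue
            counts[seq] += 1
    kept = {
        s: f for s, f in counts.items()
        if min_len <= len(s) <= max_len and f >= min_freq
    }
    if stats is not None:
        stats.update(
            reads_total=n_reads,
            reads_low_quality=n_lowq,
            reads_with_ambiguous_bases=n_with_n,
            unique_collapsed=len(counts),
            filtered_out=len(counts) - len(kept),
            fragments_kept=len(kept),
        )
    return _sorted_fragments(Counter(kept), sample)


def write_fragment_tsv(fragments, path, *, provenance: dict | None = None) -> None:
    """Write collapsed fragments with applied-filter provenance columns."""
    prov = ";".join(f"{k}={v}" for k, v in (provenance or {}).items())
    with open(path, "w") as fh:
        fh.write("sequence\tfrequency\tspecies\ttissue\tgsm\tpmid\tfilters\n")
        for fr in fragments:
            s = fr.sample
            fh.write(
                f"{fr.sequence}\t{fr.frequency}\t{s.species}\t{s.tissue}\t"
                f"{s.gsm}\t{s.pmid}\t{prov}\n"
            )
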