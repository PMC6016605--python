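"""End-to-end orchestration: reference → filter → map → resolve → classify →
summarize, with a machine-readable run report.

The report's per-stage counts telescope: each stage's output count is the
next stage's input.  All outputs are sorted deterministically, so two runs on
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .classify import (
    TRF_TYPES,
    TRFRecord,
    classify_all,
    sort_records,
    write_catalog_fasta,
    write_catalog_tsv,
)
from .errors import PtrfError, ValidationError
from .fragments import SampleMeta, load_fastq, load_fragment_table, write_fragment_tsv
from .mapping import build_index, map_fragments, resolve_mature_precursor, write_hits_tsv
from .reference import build_reference, read_bed, read_trnascan, write_manifest, write_reference_fasta

logger = logging.getLogger(__name__)

LENGTH_BINS = range(15, 29)  # fixed 15-28 nt histogram range


@dataclass
class SampleSpec:
    """One library to process: where it lives and how to read it."""

    path: str
    kind: str  # "table" | "fastq"
    meta: SampleMeta
    adapter: str | None = None


@dataclass
class PipelineConfig:
    genome: str
    annotations: str
    samples: list[SampleSpec]
    out_dir: str
    species: str = ""
    annotation_format: str = "auto"  # auto | bed | trnascan
    upstream: int = 40
    downstream: int = 40
    splice: bool = True
    min_len: int = 15
    max_len: int = 28
    min_frag_freq: int = 10
    min_read_freq: int = 101
    min_q: int = 28
    fastq_max_len: int = 100


def _load_genes(config: PipelineConfig):
    path = Path(config.annotations)
    if not path.exists():
        raise PtrfError(f"annotation file not found: {path}")
    fmt = config.annotation_format
    if fmt == "auto":
        fmt = "bed" if path.suffix.lower() in (".bed",) else "trnascan"
    return read_bed(path) if fmt == "bed" else read_trnascan(path)


def _load_sample(spec: SampleSpec, config: PipelineConfig, stats: dict):
    if not Path(spec.path).exists():
        raise PtrfError(f"sample file not found: {spec.path}")
    if spec.kind == "table":
        return load_fragment_table(
            spec.path, spec.meta, config.min_len, config.max_len,
            config.min_frag_freq, stats=stats,
        )
    if spec.kind == "fastq":
        return load_fastq(
            spec.path, spec.meta, config.min_q, config.min_len,
            config.fastq_max_len, config.min_read_freq,
            adapter=spec.adapter, stats=stats,
        )
    raise ValidationError(f"unknown sample kind {spec.kind!r}")


def run_pipeline(config: PipelineConfig) -> tuple[list[TRFRecord], pd.DataFrame, dict]:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns (classified records, per-species summary, run report).  Zero
    classified records is a success with a warning, not an error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not Path(config.genome).exists():
        raise PtrfError(f"genome file not found: {config.genome}")
    report: dict = {
        "tool": "ptrf",
        "version": __version__,
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "parameters": {
            "upstream": config.upstream, "downstream": config.downstream,
            "splice": config.splice, "min_len": config.min_len,
            "max_len": config.max_len, "min_frag_freq": config.min_frag_freq,
            "min_read_freq": config.min_read_freq, "min_q": config.min_q,
            "fastq_max_len": config.fastq_max_len,
        },
        "samples": [],
    }

    genes = _load_genes(config)
    genome = Fasta(str(config.genome))
    entries = build_reference(
        genes, genome, species=config.species,
        upstream=config.upstream, downstream=config.downstream,
        splice=config.splice,
    )
    write_reference_fasta(entries, out / "reference.fa")
    write_manifest(entries, out / "reference_manifest.tsv")
    report["reference"] = {"genes": len(genes), "entries": len(entries)}
    index = build_index(entries) if entries else None

    all_records: list[TRFRecord] = []
    all_hits = []
    for spec in config.samples:
        stats: dict = {"path": str(spec.path), "kind": spec.kind,
                       "species": spec.meta.species, "gsm": spec.meta.gsm}
        fragments = _load_sample(spec, config, stats)
        tag = spec.meta.gsm or Path(spec.path).stem
        write_fragment_tsv(fragments, out / f"fragments.{tag}.tsv",
                           provenance=report["parameters"])
        if index is None:
            stats.update(fragments_mapped=0, fragments_unmapped=len(fragments),
                         hits_total=0, hits_after_resolution=0,
                         hits_shadowed_by_mature=0, records_total=0,
                         hits_unclassified=0,
                         **{f"records_{t}": 0 for t in TRF_TYPES})
            report["samples"].append(stats)
            continue
        hits = map_fragments(fragments, index, stats=stats)
        resolved = resolve_mature_precursor(hits, stats=stats)
        records = classify_all(resolved, config.min_len, config.max_len, stats=stats)
        all_hits.extend(resolved)
        all_records.extend(records)
        report["samples"].append(stats)

    write_hits_tsv(all_hits, out / "hits.tsv")
    write_catalog_tsv(all_records, out / "catalog.tsv")
    write_catalog_fasta(all_records, out / "catalog.fa")
    summary, length_hist = summarize(all_records)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    length_hist.to_csv(out / "length_histogram.tsv", sep="\t", index=False)
    report["totals"] = {
        "records_total": len(all_records),
        **{f"records_{t}": sum(1 for r in all_records if r.trf_type == t)
           for t in TRF_TYPES},
    }
    report["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
        fh.write("\n")
    if not all_records:
        logger.warning("pipeline finished with zero classified tRF records")
    return sort_records(all_records), summary, report


def _records_frame(records: list[TRFRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species, "trf_type": r.trf_type,
                "sequence": r.sequence, "length": r.length,
            }
            for r in records
        ],
        columns=["species", "trf_type", "sequence", "length"],
    )


def summarize(records_or_df) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species summary and 15-28 nt length histograms.

    The summary has both per-type *entry* counts (sample-level records) and
    per-type *unique* counts (distinct sequences per species and type), so
    entries_* sum to total_entries and unique_* sum to total_unique.  The
    histogram counts unique (species, type, sequence) triples per length, on
    a fixed 15-28 bin range regardless of the data.
    """
    if isinstance(records_or_df, pd.DataFrame):
        df = records_or_df
    else:
        df = _records_frame(list(records_or_df))
    rows = []
    for species in sorted(df["species"].unique()):
        sub = df[df["species"] == species]
        row = {"species": species, "total_entries": len(sub)}
        for t in TRF_TYPES:
            tsub = sub[sub["trf_type"] == t]
            row[f"entries_{t}"] = len(tsub)
            row[f"unique_{t}"] = tsub["sequence"].nunique()
        # unique is (species, type, sequence)-level, so the total is the
        # per-type sum (a sequence seen as two types counts once per type)
        row["total_unique"] = sum(row[f"unique_{t}"] for t in TRF_TYPES)
        rows.append(row)
    columns = (["species", "total_entries", "total_unique"]
               + [f"entries_{t}" for t in TRF_TYPES]
               + [f"unique_{t}" for t in TRF_TYPES])
    summary = pd.DataFrame(rows, columns=columns)

    hist_rows = []
    uniq = df.drop_duplicates(["species", "trf_type", "sequence"])
    for species in sorted(df["species"].unique()):
        for t in TRF_TYPES:
            sub = uniq[(uniq["species"] == species) & (uniq["trf_type"] == t)]
            counts = sub["length"].value_counts()
            for L in LENGTH_BINS:
                hist_rows.append({"species": species, "trf_type": t,
                                  "length": L, "unique_trfs": int(counts.get(L, 0))})
    length_hist = pd.DataFrame(
        hist_rows, columns=["species", "trf_type", "length", "unique_trfs"]
    )
    return summary, length_hist


def plot_length_histogram(length_hist: pd.DataFrame, path) -> None:
    """Bar plot of unique tRFs per length (15-28 nt), stacked by type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = (length_hist.groupby(["length", "trf_type"])["unique_trfs"]
             .sum().unstack(fill_value=0).reindex(list(LENGTH_BINS), fill_value=0))
    ax = pivot.plot(kind="bar", stacked=True, figsize=(8, 4))
    ax.set_xlabel("fragment length (nt)")
    ax.set_ylabel("unique tRFs")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)


def read_samples_tsv(path) -> list[SampleSpec]:
    """Samples manifest: species, tissue, gsm, pmid, path, type[, adapter]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    specs = []
    base = Path(path).parent
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        specs.append(SampleSpec(
            path=str(p), kind=row.get("type", "table") or "table",
            meta=SampleMeta(species=row["species"], tissue=row.get("tissue", ""),
                            gsm=row.get("gsm", ""), pmid=row.get("pmid", "")),
            adapter=row.get("adapter", "") or None,
        ))
    return specs
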