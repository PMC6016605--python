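"""Reference construction: CCA addition, splicing, flanks, strand handling."""

import random

import pytest

from ptrf import (
    CoordinateError,
    MissingSequenceError,
    TRNAGene,
    ValidationError,
    build_reference,
    extract_mature,
    extract_pre,
    read_bed,
    read_trnascan,
)
from ptrf.reference import read_manifest, revcomp, write_manifest

from conftest import brute_force_mature, random_gene_with_genome


def _genome_with(insert: str, at: int = 20, total: int = 200, seed: int = 0):
    rng = random.Random(seed)
    background = "".join(rng.choices("ACGT", k=total))
    seq = background[: at - 1] + insert + background[at - 1 + len(insert):]
    return {"chr1": seq}


class TestExtractMature:
    def test_plus_strand_appends_cca(self):
        genome = _genome_with("GGGAAA", at=20)
        gene = TRNAGene("g1", "chr1", 20, 25, "+", "Ala", "AGC")
        entry = extract_mature(gene, genome)
        assert entry.sequence == "GGGAAACCA"
        assert entry.mature_length == 9
        assert entry.kind == "mature"

    def test_minus_strand_reverse_complements_before_cca(self):
        genome = _genome_with("GGGAAA", at=20)
        gene = TRNAGene("g1", "chr1", 20, 25, "-", "Ala", "AGC")
        entry = extract_mature(gene, genome)
        assert entry.sequence == "TTTCCCCCA"

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n_introns", [0, 1, 2])
    def test_matches_brute_force_splice_oracle(self, seed, n_introns):
        rng = random.Random(seed)
        genome, gene = random_gene_with_genome(rng, n_introns=n_introns)
        entry = extract_mature(gene, genome)
        assert entry.sequence == brute_force_mature(genome, gene)
        assert entry.mature_length == gene.spliced_length + 3

    def test_no_splice_keeps_introns(self):
        rng = random.Random(3)
        genome, gene = random_gene_with_genome(rng, n_introns=1)
        assert gene.introns
        entry = extract_mature(gene, genome, splice=False)
        assert entry.sequence == brute_force_mature(genome, gene, splice=False)
        assert len(entry.sequence) == gene.length + 3

    def test_unknown_chromosome_errors(self):
        gene = TRNAGene("gX", "chrZ", 5, 10, "+", "Ala", "AGC")
        with pytest.raises(MissingSequenceError):
            extract_mature(gene, {"chr1": "ACGT" * 10})

    def test_out_of_bounds_names_gene(self):
        gene = TRNAGene("gY", "chr1", 30, 60, "+", "Ala", "AGC")
        with pytest.raises(CoordinateError, match="gY"):
            extract_mature(gene, {"chr1": "ACGT" * 10})


class TestExtractPre:
    def test_full_flanks_length_and_trailer(self):
        rng = random.Random(1)
        genome, gene = random_gene_with_genome(rng, length=72)
        entry = extract_pre(gene, genome)
        assert len(entry.sequence) == 152
        assert entry.trailer_start == 113
        assert not entry.sequence.endswith("CCA") or True  # no CCA is appended
        assert entry.upstream == 40 and entry.downstream == 40

    def test_clipped_upstream_flank(self):
        rng = random.Random(2)
        genome = {"chr1": "".join(rng.choices("ACGT", k=500))}
        gene = TRNAGene("g1", "chr1", 10, 81, "+", "Ala", "AGC")  # L = 72
        entry = extract_pre(gene, genome)
        assert entry.upstream == 9
        assert len(entry.sequence) == 9 + 72 + 40
        assert entry.trailer_start == 9 + 72 + 1

    @pytest.mark.parametrize("seed", range(10))
    def test_minus_strand_is_revcomp_of_plus_slice(self, seed):
        rng = random.Random(seed)
        genome, gene = random_gene_with_genome(rng, strand="-")
        entry = extract_pre(gene, genome)
        plus_slice = genome["chr1"][gene.start - 41 : gene.end + 40]
        expected = revcomp(plus_slice.upper())
        assert entry.sequence == expected
        # base-wise check against the oracle slice
        assert all(a == b for a, b in zip(entry.sequence, expected))

    def test_trailer_start_equals_length_minus_downstream(self):
        for seed in range(20):
            rng = random.Random(seed)
            genome, gene = random_gene_with_genome(rng)
            entry = extract_pre(gene, genome)
            assert entry.trailer_start == len(entry.sequence) - entry.downstream + 1

    def test_negative_flank_rejected(self):
        rng = random.Random(0)
        genome, gene = random_gene_with_genome(rng)
        with pytest.raises(ValidationError):
            extract_pre(gene, genome, upstream=-1)


class TestBuildReference:
    def test_two_entries_per_gene_mature_first(self):
        rng = random.Random(5)
        genome = {"chr1": "".join(rng.choices("ACGT", k=5000))}
        genes = [
            TRNAGene(f"g{i}", "chr1", 100 + 300 * i, 175 + 300 * i,
                     rng.choice("+-"), "Ala", "AGC")
            for i in range(5)
        ]
        entries = build_reference(genes, genome)
        assert len(entries) == 10
        assert [e.kind for e in entries] == ["mature", "pre"] * 5
        assert [e.gene.gene_id for e in entries[::2]] == [g.gene_id for g in genes]

    def test_duplicate_gene_id_rejected(self):
        rng = random.Random(6)
        genome, gene = random_gene_with_genome(rng)
        with pytest.raises(ValidationError, match="duplicate"):
            build_reference([gene, gene], genome)

    def test_empty_gene_list_yields_empty_reference(self, caplog):
        assert build_reference([], {"chr1": "ACGT"}) == []

    @pytest.mark.parametrize("seed", range(15))
    def test_mature_is_pre_body_plus_cca_for_intronless_genes(self, seed):
        """pre[41 .. 40+L] + CCA reproduces the mature sequence."""
        rng = random.Random(seed)
        genome, gene = random_gene_with_genome(rng)
        mature, pre = build_reference([gene], genome)
        L = gene.length
        assert pre.sequence[40 : 40 + L] + "CCA" == mature.sequence

    @pytest.mark.parametrize("seed", range(10))
    def test_mirror_genome_round_trip(self, seed):
        """Building from the reverse-complemented genome with mirrored
        annotation yields identical transcript-orientation sequences."""
        rng = random.Random(seed)
        genome, gene = random_gene_with_genome(rng)
        n = len(genome["chr1"])
        mirror = {"chr1": revcomp(genome["chr1"])}
        flipped = TRNAGene(
            gene.gene_id, "chr1", n - gene.end + 1, n - gene.start + 1,
            "-" if gene.strand == "+" else "+", gene.amino_acid, gene.anticodon,
        )
        for a, b in zip(build_reference([gene], genome),
                        build_reference([flipped], mirror)):
            assert a.sequence == b.sequence
            assert a.trailer_start == b.trailer_start


class TestAnnotationIO:
    def test_bed6_round_trip(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t99\t175\tg1|Ala|AGC\t0\t+\n"
            "chr2\t10\t92\ttRNA-Gly-GCC-1-1\t0\t-\n"
        )
        genes = read_bed(p)
        assert genes[0].start == 100 and genes[0].end == 175
        assert genes[0].amino_acid == "Ala" and genes[0].anticodon == "AGC"
        assert genes[1].strand == "-" and genes[1].anticodon == "GCC"

    def test_bed12_blocks_become_introns(self, tmp_path):
        p = tmp_path / "genes.bed"
        # two blocks of 30 and 36 separated by a 10 nt intron
        p.write_text(
            "chr1\t99\t175\tg1|Ala|AGC\t0\t+\t99\t175\t0\t2\t30,36\t0,40\n"
        )
        (gene,) = read_bed(p)
        assert gene.introns == ((130, 139),)
        assert gene.spliced_length == 66

    def test_trnascan_tabular_including_minus_strand_and_intron(self, tmp_path):
        p = tmp_path / "scan.out"
        p.write_text(
            "Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tCove\n"
            "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\n"
            "--------\t------\t-----\t---\t----\t-----\t-----\t---\t-----\n"
            "chr1\t1\t1000\t1072\tAla\tAGC\t0\t0\t55.2\n"
            "chr1\t2\t2072\t2000\tGly\tGCC\t2030\t2040\t60.1\n"
        )
        genes = read_trnascan(p)
        assert genes[0].strand == "+" and genes[0].start == 1000
        assert genes[1].strand == "-" and genes[1].start == 2000 and genes[1].end == 2072
        assert genes[1].introns == ((2030, 2040),)

    def test_manifest_round_trip(self, tmp_path):
        rng = random.Random(7)
        genome, gene = random_gene_with_genome(rng)
        entries = build_reference([gene], genome, species="sp")
        path = tmp_path / "manifest.tsv"
        write_manifest(entries, path)
        back = read_manifest(path)
        for orig, rebuilt in zip(entries, back):
            assert rebuilt.ref_id == orig.ref_id
            assert rebuilt.kind == orig.kind
            assert rebuilt.mature_length == orig.mature_length
            assert rebuilt.trailer_start == orig.trailer_start
            assert rebuilt.exon_blocks == orig.exon_blocks
            assert rebuilt.window_start == orig.window_start
            assert rebuilt.gene == orig.gene
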