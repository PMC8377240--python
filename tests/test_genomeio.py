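"""Genome/FASTA/FASTQ/BED/VCF I/O and interval algebra."""
import pytest

from conftest import bitmap_cover, intervals_from_bitmap, random_intervals
from mcrkit.genomeio import (
    FastaFormatError,
    Genome,
    Interval,
    PairedRead,
    VariantRecord,
    coverage_fraction,
    extract_variants_in_regions,
    interval_algebra,
    intersect_intervals,
    merge_intervals,
    read_bed,
    read_fasta,
    read_read_pairs,
    write_bed,
    write_read_pairs,
    write_vcf,
    read_vcf,
)


class TestFasta:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACGT\n")
        g = read_fasta(p)
        assert g.names == ["chr1"]
        assert g.length("chr1") == 4

    def test_lowercase_uppercased_and_order_preserved(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">b\nacgtn\n>a\nTTTT\n")
        g = read_fasta(p)
        assert g.names == ["b", "a"]
        assert g.seq("b") == "ACGTN"

    def test_illegal_base_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACXGT\n")
        with pytest.raises(FastaFormatError, match="X"):
            read_fasta(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("ACGT\n")
        with pytest.raises(FastaFormatError, match="line 1"):
            read_fasta(p)

    def test_roundtrip(self, small_genome, tmp_path):
        p = tmp_path / "g.fa"
        small_genome.to_fasta(p)
        g2 = read_fasta(p)
        assert g2.names == small_genome.names
        assert all(g2.seq(n) == small_genome.seq(n) for n in g2.names)


class TestFastq:
    def test_pair_files_have_four_lines_each(self, tmp_path):
        pairs = [PairedRead("r0", "A" * 75, "I" * 75, "C" * 75, "I" * 75)]
        write_read_pairs(pairs, tmp_path / "1.fq", tmp_path / "2.fq")
        assert len((tmp_path / "1.fq").read_text().splitlines()) == 4
        assert len((tmp_path / "2.fq").read_text().splitlines()) == 4

    def test_zero_pairs_give_empty_files(self, tmp_path):
        write_read_pairs([], tmp_path / "1.fq", tmp_path / "2.fq")
        assert (tmp_path / "1.fq").read_text() == ""
        assert (tmp_path / "2.fq").read_text() == ""

    def test_roundtrip_reproduces_sequences(self, tmp_path, rng):
        pairs = [
            PairedRead(
                f"r{i}",
                "".join(rng.choice(list("ACGT"), 50)),
                "".join(chr(33 + int(q)) for q in rng.integers(2, 41, 50)),
                "".join(rng.choice(list("ACGT"), 50)),
                "J" * 50,
            )
            for i in range(20)
        ]
        write_read_pairs(pairs, tmp_path / "1.fq", tmp_path / "2.fq")
        back = read_read_pairs(tmp_path / "1.fq", tmp_path / "2.fq")
        assert [(p.name, p.seq1, p.qual1, p.seq2) for p in back] == [
            (p.name, p.seq1, p.qual1, p.seq2) for p in pairs
        ]

    def test_length_mismatch_rejected(self, tmp_path):
        bad = [PairedRead("r", "ACGT", "III", "ACGT", "IIII")]
        with pytest.raises(ValueError, match="mismatch"):
            write_read_pairs(bad, tmp_path / "1.fq", tmp_path / "2.fq")


class TestIntervalAlgebra:
    def test_union_and_coverage_arithmetic(self):
        g = Genome([("c", "A" * 100)])
        u = interval_algebra(
            [Interval("c", 0, 10)], [Interval("c", 5, 15)], "union", g
        )
        assert u == [Interval("c", 0, 15)]
        assert coverage_fraction(u, g) == pytest.approx(0.15)

    def test_intersect_disjoint_is_empty(self):
        assert intersect_intervals([Interval("c", 0, 10)], [Interval("c", 20, 30)]) == []

    def test_out_of_bounds_rejected(self):
        g = Genome([("c", "A" * 100)])
        with pytest.raises(Exception, match="exceeds"):
            interval_algebra([Interval("c", 0, 101)], [], "union", g)

    def test_union_is_sorted_minimal_nonoverlapping(self, rng):
        lengths = {"c1": 10_000, "c2": 5_000}
        ivs = random_intervals(rng, lengths, 60)
        u = merge_intervals(ivs)
        for a, b in zip(u, u[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start  # gaps strictly positive: minimal

    @pytest.mark.parametrize("mode", ["union", "intersect", "subtract"])
    def test_matches_bitmap_oracle(self, rng, mode):
        lengths = {"c1": 10_000, "c2": 5_000}
        for _ in range(15):
            a = random_intervals(rng, lengths, int(rng.integers(0, 30)))
            b = random_intervals(rng, lengths, int(rng.integers(1, 30)))
            got = interval_algebra(a, b, mode)
            ba, bb = bitmap_cover(a, lengths), bitmap_cover(b, lengths)
            if mode == "union":
                exp = {n: ba[n] | bb[n] for n in lengths}
            elif mode == "intersect":
                exp = {n: ba[n] & bb[n] for n in lengths}
            else:
                exp = {n: ba[n] & ~bb[n] for n in lengths}
            assert got == intervals_from_bitmap(exp)

    def test_coverage_matches_bitmap(self, rng):
        lengths = {"c1": 10_000, "c2": 5_000}
        g = Genome([("c1", "A" * 10_000), ("c2", "A" * 5_000)])
        ivs = random_intervals(rng, lengths, 40)
        bm = bitmap_cover(ivs, lengths)
        exp = sum(m.sum() for m in bm.values()) / 15_000
        assert coverage_fraction(ivs, g) == pytest.approx(exp)


class TestVariantRecords:
    def test_validation(self):
        with pytest.raises(ValueError):
            VariantRecord("c", 5, "A", "A")
        with pytest.raises(ValueError):
            VariantRecord("c", 5, "A", "N")
        with pytest.raises(ValueError):
            VariantRecord("c", 5, "A", "C", genotype="0/1")

    def test_vcf_roundtrip_is_one_based_on_disk(self, small_genome, tmp_path):
        ref = small_genome.seq("c1")[99]
        alt = "A" if ref != "A" else "G"
        vs = [VariantRecord("c1", 99, ref, alt, "hom")]
        p = tmp_path / "v.vcf"
        write_vcf(vs, p, small_genome)
        line = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        assert line.split("\t")[1] == "100"  # 0-based 99 renders as POS 100
        back = read_vcf(p)
        assert back[0].pos == 99 and back[0].genotype == "hom"


class TestExtractVariantsInRegions:
    def _write(self, tmp_path, variants, genome):
        p = tmp_path / "in.vcf"
        write_vcf(variants, p, genome)
        return p

    def test_boundary_conventions(self, small_genome, tmp_path):
        ref = small_genome.seq("c1")[99]
        alt = "A" if ref != "A" else "C"
        v = VariantRecord("c1", 99, ref, alt)  # 1-based POS 100
        vcf = self._write(tmp_path, [v], small_genome)
        kept, _ = extract_variants_in_regions(vcf, [Interval("c1", 99, 100)])
        assert len(kept) == 1
        kept, _ = extract_variants_in_regions(vcf, [Interval("c1", 99, 200)])
        assert len(kept) == 1
        kept, _ = extract_variants_in_regions(vcf, [Interval("c1", 0, 99)])
        assert len(kept) == 0

    def test_membership_oracle_on_random_variants(self, small_genome, tmp_path, rng):
        lengths = small_genome.lengths
        variants = []
        seen = set()
        while len(variants) < 500:
            c = small_genome.names[int(rng.integers(2))]
            pos = int(rng.integers(0, lengths[c]))
            if (c, pos) in seen:
                continue
            seen.add((c, pos))
            ref = small_genome.seq(c)[pos]
            if ref == "N":
                continue
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            variants.append(VariantRecord(c, pos, ref, alt))
        variants.sort(key=lambda v: (v.chrom, v.pos))
        regions = random_intervals(rng, lengths, 25)
        vcf = self._write(tmp_path, variants, small_genome)
        kept, skipped = extract_variants_in_regions(vcf, regions)
        bm = bitmap_cover(regions, lengths)
        expected = [v for v in variants if bm[v.chrom][v.pos]]
        assert [(v.chrom, v.pos) for v in kept] == [
            (v.chrom, v.pos) for v in expected
        ]
        assert skipped == 0

    def test_whole_genome_keeps_all_and_empty_keeps_none(
        self, small_genome, tmp_path
    ):
        ref = small_genome.seq("c1")[10]
        alt = "A" if ref != "A" else "C"
        vcf = self._write(tmp_path, [VariantRecord("c1", 10, ref, alt)], small_genome)
        whole = [Interval(n, 0, ln) for n, ln in small_genome.lengths.items()]
        assert len(extract_variants_in_regions(vcf, whole)[0]) == 1
        assert len(extract_variants_in_regions(vcf, [Interval("c1", 2000, 2005)])[0]) == 0

    def test_unknown_chromosome_skipped_and_counted(self, small_genome, tmp_path):
        ref = small_genome.seq("c1")[10]
        alt = "A" if ref != "A" else "C"
        vcf = self._write(tmp_path, [VariantRecord("c1", 10, ref, alt)], small_genome)
        with pytest.warns(UserWarning, match="absent"):
            kept, skipped = extract_variants_in_regions(vcf, [Interval("cX", 0, 100)])
        assert kept == [] and skipped == 1

    def test_output_vcf_written(self, small_genome, tmp_path):
        ref = small_genome.seq("c1")[10]
        alt = "A" if ref != "A" else "C"
        vcf = self._write(tmp_path, [VariantRecord("c1", 10, ref, alt)], small_genome)
        out = tmp_path / "out.vcf"
        extract_variants_in_regions(vcf, [Interval("c1", 0, 100)], out_vcf=out)
        assert len(read_vcf(out)) == 1


def test_bed_roundtrip(tmp_path):
    ivs = [
        Interval("c1", 0, 10, label="a", strand="+"),
        Interval("c2", 5, 8, label="b", strand="-"),
    ]
    p = tmp_path / "x.bed"
    write_bed(ivs, p)
    back = read_bed(p)
    assert [(i.chrom, i.start, i.end, i.label, i.strand) for i in back] == [
        (i.chrom, i.start, i.end, i.label, i.strand) for i in ivs
    ]
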