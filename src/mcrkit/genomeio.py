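"""Genome, interval and variant containers plus readers/writers for the
standard formats the pipeline touches (FASTA, FASTQ, BED, VCF).

Coordinate conventions
----------------------
Internal coordinates are 0-based, half-open everywhere.  BED files are read
and written as-is (0-based, half-open).  VCF POS is rendered 1-based on
output and converted back to 0-based on input, so a variant at internal
position ``p`` appears in a VCF as ``POS = p + 1``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

from . import _seq

_ALLOWED = set("ACGTN")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (bad header or illegal characters)."""


class CoordinateError(ValueError):
    """Raised when an interval or variant falls outside its chromosome."""


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally labelled/stranded."""

    chrom: str
    start: int
    end: int
    label: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class VariantRecord:
    """A biallelic SNV.  ``pos`` is 0-based; genotype is 'het' or 'hom'."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = "het"
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.genotype not in ("het", "hom"):
            raise ValueError(f"genotype must be het/hom, got {self.genotype!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.alt)


@dataclass
class PairedRead:
    """One read pair destined for a pair of FASTQ files."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


DEFAULT_PHRED = 35  # constant base quality used for all simulated reads


class Genome:
    """An ordered collection of named sequences over {A,C,G,T,N}."""

    def __init__(self, records: Sequence[tuple[str, str]]):
        names = [n for n, _ in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names")
        self._names: list[str] = []
        self._seqs: dict[str, str] = {}
        self._codes: dict[str, np.ndarray] = {}
        for name, seq in records:
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence {name!r}")
            bad = set(seq) - _ALLOWED
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FastaFormatError(
                    f"record {name!r}: illegal base {seq[pos]!r} at position {pos}"
                )
            self._names.append(name)
            self._seqs[name] = seq

    # -- accessors ---------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self._names)

    def seq(self, name: str) -> str:
        return self._seqs[name]

    def codes(self, name: str) -> np.ndarray:
        """uint8 code array for one chromosome (cached)."""
        if name not in self._codes:
            self._codes[name] = _seq.encode(self._seqs[name])
        return self._codes[name]

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(self._seqs[n]) for n in self._names}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __iter__(self):
        return ((n, self._seqs[n]) for n in self._names)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        self.check_interval(Interval(chrom, start, end))
        return self._seqs[chrom][start:end]

    def check_interval(self, iv: Interval) -> None:
        if iv.chrom not in self._seqs:
            raise CoordinateError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > len(self._seqs[iv.chrom]):
            raise CoordinateError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {len(self._seqs[iv.chrom])}"
            )

    # -- FASTA -------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        return read_fasta(path)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self._names:
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-record) FASTA file into a Genome.

    Sequences are uppercased; record order is preserved; any character
    outside {A,C,G,T,N} raises :class:`FastaFormatError` naming the record
    and offset.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FastaFormatError(f"{path}: line 1 does not start with '>'")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    try:
        return Genome(records)
    except FastaFormatError as exc:
        raise FastaFormatError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_read_pairs(
    pairs: Iterable[PairedRead], path_r1: str | Path, path_r2: str | Path
) -> int:
    """Write mate pairs to two 4-line FASTQ files with /1 and /2 naming.

    Returns the number of pairs written.  Mate order is identical in both
    files.  A sequence/quality length mismatch raises ``ValueError``.
    """
    n = 0
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for p in pairs:
            if len(p.seq1) != len(p.qual1) or len(p.seq2) != len(p.qual2):
                raise ValueError(f"read {p.name!r}: sequence/quality length mismatch")
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def read_read_pairs(path_r1: str | Path, path_r2: str | Path) -> list[PairedRead]:
    """Read paired FASTQ files back into :class:`PairedRead` objects."""
    r1 = list(SeqIO.parse(str(path_r1), "fastq"))
    r2 = list(SeqIO.parse(str(path_r2), "fastq"))
    if len(r1) != len(r2):
        raise ValueError("mate files have different record counts")
    out = []
    for a, b in zip(r1, r2):
        name = a.id.rsplit("/", 1)[0]
        out.append(
            PairedRead(
                name,
                str(a.seq),
                "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"]),
                str(b.seq),
                "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _by_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    d: dict[str, list[Interval]] = {}
    for iv in intervals:
        d.setdefault(iv.chrom, []).append(iv)
    for lst in d.values():
        lst.sort(key=lambda iv: (iv.start, iv.end))
    return d


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union: sorted, non-overlapping, minimal interval list."""
    out: list[Interval] = []
    for chrom in sorted(_by_chrom(intervals)):
        cur_s = cur_e = None
        for iv in _by_chrom(intervals)[chrom]:
            if cur_s is None:
                cur_s, cur_e = iv.start, iv.end
            elif iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        if cur_s is not None:
            out.append(Interval(chrom, cur_s, cur_e))
    return out


def intersect_intervals(
    set_a: Iterable[Interval], set_b: Iterable[Interval]
) -> list[Interval]:
    a = merge_intervals(set_a)
    b = merge_intervals(set_b)
    by_b = _by_chrom(b)
    out = []
    for iv in a:
        for jv in by_b.get(iv.chrom, []):
            s, e = max(iv.start, jv.start), min(iv.end, jv.end)
            if s < e:
                out.append(Interval(iv.chrom, s, e))
    return merge_intervals(out)


def subtract_intervals(
    set_a: Iterable[Interval], set_b: Iterable[Interval]
) -> list[Interval]:
    a = merge_intervals(set_a)
    by_b = _by_chrom(merge_intervals(set_b))
    out = []
    for iv in a:
        cuts = [jv for jv in by_b.get(iv.chrom, []) if jv.start < iv.end and jv.end > iv.start]
        pos = iv.start
        for jv in cuts:
            if jv.start > pos:
                out.append(Interval(iv.chrom, pos, jv.start))
            pos = max(pos, jv.end)
        if pos < iv.end:
            out.append(Interval(iv.chrom, pos, iv.end))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


def coverage_fraction(intervals: Iterable[Interval], genome: Genome) -> float:
    """Fraction of the genome covered by the union of ``intervals``."""
    ivs = list(intervals)
    for iv in ivs:
        genome.check_interval(iv)
    return total_length(ivs) / genome.total_length


def interval_algebra(set_a, set_b, mode: str, genome: Genome | None = None):
    """Dispatch union/intersect/subtract/coverage_fraction on interval sets."""
    if genome is not None:
        for iv in list(set_a) + list(set_b or []):
            genome.check_interval(iv)
    if mode == "union":
        return merge_intervals(list(set_a) + list(set_b))
    if mode == "intersect":
        return intersect_intervals(set_a, set_b)
    if mode == "subtract":
        return subtract_intervals(set_a, set_b)
    if mode == "coverage_fraction":
        if genome is None:
            raise ValueError("coverage_fraction requires a genome")
        return coverage_fraction(list(set_a) + list(set_b or []), genome)
    raise ValueError(f"unknown mode {mode!r}")


def build_trees(intervals: Iterable[Interval]) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees for point/overlap queries."""
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.label)
    return trees


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 (0-based half-open); track/comment lines are skipped."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            label = f[3] if len(f) > 3 and f[3] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in "+-" else None
            out.append(Interval(f[0], int(f[1]), int(f[2]), label=label, strand=strand))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label is None and iv.strand is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t"
                    f"{iv.strand or '.'}\n"
                )


# ---------------------------------------------------------------------------
# VCF (minimal: CHROM POS ID REF ALT QUAL FILTER INFO FORMAT GT)
# ---------------------------------------------------------------------------

_VCF_INFO_DEFS = [
    ("STRATUM", "1", "String", "Region stratum the variant position falls in"),
    ("DP", "1", "Integer", "Retained read depth at the site"),
    ("AF", "A", "Float", "Alternate allele fraction among retained reads"),
]


def write_vcf(
    variants: Iterable[VariantRecord],
    path: str | Path,
    genome: Genome | None = None,
    sample: str = "SIM",
) -> None:
    """Write SNVs as minimal VCF v4.2 with a single-sample GT column."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mcrkit\n")
        if genome is not None:
            for name, ln in genome.lengths.items():
                fh.write(f"##contig=<ID={name},length={ln}>\n")
        for key, num, typ, desc in _VCF_INFO_DEFS:
            fh.write(
                f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for v in variants:
            known = {k: v.info[k] for k in ("STRATUM", "DP", "AF") if k in v.info}
            info = (
                ";".join(f"{k}={known[k]}" for k in known) if known else "."
            )
            gt = "1/1" if v.genotype == "hom" else "0/1"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT\t{gt}\n"
            )


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF through pysam; multi-allelic/indel records are rejected."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        has_samples = bool(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{path}: record at {rec.chrom}:{rec.pos} not biallelic")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"{path}: indel at {rec.chrom}:{rec.pos} unsupported")
            genotype = "het"
            if has_samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and all(a == 1 for a in gt if a is not None):
                    genotype = "hom"
            info = {k: rec.info[k] for k in rec.info}
            out.append(
                VariantRecord(rec.chrom, rec.start, ref, alt, genotype, info)
            )
    return out


def extract_variants_in_regions(
    vcf_path: str | Path,
    region_bed: str | Path | Sequence[Interval],
    out_vcf: str | Path | None = None,
) -> tuple[list[VariantRecord], int]:
    """Select the VCF records whose position falls inside a region set.

    Returns ``(kept_records, n_skipped_unknown_chrom)``.  Input order is
    preserved.  Records on chromosomes absent from the region namespace are
    skipped with a warning and counted.  If ``out_vcf`` is given the kept
    records are re-emitted as VCF with the input's header.
    """
    import pysam

    regions = (
        read_bed(region_bed)
        if isinstance(region_bed, (str, Path))
        else list(region_bed)
    )
    trees = build_trees(regions)
    chrom_space = set(trees)

    kept: list[VariantRecord] = []
    kept_raw = []
    skipped = 0
    warned = False
    with pysam.VariantFile(str(vcf_path)) as vf:
        header = vf.header
        for rec in vf:
            if rec.chrom not in chrom_space:
                skipped += 1
                if not warned:
                    warnings.warn(
                        f"chromosome {rec.chrom!r} absent from region set; "
                        "records skipped and counted"
                    )
                    warned = True
                continue
            if trees[rec.chrom].overlaps(rec.start):
                alt = rec.alts[0] if rec.alts else None
                if alt is None or len(rec.ref) != 1 or len(alt) != 1:
                    continue
                genotype = "het"
                if header.samples:
                    gt = rec.samples[0].get("GT")
                    if gt is not None and all(a == 1 for a in gt if a is not None):
                        genotype = "hom"
                kept.append(
                    VariantRecord(
                        rec.chrom, rec.start, rec.ref, alt, genotype,
                        {k: rec.info[k] for k in rec.info},
                    )
                )
                kept_raw.append(rec)
    if out_vcf is not None:
        with pysam.VariantFile(str(out_vcf), "w", header=header) as out:
            for rec in kept_raw:
                out.write(rec)
    return kept, skipped
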