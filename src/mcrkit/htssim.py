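"""Simulation of high-throughput sequencing data over repeat strata.

SNVs are planted at a configurable rate (default one per kb) in the
multi-copy regions and in matched flanking regions of the same total
length, genotypes are realised on a diploid pair of haplotypes, and
paired-end reads are drawn wgsim-style: uniform fragment starts, normal
insert sizes, uniform per-base substitution errors, constant base quality.
Reads are generated from the haplotypes, not the reference, so repeat
copies carry their planted alleles faithfully.
"""
from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass

import numpy as np

from ._seq import COMP_CODE, decode
from .genomeio import (
    DEFAULT_PHRED,
    Genome,
    Interval,
    PairedRead,
    VariantRecord,
    merge_intervals,
    write_read_pairs,
)


@dataclass
class SimStrategy:
    """One sequencing strategy: read length x depth plus the error model."""

    read_length: int = 150
    depth: float = 30.0
    error_rate: float = 0.01
    insert_mean: float = 400.0
    insert_sd: float = 50.0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 16:
            raise ValueError("read length must be >= 16")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert mean must be >= 2 x read length")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must be in [0, 0.5)")
        if self.insert_sd <= 0:
            raise ValueError("insert sd must be positive")

    @property
    def label(self) -> str:
        d = int(self.depth) if float(self.depth).is_integer() else self.depth
        return f"PE{self.read_length}-{d}x"

    @property
    def max_fragment(self) -> int:
        return int(round(self.insert_mean + 4 * self.insert_sd))


@dataclass
class SimulatedReadPair:
    """One simulated pair with its truth origin."""

    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    chrom: str
    frag_start: int
    frag_len: int
    hap: int
    flip: bool


@dataclass
class ReadBatch:
    """A column-oriented batch of simulated pairs (codes, not strings)."""

    read_length: int
    chrom_names: list[str]
    chrom_idx: np.ndarray
    frag_start: np.ndarray
    frag_len: np.ndarray
    hap: np.ndarray
    flip: np.ndarray
    reads1: np.ndarray  # (n, read_length) uint8 codes, as sequenced
    reads2: np.ndarray
    phred: int = DEFAULT_PHRED

    def __len__(self) -> int:
        return int(self.chrom_idx.size)

    def iter_pairs(self):
        q = chr(33 + self.phred) * self.read_length
        for i in range(len(self)):
            yield SimulatedReadPair(
                f"sim{i}",
                decode(self.reads1[i]),
                q,
                decode(self.reads2[i]),
                q,
                self.chrom_names[int(self.chrom_idx[i])],
                int(self.frag_start[i]),
                int(self.frag_len[i]),
                int(self.hap[i]),
                bool(self.flip[i]),
            )

    def to_fastq(self, path_r1, path_r2) -> int:
        q = chr(33 + self.phred) * self.read_length
        return write_read_pairs(
            (
                PairedRead(f"sim{i}", decode(self.reads1[i]), q, decode(self.reads2[i]), q)
                for i in range(len(self))
            ),
            path_r1,
            path_r2,
        )


@dataclass
class Haplotypes:
    """Two SNV-bearing copies of every chromosome (codes)."""

    genome: Genome
    arrays: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def names(self) -> list[str]:
        return self.genome.names

    @property
    def lengths(self) -> dict[str, int]:
        return self.genome.lengths


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

def define_strata(
    mcr_intervals: list[Interval], genome: Genome
) -> dict[str, list[Interval]]:
    """MCR stratum plus flanks of matched total length.

    Each merged MCR interval contributes flanking sequence totalling its own
    length, split half upstream / half downstream; flanks are clipped at
    chromosome ends and trimmed so they never overlap any MCR or previously
    allocated flank, with clipped length reallocated to the other side when
    possible.  Total flank length <= total MCR length, with equality when
    nothing was clipped.
    """
    mcrs = merge_intervals(mcr_intervals)
    for iv in mcrs:
        genome.check_interval(iv)
    lengths = genome.lengths
    occupied: dict[str, list[tuple[int, int]]] = {}
    for iv in mcrs:
        occupied.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for lst in occupied.values():
        lst.sort()

    flanks: list[Interval] = []
    for iv in mcrs:
        occ = occupied[iv.chrom]
        chrom_len = lengths[iv.chrom]
        i = bisect.bisect_left(occ, (iv.start, iv.end))
        prev_end = occ[i - 1][1] if i > 0 else 0
        next_start = occ[i + 1][0] if i + 1 < len(occ) else chrom_len
        avail_up = iv.start - prev_end
        avail_down = next_start - iv.end
        want_up = len(iv) // 2
        want_down = len(iv) - want_up
        take_up = min(want_up, avail_up)
        want_down += want_up - take_up
        take_down = min(want_down, avail_down)
        take_up += min(want_down - take_down, avail_up - take_up)
        if take_up + take_down == 0:
            warnings.warn(
                f"MCR {iv.chrom}:{iv.start}-{iv.end} has no room for flanks"
            )
        if take_up:
            f = (iv.start - take_up, iv.start)
            flanks.append(Interval(iv.chrom, *f, label="flank"))
            bisect.insort(occ, f)
        if take_down:
            f = (iv.end, iv.end + take_down)
            flanks.append(Interval(iv.chrom, *f, label="flank"))
            bisect.insort(occ, f)

    mcr_labeled = [
        Interval(iv.chrom, iv.start, iv.end, label="MCR") for iv in mcrs
    ]
    return {"MCR": mcr_labeled, "flank": sorted(flanks)}


# ---------------------------------------------------------------------------
# SNV planting and haplotypes
# ---------------------------------------------------------------------------

def plant_snvs(
    strata: dict[str, list[Interval]],
    genome: Genome,
    rate: float = 0.001,
    het_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> list[VariantRecord]:
    """Plant SNVs independently per base at ``rate``; record genotypes.

    Alt alleles are uniform over the three non-reference bases; genotype is
    het with probability ``het_fraction``, else hom.  Positions whose
    reference base is N are never mutated.
    """
    if not (0 < rate <= 0.1):
        raise ValueError("rate must be in (0, 0.1]")
    if not (0 <= het_fraction <= 1):
        raise ValueError("het_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[VariantRecord] = []
    for stratum in sorted(strata):
        ivs = sorted(strata[stratum])
        if not ivs:
            warnings.warn(f"stratum {stratum!r} is empty")
            continue
        for iv in ivs:
            genome.check_interval(iv)
            codes = genome.codes(iv.chrom)[iv.start : iv.end]
            hits = np.nonzero(rng.random(len(iv)) < rate)[0]
            if hits.size == 0:
                continue
            refs = codes[hits]
            alts = (refs + rng.integers(1, 4, size=hits.size)) % 4
            het = rng.random(hits.size) < het_fraction
            for off, rc, ac, h in zip(hits, refs, alts, het):
                if rc == 4:  # N reference
                    continue
                out.append(
                    VariantRecord(
                        iv.chrom,
                        iv.start + int(off),
                        "ACGT"[rc],
                        "ACGT"[ac],
                        "het" if h else "hom",
                        {"STRATUM": stratum},
                    )
                )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def build_haplotypes(
    genome: Genome,
    truth_variants: list[VariantRecord],
    seed: int | np.random.Generator = 0,
) -> Haplotypes:
    """Apply hom variants to both haplotypes, het variants to one chosen
    uniformly; the chosen haplotype index is recorded in ``info['HAP']``."""
    keys = [(v.chrom, v.pos) for v in truth_variants]
    if len(set(keys)) != len(keys):
        raise ValueError("conflicting variants: duplicate positions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arrays = {
        n: (genome.codes(n).copy(), genome.codes(n).copy()) for n in genome.names
    }
    for v in truth_variants:
        alt_code = "ACGT".index(v.alt)
        if genome.codes(v.chrom)[v.pos] != "ACGT".index(v.ref):
            raise ValueError(f"reference mismatch at {v.chrom}:{v.pos}")
        if v.genotype == "hom":
            arrays[v.chrom][0][v.pos] = alt_code
            arrays[v.chrom][1][v.pos] = alt_code
            v.info["HAP"] = -1
        else:
            h = int(rng.integers(2))
            arrays[v.chrom][h][v.pos] = alt_code
            v.info["HAP"] = h
    return Haplotypes(genome, arrays)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _allowed_segments(
    haplotypes: Haplotypes,
    strategy: SimStrategy,
    regions: list[Interval] | None,
    pad: int | None,
) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome segments from which fragment starts may be drawn."""
    lengths = haplotypes.lengths
    maxfrag = strategy.max_fragment
    segs: dict[str, list[tuple[int, int]]] = {}
    for name, ln in lengths.items():
        if ln < maxfrag:
            warnings.warn(
                f"chromosome {name!r} shorter than the maximum fragment; excluded"
            )
            continue
        segs[name] = []
    if regions is None:
        for name in segs:
            segs[name].append((0, lengths[name]))
    else:
        pad = strategy.max_fragment if pad is None else pad
        padded = merge_intervals(
            [
                Interval(iv.chrom, max(0, iv.start - pad), min(lengths[iv.chrom], iv.end + pad))
                for iv in regions
            ]
        )
        for iv in padded:
            if iv.chrom in segs:
                segs[iv.chrom].append((iv.start, iv.end))
    return {n: s for n, s in segs.items() if s}


def simulate_read_pairs(
    haplotypes: Haplotypes,
    strategy: SimStrategy,
    seed: int | np.random.Generator = 0,
    regions: list[Interval] | None = None,
    pad: int | None = None,
) -> ReadBatch:
    """Draw paired-end reads wgsim-style from a diploid haplotype pair.

    Pair count = round(depth x sampled-space length / (2 x read length));
    fragment starts are uniform over the sampled space, fragment lengths
    normal(insert_mean, insert_sd) truncated to >= 2 x read length, the
    haplotype is chosen uniformly per fragment, and every base is flipped to
    a uniformly chosen different base with probability ``error_rate``.
    ``regions`` restricts sampling to the given intervals padded by ``pad``
    (default: the maximum fragment length), preserving the per-base target
    depth inside them.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rl = strategy.read_length
    segs = _allowed_segments(haplotypes, strategy, regions, pad)
    if not segs:
        raise ValueError("no chromosome is long enough to sample fragments from")
    names = sorted(segs)
    seg_list = [(n, s, e) for n in names for s, e in segs[n]]
    seg_len = np.array([e - s for _, s, e in seg_list], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_len)])
    total = int(cum[-1])
    n_pairs = int(round(strategy.depth * total / (2 * rl)))

    chrom_names = haplotypes.names
    chrom_of = {n: i for i, n in enumerate(chrom_names)}
    lengths = haplotypes.lengths
    min_frag = 2 * rl

    # fragment starts: uniform over the sampled space
    u = rng.integers(0, total, size=n_pairs)
    seg_i = np.searchsorted(cum, u, side="right") - 1
    start = u - cum[seg_i] + np.array([s for _, s, _ in seg_list])[seg_i]
    chrom_idx = np.array([chrom_of[seg_list[i][0]] for i in seg_i], dtype=np.int32)
    chrom_len = np.array([lengths[n] for n in chrom_names], dtype=np.int64)

    # fragment lengths: truncated normal (redraw below the 2x read-length floor)
    flen = np.rint(rng.normal(strategy.insert_mean, strategy.insert_sd, n_pairs)).astype(np.int64)
    for _ in range(100):
        bad = flen < min_frag
        if not bad.any():
            break
        flen[bad] = np.rint(
            rng.normal(strategy.insert_mean, strategy.insert_sd, int(bad.sum()))
        ).astype(np.int64)

    # keep fragments inside their chromosome (redraw overshooting starts)
    for _ in range(100):
        bad = start + flen > chrom_len[chrom_idx]
        if not bad.any():
            break
        nb = int(bad.sum())
        u = rng.integers(0, total, size=nb)
        seg_i = np.searchsorted(cum, u, side="right") - 1
        start[bad] = u - cum[seg_i] + np.array([s for _, s, _ in seg_list])[seg_i]
        chrom_idx[bad] = np.array([chrom_of[seg_list[i][0]] for i in seg_i], dtype=np.int32)
    else:
        raise RuntimeError("could not fit fragments inside chromosomes")

    hap = rng.integers(0, 2, size=n_pairs).astype(np.int8)
    flip = rng.random(n_pairs) < 0.5

    left = np.empty((n_pairs, rl), dtype=np.uint8)
    right_rc = np.empty((n_pairs, rl), dtype=np.uint8)
    offs = np.arange(rl)
    for ci, cname in enumerate(chrom_names):
        for h in (0, 1):
            sel = np.nonzero((chrom_idx == ci) & (hap == h))[0]
            if sel.size == 0:
                continue
            arr = haplotypes.arrays[cname][h]
            left[sel] = arr[start[sel, None] + offs]
            tail = arr[(start[sel] + flen[sel] - rl)[:, None] + offs]
            right_rc[sel] = COMP_CODE[tail][:, ::-1]

    reads1 = np.where(flip[:, None], right_rc, left)
    reads2 = np.where(flip[:, None], left, right_rc)

    if strategy.error_rate > 0:
        for arr in (reads1, reads2):
            mask = rng.random(arr.shape) < strategy.error_rate
            mask &= arr < 4
            k = int(mask.sum())
            if k:
                arr[mask] = (arr[mask] + rng.integers(1, 4, size=k)) % 4

    return ReadBatch(
        read_length=rl,
        chrom_names=chrom_names,
        chrom_idx=chrom_idx,
        frag_start=start.astype(np.int64),
        frag_len=flen,
        hap=hap,
        flip=flip,
        reads1=reads1,
        reads2=reads2,
    )
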