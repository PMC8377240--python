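"""Synthetic genomes with known planted duplications.

The generator emulates the statistical structure the repeat analysis
assumes: long exact duplications embedded in an i.i.d. background, so that
the planted copies are, with overwhelming probability, the only repeats of
window length or more.  Background 300-mers collide by chance with
probability < 1e-80 for genomes up to a megabase, which makes truth-vs-found
comparisons sharp set equalities.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _seq
from .genomeio import Genome, Interval, merge_intervals, subtract_intervals


class PlacementError(RuntimeError):
    """Raised when duplications cannot be placed within margin constraints."""


@dataclass
class DuplicationSpec:
    """One planted duplication group.

    ``length`` is the copied segment length in bp; ``copies`` the total copy
    number (>= 2); ``mode`` one of intra/inter/tandem; ``strands`` the strand
    of each extra copy relative to the source; ``divergence`` a per-bp
    substitution rate applied independently to each extra copy (0 = exact).
    """

    length: int
    copies: int = 2
    mode: str = "inter"
    strands: tuple[str, ...] = ()
    divergence: float = 0.0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.copies < 2:
            raise ValueError("copy number must be >= 2")
        if self.mode not in ("intra", "inter", "tandem"):
            raise ValueError(f"unknown placement mode {self.mode!r}")
        if not (0 <= self.divergence < 1):
            raise ValueError("divergence must be in [0, 1)")
        if not self.strands:
            self.strands = ("+",) * (self.copies - 1)
        if len(self.strands) != self.copies - 1:
            raise ValueError("need one strand per extra copy")
        if any(s not in "+-" for s in self.strands):
            raise ValueError("strands must be + or -")


@dataclass
class TruthBuild:
    """A synthetic genome plus its truth annotation."""

    genome: Genome
    truth: list[Interval]            # every planted copy, label = group id
    unique_regions: list[Interval]   # complement of the planted copies

    def truth_groups(self) -> dict[str, list[Interval]]:
        groups: dict[str, list[Interval]] = {}
        for iv in self.truth:
            groups.setdefault(iv.label, []).append(iv)
        return groups


def generate_background(
    chrom_lengths: dict[str, int] | list[tuple[str, int]],
    gc_content: float = 0.41,
    seed: int | np.random.Generator = 0,
) -> Genome:
    """i.i.d. background sequence with P(G)+P(C) = ``gc_content``.

    The default GC of 0.41 matches the human genome average.  Reproducible
    given the seed.
    """
    items = list(chrom_lengths.items()) if isinstance(chrom_lengths, dict) else list(chrom_lengths)
    if any(ln < 1000 for _, ln in items):
        raise ValueError("chromosome lengths must be >= 1 kb")
    if not (0 < gc_content < 1):
        raise ValueError("gc_content must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at = (1 - gc_content) / 2
    gc = gc_content / 2
    p = [at, gc, gc, at]  # A C G T
    records = []
    for name, ln in items:
        codes = rng.choice(4, size=ln, p=p).astype(np.uint8)
        records.append((name, _seq.decode(codes)))
    return Genome(records)


def _diverge(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return codes
    codes = codes.copy()
    hits = np.nonzero(rng.random(codes.size) < rate)[0]
    if hits.size:
        codes[hits] = (codes[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return codes


def plant_duplications(
    genome: Genome,
    specs: list[DuplicationSpec],
    seed: int | np.random.Generator = 0,
    margin: int = 1000,
    max_tries: int = 500,
    distinct_flanks: bool = True,
) -> TruthBuild:
    """Copy source segments into extra loci, overwriting background.

    Each planted segment is flanked by at least ``margin`` bp that is free of
    any other planted segment, so seed-merge boundaries are unambiguous and
    flank strata never collide.  Bounded rejection sampling; raises
    :class:`PlacementError` when placement fails.

    With ``distinct_flanks`` (the default) the bases immediately adjacent to
    each copy are set pairwise-distinct across the copies of a group (up to 4
    dispersed copies; outer boundaries only for tandem arrays), so a shared
    block never extends past a planted boundary by a chance base match and
    the truth intervals are recovered exactly by exact-repeat detection.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total_planted = sum(s.length * s.copies for s in specs)
    if total_planted > genome.total_length // 2:
        raise ValueError("total planted length exceeds 50% of the genome")

    names = genome.names
    arrays = {n: genome.codes(n).copy() for n in names}
    lengths = genome.lengths
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def fits(chrom: str, start: int, end: int) -> bool:
        if start < margin or end > lengths[chrom] - margin:
            return False
        for s, e in occupied[chrom]:
            if start - margin < e and end + margin > s:
                return False
        return True

    def place_block(length: int, chroms: list[str]) -> tuple[str, int]:
        weights = np.array([lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            hi = lengths[chrom] - margin - length
            if hi <= margin:
                continue
            start = int(rng.integers(margin, hi))
            if fits(chrom, start, start + length):
                return chrom, start
        raise PlacementError(
            f"could not place a {length} bp block after {max_tries} tries"
        )

    truth: list[Interval] = []
    for gi, spec in enumerate(specs):
        gid = f"dup{gi}"
        if spec.mode == "tandem":
            chrom, start = place_block(spec.length * spec.copies, names)
            src = arrays[chrom][start : start + spec.length].copy()
            loci = []
            for ci in range(spec.copies):
                s = start + ci * spec.length
                strand = "+" if ci == 0 else spec.strands[ci - 1]
                seg = src if ci == 0 else _diverge(src, spec.divergence, rng)
                if strand == "-":
                    seg = _seq.revcomp_codes(seg)
                arrays[chrom][s : s + spec.length] = seg
                loci.append((chrom, s, strand))
            occupied[chrom].append((start, start + spec.length * spec.copies))
            if distinct_flanks:
                # outer boundaries only: the array must not extend by chance
                end = start + spec.length * spec.copies
                if arrays[chrom][start - 1] == src[-1]:
                    arrays[chrom][start - 1] = (src[-1] + 1) % 4
                if arrays[chrom][end] == src[0]:
                    arrays[chrom][end] = (src[0] + 1) % 4
        else:
            chrom, start = place_block(spec.length, names)
            occupied[chrom].append((start, start + spec.length))
            src = arrays[chrom][start : start + spec.length].copy()
            loci = [(chrom, start, "+")]
            for ci in range(1, spec.copies):
                if spec.mode == "intra":
                    cands = [chrom]
                else:  # inter: prefer a different chromosome when one exists
                    cands = [n for n in names if n != chrom] or names
                c2, s2 = place_block(spec.length, cands)
                strand = spec.strands[ci - 1]
                seg = _diverge(src, spec.divergence, rng)
                if strand == "-":
                    seg = _seq.revcomp_codes(seg)
                arrays[c2][s2 : s2 + spec.length] = seg
                occupied[c2].append((s2, s2 + spec.length))
                loci.append((c2, s2, strand))
            if distinct_flanks and spec.copies <= 4:
                # give every copy a distinct effective boundary base on both
                # sides, so no pair of copies extends past the planted segment
                for ci, (c, s, strand) in enumerate(loci):
                    code = ci  # ACGT by copy rank; pairwise distinct
                    e = s + spec.length
                    if strand == "+":
                        arrays[c][s - 1] = code
                        arrays[c][e] = code
                    else:
                        arrays[c][s - 1] = 3 - code
                        arrays[c][e] = 3 - code
        for c, s, strand in loci:
            truth.append(Interval(c, s, s + spec.length, label=gid, strand=strand))

    new_genome = Genome([(n, _seq.decode(arrays[n])) for n in names])
    whole = [Interval(n, 0, lengths[n]) for n in names]
    unique = subtract_intervals(whole, merge_intervals(truth))
    return TruthBuild(new_genome, truth, unique)


def build_truth_genome(
    chrom_lengths,
    specs: list[DuplicationSpec],
    gc_content: float = 0.41,
    seed: int = 0,
    margin: int = 1000,
) -> TruthBuild:
    """Background + planted duplications in one call (single seed)."""
    rng = np.random.default_rng(seed)
    bg = generate_background(chrom_lengths, gc_content, rng)
    return plant_duplications(bg, specs, rng, margin=margin)
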