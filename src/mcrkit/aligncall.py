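"""Seed-and-verify read mapping with a strict unique-mapping filter, and a
pileup SNV caller.

The mapper gathers candidate placements from exact k-mer anchors of both
mates (with a windowed mate-rescue when one mate's anchors all miss),
scores concordant placements by total mismatches, and keeps a pair only
when exactly one placement attains the minimum score — a strict
co-optimality test with no mapping-quality heuristics.  Pairs lying fully
inside one copy of an exact repeat therefore always tie across copies and
are discarded, which is the mechanism that starves exact repeats of
retained coverage.

The caller piles up retained alignments and emits a site as a variant when
depth, alternate count and alternate fraction clear explicit thresholds;
ties between equally frequent alternate bases break lexicographically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import COMP_CODE
from .genomeio import Genome, VariantRecord
from .htssim import ReadBatch


@dataclass
class Alignment:
    """Placement of one read pair (local, 0-based coordinates)."""

    pair_id: int
    placed: bool
    unique: bool
    chrom: str | None = None
    left_start: int | None = None   # genome-forward mate start
    right_start: int | None = None  # start of the reverse mate (forward coords)
    mismatches: int | None = None


class KmerIndex:
    """Exact k-mer position index over a genome (forward strand).

    Reverse-strand placements are found by querying the reverse complement
    of the read, so the index itself is single-stranded.  k must be odd
    (no self-complementary k-mers) and in [15, 63]; k <= 31 uses a packed
    uint64 sorted-array index, larger k a byte-string dictionary.
    """

    def __init__(self, genome: Genome, k: int = 31):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        if not (15 <= k <= 63):
            raise ValueError("k must be in [15, 63]")
        self.genome = genome
        self.k = k
        self.chrom_names = genome.names
        self.chrom_starts = np.zeros(len(self.chrom_names) + 1, dtype=np.int64)
        parts = []
        for i, name in enumerate(self.chrom_names):
            codes = genome.codes(name)
            parts.append(codes)
            self.chrom_starts[i + 1] = self.chrom_starts[i] + codes.size
        self.concat = np.concatenate(parts)
        self.packed = k <= 31
        if self.packed:
            codes_l, pos_l = [], []
            for i, name in enumerate(self.chrom_names):
                c, v = _window_codes(genome.codes(name), k)
                if c.size:
                    codes_l.append(c[v])
                    pos_l.append(np.nonzero(v)[0] + self.chrom_starts[i])
            allc = np.concatenate(codes_l) if codes_l else np.empty(0, np.uint64)
            allp = np.concatenate(pos_l) if pos_l else np.empty(0, np.int64)
            order = np.argsort(allc, kind="stable")
            self.sorted_codes = allc[order]
            self.sorted_pos = allp[order]
        else:
            self.table: dict[bytes, list[int]] = {}
            for i, name in enumerate(self.chrom_names):
                codes = genome.codes(name)
                off = int(self.chrom_starts[i])
                buf = codes.tobytes()
                for p in range(codes.size - k + 1):
                    win = buf[p : p + k]
                    if 4 in win:
                        continue
                    self.table.setdefault(win, []).append(off + p)

    def chrom_of(self, gpos: int) -> int:
        return int(np.searchsorted(self.chrom_starts, gpos, side="right") - 1)

    def lookup_codes(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) slice bounds into ``sorted_pos`` for packed k-mer codes."""
        lo = np.searchsorted(self.sorted_codes, codes, side="left")
        hi = np.searchsorted(self.sorted_codes, codes, side="right")
        return lo, hi

    def lookup_window(self, read_codes: np.ndarray, offset: int) -> np.ndarray:
        """Positions of the k-mer starting at ``offset`` of a single read."""
        win = read_codes[offset : offset + self.k]
        if (win == 4).any():
            return np.empty(0, dtype=np.int64)
        if self.packed:
            code = np.uint64(0)
            for b in win:
                code = code * np.uint64(4) + np.uint64(b)
            lo = int(np.searchsorted(self.sorted_codes, code, side="left"))
            hi = int(np.searchsorted(self.sorted_codes, code, side="right"))
            return self.sorted_pos[lo:hi]
        return np.asarray(self.table.get(win.tobytes(), []), dtype=np.int64)


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit codes for every window plus an N-free validity mask."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    c = codes.astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        b = c[j : j + n]
        out = out * np.uint64(4) + (b & np.uint64(3))
        valid &= b != 4
    return out, valid


def build_index(genome: Genome, k: int = 31) -> KmerIndex:
    """Build the exact k-mer position index for a genome."""
    return KmerIndex(genome, k)


@dataclass
class MapResult:
    """Batch mapping outcome: per-pair flags plus retained placements."""

    n_pairs: int
    n_unique: int
    n_multi: int
    n_unmapped: int
    chrom_names: list[str]
    chrom_starts: np.ndarray
    placed: np.ndarray
    unique: np.ndarray
    # retained (uniquely mapped) pairs only, concatenated coordinates:
    ret_pair: np.ndarray
    ret_left_start: np.ndarray
    ret_right_start: np.ndarray
    ret_left_reads: np.ndarray   # genome-forward codes (m, rl)
    ret_right_reads: np.ndarray

    def stats(self) -> dict[str, int]:
        return {
            "pairs_total": self.n_pairs,
            "pairs_unique": self.n_unique,
            "pairs_multi_discarded": self.n_multi,
            "pairs_unmapped": self.n_unmapped,
        }


def default_max_mismatch(read_length: int) -> int:
    """ceil(0.04 x read length): tolerates the default error rate with margin."""
    return math.ceil(0.04 * read_length)


def _anchor_code_matrix(reads: np.ndarray, offsets: list[int], k: int) -> np.ndarray:
    """Packed anchor codes, shape (n_offsets, n_reads); N windows -> max."""
    n = reads.shape[0]
    out = np.zeros((len(offsets), n), dtype=np.uint64)
    bad = np.zeros((len(offsets), n), dtype=bool)
    for a, off in enumerate(offsets):
        acc = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            b = reads[:, off + j].astype(np.uint64)
            acc = acc * np.uint64(4) + (b & np.uint64(3))
            bad[a] |= reads[:, off + j] == 4
        out[a] = acc
    out[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)  # never present in the index
    return out


def _mismatch_scan(concat: np.ndarray, read: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Mismatch counts of ``read`` placed at every start in [lo, hi)."""
    rl = read.size
    seg = concat[lo : hi + rl - 1]
    if seg.size < rl:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(seg, rl)
    return (win != read).sum(axis=1)


def map_batch(
    batch: ReadBatch,
    index: KmerIndex,
    max_mismatch_per_read: int | None = None,
    insert_mean: float = 400.0,
    insert_sd: float = 50.0,
    rescue_limit: int = 4,
    chunk_size: int = 65536,
) -> MapResult:
    """Map every pair of a batch; retain strictly unique concordant optima."""
    rl = batch.read_length
    k = index.k
    if rl < 2 * k:
        raise ValueError("read length must be >= 2 x k for anchoring")
    maxmm = (
        default_max_mismatch(rl) if max_mismatch_per_read is None else max_mismatch_per_read
    )
    minfrag = max(2 * rl, int(round(insert_mean - 4 * insert_sd)))
    maxfrag = int(round(insert_mean + 4 * insert_sd))
    concat = index.concat
    starts = index.chrom_starts
    n = len(batch)
    offsets = [0, rl - k]

    placed = np.zeros(n, dtype=bool)
    unique = np.zeros(n, dtype=bool)
    ret_pair, ret_ls, ret_rs = [], [], []
    ret_lr, ret_rr = [], []

    chrom_end_of = lambda ci: int(starts[ci + 1])
    chrom_start_of = lambda ci: int(starts[ci])

    for c0 in range(0, n, chunk_size):
        c1 = min(n, c0 + chunk_size)
        r1 = batch.reads1[c0:c1]
        r2 = batch.reads2[c0:c1]
        rc1 = COMP_CODE[r1][:, ::-1]
        rc2 = COMP_CODE[r2][:, ::-1]
        # orientation A: r1 is the forward (left) mate; orientation B: r2 is.
        mats = {"A": (r1, rc2), "B": (r2, rc1)}
        if index.packed:
            anchor_hits = {}
            for ori, (lf, rf) in mats.items():
                for side, arr in (("L", lf), ("R", rf)):
                    codes = _anchor_code_matrix(arr, offsets, k)
                    lo, hi = index.lookup_codes(codes)
                    anchor_hits[(ori, side)] = (lo, hi)

        for i in range(c1 - c0):
            gi = c0 + i
            cands = []  # (score, ori, sL, sR)
            seen = set()
            for ori in ("A", "B"):
                lf, rf = mats[ori]
                lstarts: set[int] = set()
                rstarts: set[int] = set()
                for a, off in enumerate(offsets):
                    for side, store in (("L", lstarts), ("R", rstarts)):
                        if index.packed:
                            lo, hi = anchor_hits[(ori, side)]
                            pos = index.sorted_pos[lo[a, i] : hi[a, i]]
                        else:
                            arr = lf if side == "L" else rf
                            pos = index.lookup_window(arr[i], off)
                        for p in pos.tolist():
                            store.add(p - off)
                # windowed mate rescue when one side's anchors all missed
                if lstarts and not rstarts:
                    for sL in sorted(lstarts)[:rescue_limit]:
                        ci = index.chrom_of(sL)
                        lo = max(chrom_start_of(ci), sL + minfrag - rl)
                        hi = min(chrom_end_of(ci) - rl, sL + maxfrag - rl)
                        if hi < lo:
                            continue
                        mm = _mismatch_scan(concat, rf[i], lo, hi)
                        for j in np.nonzero(mm <= maxmm)[0].tolist():
                            rstarts.add(lo + j)
                elif rstarts and not lstarts:
                    for sR in sorted(rstarts)[:rescue_limit]:
                        ci = index.chrom_of(sR)
                        lo = max(chrom_start_of(ci), sR + rl - maxfrag)
                        hi = min(chrom_end_of(ci) - rl, sR + rl - minfrag)
                        if hi < lo:
                            continue
                        mm = _mismatch_scan(concat, lf[i], lo, hi)
                        for j in np.nonzero(mm <= maxmm)[0].tolist():
                            lstarts.add(lo + j)
                if not lstarts or not rstarts:
                    continue
                for sL in lstarts:
                    ci = index.chrom_of(sL)
                    if sL < chrom_start_of(ci) or sL + rl > chrom_end_of(ci):
                        continue
                    mm1 = None
                    for sR in rstarts:
                        flen = sR + rl - sL
                        if not (minfrag <= flen <= maxfrag):
                            continue
                        if sR + rl > chrom_end_of(ci) or sR < chrom_start_of(ci):
                            continue
                        if (ori, sL, sR) in seen:
                            continue
                        seen.add((ori, sL, sR))
                        if mm1 is None:
                            mm1 = int(np.count_nonzero(concat[sL : sL + rl] != lf[i]))
                        if mm1 > maxmm:
                            break
                        mm2 = int(np.count_nonzero(concat[sR : sR + rl] != rf[i]))
                        if mm2 > maxmm:
                            continue
                        cands.append((mm1 + mm2, ori, sL, sR))
            if not cands:
                continue
            best = min(c[0] for c in cands)
            top = [c for c in cands if c[0] == best]
            placed[gi] = True
            if len(top) == 1:
                unique[gi] = True
                _, ori, sL, sR = top[0]
                lf, rf = mats[ori]
                ret_pair.append(gi)
                ret_ls.append(sL)
                ret_rs.append(sR)
                ret_lr.append(lf[i])
                ret_rr.append(rf[i])

    m = len(ret_pair)
    return MapResult(
        n_pairs=n,
        n_unique=int(unique.sum()),
        n_multi=int(placed.sum() - unique.sum()),
        n_unmapped=int(n - placed.sum()),
        chrom_names=index.chrom_names,
        chrom_starts=starts,
        placed=placed,
        unique=unique,
        ret_pair=np.asarray(ret_pair, dtype=np.int64),
        ret_left_start=np.asarray(ret_ls, dtype=np.int64),
        ret_right_start=np.asarray(ret_rs, dtype=np.int64),
        ret_left_reads=(
            np.stack(ret_lr) if m else np.empty((0, rl), dtype=np.uint8)
        ),
        ret_right_reads=(
            np.stack(ret_rr) if m else np.empty((0, rl), dtype=np.uint8)
        ),
    )


def map_pair(
    pair,
    index: KmerIndex,
    genome: Genome | None = None,
    max_mismatch_per_read: int | None = None,
    insert_mean: float = 400.0,
    insert_sd: float = 50.0,
) -> Alignment:
    """Map a single pair; see :func:`map_batch` for the placement contract.

    ``pair`` may be a :class:`~mcrkit.htssim.SimulatedReadPair` or any
    object with ``seq1``/``seq2`` string attributes.
    """
    from ._seq import encode

    rl = len(pair.seq1)
    batch = ReadBatch(
        read_length=rl,
        chrom_names=index.chrom_names,
        chrom_idx=np.zeros(1, np.int32),
        frag_start=np.zeros(1, np.int64),
        frag_len=np.zeros(1, np.int64),
        hap=np.zeros(1, np.int8),
        flip=np.zeros(1, bool),
        reads1=encode(pair.seq1)[None, :],
        reads2=encode(pair.seq2)[None, :],
    )
    res = map_batch(
        batch,
        index,
        max_mismatch_per_read=max_mismatch_per_read,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
    )
    if res.n_unique == 1:
        sL = int(res.ret_left_start[0])
        sR = int(res.ret_right_start[0])
        ci = index.chrom_of(sL)
        off = int(index.chrom_starts[ci])
        lread = res.ret_left_reads[0]
        rread = res.ret_right_reads[0]
        mm = int(
            np.count_nonzero(index.concat[sL : sL + rl] != lread)
            + np.count_nonzero(index.concat[sR : sR + rl] != rread)
        )
        return Alignment(
            0, True, True, index.chrom_names[ci], sL - off, sR - off, mm
        )
    return Alignment(0, bool(res.placed[0]), False)


# ---------------------------------------------------------------------------
# pileup calling
# ---------------------------------------------------------------------------

def pileup_and_call(
    alignments: MapResult,
    genome: Genome,
    min_depth: int = 4,
    min_alt_count: int = 2,
    min_alt_frac: float = 0.2,
    hom_frac: float = 0.8,
) -> list[VariantRecord]:
    """Pileup retained alignments and call SNVs by explicit thresholds.

    Per site the alternate allele is the most frequent non-reference base
    (lexicographic tie-break); a call requires depth >= ``min_depth``,
    alternate count >= ``min_alt_count`` and alternate fraction >=
    ``min_alt_frac``; genotype is hom when the fraction reaches
    ``hom_frac``, else het.
    """
    starts = alignments.chrom_starts
    total = int(starts[-1])
    rl = alignments.ret_left_reads.shape[1] if alignments.ret_left_reads.size else 0
    counts = np.zeros((4, total), dtype=np.int32)
    if rl:
        offs = np.arange(rl)
        for st, reads in (
            (alignments.ret_left_start, alignments.ret_left_reads),
            (alignments.ret_right_start, alignments.ret_right_reads),
        ):
            if st.size == 0:
                continue
            pos = (st[:, None] + offs).ravel()
            base = reads.ravel()
            ok = base < 4
            np.add.at(counts, (base[ok], pos[ok]), 1)

    refc = np.concatenate([genome.codes(n) for n in alignments.chrom_names])
    depth = counts.sum(axis=0)
    cand = np.nonzero(depth >= min_depth)[0]
    out: list[VariantRecord] = []
    if cand.size:
        sub = counts[:, cand].astype(np.int64)
        rc = refc[cand]
        valid_ref = rc < 4
        sub_masked = sub.copy()
        sub_masked[rc.clip(max=3), np.arange(cand.size)] = -1
        alt = sub_masked.argmax(axis=0)
        altc = sub_masked[alt, np.arange(cand.size)]
        d = depth[cand]
        frac = np.where(d > 0, altc / np.maximum(d, 1), 0.0)
        call = valid_ref & (altc >= min_alt_count) & (frac >= min_alt_frac)
        idx = np.nonzero(call)[0]
        for j in idx.tolist():
            gpos = int(cand[j])
            ci = int(np.searchsorted(starts, gpos, side="right") - 1)
            out.append(
                VariantRecord(
                    alignments.chrom_names[ci],
                    gpos - int(starts[ci]),
                    "ACGT"[int(rc[j])],
                    "ACGT"[int(alt[j])],
                    "hom" if frac[j] >= hom_frac else "het",
                    {
                        "DP": int(d[j]),
                        "AF": round(float(frac[j]), 4),
                    },
                )
            )
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out
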