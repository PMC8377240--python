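"""Exact multi-copy sequence (MCS) discovery by tiling-seed merging.

A *seed* is a w-mer window (default w = 300, tiled at 1 bp steps) that
occurs, exactly and with no mismatches or indels, at two or more genomic
loci; reverse-complement occurrences count by default.  Runs of consecutive
seeds whose occurrences shift in lockstep are merged into maximal shared
blocks; blocks are then fused into MCS groups, each of which is a single
shared sequence of length >= w together with every locus (a multi-copy
region, MCR) that spells it.

Matching is implemented by genome-wide exact window indexing, not by an
external aligner, so *all* occurrences are enumerated with no multi-hit
cap.  Windows containing 'N' never participate in a match.

``brute_force_repeat_oracle`` recomputes the identical decomposition by a
different route (per-pair longest-common-extension from seed matches) and is
used as an independent cross-check in the test-suite.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

from ._seq import revcomp
from .genomeio import Genome, Interval, merge_intervals, total_length


@dataclass
class SeedHit:
    """One multi-hit tiling window and all of its exact occurrences.

    ``occurrences`` holds (chrom, pos, strand) tuples, strand being relative
    to this window's forward orientation; the origin itself is included with
    strand '+'.
    """

    chrom: str
    start: int
    w: int
    occurrences: list[tuple[str, int, str]]


@dataclass
class McsGroup:
    """A maximal shared sequence and the loci that carry it.

    ``loci`` holds (chrom, start, strand); all loci spell the identical
    sequence of ``length`` bp (reverse-complemented for '-' loci).
    """

    group_id: str
    length: int
    loci: list[tuple[str, int, str]]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def intervals(self) -> list[Interval]:
        return [
            Interval(c, s, s + self.length, label=self.group_id, strand=st)
            for c, s, st in self.loci
        ]

    @property
    def is_intra(self) -> bool:
        return len({c for c, _, _ in self.loci}) == 1


@dataclass
class McrSummary:
    """Genome-level summary of an MCS group catalogue."""

    coverage_fraction: float
    per_chrom_fraction: dict[str, float]
    length_hist: dict[int, int]       # bin start (bp) -> group count
    copy_number_hist: dict[int, int]  # loci per group -> group count
    n_groups: int
    n_loci: int
    n_intra: int
    n_inter: int
    bin_width: int


# ---------------------------------------------------------------------------
# window enumeration
# ---------------------------------------------------------------------------

def _window_stream(genome: Genome, w: int):
    """Yield (chrom_idx, start, forward_code, revcomp_code) for every N-free
    window, via 2-bit rolling encodings (exact, no hashing collisions)."""
    mask = (1 << (2 * w)) - 1
    hi_shift = 2 * (w - 1)
    for ci, name in enumerate(genome.names):
        codes = genome.codes(name).tolist()
        f = r = 0
        valid = 0
        for i, b in enumerate(codes):
            if b == 4:  # N resets the window
                valid = 0
                f = r = 0
                continue
            f = ((f << 2) | b) & mask
            r = (r >> 2) | ((3 - b) << hi_shift)
            valid += 1
            if valid >= w:
                yield ci, i - w + 1, f, r


def enumerate_seed_hits(
    genome: Genome,
    w: int = 300,
    step: int = 1,
    strand_mode: str = "both",
    max_occurrences: int | None = None,
) -> list[SeedHit]:
    """Enumerate every tiling window with >= 2 exact occurrences genome-wide.

    One :class:`SeedHit` is emitted per multi-hit window *origin* (so a
    2-copy repeat of a single window yields two hits, one per copy).  With
    ``strand_mode='forward'`` reverse-complement occurrences are ignored.
    ``max_occurrences`` is a performance guard only (default: no cap);
    windows exceeding it are dropped entirely.
    """
    if w < 2:
        raise ValueError("window length must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if w > max(genome.lengths.values()):
        raise ValueError("window longer than the longest chromosome")
    if strand_mode not in ("both", "forward"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    both = strand_mode == "both"

    counts: dict[int, int] = {}
    for ci, p, f, r in _window_stream(genome, w):
        if p % step:
            continue
        key = min(f, r) if both else f
        counts[key] = counts.get(key, 0) + 1

    occ: dict[int, list[tuple[int, int, bool]]] = {}
    for ci, p, f, r in _window_stream(genome, w):
        if p % step:
            continue
        key = min(f, r) if both else f
        if counts[key] >= 2:
            occ.setdefault(key, []).append((ci, p, f <= r if both else True))

    names = genome.names
    hits: list[SeedHit] = []
    for key, lst in occ.items():
        if max_occurrences is not None and len(lst) > max_occurrences:
            continue
        for ci, p, o in lst:
            occs = [
                (names[cj], q, "+" if oj == o else "-") for cj, q, oj in lst
            ]
            hits.append(SeedHit(names[ci], p, w, occs))
    hits.sort(key=lambda h: (h.chrom, h.start))
    return hits


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def _pairwise_blocks(seed_hits: list[SeedHit], step: int):
    """Maximal lockstep runs for every unordered locus pair.

    Returns a set of blocks ``(locus_a, locus_b, rel)`` with each locus a
    (chrom, start, end) tuple, loci sorted, and ``rel`` '+' when the two
    loci share orientation, '-' otherwise.
    """
    if not seed_hits:
        return set(), 0
    w = seed_hits[0].w
    runs: dict[tuple, list[int]] = {}
    for h in seed_hits:
        c, p = h.chrom, h.start
        for c2, q, s in h.occurrences:
            if c2 == c and q == p and s == "+":
                continue  # the origin itself
            diag = q - p if s == "+" else q + p
            runs.setdefault((c, c2, s, diag), []).append(p)

    blocks = set()
    for (c, c2, s, diag), ps in runs.items():
        ps.sort()
        i = 0
        while i < len(ps):
            j = i
            while j + 1 < len(ps) and ps[j + 1] - ps[j] == step:
                j += 1
            p0, p1 = ps[i], ps[j]
            length = p1 - p0 + w
            loc_a = (c, p0, p0 + length)
            if s == "+":
                loc_b = (c2, diag + p0, diag + p1 + w)
            else:
                loc_b = (c2, diag - p1, diag - p0 + w)
            if loc_a != loc_b:
                a, b = sorted((loc_a, loc_b))
                blocks.add((a, b, s))
            i = j + 1
    return blocks, w


def _fuse_blocks(blocks) -> list[McsGroup]:
    """Fuse pairwise blocks sharing identical interval extents into groups,
    propagating relative orientations, and canonicalize strands."""
    parent: dict[tuple, tuple] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    adj: dict[tuple, list[tuple[tuple, int]]] = {}
    for a, b, rel in blocks:
        for node in (a, b):
            parent.setdefault(node, node)
            adj.setdefault(node, [])
        union(a, b)
        par = 0 if rel == "+" else 1
        adj[a].append((b, par))
        adj[b].append((a, par))

    comps: dict[tuple, list[tuple]] = {}
    for node in parent:
        comps.setdefault(find(node), []).append(node)

    groups: list[McsGroup] = []
    for nodes in comps.values():
        nodes.sort()
        lens = {e - s for _, s, e in nodes}
        if len(lens) != 1:  # cannot happen: identical extents imply one length
            raise AssertionError("inconsistent block lengths in a fused group")
        length = lens.pop()
        # BFS parity from the first locus
        parity = {nodes[0]: 0}
        stack = [nodes[0]]
        while stack:
            u = stack.pop()
            for v, par in adj[u]:
                if v not in parity:
                    parity[v] = parity[u] ^ par
                    stack.append(v)
        loci = [
            (c, s, "+" if parity[(c, s, e)] == 0 else "-") for c, s, e in nodes
        ]
        groups.append(McsGroup("", length, loci))

    groups.sort(key=lambda g: (g.loci[0][0], g.loci[0][1], g.length))
    width = max(4, len(str(len(groups))))
    for i, g in enumerate(groups, 1):
        g.group_id = f"mcs{i:0{width}d}"
    return groups


def merge_seed_runs(seed_hits: list[SeedHit], step: int = 1) -> list[McsGroup]:
    """Merge consecutive co-occurring seeds into maximal MCS groups.

    For each unordered locus pair co-occurring in a seed, maximal runs of
    window positions whose paired occurrences shift in lockstep (+1/+1 for
    same-orientation pairs, +1/-1 for opposite) become blocks of length
    ``last_offset - first_offset + w``; blocks sharing identical interval
    extents are fused into one group carrying all participating loci.
    """
    blocks, _ = _pairwise_blocks(seed_hits, step)
    return _fuse_blocks(blocks)


def find_mcrs(
    genome: Genome,
    w: int = 300,
    step: int = 1,
    strand_mode: str = "both",
) -> list[McsGroup]:
    """End-to-end: enumerate multi-hit seeds and merge them into MCS groups."""
    return merge_seed_runs(
        enumerate_seed_hits(genome, w=w, step=step, strand_mode=strand_mode),
        step=step,
    )


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_repeat_oracle(
    genome: Genome,
    w: int = 300,
    strand_mode: str = "both",
    max_total_bp: int = 200_000,
) -> list[McsGroup]:
    """Independent recomputation of the MCS decomposition.

    Finds seed matches by direct substring collection and grows each matched
    locus pair by character-by-character longest-common-extension, then
    fuses identical-extent blocks with networkx connected components.
    Quadratic-ish; guarded to genomes of ``max_total_bp`` or less.
    """
    import networkx as nx

    if genome.total_length > max_total_bp:
        raise ValueError(
            f"oracle limited to {max_total_bp} bp total (got {genome.total_length})"
        )
    if strand_mode not in ("both", "forward"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")

    names = genome.names
    seqs = {n: genome.seq(n) for n in names}

    table: dict[str, list[tuple[str, int]]] = {}
    for name in names:
        s = seqs[name]
        for p in range(len(s) - w + 1):
            win = s[p : p + w]
            if "N" in win:
                continue
            table.setdefault(win, []).append((name, p))

    covered: dict[tuple, list[tuple[int, int]]] = {}
    blocks = set()

    def seen(key, p1) -> bool:
        for lo, hi in covered.get(key, ()):  # few runs per diagonal
            if lo <= p1 <= hi:
                return True
        return False

    def extend_same(c1, p1, c2, p2):
        key = (c1, c2, "+", p2 - p1)
        if seen(key, p1):
            return
        s1, s2 = seqs[c1], seqs[c2]
        l = 0
        while p1 - l - 1 >= 0 and p2 - l - 1 >= 0:
            a = s1[p1 - l - 1]
            if a == "N" or a != s2[p2 - l - 1]:
                break
            l += 1
        r = 0
        while p1 + w + r < len(s1) and p2 + w + r < len(s2):
            a = s1[p1 + w + r]
            if a == "N" or a != s2[p2 + w + r]:
                break
            r += 1
        loc_a = (c1, p1 - l, p1 + w + r)
        loc_b = (c2, p2 - l, p2 + w + r)
        covered.setdefault(key, []).append((p1 - l, p1 + r))
        if loc_a != loc_b:
            a, b = sorted((loc_a, loc_b))
            blocks.add((a, b, "+"))

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def extend_opp(c1, p1, c2, p2):
        key = (c1, c2, "-", p1 + p2)
        if seen(key, p1):
            return
        s1, s2 = seqs[c1], seqs[c2]
        r = 0
        while p1 + w + r < len(s1) and p2 - r - 1 >= 0:
            a = s1[p1 + w + r]
            if a == "N" or a != comp[s2[p2 - r - 1]]:
                break
            r += 1
        l = 0
        while p1 - l - 1 >= 0 and p2 + w + l < len(s2):
            a = s1[p1 - l - 1]
            if a == "N" or a != comp[s2[p2 + w + l]]:
                break
            l += 1
        loc_a = (c1, p1 - l, p1 + w + r)
        loc_b = (c2, p2 - r, p2 + w + l)
        covered.setdefault(key, []).append((p1 - l, p1 + r))
        if loc_a != loc_b:
            a, b = sorted((loc_a, loc_b))
            blocks.add((a, b, "-"))

    for win, lst in table.items():
        if len(lst) >= 2:
            for (c1, p1), (c2, p2) in itertools.combinations(lst, 2):
                extend_same(c1, p1, c2, p2)
        if strand_mode == "both":
            rc = revcomp(win)
            if rc in table and win < rc:
                for (c1, p1), (c2, p2) in itertools.product(table[win], table[rc]):
                    extend_opp(c1, p1, c2, p2)

    graph = nx.Graph()
    for a, b, rel in blocks:
        graph.add_edge(a, b, parity=0 if rel == "+" else 1)
    groups = []
    for comp_nodes in nx.connected_components(graph):
        nodes = sorted(comp_nodes)
        length = nodes[0][2] - nodes[0][1]
        parity = {nodes[0]: 0}
        for u, v in nx.bfs_edges(graph, nodes[0]):
            parity[v] = parity[u] ^ graph[u][v]["parity"]
        loci = [(c, s, "+" if parity[(c, s, e)] == 0 else "-") for c, s, e in nodes]
        groups.append(McsGroup("", length, loci))
    groups.sort(key=lambda g: (g.loci[0][0], g.loci[0][1], g.length))
    width = max(4, len(str(len(groups))))
    for i, g in enumerate(groups, 1):
        g.group_id = f"mcs{i:0{width}d}"
    return groups


def canonical_groups(groups: list[McsGroup]) -> set[tuple]:
    """Order- and id-independent canonical form for set comparison of group
    catalogues (used to assert finder == oracle)."""
    return {(g.length, tuple(sorted(g.loci))) for g in groups}


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def summarize_mcrs(
    groups: list[McsGroup], genome: Genome, bin_width: int = 50
) -> McrSummary:
    """Coverage, per-chromosome fraction, length and copy-number histograms."""
    all_ivs = [iv for g in groups for iv in g.intervals]
    for iv in all_ivs:
        genome.check_interval(iv)
    union = merge_intervals(all_ivs)
    cov = total_length(union) / genome.total_length
    per_chrom = {}
    for name, ln in genome.lengths.items():
        covered = sum(len(iv) for iv in union if iv.chrom == name)
        per_chrom[name] = covered / ln
    length_hist: dict[int, int] = {}
    copy_hist: dict[int, int] = {}
    n_intra = 0
    for g in groups:
        b = (g.length // bin_width) * bin_width
        length_hist[b] = length_hist.get(b, 0) + 1
        copy_hist[g.n_loci] = copy_hist.get(g.n_loci, 0) + 1
        n_intra += g.is_intra
    return McrSummary(
        coverage_fraction=cov,
        per_chrom_fraction=per_chrom,
        length_hist=dict(sorted(length_hist.items())),
        copy_number_hist=dict(sorted(copy_hist.items())),
        n_groups=len(groups),
        n_loci=sum(g.n_loci for g in groups),
        n_intra=n_intra,
        n_inter=len(groups) - n_intra,
        bin_width=bin_width,
    )
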