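import numpy as np
import pytest

from mcrkit.genomeio import Interval
from mcrkit.synthgenome import DuplicationSpec, build_truth_genome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_genome():
    """50 kb duplication-free background."""
    from mcrkit.synthgenome import generate_background

    return generate_background({"c1": 30_000, "c2": 20_000}, seed=101)


@pytest.fixture(scope="session")
def two_copy_build():
    """100 kb x 2 build with one 3 kb exact inter-chromosome duplication."""
    return build_truth_genome(
        {"c1": 100_000, "c2": 100_000},
        [DuplicationSpec(3000, 2, "inter")],
        seed=77,
    )


def bitmap_cover(intervals, lengths):
    """Per-base boolean bitmap oracle used to cross-check interval algebra."""
    maps = {n: np.zeros(ln, dtype=bool) for n, ln in lengths.items()}
    for iv in intervals:
        maps[iv.chrom][iv.start : iv.end] = True
    return maps


def intervals_from_bitmap(maps):
    out = []
    for name in sorted(maps):
        m = maps[name]
        edges = np.flatnonzero(np.diff(np.concatenate([[0], m.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(Interval(name, int(s), int(e)))
    return out


def random_intervals(rng, lengths, n, max_len=800):
    out = []
    names = list(lengths)
    for _ in range(n):
        c = names[int(rng.integers(len(names)))]
        ln = int(rng.integers(1, max_len))
        s = int(rng.integers(0, lengths[c] - ln))
        out.append(Interval(c, s, s + ln))
    return out
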