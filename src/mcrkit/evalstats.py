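"""Accuracy / false-positive / false-negative evaluation of called variants
against planted truth, stratified by region class, plus the matched-random-
region chi-squared enrichment test.

Definitions (applied per simulated dataset):

* TP — called variants present in the truth set (chrom, pos, alt);
* FP — called variants absent from the truth; FN — truth absent from calls;
* accuracy = TP/(TP+FP); fp_rate = FP/(TP+FP); fn_rate = FN/(TP+FN).

With an empty called set, accuracy and fp_rate are undefined and reported
as missing (NaN), never as zero.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomeio import Genome, Interval, VariantRecord, build_trees, merge_intervals


# ---------------------------------------------------------------------------
# classification and rates
# ---------------------------------------------------------------------------

def classify_calls(
    truth: list[VariantRecord],
    called: list[VariantRecord],
    match_on_genotype: bool = False,
) -> dict:
    """Partition calls into TP/FP and truth into TP/FN.

    A call is a true positive iff a truth variant shares chrom, pos and alt
    (and genotype when ``match_on_genotype``).  Genotype concordance among
    the TP is reported separately.  Duplicate positions within either set
    raise ``ValueError``.
    """
    for name, vs in (("truth", truth), ("called", called)):
        pos = [(v.chrom, v.pos) for v in vs]
        if len(set(pos)) != len(pos):
            raise ValueError(f"duplicate positions in the {name} set")

    def key(v):
        return v.key + ((v.genotype,) if match_on_genotype else ())

    truth_by_key = {key(v): v for v in truth}
    tp, fp = [], []
    for v in called:
        if key(v) in truth_by_key:
            tp.append(v)
        else:
            fp.append(v)
    tp_keys = {key(v) for v in tp}
    fn = [v for v in truth if key(v) not in tp_keys]
    gt_concordant = sum(
        1 for v in tp if truth_by_key[key(v)].genotype == v.genotype
    )
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "genotype_concordant": gt_concordant,
    }


def compute_rates(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(accuracy, fp_rate, fn_rate); undefined ratios are NaN, never 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    called = tp + fp
    truth = tp + fn
    acc = tp / called if called else float("nan")
    fpr = fp / called if called else float("nan")
    fnr = fn / truth if truth else float("nan")
    return acc, fpr, fnr


def assign_stratum(
    variants: list[VariantRecord], strata: dict[str, list[Interval]]
) -> list[str]:
    """Stratum of each variant's position; 'other' when in no stratum."""
    trees = {name: build_trees(ivs) for name, ivs in strata.items()}
    out = []
    for v in variants:
        s = "other"
        for name, t in trees.items():
            if v.chrom in t and t[v.chrom].overlaps(v.pos):
                s = name
                break
        out.append(s)
    return out


def evaluate_calls(
    truth: list[VariantRecord],
    called: list[VariantRecord],
    strata: dict[str, list[Interval]],
    strategy: str = "",
    replicate: int = 0,
    match_on_genotype: bool = False,
) -> pd.DataFrame:
    """One evaluation row per stratum (TP/FP/FN counts and the three rates).

    Calls falling outside every stratum are tallied under 'other' so that
    mis-mapped false positives are never silently dropped.
    """
    cls = classify_calls(truth, called, match_on_genotype)
    strata_names = list(strata) + ["other"]
    tallies = {s: {"TP": 0, "FP": 0, "FN": 0} for s in strata_names}
    for group in ("TP", "FP", "FN"):
        for v, s in zip(cls[group], assign_stratum(cls[group], strata)):
            tallies[s][group] += 1
    rows = []
    for s in strata_names:
        t = tallies[s]
        acc, fpr, fnr = compute_rates(t["TP"], t["FP"], t["FN"])
        rows.append(
            {
                "strategy": strategy,
                "replicate": replicate,
                "stratum": s,
                "TP": t["TP"],
                "FP": t["FP"],
                "FN": t["FN"],
                "accuracy": acc,
                "fp_rate": fpr,
                "fn_rate": fnr,
            }
        )
    return pd.DataFrame(rows)


def compare_strategies_ttest(
    reports: pd.DataFrame,
    metric: str = "accuracy",
    stratum: str | None = None,
    alpha_star: float = 1e-4,
) -> dict[str, pd.DataFrame]:
    """All-to-all two-sample t-tests on per-replicate metric values.

    Returns symmetric matrices of t statistics, p-values and significance
    stars (p < ``alpha_star``).  Identical zero-variance groups get p = 1
    by convention.
    """
    df = reports
    if stratum is not None:
        df = df[df["stratum"] == stratum]
    groups = {
        s: g[metric].dropna().to_numpy() for s, g in df.groupby("strategy", sort=True)
    }
    names = list(groups)
    for s, v in groups.items():
        if v.size < 2:
            raise ValueError(f"strategy {s!r} has fewer than 2 replicates")
    t_mat = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    p_mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            x, y = groups[a], groups[b]
            if np.var(x) == 0 and np.var(y) == 0:
                t, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(x, y, equal_var=True)
            t_mat.loc[a, b] = t
            t_mat.loc[b, a] = -t
            p_mat.loc[a, b] = p_mat.loc[b, a] = p
    star = p_mat.map(lambda p: "****" if p < alpha_star else "NS")
    for s in names:
        star.loc[s, s] = ""
    return {"t": t_mat, "p": p_mat, "stars": star}


# ---------------------------------------------------------------------------
# matched random regions and enrichment
# ---------------------------------------------------------------------------

def sample_matched_regions(
    template_intervals: list[Interval],
    genome: Genome,
    seed: int | np.random.Generator = 0,
    max_tries: int = 1000,
) -> list[Interval]:
    """Random non-overlapping regions matching the template's number and
    length multiset.

    Chromosomes are chosen with probability proportional to length,
    placement is uniform given the chromosome, and overlaps are rejected
    with bounded retries (longest regions placed first to ease packing).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = genome.names
    lens = np.array([genome.length(n) for n in names], dtype=float)
    p = lens / lens.sum()
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    out = []
    for L in sorted((len(iv) for iv in template_intervals), reverse=True):
        ok_chrom = [i for i, n in enumerate(names) if genome.length(n) >= L]
        if not ok_chrom:
            raise RuntimeError(f"no chromosome can host a {L} bp region")
        pc = p[ok_chrom] / p[ok_chrom].sum()
        placed = False
        for _ in range(max_tries):
            ci = ok_chrom[int(rng.choice(len(ok_chrom), p=pc))]
            name = names[ci]
            hi = genome.length(name) - L
            s = int(rng.integers(0, hi + 1))
            e = s + L
            if any(s < oe and e > os_ for os_, oe in occupied[name]):
                continue
            occupied[name].append((s, e))
            out.append(Interval(name, s, e))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {L} bp region after {max_tries} tries"
            )
    return sorted(out)


def chi_squared_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected chi-squared for the 2x2 table [[a, b], [c, d]].

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); returns (chi2, p) with
    1 degree of freedom.  Degenerate margins give (0, 1).
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / denom
    return chi2, float(stats.chi2.sf(chi2, df=1))


@dataclass
class EnrichmentResult:
    """Observed vs matched-shuffle overlap with chi-squared statistics."""

    observed: int
    n_query: int
    shuffled: np.ndarray          # overlap count per simulation
    chi2_per_sim: np.ndarray
    p_per_sim: np.ndarray
    pooled_chi2: float
    pooled_p: float
    empirical_p: float
    direction: str                # 'over', 'under' or 'none'


def count_overlapping(
    query: list[Interval], feature_trees: dict
) -> int:
    """Number of query intervals overlapping at least one feature."""
    n = 0
    for iv in query:
        t = feature_trees.get(iv.chrom)
        if t is not None and t.overlap(iv.start, iv.end):
            n += 1
    return n


def enrichment_test(
    query_intervals: list[Interval],
    feature_intervals: list[Interval],
    genome: Genome,
    n_sims: int = 1000,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Matched-random-region enrichment of query intervals in a feature set.

    The observed statistic is the number of query intervals overlapping at
    least one feature.  Each of ``n_sims`` simulations redraws the query as
    matched random regions (same number, same length multiset) and computes
    the same count; every simulation contributes a 2x2 chi-squared of
    (overlap, non-overlap) x (real, shuffled).  The headline p-value is the
    empirical two-sided permutation p; the per-simulation chi-squared tests
    are reported alongside.
    """
    if n_sims < 100:
        warnings.warn("fewer than 100 simulations: empirical p is unstable")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for iv in query_intervals:
        genome.check_interval(iv)
    ftrees = build_trees(merge_intervals(feature_intervals))
    nq = len(query_intervals)
    observed = count_overlapping(query_intervals, ftrees)

    shuffled = np.zeros(n_sims, dtype=np.int64)
    chi2s = np.zeros(n_sims)
    ps = np.ones(n_sims)
    for s in range(n_sims):
        rand = sample_matched_regions(query_intervals, genome, rng)
        cnt = count_overlapping(rand, ftrees)
        shuffled[s] = cnt
        chi2s[s], ps[s] = chi_squared_2x2(
            observed, nq - observed, cnt, nq - cnt
        )
    pooled_chi2, pooled_p = chi_squared_2x2(
        observed, nq - observed, int(shuffled.sum()), int(n_sims * nq - shuffled.sum())
    )
    # add-one two-sided permutation p (both tails, so a saturated statistic
    # where every shuffle ties the observed count yields p = 1)
    r_ge = (1 + int((shuffled >= observed).sum())) / (n_sims + 1)
    r_le = (1 + int((shuffled <= observed).sum())) / (n_sims + 1)
    empirical_p = min(1.0, 2 * min(r_ge, r_le))
    mean_sh = float(shuffled.mean())
    if observed > mean_sh:
        direction = "over"
    elif observed < mean_sh:
        direction = "under"
    else:
        direction = "none"
    return EnrichmentResult(
        observed=observed,
        n_query=nq,
        shuffled=shuffled,
        chi2_per_sim=chi2s,
        p_per_sim=ps,
        pooled_chi2=pooled_chi2,
        pooled_p=pooled_p,
        empirical_p=empirical_p,
        direction=direction,
    )
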