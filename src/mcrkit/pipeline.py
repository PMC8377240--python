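"""Orchestration of the full simulation grid.

A grid run crosses read lengths with sequencing depths, simulates the
configured number of replicate datasets per strategy (plant SNVs, build
haplotypes, simulate reads, map, call, evaluate), and returns one
evaluation row per (strategy, replicate, stratum) plus a manifest with
every derived seed and output checksum.  Per-cell seeds are derived from
``SeedSequence([base_seed, read_length, depth, replicate])`` so cells are
independent, and a run with the same config is bit-reproducible and
resumable cell by cell.
"""
from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .aligncall import build_index, map_batch, pileup_and_call
from .evalstats import evaluate_calls
from .genomeio import Genome, Interval, read_bed, read_fasta
from .htssim import SimStrategy, build_haplotypes, define_strata, plant_snvs, simulate_read_pairs
from .mcrfinder import find_mcrs
from .synthgenome import DuplicationSpec, build_truth_genome


@dataclass
class ExperimentConfig:
    """Configuration of one experiment grid.

    By default a synthetic build with two 500 kb chromosomes and ten
    planted 2-copy exact duplications of 2–5 kb is generated; a FASTA path
    (plus optional MCR BED) may be supplied instead.  The default strategy
    grid mirrors PE75/PE150 x {10, 30, 50, 100}x with 20 replicates.
    """

    # genome source
    fasta_path: str | None = None
    mcr_bed: str | None = None
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 500_000}
    )
    gc_content: float = 0.41
    n_duplications: int = 10
    dup_length_range: tuple[int, int] = (2000, 5000)
    dup_copies: int = 2
    # finder
    window: int = 300
    step: int = 1
    strand_mode: str = "both"
    # variants and sequencing
    snv_rate: float = 0.001
    het_fraction: float = 0.5
    error_rate: float = 0.01
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    kmer: int = 31
    # grid
    read_lengths: tuple[int, ...] = (75, 150)
    depths: tuple[float, ...] = (10, 30, 50, 100)
    replicates: int = 20
    base_seed: int = 1
    # sampling restriction: draw fragments only around the evaluation strata
    # (padded by the maximum fragment length), preserving local depth
    restrict_to_strata: bool = True
    out_dir: str | None = None

    def __post_init__(self):
        if not self.read_lengths or not self.depths:
            raise ValueError("strategy grid must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")

    def cells(self) -> list[tuple[int, float, int]]:
        """All (read_length, depth, replicate) cells of the factorial grid."""
        return [
            (rl, d, rep)
            for rl in self.read_lengths
            for d in self.depths
            for rep in range(self.replicates)
        ]


def cell_seed_sequence(
    base_seed: int, read_length: int, depth: float, replicate: int
) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(base_seed), int(read_length), int(depth), int(replicate)]
    )


@dataclass
class PreparedExperiment:
    """Genome, MCR catalogue, strata and read-mapping index shared by cells."""

    genome: Genome
    mcr_intervals: list[Interval]
    strata: dict[str, list[Interval]]
    index: object
    truth_bed: list[Interval] | None = None


def prepare_experiment(config: ExperimentConfig) -> PreparedExperiment:
    """Build or load the genome, discover MCRs and define strata once."""
    truth = None
    if config.fasta_path is not None:
        genome = read_fasta(config.fasta_path)
        if config.mcr_bed is not None:
            mcr_ivs = read_bed(config.mcr_bed)
        else:
            groups = find_mcrs(
                genome, w=config.window, step=config.step, strand_mode=config.strand_mode
            )
            mcr_ivs = [iv for g in groups for iv in g.intervals]
    else:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.base_seed, 0xB0117])
        )
        lo, hi = config.dup_length_range
        specs = [
            DuplicationSpec(int(rng.integers(lo, hi + 1)), config.dup_copies, "inter")
            for _ in range(config.n_duplications)
        ]
        build = build_truth_genome(
            config.chrom_lengths,
            specs,
            gc_content=config.gc_content,
            seed=int(rng.integers(0, 2**31)),
        )
        genome = build.genome
        truth = build.truth
        groups = find_mcrs(
            genome, w=config.window, step=config.step, strand_mode=config.strand_mode
        )
        mcr_ivs = [iv for g in groups for iv in g.intervals]
    strata = define_strata(mcr_ivs, genome)
    index = build_index(genome, k=config.kmer)
    return PreparedExperiment(genome, mcr_ivs, strata, index, truth)


def run_cell(
    prep: PreparedExperiment,
    config: ExperimentConfig,
    read_length: int,
    depth: float,
    replicate: int,
) -> tuple[pd.DataFrame, dict]:
    """Plant -> simulate -> map -> call -> evaluate for one grid cell."""
    ss = cell_seed_sequence(config.base_seed, read_length, depth, replicate)
    rng_plant, rng_hap, rng_sim = (np.random.default_rng(c) for c in ss.spawn(3))
    strategy = SimStrategy(
        read_length=read_length,
        depth=depth,
        error_rate=config.error_rate,
        insert_mean=config.insert_mean,
        insert_sd=config.insert_sd,
    )
    variants = plant_snvs(
        prep.strata, prep.genome, config.snv_rate, config.het_fraction, rng_plant
    )
    haps = build_haplotypes(prep.genome, variants, rng_hap)
    regions = None
    if config.restrict_to_strata:
        regions = prep.strata["MCR"] + prep.strata["flank"]
    batch = simulate_read_pairs(haps, strategy, rng_sim, regions=regions)
    res = map_batch(
        batch,
        prep.index,
        insert_mean=config.insert_mean,
        insert_sd=config.insert_sd,
    )
    called = pileup_and_call(res, prep.genome)
    report = evaluate_calls(
        variants, called, prep.strata, strategy.label, replicate
    )
    meta = {
        "strategy": strategy.label,
        "replicate": replicate,
        "seed_entropy": [int(x) for x in ss.entropy],
        "n_truth": len(variants),
        "n_called": len(called),
        **res.stats(),
    }
    return report, meta


def _cell_path(out_dir: Path, label: str, rep: int) -> Path:
    return out_dir / "cells" / f"{label}_rep{rep}.tsv"


def run_experiment_grid(
    config: ExperimentConfig,
    prep: PreparedExperiment | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full factorial grid; returns (report table, manifest).

    With ``config.out_dir`` set, per-cell reports are written as TSV and a
    finished cell found on disk is loaded instead of recomputed, so a run
    is resumable cell by cell.  A failing cell is recorded in the manifest
    and does not abort the others.
    """
    if prep is None:
        prep = prepare_experiment(config)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        (out_dir / "cells").mkdir(parents=True, exist_ok=True)

    frames = []
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "n_cells": len(config.cells()),
        "cells": [],
        "failures": [],
    }
    for rl, depth, rep in config.cells():
        label = SimStrategy(
            read_length=rl, depth=depth, insert_mean=config.insert_mean
        ).label
        t0 = time.perf_counter()
        try:
            if out_dir and _cell_path(out_dir, label, rep).exists():
                df = pd.read_csv(_cell_path(out_dir, label, rep), sep="\t")
                meta = {"strategy": label, "replicate": rep, "resumed": True}
            else:
                df, meta = run_cell(prep, config, rl, depth, rep)
                if out_dir:
                    df.to_csv(_cell_path(out_dir, label, rep), sep="\t", index=False)
        except Exception as exc:  # cell independence: record and continue
            warnings.warn(f"cell {label} rep {rep} failed: {exc}")
            manifest["failures"].append(
                {"strategy": label, "replicate": rep, "error": str(exc)}
            )
            continue
        csum = hashlib.sha256(
            df.to_csv(sep="\t", index=False).encode()
        ).hexdigest()
        meta["checksum"] = csum
        meta["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["cells"].append(meta)
        frames.append(df)

    report = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "strategy", "replicate", "stratum",
                "TP", "FP", "FN", "accuracy", "fp_rate", "fn_rate",
            ]
        )
    )
    if out_dir:
        report.to_csv(out_dir / "report.tsv", sep="\t", index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return report, manifest
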