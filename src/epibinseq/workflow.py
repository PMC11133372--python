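"""End-to-end binning experiments: simulate -> sort -> sequence -> count
-> enrich -> classify.

One experiment stains the displayed-clone cell library with a reference
antibody at a chosen concentration, sorts the rAb-non-binding
population, sequences barcoded amplicons from the sorted cells and from
the unsorted library, processes the reads into clone counts, and
computes negative-control-anchored relative enrichment; clones enriched
under an rAb join that rAb's epitope bin.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .amplicon import AmpliconDesign, default_design, generate_reads, write_fastq
from .clones import CloneSpec, RAbSpec, default_library, default_rabs
from .cytometry import GateResult, SimConfig, gate_and_sort, simulate_cell_events
from .enrichment import (
    BinResult,
    EnrichmentTable,
    classify_bins,
    compute_enrichment,
)
from .pipeline import CountTable, RunQC, process_run

__all__ = [
    "Condition",
    "ExperimentConfig",
    "BinningRun",
    "percent_rab_negative",
    "run_binning_experiment",
]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass(frozen=True)
class Condition:
    """One staining/sorting condition of the experiment."""

    sample_id: str
    rab_id: str
    concentration: float  # nM


@dataclass
class ExperimentConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    conditions: tuple[Condition, ...] = ()
    binning_samples: tuple[str, ...] = ()  # conditions whose RER defines bins
    library_sample: str = "library"
    n_reads: int = 100_000
    negative_control: str = "Niv"
    threshold: float = 3.0


@dataclass
class BinningRun:
    """Everything one experiment produced."""

    gates: dict[str, GateResult]
    count_tables: dict[str, CountTable]
    qc: RunQC
    enrichment: dict[str, EnrichmentTable]  # sample_id -> table
    bins: BinResult | None


def percent_rab_negative(
    config: SimConfig,
    clone: CloneSpec,
    rab: RAbSpec,
    seed: int | None = None,
) -> float:
    """Percent of cells of one displayed clone below the auto rAb gate.

    Simulates a pure population of ``clone`` stained with ``rab`` and
    gates at the background quantile, as in a single-clone FCM
    epitope-blocking readout.
    """
    seed = config.seed if seed is None else seed
    pure = replace(clone, library_frequency=1.0)
    events = simulate_cell_events(config, [pure], [rab], seed=seed)
    gate = gate_and_sort(events, rab.channel, "auto", config, seed=seed + 1)
    return gate.percent_negative


def run_binning_experiment(
    config: ExperimentConfig,
    library: Sequence[CloneSpec] | None = None,
    rabs: Mapping[str, RAbSpec] | None = None,
    design: AmpliconDesign | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> BinningRun:
    """Run the full pipeline for every configured condition.

    The unsorted library sample is sequenced from the simulated cell
    population's clone counts; each sorted sample from the clone counts
    of the rAb(-) gate of its own staining simulation.  All randomness
    descends deterministically from ``seed``.
    """
    library = list(default_library() if library is None else library)
    rabs = dict(default_rabs() if rabs is None else rabs)
    design = default_design() if design is None else design

    samples = [config.library_sample, *(c.sample_id for c in config.conditions)]
    for s in samples:
        if s not in design.sample_barcodes:
            raise KeyError(f"sample {s!r} has no barcode in the amplicon design")

    seeds = spawn_seeds(seed, 2 * len(config.conditions) + 3)
    seed_iter = iter(seeds)

    # unsorted library population -> library-sample clone frequencies
    lib_events = simulate_cell_events(config.sim, library, [], seed=next(seed_iter))
    lib_counts = lib_events["clone_id"].value_counts().to_dict()
    lib_total = sum(lib_counts.values())
    lib_freqs = {c: n / lib_total for c, n in lib_counts.items()}

    gates: dict[str, GateResult] = {}
    sorted_freqs: dict[str, dict[str, float]] = {}
    for cond in config.conditions:
        if cond.rab_id not in rabs:
            raise KeyError(f"unknown rAb {cond.rab_id!r}")
        rab = rabs[cond.rab_id].at(cond.concentration)
        events = simulate_cell_events(config.sim, library, [rab], seed=next(seed_iter))
        gate = gate_and_sort(events, rab.channel, "auto", config.sim, seed=next(seed_iter))
        if gate.n_sorted == 0:
            raise RuntimeError(f"condition {cond.sample_id!r}: no cells passed the sort gate")
        gates[cond.sample_id] = gate
        total = gate.n_sorted
        sorted_freqs[cond.sample_id] = {c: n / total for c, n in gate.sorted_counts.items()}

    # sequencing
    read_seeds = spawn_seeds(seeds[-1], len(samples))
    all_reads = []
    for s, rs in zip(samples, read_seeds):
        freqs = lib_freqs if s == config.library_sample else sorted_freqs[s]
        all_reads.extend(generate_reads(freqs, design, library, s, config.n_reads, rs))

    if out_dir is None:
        tmp = tempfile.TemporaryDirectory()
        fastq_path = Path(tmp.name) / "run.fastq"
    else:
        tmp = None
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fastq_path = out_dir / "run.fastq"
    try:
        write_fastq(all_reads, fastq_path)
        tables, qc = process_run(fastq_path, design, library, samples)
    finally:
        if tmp is not None:
            tmp.cleanup()

    lib_table = tables[config.library_sample]
    enrichment: dict[str, EnrichmentTable] = {}
    for cond in config.conditions:
        enrichment[cond.sample_id] = compute_enrichment(
            lib_table, tables[cond.sample_id], config.negative_control
        )

    bins = None
    if config.binning_samples:
        rab_of = {c.sample_id: c.rab_id for c in config.conditions}
        by_rab = {rab_of[s]: enrichment[s] for s in config.binning_samples}
        bins = classify_bins(by_rab, config.threshold)

    run = BinningRun(gates, tables, qc, enrichment, bins)
    if out_dir is not None:
        for s, table in tables.items():
            table.write_tsv(out_dir / f"counts_{s}.tsv")
        for s, et in enrichment.items():
            et.write_tsv(out_dir / f"enrichment_{s}.tsv")
        if bins is not None:
            bins.write_json(out_dir / "bins.json")
    return run
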