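"""Read processing: quality filter -> primer match -> demux -> assign.

Mirrors the wet-lab amplicon analysis chain: sliding-window quality
trimming with a minimum-length floor, retention of reads carrying the
forward primer, barcode demultiplexing into samples, translation of the
in-frame insert segment, and exact-match assignment of the translated
identification window to a clone reference.  Every attrition step is
tallied so the QC chain

    reads_assigned <= reads_demuxed <= reads_primer_matched
                   <= reads_after_quality <= reads_in

can be asserted on any run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .amplicon import AmpliconDesign, ReadRecord, read_fastq
from .clones import CloneSpec, translate

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "RunQC",
    "quality_filter",
    "demux_and_match",
    "translate_and_assign",
    "process_run",
]

UNASSIGNED = "unassigned"


@dataclass
class RunQC:
    """Attrition tallies over one processed FASTQ."""

    reads_in: int = 0
    reads_after_quality: int = 0
    reads_primer_matched: int = 0
    reads_demuxed: int = 0
    reads_assigned: int = 0

    def assert_chain(self) -> None:
        chain = (
            self.reads_assigned,
            self.reads_demuxed,
            self.reads_primer_matched,
            self.reads_after_quality,
            self.reads_in,
        )
        if any(a > b for a, b in zip(chain, chain[1:])):
            raise AssertionError(f"QC tally chain is not monotone: {self}")

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_in": self.reads_in,
            "reads_after_quality": self.reads_after_quality,
            "reads_primer_matched": self.reads_primer_matched,
            "reads_demuxed": self.reads_demuxed,
            "reads_assigned": self.reads_assigned,
        }


@dataclass
class CountTable:
    """Per-sample clone read counts plus the run's QC tallies.

    The first three QC fields are run-level (quality filtering and
    primer matching happen before reads have a sample identity);
    ``reads_demuxed`` and ``reads_assigned`` are specific to this
    sample.
    """

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    qc: RunQC = field(default_factory=RunQC)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def assert_invariants(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise AssertionError("negative clone count")
        if self.total != self.qc.reads_assigned:
            raise AssertionError("sum(counts) != reads_assigned")
        self.qc.assert_chain()

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tclone_id\tcount\n")
            for cid in sorted(self.counts):
                fh.write(f"{self.sample_id}\t{cid}\t{self.counts[cid]}\n")

    @staticmethod
    def read_tsv(path) -> "CountTable":
        lines = Path(path).read_text().splitlines()
        table: CountTable | None = None
        for row in lines[1:]:
            if not row.strip():
                continue
            sample_id, clone_id, count = row.split("\t")
            if table is None:
                table = CountTable(sample_id)
            elif table.sample_id != sample_id:
                raise ValueError(f"multiple samples in {path}")
            table.counts[clone_id] = table.counts.get(clone_id, 0) + int(count)
        if table is None:
            raise ValueError(f"no count rows in {path}")
        table.qc.reads_assigned = table.total
        table.qc.reads_demuxed = table.total
        table.qc.reads_primer_matched = table.total
        table.qc.reads_after_quality = table.total
        table.qc.reads_in = table.total
        return table


def quality_filter(
    read: ReadRecord,
    window: int = 20,
    min_mean_q: float = 20.0,
    min_len: int = 50,
) -> ReadRecord | None:
    """Sliding-window quality trim with a minimum-length floor.

    Scanning 5'->3', the read is cut immediately before the start of the
    first length-``window`` window whose mean Phred quality drops below
    ``min_mean_q``; reads shorter than the window are judged as a single
    window of their full length.  Reads shorter than ``min_len`` after
    trimming are dropped (``None``).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(read.qualities, dtype=float)
    n = len(q)
    if n == 0:
        return None
    if n < window:
        keep = n if q.mean() >= min_mean_q else 0
    else:
        csum = np.concatenate(([0.0], np.cumsum(q)))
        means = (csum[window:] - csum[:-window]) / window  # means[i] = window at i
        failing = np.nonzero(means < min_mean_q)[0]
        keep = int(failing[0]) if len(failing) else n
    if keep < min_len:
        return None
    if keep == n:
        return read
    return ReadRecord(read.read_id, read.sequence[:keep], read.qualities[:keep])


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demux_and_match(
    read: ReadRecord,
    design: AmpliconDesign,
    max_primer_mismatch: int = 0,
) -> tuple[str, bool]:
    """Primer-match and barcode-assign one quality-filtered read.

    Returns ``(sample_id, primer_matched)``; ``sample_id`` is
    ``"unassigned"`` when the primer does not match within
    ``max_primer_mismatch`` substitutions or the 6-bp barcode prefix is
    not registered (barcode matching is exact).
    """
    bl = design.barcode_length
    primer = design.fwd_primer
    segment = read.sequence[bl : bl + len(primer)]
    if len(segment) < len(primer) or _mismatches(segment, primer) > max_primer_mismatch:
        return UNASSIGNED, False
    barcode = read.sequence[:bl]
    for sample_id, bc in design.sample_barcodes.items():
        if barcode == bc:
            return sample_id, True
    return UNASSIGNED, True


def prepare_reference_windows(
    design: AmpliconDesign, reference: Sequence[CloneSpec]
) -> dict[str, str]:
    """Map each clone's identification window (over the design's codon
    span) to its clone_id, verifying uniqueness."""
    lo, hi = design.aa_window_span
    windows: dict[str, str] = {}
    for clone in reference:
        aa = clone.aa_window
        if len(aa) < hi:
            raise ValueError(
                f"{clone.clone_id}: aa_window shorter than the design window span"
            )
        key = aa[lo:hi]
        if key in windows:
            raise ValueError(
                f"identification window {key!r} shared by "
                f"{windows[key]!r} and {clone.clone_id!r}"
            )
        windows[key] = clone.clone_id
    return windows


def translate_and_assign(
    read: ReadRecord,
    design: AmpliconDesign,
    reference: Sequence[CloneSpec] | Mapping[str, str],
) -> str:
    """Translate the insert and match the identification window exactly.

    The in-frame segment starts ``insert_frame_offset`` bases after the
    forward primer; the ``aa_window_span`` codons are translated and
    compared by exact string equality against the reference windows.
    Ambiguous bases or stop codons inside the window, or a read too
    short to cover it, give ``"unassigned"``.
    """
    windows = (
        reference
        if isinstance(reference, Mapping)
        else prepare_reference_windows(design, reference)
    )
    lo, hi = design.aa_window_span
    start = design.prefix_length + design.insert_frame_offset + 3 * lo
    end = design.prefix_length + design.insert_frame_offset + 3 * hi
    if len(read.sequence) < end:
        return UNASSIGNED
    segment = read.sequence[start:end]
    if set(segment) - set("ACGT"):
        return UNASSIGNED
    aa = translate(segment)
    if "*" in aa:
        return UNASSIGNED
    return windows.get(aa, UNASSIGNED)


def process_run(
    fastq_path,
    design: AmpliconDesign,
    reference: Sequence[CloneSpec],
    samples: Sequence[str] | None = None,
    *,
    window: int = 20,
    min_mean_q: float = 20.0,
    min_len: int = 50,
    max_primer_mismatch: int = 0,
) -> tuple[dict[str, CountTable], RunQC]:
    """Run the full chain over a FASTQ and emit per-sample count tables.

    ``samples`` defaults to every sample in the design.  Deterministic
    given the input file.  Malformed FASTQ raises a format error naming
    the offending record.
    """
    if samples is None:
        samples = list(design.sample_barcodes)
    unknown = set(samples) - set(design.sample_barcodes)
    if unknown:
        raise KeyError(f"samples without barcodes: {sorted(unknown)}")
    windows = prepare_reference_windows(design, reference)

    run_qc = RunQC()
    tables = {s: CountTable(s) for s in samples}
    demuxed = {s: 0 for s in samples}
    assigned = {s: 0 for s in samples}

    for read in read_fastq(fastq_path):
        run_qc.reads_in += 1
        trimmed = quality_filter(read, window=window, min_mean_q=min_mean_q, min_len=min_len)
        if trimmed is None:
            continue
        run_qc.reads_after_quality += 1
        sample_id, matched = demux_and_match(trimmed, design, max_primer_mismatch)
        if not matched:
            continue
        run_qc.reads_primer_matched += 1
        if sample_id == UNASSIGNED or sample_id not in tables:
            continue
        run_qc.reads_demuxed += 1
        demuxed[sample_id] += 1
        clone_id = translate_and_assign(trimmed, design, windows)
        if clone_id == UNASSIGNED:
            continue
        run_qc.reads_assigned += 1
        assigned[sample_id] += 1
        table = tables[sample_id]
        table.counts[clone_id] = table.counts.get(clone_id, 0) + 1

    for s, table in tables.items():
        table.qc = RunQC(
            reads_in=run_qc.reads_in,
            reads_after_quality=run_qc.reads_after_quality,
            reads_primer_matched=run_qc.reads_primer_matched,
            reads_demuxed=demuxed[s],
            reads_assigned=assigned[s],
        )
        table.assert_invariants()
    run_qc.assert_chain()
    logger.info("processed %s: %s", fastq_path, run_qc.as_dict())
    return tables, run_qc


def write_qc_json(qc: RunQC, path) -> None:
    Path(path).write_text(json.dumps(qc.as_dict(), indent=2) + "\n")
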