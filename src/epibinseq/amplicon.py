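"""Barcoded amplicon read simulation and FASTQ I/O.

Reads follow the nested-PCR amplicon architecture used for clone
counting: a 6-bp sample barcode, a fixed forward primer, then the clone
variable-region insert, sequenced single-end.  Substitution errors are
iid per base; qualities follow a configurable per-position profile with
Gaussian jitter, high (~Q35) over the head of the read and decaying
toward ~Q15 over the final 20%, which exercises downstream
sliding-window trimming.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .clones import CloneSpec

__all__ = [
    "AmpliconDesign",
    "ReadRecord",
    "default_design",
    "generate_reads",
    "write_fastq",
    "read_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

FWD_PRIMER = "TGGGTAAGACAAGCTCCAGG"
REV_PRIMER = "CCTTGTCCCCAATAGTC"


@dataclass(frozen=True)
class ReadRecord:
    """One single-end read: id, bases, per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")
        if self.qualities and not all(0 <= q <= 60 for q in self.qualities):
            raise ValueError(f"{self.read_id}: Phred qualities outside [0, 60]")


def _default_quality_profile(read_length: int) -> tuple[float, ...]:
    """Q35 head decaying to a ~Q15 tail beyond 80% of the read.

    The low tail drives the downstream sliding-window trimmer to cut
    reads back to roughly the first 80%, which still covers the
    identification window.
    """
    knee = int(0.8 * read_length)
    ramp = min(8, max(read_length - knee, 1))
    prof = np.full(read_length, 35.0)
    if read_length > knee:
        prof[knee : knee + ramp] = np.linspace(35.0, 15.0, ramp)
        prof[knee + ramp :] = 15.0
    return tuple(prof)


@dataclass(frozen=True)
class AmpliconDesign:
    """Amplicon layout shared by the simulator and the read pipeline."""

    sample_barcodes: Mapping[str, str]
    fwd_primer: str = FWD_PRIMER
    rev_primer: str = REV_PRIMER
    barcode_length: int = 6
    read_length: int = 116
    insert_frame_offset: int = 0  # bases from primer end to first full codon
    aa_window_span: tuple[int, int] = (5, 15)  # codon interval, 0-based half-open
    per_base_error_rate: float = 1e-3
    quality_profile: tuple[float, ...] | None = None
    quality_jitter_sd: float = 2.0

    def __post_init__(self) -> None:
        seen = set()
        for sample, bc in self.sample_barcodes.items():
            if len(bc) != self.barcode_length:
                raise ValueError(f"barcode for {sample!r} is not {self.barcode_length} bp")
            if set(bc) - set("ACGT"):
                raise ValueError(f"barcode for {sample!r} contains non-ACGT characters")
            if bc in seen:
                raise ValueError(f"duplicate barcode {bc!r}")
            seen.add(bc)
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate must lie in [0, 1)")
        lo, hi = self.aa_window_span
        needed = self.barcode_length + len(self.fwd_primer) + self.insert_frame_offset + 3 * hi
        if self.read_length < needed:
            raise ValueError(
                f"read_length {self.read_length} too short to cover the "
                f"identification window (needs >= {needed})"
            )
        if self.quality_profile is None:
            object.__setattr__(self, "quality_profile", _default_quality_profile(self.read_length))
        elif len(self.quality_profile) != self.read_length:
            raise ValueError("quality_profile length must equal read_length")

    @property
    def prefix_length(self) -> int:
        return self.barcode_length + len(self.fwd_primer)


def default_design() -> AmpliconDesign:
    """Design shipped with the package: five barcoded samples."""
    return AmpliconDesign(
        sample_barcodes={
            "library": "ACGTAC",
            "sorted_pert_0.1nM": "TGCATG",
            "sorted_pert_10nM": "GATCGA",
            "sorted_tras_0.1nM": "CTAGCT",
            "sorted_tras_10nM": "AGATCG",
        }
    )


def generate_reads(
    freqs: Mapping[str, float],
    design: AmpliconDesign,
    reference: Sequence[CloneSpec],
    sample_id: str,
    n_reads: int,
    seed: int,
) -> list[ReadRecord]:
    """Simulate single-end reads for one barcoded sample.

    Each read's source clone is multinomial in ``freqs``; its sequence
    is barcode + forward primer + clone insert, truncated to the design
    read length; substitution errors are iid at the design error rate.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if sample_id not in design.sample_barcodes:
        raise KeyError(f"sample {sample_id!r} has no registered barcode")
    clone_ids = sorted(freqs)
    p = np.array([freqs[c] for c in clone_ids], dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"clone frequencies sum to {p.sum()}, not 1")
    p = p / p.sum()
    by_id = {c.clone_id: c for c in reference}
    for cid in clone_ids:
        if cid not in by_id:
            raise KeyError(f"clone {cid!r} absent from reference")
    if n_reads == 0:
        return []

    rng = np.random.default_rng(seed)
    barcode = design.sample_barcodes[sample_id]
    templates = {}
    for cid in clone_ids:
        full = barcode + design.fwd_primer + by_id[cid].dna_insert
        templates[cid] = np.frombuffer(
            full[: design.read_length].encode(), dtype="S1"
        )

    assignment = rng.choice(len(clone_ids), size=n_reads, p=p)
    profile = np.asarray(design.quality_profile, dtype=float)

    reads = []
    for i in range(n_reads):
        cid = clone_ids[assignment[i]]
        bases = templates[cid].copy()
        L = len(bases)
        if design.per_base_error_rate > 0:
            err = rng.random(L) < design.per_base_error_rate
            n_err = int(err.sum())
            if n_err:
                # substitute with one of the three other bases
                shift = rng.integers(1, 4, size=n_err)
                idx = np.searchsorted(_BASES, bases[err])
                bases[err] = _BASES[(idx + shift) % 4]
        quals = np.clip(
            np.rint(profile[:L] + rng.normal(0.0, design.quality_jitter_sd, L)), 2, 41
        ).astype(int)
        reads.append(
            ReadRecord(
                read_id=f"{sample_id}:{cid}:{i}",
                sequence=bases.tobytes().decode(),
                qualities=tuple(int(q) for q in quals),
            )
        )
    return reads


# --- FASTQ I/O (Phred+33) ---------------------------------------------------

def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path) -> Iterator[ReadRecord]:
    """Parse a Phred+33 FASTQ (plain or gzip), validating record structure."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record at {header!r}")
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch in record {header!r}")
            yield ReadRecord(
                read_id=header[1:].split()[0] if len(header) > 1 else "",
                sequence=seq,
                qualities=tuple(ord(c) - 33 for c in qual),
            )
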