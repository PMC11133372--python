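"""Enrichment statistics and epitope-bin classification.

A clone's *occupancy* is its read count divided by the sample's total
assigned count.  The *enrichment ratio* (ER) compares sorted-sample
occupancy to original-library occupancy; the *relative enrichment
ratio* (RER) rescales ER so the antigen-non-binding negative control
equals exactly 1.  A clone is substantially enriched under an rAb when
RER > 3 (strict), and the set of rAbs under which it is enriched is its
epitope bin; clones enriched under none are "ungrouped".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .pipeline import CountTable

__all__ = [
    "EnrichmentTable",
    "BinResult",
    "compute_occupancy",
    "compute_enrichment",
    "classify_bins",
    "pool_size_capability",
    "UNGROUPED",
]

UNGROUPED = "ungrouped"
DEFAULT_THRESHOLD = 3.0


def compute_occupancy(
    counts: CountTable, clone_ids: Sequence[str] | None = None, pseudocount: float = 0.0
) -> dict[str, float]:
    """Fraction of assigned reads per clone.

    ``clone_ids`` extends the output to clones absent from the counts
    (occupancy 0, or the pseudocount share when ``pseudocount > 0``).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    ids = sorted(set(counts.counts) | set(clone_ids or []))
    n_clones = len(ids)
    total = counts.total + pseudocount * n_clones
    if total <= 0:
        raise ValueError(f"sample {counts.sample_id!r} has no assigned reads")
    return {cid: (counts.counts.get(cid, 0) + pseudocount) / total for cid in ids}


@dataclass
class EnrichmentTable:
    """Per-clone occupancy, ER and RER for one sorted sample."""

    table: pd.DataFrame  # index clone_id; columns occupancy_library, occupancy_sorted, enrichment_ratio, relative_enrichment
    negative_control_id: str
    excluded: tuple[str, ...] = ()
    threshold: float = DEFAULT_THRESHOLD

    def rer(self, clone_id: str) -> float:
        return float(self.table.loc[clone_id, "relative_enrichment"])

    @property
    def clone_ids(self) -> list[str]:
        return list(self.table.index)

    def enriched(self, threshold: float | None = None) -> set[str]:
        t = self.threshold if threshold is None else threshold
        col = self.table["relative_enrichment"]
        return set(col.index[col > t])

    def assert_invariants(self) -> None:
        for col in ("occupancy_library", "occupancy_sorted"):
            s = self.table[col].sum()
            if abs(s - 1.0) > 1e-9:
                raise AssertionError(f"{col} sums to {s}, not 1")
        if abs(self.rer(self.negative_control_id) - 1.0) > 0:
            raise AssertionError("negative-control RER != 1")
        if (self.table[["enrichment_ratio", "relative_enrichment"]] < 0).any().any():
            raise AssertionError("negative enrichment value")

    def write_tsv(self, path) -> None:
        out = self.table.sort_index()
        out.to_csv(path, sep="\t", index_label="clone_id")

    @staticmethod
    def read_tsv(path, negative_control_id: str) -> "EnrichmentTable":
        df = pd.read_csv(path, sep="\t", index_col="clone_id")
        return EnrichmentTable(df, negative_control_id)


def compute_enrichment(
    library: CountTable,
    sorted_sample: CountTable,
    negative_control_id: str,
    pseudocount: float = 0.0,
) -> EnrichmentTable:
    """ER and negative-control-anchored RER for every clone.

    Clones with zero library occupancy (and zero pseudocount) cannot
    receive a finite ER; they are excluded from the table and reported
    in ``excluded``.  The negative control must have nonzero occupancy
    in both samples.
    """
    all_ids = sorted(set(library.counts) | set(sorted_sample.counts))
    occ_lib = compute_occupancy(library, all_ids, pseudocount)
    occ_sorted = compute_occupancy(sorted_sample, all_ids, pseudocount)

    if negative_control_id not in all_ids:
        raise ValueError(f"negative control {negative_control_id!r} absent from counts")
    if occ_lib[negative_control_id] == 0 or occ_sorted[negative_control_id] == 0:
        raise ValueError(
            f"negative control {negative_control_id!r} has zero occupancy; "
            "cannot anchor relative enrichment"
        )

    excluded = tuple(cid for cid in all_ids if occ_lib[cid] == 0)
    kept = [cid for cid in all_ids if occ_lib[cid] > 0]

    er = {cid: occ_sorted[cid] / occ_lib[cid] for cid in kept}
    er_control = er[negative_control_id]
    rer = {cid: er[cid] / er_control for cid in kept}
    # renormalise occupancies over the kept clones so the table's
    # normalisation invariant holds after exclusions
    lib_sum = sum(occ_lib[c] for c in kept)
    srt_sum = sum(occ_sorted[c] for c in kept)
    df = pd.DataFrame(
        {
            "occupancy_library": [occ_lib[c] / lib_sum for c in kept],
            "occupancy_sorted": [occ_sorted[c] / srt_sum for c in kept],
            "enrichment_ratio": [er[c] for c in kept],
            "relative_enrichment": [rer[c] for c in kept],
        },
        index=pd.Index(kept, name="clone_id"),
    )
    result = EnrichmentTable(df, negative_control_id, excluded)
    result.assert_invariants()
    return result


@dataclass
class BinResult:
    """Epitope-bin membership per clone: one label per enriching rAb."""

    bins: dict[str, tuple[str, ...]]  # clone_id -> sorted rAb ids (empty = ungrouped)
    threshold: float = DEFAULT_THRESHOLD

    def label(self, clone_id: str) -> str:
        members = self.bins[clone_id]
        return "+".join(members) if members else UNGROUPED

    def members_of(self, rab_id: str) -> set[str]:
        return {c for c, labels in self.bins.items() if rab_id in labels}

    @property
    def ungrouped(self) -> set[str]:
        return {c for c, labels in self.bins.items() if not labels}

    def n_bins(self) -> int:
        """Number of distinct labels over the panel, counting ungrouped
        (if any clone is ungrouped) as one bin."""
        return len({self.label(c) for c in self.bins})

    def write_json(self, path) -> None:
        payload = {
            "threshold": self.threshold,
            "bins": {c: list(v) for c, v in sorted(self.bins.items())},
            "labels": {c: self.label(c) for c in sorted(self.bins)},
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def classify_bins(
    tables: Mapping[str, EnrichmentTable],
    threshold: float = DEFAULT_THRESHOLD,
) -> BinResult:
    """Assign each clone to the bins of every rAb with RER > threshold.

    The inequality is strict: RER exactly at the threshold is not
    enriched.  All tables must cover the same clone set.
    """
    rab_ids = sorted(tables)
    if not rab_ids:
        raise ValueError("no enrichment tables given")
    clone_sets = {rid: set(tables[rid].clone_ids) for rid in rab_ids}
    reference_set = clone_sets[rab_ids[0]]
    for rid in rab_ids[1:]:
        if clone_sets[rid] != reference_set:
            raise ValueError("enrichment tables cover inconsistent clone sets")

    bins = {}
    for cid in sorted(reference_set):
        labels = tuple(r for r in rab_ids if tables[r].rer(cid) > threshold)
        bins[cid] = labels
    return BinResult(bins, threshold)


def pool_size_capability(
    library_occupancies: Mapping[str, float],
    enriched: set[str] | Sequence[str],
) -> int:
    """Library diversity at which the rarest recovered clone is one-in-N.

    The reciprocal of the smallest library occupancy among the
    substantially enriched clones: recovering a clone present at
    occupancy f demonstrates identification from a pool of
    floor(1/f) equally represented species.
    """
    enriched = set(enriched)
    if not enriched:
        raise ValueError("pool-size capability is undefined for an empty enriched set")
    occs = []
    for cid in enriched:
        occ = library_occupancies.get(cid)
        if occ is None or occ <= 0:
            raise ValueError(f"enriched clone {cid!r} lacks a positive library occupancy")
        occs.append(occ)
    return math.floor(1.0 / min(occs))
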