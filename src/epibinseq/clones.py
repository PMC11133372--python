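"""Query-antibody clone panel: specifications, mutagenesis, reference I/O.

The panel models a 14-member scFv library used for competitive epitope
binning: a pertuzumab-derived lineage (wild type ``Per`` plus five
single-alanine mutants at heavy-chain positions 52-56), a
trastuzumab-derived lineage (``Tra`` plus five alanine mutants at
positions 101-105), and two antigen-non-binding controls (``Dac``,
``Niv``).  Each clone carries a DNA insert (the amplicon the nested PCR
recovers) whose translation over a fixed codon window uniquely
identifies the clone.

The shipped insert sequences are synthetic stand-ins: they encode the
published residue identities at the mutated positions (N,P,N,S,G at
52-56 for the pertuzumab lineage; G,D,G,F,Y at 101-105 for the
trastuzumab lineage) inside otherwise invented framework context, which
is all that read-based clone assignment requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "CloneSpec",
    "RAbSpec",
    "MutationSpec",
    "build_clone_reference",
    "default_library",
    "default_rabs",
    "write_reference",
    "read_reference",
    "PER_EPITOPE",
    "TRA_EPITOPE",
]

PER_EPITOPE = "pertuzumab-epitope"
TRA_EPITOPE = "trastuzumab-epitope"

ALANINE_CODONS = ("GCT", "GCC", "GCA", "GCG")


@dataclass(frozen=True)
class CloneSpec:
    """One displayed scFv clone.

    ``kd_qab`` is the clone's equilibrium dissociation constant for the
    antigen in nM; ``None`` marks an antigen non-binder (the Dac/Niv
    controls).  ``aa_window`` is the translated identification window of
    ``dna_insert`` used for read assignment.  ``window_start_pos`` maps
    the first window residue to 1-based protein numbering so that clone
    names like N52A refer to real positions.
    """

    clone_id: str
    lineage: str  # "pertuzumab" | "trastuzumab" | "none"
    blocked_epitope: str | None
    kd_qab: float | None  # nM; None = antigen non-binder
    dna_insert: str
    aa_window: str
    library_frequency: float = 0.0
    window_start_pos: int = 1  # 1-based protein position of aa_window[0]

    @property
    def is_binder(self) -> bool:
        return self.kd_qab is not None

    def __post_init__(self) -> None:
        if self.kd_qab is not None and self.kd_qab <= 0:
            raise ValueError(f"{self.clone_id}: kd_qab must be positive, got {self.kd_qab}")
        if not 0.0 <= self.library_frequency <= 1.0:
            raise ValueError(f"{self.clone_id}: library_frequency outside [0, 1]")


@dataclass(frozen=True)
class RAbSpec:
    """A fluorescently labeled reference antibody of known epitope."""

    rab_id: str
    epitope_id: str
    concentration: float  # nM
    kd_rab: float  # nM
    channel: str

    def __post_init__(self) -> None:
        if self.kd_rab <= 0:
            raise ValueError(f"{self.rab_id}: kd_rab must be positive")
        if self.concentration < 0:
            raise ValueError(f"{self.rab_id}: concentration must be non-negative")

    def at(self, concentration: float) -> "RAbSpec":
        """Same antibody at a different staining concentration."""
        return replace(self, concentration=concentration)


@dataclass(frozen=True)
class MutationSpec:
    """A single-residue substitution relative to a parent clone."""

    parent_id: str
    position: int  # 1-based protein numbering
    original: str
    replacement: str

    @property
    def clone_id(self) -> str:
        parent_short = self.parent_id
        return f"{parent_short}-{self.original}{self.position}{self.replacement}"


def translate(dna: str) -> str:
    return str(Seq(dna).translate())


def _minimal_alanine_codon(parent_codon: str) -> str:
    """Alanine codon with the fewest base changes from ``parent_codon``."""
    def hamming(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    return min(ALANINE_CODONS, key=lambda c: (hamming(parent_codon, c), c))


def apply_mutation(parent: CloneSpec, mut: MutationSpec) -> CloneSpec:
    """Derive a mutant CloneSpec by the minimal codon edit at ``mut.position``.

    Raises ``ValueError`` when the stated original residue disagrees with
    the parent sequence at that position.
    """
    window_index = mut.position - parent.window_start_pos
    protein = translate(parent.dna_insert)
    if not 0 <= window_index < len(protein):
        raise ValueError(
            f"{mut.clone_id}: position {mut.position} outside the insert of {parent.clone_id}"
        )
    if protein[window_index] != mut.original:
        raise ValueError(
            f"{mut.clone_id}: parent {parent.clone_id} has "
            f"{protein[window_index]} at position {mut.position}, expected {mut.original}"
        )
    if mut.replacement != "A":
        raise ValueError(f"{mut.clone_id}: only alanine substitutions are supported")

    codon_start = 3 * window_index
    parent_codon = parent.dna_insert[codon_start : codon_start + 3]
    new_codon = _minimal_alanine_codon(parent_codon)
    dna = parent.dna_insert[:codon_start] + new_codon + parent.dna_insert[codon_start + 3 :]
    return replace(
        parent,
        clone_id=mut.clone_id,
        dna_insert=dna,
        aa_window=translate(dna),
        library_frequency=0.0,
    )


def build_clone_reference(
    parents: Sequence[CloneSpec],
    mutation_table: Iterable[MutationSpec],
) -> list[CloneSpec]:
    """Expand parent clones plus a mutation table into the full panel.

    Every parent appears in the output, followed by one mutant per
    mutation row.  Mutant DNA differs from the parent by the minimal
    codon edit producing the alanine substitution; the amino-acid window
    is re-derived by translation.
    """
    by_id = {p.clone_id: p for p in parents}
    clones = list(parents)
    for mut in mutation_table:
        if mut.parent_id not in by_id:
            raise ValueError(f"mutation names unknown parent {mut.parent_id!r}")
        clones.append(apply_mutation(by_id[mut.parent_id], mut))
    ids = [c.clone_id for c in clones]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate clone_id in reference")
    windows = [c.aa_window for c in clones]
    if len(set(windows)) != len(windows):
        raise ValueError("clone identification windows are not unique")
    return clones


# --- shipped synthetic panel ------------------------------------------------

# Fragment layout: each insert is 30 codons beginning in frame.  For the
# pertuzumab lineage the fragment covers protein positions 45-74 (so the
# mutated stretch 52-56 sits at fragment indices 7-11); for the
# trastuzumab lineage it covers 94-123 (101-105 at indices 7-11).
_PER_FRAGMENT_AA = "SGKGLEW" + "NPNSG" + "GSIYNQRFKG" + "RFTLSVDR"
_TRA_FRAGMENT_AA = "YCSRWGG" + "GDGFY" + "AMDYWGQGTL" + "VTVSSGGT"
_DAC_FRAGMENT_AA = "QVQLVESGGGVVQPGRSLRLSCAASGFTFS"
_NIV_FRAGMENT_AA = "EVQLVQSGAEVKKPGASVKVSCKASGYTFT"

# One fixed sense codon per residue keeps the synthetic inserts simple
# and reproducible.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _reverse_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein)


# Affinities (nM) are free parameters of the shipped panel, constrained
# by the published ordering: the wild types bind tightest, N52A is the
# weakest of the pertuzumab lineage, and every mutant is weaker than its
# parent.
_PER_MUTANT_KD = {"N52A": 4.5, "P53A": 1.0, "N54A": 1.5, "S55A": 2.2, "G56A": 3.2}
_TRA_MUTANT_KD = {"G101A": 4.5, "D102A": 1.5, "G103A": 2.2, "F104A": 1.0, "Y105A": 3.2}

# Skewed library composition: pertuzumab lineage and Niv abundant,
# trastuzumab lineage and Dac rare, Tra-G103A at 0.018%.
_LIBRARY_FREQ = {
    "Per": 0.105, "Per-N52A": 0.105, "Per-P53A": 0.105, "Per-N54A": 0.105,
    "Per-S55A": 0.105, "Per-G56A": 0.105,
    "Niv": 0.36,
    "Dac": 0.003,
    "Tra": 0.002, "Tra-G101A": 0.0012, "Tra-D102A": 0.0012, "Tra-G103A": 0.00018,
    "Tra-F104A": 0.0012, "Tra-Y105A": 0.00122,
}


def default_parents() -> list[CloneSpec]:
    per = CloneSpec(
        clone_id="Per",
        lineage="pertuzumab",
        blocked_epitope=PER_EPITOPE,
        kd_qab=0.8,
        dna_insert=_reverse_translate(_PER_FRAGMENT_AA),
        aa_window=_PER_FRAGMENT_AA,
        window_start_pos=45,
    )
    tra = CloneSpec(
        clone_id="Tra",
        lineage="trastuzumab",
        blocked_epitope=TRA_EPITOPE,
        kd_qab=0.8,
        dna_insert=_reverse_translate(_TRA_FRAGMENT_AA),
        aa_window=_TRA_FRAGMENT_AA,
        window_start_pos=94,
    )
    dac = CloneSpec(
        clone_id="Dac",
        lineage="none",
        blocked_epitope=None,
        kd_qab=None,
        dna_insert=_reverse_translate(_DAC_FRAGMENT_AA),
        aa_window=_DAC_FRAGMENT_AA,
    )
    niv = CloneSpec(
        clone_id="Niv",
        lineage="none",
        blocked_epitope=None,
        kd_qab=None,
        dna_insert=_reverse_translate(_NIV_FRAGMENT_AA),
        aa_window=_NIV_FRAGMENT_AA,
    )
    return [per, tra, dac, niv]


def default_mutation_table() -> list[MutationSpec]:
    table = []
    for name in _PER_MUTANT_KD:
        table.append(MutationSpec("Per", int(name[1:-1]), name[0], "A"))
    for name in _TRA_MUTANT_KD:
        table.append(MutationSpec("Tra", int(name[1:-1]), name[0], "A"))
    return table


def default_library() -> list[CloneSpec]:
    """The shipped 14-clone panel with skewed abundances and affinities."""
    clones = build_clone_reference(default_parents(), default_mutation_table())
    out = []
    for c in clones:
        kd = c.kd_qab
        if c.clone_id.startswith("Per-"):
            kd = _PER_MUTANT_KD[c.clone_id.split("-")[1]]
        elif c.clone_id.startswith("Tra-"):
            kd = _TRA_MUTANT_KD[c.clone_id.split("-")[1]]
        out.append(replace(c, kd_qab=kd, library_frequency=_LIBRARY_FREQ[c.clone_id]))
    total = sum(c.library_frequency for c in out)
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"library frequencies sum to {total}, not 1")
    return out


def default_rabs() -> dict[str, RAbSpec]:
    """The two reference antibodies, at a placeholder 1 nM concentration."""
    return {
        "Pert-AF647": RAbSpec("Pert-AF647", PER_EPITOPE, 1.0, 0.5, "AF647"),
        "Tras-AF647": RAbSpec("Tras-AF647", TRA_EPITOPE, 1.0, 0.5, "AF647"),
        "Tras-AF488": RAbSpec("Tras-AF488", TRA_EPITOPE, 1.0, 0.5, "AF488"),
    }


# --- reference I/O ----------------------------------------------------------

def write_reference(clones: Sequence[CloneSpec], fasta_path, table_path) -> None:
    """Write the panel as a DNA FASTA plus a clone table TSV."""
    fasta_path, table_path = Path(fasta_path), Path(table_path)
    with open(fasta_path, "w") as fh:
        for c in clones:
            fh.write(f">{c.clone_id}\n{c.dna_insert}\n")
    with open(table_path, "w") as fh:
        fh.write(
            "clone_id\tlineage\tblocked_epitope\tkd_qab_nM\t"
            "library_frequency\twindow_start_pos\taa_window\n"
        )
        for c in clones:
            kd = "" if c.kd_qab is None else repr(c.kd_qab)
            epi = c.blocked_epitope or ""
            fh.write(
                f"{c.clone_id}\t{c.lineage}\t{epi}\t{kd}\t"
                f"{c.library_frequency!r}\t{c.window_start_pos}\t{c.aa_window}\n"
            )


def read_reference(fasta_path, table_path) -> list[CloneSpec]:
    """Read a panel written by :func:`write_reference`."""
    seqs: dict[str, str] = {}
    name = None
    for line in Path(fasta_path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        else:
            seqs[name] += line
    clones = []
    lines = Path(table_path).read_text().splitlines()
    header = lines[0].split("\t")
    for row in lines[1:]:
        if not row.strip():
            continue
        rec: Mapping[str, str] = dict(zip(header, row.split("\t")))
        cid = rec["clone_id"]
        if cid not in seqs:
            raise ValueError(f"clone {cid!r} missing from FASTA")
        clone = CloneSpec(
            clone_id=cid,
            lineage=rec["lineage"],
            blocked_epitope=rec["blocked_epitope"] or None,
            kd_qab=float(rec["kd_qab_nM"]) if rec["kd_qab_nM"] else None,
            dna_insert=seqs[cid],
            aa_window=rec["aa_window"],
            library_frequency=float(rec["library_frequency"]),
            window_start_pos=int(rec["window_start_pos"]),
        )
        if translate(clone.dna_insert) != clone.aa_window:
            raise ValueError(f"clone {cid!r}: aa_window does not match translated insert")
        clones.append(clone)
    return clones
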