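"""Modular immunogenic peptide constructs.

A nanovaccine peptide is assembled from functional elements: a gold-binding
anchor (CALNN, whose cysteine thiol tethers the peptide to the particle
surface), a protease-cleavable or flexible spacer (KK, GPGPG), a T-cell
epitope, and optionally an arginine-rich cell-penetrating peptide (the HIV
TAT segment).  This module models such constructs over plain one-letter
sequences, annotates the elements by motif matching, and computes the charge
descriptors that drive nanoparticle surface-charge behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
REGION_KINDS = ("anchor", "spacer", "epitope", "cpp", "other")

#: Default motif library, in priority order.  Earlier entries win when two
#: motifs could claim the same position.
DEFAULT_MOTIF_LIBRARY: tuple[tuple[str, str], ...] = (
    ("CALNN", "anchor"),
    ("KK", "spacer"),
    ("GPGPG", "spacer"),
    ("PKYVKQNTLKLAT", "epitope"),
    ("RKKRQRRR", "cpp"),
)


class AlphabetError(ValueError):
    """Sequence contains a character outside the 20 standard amino acids."""


def validate_sequence(sequence: str) -> str:
    """Uppercase *sequence* and reject non-standard residues.

    B, J, O, U, X and Z are rejected along with any non-letter; the error
    message names the first offending 1-based position.
    """
    if not sequence:
        raise AlphabetError("sequence is empty")
    seq = sequence.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i}: "
                f"allowed alphabet is {AMINO_ACIDS}"
            )
    return seq


@dataclass(frozen=True)
class Region:
    """A functional element of a construct, 1-based inclusive coordinates."""

    kind: str
    start: int
    end: int
    motif: str

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad region coordinates [{self.start}, {self.end}]")
        if len(self.motif) != self.end - self.start + 1:
            raise ValueError("motif length does not match region span")


@dataclass
class PeptideConstruct:
    """An annotated vaccine peptide.

    ``regions`` are sorted, non-overlapping and need not tile the sequence.
    ``c_terminal_amide`` records whether the C-terminus is amidated (true for
    peptides made on Rink amide resin), which removes the C-terminal carboxyl
    negative charge.
    """

    id: str
    sequence: str
    regions: list[Region] = field(default_factory=list)
    c_terminal_amide: bool = True

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence)
        self.regions = sorted(self.regions, key=lambda r: r.start)
        last_end = 0
        for r in self.regions:
            if r.start <= last_end:
                raise ValueError(f"overlapping regions at position {r.start}")
            if r.end > len(self.sequence):
                raise ValueError(f"region [{r.start},{r.end}] exceeds sequence length")
            claimed = self.sequence[r.start - 1 : r.end]
            if claimed != r.motif:
                raise ValueError(
                    f"region motif {r.motif!r} does not equal sequence slice {claimed!r}"
                )
            last_end = r.end

    def __len__(self) -> int:
        return len(self.sequence)

    def region_of_kind(self, kind: str) -> list[Region]:
        return [r for r in self.regions if r.kind == kind]


@dataclass(frozen=True)
class ChargeSummary:
    """Ionizable-group counts under a stated charge convention.

    The default convention counts Lys and Arg side chains plus the single
    free N-terminal amine as positive (His excluded at neutral pH), and Asp
    and Glu plus the C-terminal carboxyl — when not amidated — as negative.
    """

    n_lys: int
    n_arg: int
    n_his: int
    n_nterm: int
    n_positive: int
    n_negative: int


def parse_construct(
    id: str,
    sequence: str,
    motif_library: Sequence[tuple[str, str]] = DEFAULT_MOTIF_LIBRARY,
    c_terminal_amide: bool = True,
) -> PeptideConstruct:
    """Annotate *sequence* by greedy left-to-right motif matching.

    Scanning proceeds from the N-terminus; at each position the first library
    motif (in priority order) matching there is claimed and the scan resumes
    after it.  Overlapping claims are therefore resolved by library order and
    leftmost position, never an error.  Unmatched stretches get no region.
    """
    seq = validate_sequence(sequence)
    regions: list[Region] = []
    pos = 0
    n = len(seq)
    while pos < n:
        for motif, kind in motif_library:
            motif = motif.upper()
            if seq.startswith(motif, pos):
                regions.append(
                    Region(kind=kind, start=pos + 1, end=pos + len(motif), motif=motif)
                )
                pos += len(motif)
                break
        else:
            pos += 1
    return PeptideConstruct(
        id=id, sequence=seq, regions=regions, c_terminal_amide=c_terminal_amide
    )


def charge_summary(
    construct: PeptideConstruct,
    count_n_terminus: bool = True,
    count_histidine: bool = False,
) -> ChargeSummary:
    """Count charged groups of a construct.

    ``count_n_terminus`` adds one positive charge for the free N-terminal
    amine (the default convention); ``count_histidine`` optionally includes
    His in the positive count (off at neutral pH).
    """
    seq = construct.sequence
    n_lys = seq.count("K")
    n_arg = seq.count("R")
    n_his = seq.count("H")
    n_nterm = 1 if count_n_terminus else 0
    n_positive = n_lys + n_arg + n_nterm + (n_his if count_histidine else 0)
    n_negative = seq.count("D") + seq.count("E")
    if not construct.c_terminal_amide:
        n_negative += 1
    return ChargeSummary(
        n_lys=n_lys,
        n_arg=n_arg,
        n_his=n_his,
        n_nterm=n_nterm,
        n_positive=n_positive,
        n_negative=n_negative,
    )


def locate_epitope_core(construct: PeptideConstruct, core: str) -> list[int]:
    """All 1-based start positions of exact (possibly overlapping) matches."""
    if not core:
        raise ValueError("core must be non-empty")
    core = core.upper()
    seq = construct.sequence
    hits, start = [], 0
    while True:
        idx = seq.find(core, start)
        if idx < 0:
            return hits
        hits.append(idx + 1)
        start = idx + 1


# ---------------------------------------------------------------------------
# FASTA I/O.  Region annotation travels in the record description as
# whitespace-separated `kind:start-end` tokens.

def _regions_to_description(regions: Iterable[Region]) -> str:
    return " ".join(f"{r.kind}:{r.start}-{r.end}" for r in regions)


def _description_to_regions(description: str, sequence: str) -> list[Region]:
    regions = []
    for token in description.split():
        kind, _, span = token.partition(":")
        if kind not in REGION_KINDS or "-" not in span:
            continue
        start_s, _, end_s = span.partition("-")
        start, end = int(start_s), int(end_s)
        regions.append(
            Region(kind=kind, start=start, end=end, motif=sequence[start - 1 : end])
        )
    return regions


def write_fasta(constructs: Iterable[PeptideConstruct], path: str | Path) -> None:
    records = []
    for c in constructs:
        rec = SeqRecord(
            Seq(c.sequence), id=c.id, description=_regions_to_description(c.regions)
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[PeptideConstruct]:
    """Read constructs; `kind:start-end` description tokens restore regions."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = validate_sequence(str(rec.seq))
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append(
            PeptideConstruct(
                id=rec.id, sequence=seq, regions=_description_to_regions(desc, seq)
            )
        )
    return out


# The four study constructs, used throughout the examples and tests.
STUDY_SEQUENCES: dict[str, str] = {
    "p1": "CALNNKKPKYVKQNTLKLAT",
    "p2": "CALNNKKPKYVKQNTLKLATRKKRQRRR",
    "p3": "CALNNGPGPGPKYVKQNTLKLAT",
    "p4": "CALNNGPGPGPKYVKQNTLKLATRKKRQRRR",
}

#: Nonameric MHC class II binding core of the influenza HA epitope.
EPITOPE_CORE = "YVKQNTLKL"


def study_constructs() -> dict[str, PeptideConstruct]:
    """The four annotated study constructs p1–p4."""
    return {pid: parse_construct(pid, seq) for pid, seq in STUDY_SEQUENCES.items()}
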