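"""Protein sequence containers, FASTA I/O and coordinate conventions.

Every position in this library is 1-based and inclusive, matching the way
residues are labelled in the literature (e.g. the CaMKIIA calmodulin-binding
domain spans residues 296-311 of the kinase).  A :class:`ProteinSequence`
therefore carries an ``offset``: the parent-protein position of its first
residue.  Peptides excised from a larger protein keep their native numbering,
so a motif anchor reported at position 299 really is Leu299 of the parent.

FASTA records may encode the numbering offset in their header with a
``start=<int>`` token; absent that, numbering starts at 1.  The only place a
different convention appears is BED export (0-based, half-open), handled in
:mod:`camscan.report`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Letters accepted in input sequences.  ``X`` (unknown residue) is allowed
#: but never matches an anchor set or a bracketed pattern class.
ALLOWED_LETTERS = CANONICAL_AA | frozenset("X")

_GAP_CHARS = frozenset("-.*")

_START_TOKEN = re.compile(r"\bstart=(\d+)\b")


@dataclass(frozen=True)
class ProteinSequence:
    """A protein (or peptide) with 1-based numbering into its parent.

    Parameters
    ----------
    id : str
        Record identifier.
    residues : str
        Uppercase one-letter residue string over the canonical alphabet
        (plus ``X``).  Lowercase input is uppercased on construction.
    offset : int
        Parent-protein position of the first residue (1-based, default 1).
    description : str
        Free-text annotation (never interpreted, except that synthetic
        sequences record their embedded-segment coordinates here).
    """

    id: str
    residues: str
    offset: int = 1
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.offset < 1:
            raise ValueError(f"record {self.id!r}: offset must be >= 1, got {self.offset}")
        for i, ch in enumerate(self.residues):
            if ch not in ALLOWED_LETTERS:
                pos = self.offset + i
                kind = "gap character" if ch in _GAP_CHARS else "illegal residue"
                raise ValueError(f"record {self.id!r}: {kind} {ch!r} at position {pos}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def end(self) -> int:
        """Parent-protein position of the last residue."""
        return self.offset + len(self.residues) - 1

    def position(self, i: int) -> int:
        """Parent position of the ``i``-th residue (0-based index in)."""
        if not 0 <= i < len(self.residues):
            raise IndexError(f"index {i} out of range for {len(self.residues)}-residue sequence")
        return self.offset + i

    def index(self, position: int) -> int:
        """0-based index of the residue at a 1-based parent ``position``."""
        if not self.offset <= position <= self.end:
            raise ValueError(
                f"position {position} outside {self.id!r} ({self.offset}-{self.end})"
            )
        return position - self.offset

    def residue_at(self, position: int) -> str:
        return self.residues[self.index(position)]


@dataclass(frozen=True)
class SequenceRegion:
    """A closed interval ``[start, end]`` in parent-protein coordinates."""

    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def to_bed(self) -> tuple[int, int]:
        """(start, end) under the BED convention: 0-based, half-open."""
        return self.start - 1, self.end


def _parse_header(record: SeqRecord) -> tuple[int, str]:
    """Extract the numbering offset from a FASTA header.

    Returns ``(offset, description-without-start-token)``.
    """
    desc = record.description
    if desc.startswith(record.id):
        desc = desc[len(record.id):].strip()
    m = _START_TOKEN.search(desc)
    offset = 1
    if m:
        offset = int(m.group(1))
        desc = (desc[: m.start()] + desc[m.end():]).strip()
    return offset, desc


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a (possibly multi-record, possibly line-wrapped) FASTA file.

    The header token ``start=<n>`` sets the numbering offset of a record;
    otherwise numbering starts at 1.  Raises ``ValueError`` on an empty file
    or on any residue letter outside the allowed alphabet, naming the record
    and the offending position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    sequences = []
    for rec in records:
        offset, desc = _parse_header(rec)
        sequences.append(
            ProteinSequence(id=rec.id, residues=str(rec.seq), offset=offset, description=desc)
        )
    return sequences


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write sequences to FASTA, encoding each offset as ``start=<n>``."""
    records = []
    for seq in sequences:
        desc = f"start={seq.offset}"
        if seq.description:
            desc += f" {seq.description}"
        records.append(SeqRecord(Seq(seq.residues), id=seq.id, description=desc))
    SeqIO.write(records, str(Path(path)), "fasta")


def extract_region(seq: ProteinSequence, region: SequenceRegion) -> ProteinSequence:
    """Excise ``region`` (parent coordinates) from ``seq``.

    The returned peptide keeps parent numbering: its offset equals
    ``region.start``.
    """
    if region.parent_id and region.parent_id != seq.id:
        raise ValueError(f"region parent {region.parent_id!r} does not match sequence {seq.id!r}")
    if region.start < seq.offset or region.end > seq.end:
        raise ValueError(
            f"region {region.start}-{region.end} outside {seq.id!r} "
            f"({seq.offset}-{seq.end})"
        )
    i0 = seq.index(region.start)
    i1 = seq.index(region.end)
    return ProteinSequence(
        id=seq.id,
        residues=seq.residues[i0 : i1 + 1],
        offset=region.start,
        description=seq.description,
    )
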