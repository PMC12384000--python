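"""Published CaMBD peptide fixtures and a seeded synthetic-protein generator.

Every CaM-binding-domain peptide printed in the underlying survey of Tau
kinases/phosphatase and TGM2 ships here with its printed annotation.  Each
fixture carries a curation ``status``:

* ``clean`` — the exhaustive curated scan (core anchors) reproduces the
  printed motif count and classes exactly; these back the count-based
  acceptance checks.
* ``label-inconsistent`` — the printed start/end labels disagree with the
  printed string itself (probable typos); the string and printed start are
  kept authoritative and the end recomputed.
* ``curation-ambiguous`` — the printed motif list cannot be reproduced by
  exhaustive scanning with the stated anchor set; packaged as printed, but
  excluded from count-based tests (no attempt is made to guess the
  curators' intent).

The synthetic generator produces seeded random backgrounds drawn from an
alphabet that excludes both the core anchor residues (F, I, L, V, W) and
the charged basics/acidics relevant to the predictor (R, K), so embedded
signals sit on a zero-false-positive floor; a ``realistic`` mode draws
uniformly from all 20 letters for stress testing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .sequences import CANONICAL_AA, ProteinSequence, SequenceRegion, read_fasta

#: Background alphabet: 20 canonical letters minus core anchors minus {R, K}.
BACKGROUND_ALPHABET = "ACDEGHMNPQSTY"

#: All 20 canonical letters, for the "realistic" background mode.
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: A basic amphipathic 20-mer used as the standard embedded test signal.
BASIC_AMPHIPATHIC_20MER = "KLWKKLLKLFSKLWKQIKKV"

#: MARK4's CaMBD sequence is only available as a figure image in the source
#: and is not packaged; its printed motif list is recorded as metadata.
#: The printed "1-1-12" is treated as a typo for "1-12".
MARK4_PRINTED_MOTIFS: tuple[str, ...] = ("1-14", "1-12")
MARK4_PRINTED_MOTIFS_NOTE = (
    "sequence unavailable (figure-only); printed list was 'one 1-14; one 1-1-12', "
    "with 1-1-12 recorded as a typo for 1-12"
)

_EMBED_TOKEN = re.compile(r"\bembed_start=(\d+) embed_end=(\d+)\b")


@dataclass(frozen=True)
class Fixture:
    """A printed CaMBD peptide with its printed annotation."""

    name: str
    protein: str
    sequence: ProteinSequence
    printed_start: int
    printed_end: int
    printed_count: int
    printed_annotation: tuple[str, ...]
    status: str
    notes: str = ""


def fixture_library() -> list[Fixture]:
    """Load the 12 packaged CaMBD fixtures (FASTA + TSV annotation sidecar)."""
    data = resources.files("camscan.data")
    with resources.as_file(data.joinpath("cambd_fixtures.fasta")) as p:
        seqs = {s.id: s for s in read_fasta(p)}
    with resources.as_file(data.joinpath("cambd_fixtures.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", keep_default_na=False, na_values=[])
    fixtures = []
    for row in frame.to_dict("records"):
        notes = row.get("notes", "")
        if not isinstance(notes, str):
            notes = ""
        fixtures.append(
            Fixture(
                name=str(row["name"]),
                protein=str(row["protein"]),
                sequence=seqs[str(row["name"])],
                printed_start=int(row["printed_start"]),
                printed_end=int(row["printed_end"]),
                printed_count=int(row["printed_count"]),
                printed_annotation=tuple(str(row["printed_classes"]).split(";")),
                status=str(row["status"]),
                notes=notes,
            )
        )
    return fixtures


def get_fixture(name: str) -> Fixture:
    for fx in fixture_library():
        if fx.name == name:
            return fx
    raise KeyError(f"no fixture named {name!r}")


def synth_protein(
    seed: int,
    bg_len: int,
    embed: str | None = None,
    embed_pos: int | None = None,
    realistic: bool = False,
    seq_id: str | None = None,
) -> ProteinSequence:
    """Generate a seeded synthetic protein, optionally with an embedded segment.

    The background is drawn uniformly from :data:`BACKGROUND_ALPHABET`
    (anchor- and R/K-free) unless ``realistic`` is set, in which case all 20
    letters are used.  ``embed``, when given, replaces the background at
    1-based position ``embed_pos`` (drawn from the same seeded stream when
    omitted); total length stays ``bg_len``.  The embedded span is recorded
    in the description as ``embed_start=<a> embed_end=<b>`` and recoverable
    via :func:`embedded_region`.  Output is deterministic for a fixed seed.
    """
    if bg_len < 1:
        raise ValueError(f"bg_len must be >= 1, got {bg_len}")
    rng = np.random.default_rng(seed)
    alphabet = FULL_ALPHABET if realistic else BACKGROUND_ALPHABET
    residues = "".join(rng.choice(list(alphabet), size=bg_len))
    description = f"synthetic seed={seed} bg_len={bg_len} mode={'realistic' if realistic else 'anchor-free'}"
    if embed is not None:
        embed = embed.upper()
        bad = set(embed) - CANONICAL_AA
        if bad:
            raise ValueError(f"embed contains non-canonical letters {sorted(bad)}")
        if len(embed) > bg_len:
            raise ValueError(f"embed ({len(embed)} aa) longer than background ({bg_len} aa)")
        last_start = bg_len - len(embed) + 1
        if embed_pos is None:
            embed_pos = int(rng.integers(1, last_start + 1))
        if not 1 <= embed_pos <= last_start:
            raise ValueError(f"embed_pos {embed_pos} out of bounds (1-{last_start})")
        i0 = embed_pos - 1
        residues = residues[:i0] + embed + residues[i0 + len(embed):]
        description += f" embed_start={embed_pos} embed_end={embed_pos + len(embed) - 1}"
    return ProteinSequence(
        id=seq_id or f"synthetic-{seed}",
        residues=residues,
        offset=1,
        description=description,
    )


def embedded_region(seq: ProteinSequence) -> SequenceRegion | None:
    """The embedded-segment span recorded by :func:`synth_protein`, if any."""
    m = _EMBED_TOKEN.search(seq.description)
    if not m:
        return None
    return SequenceRegion(seq.id, int(m.group(1)), int(m.group(2)))
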