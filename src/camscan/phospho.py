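"""Tau phosphorylation/dephosphorylation site tables and overlap queries.

The packaged table transcribes site-level reports of which kinases
phosphorylate, and which phosphatase dephosphorylates, specific residues of
Tau, all in 2N4R (441-residue) numbering.  Where a site-specific effect size
was reported (calcineurin's percent decrease in phosphorylation at five
sites) it is stored as ``effect_pct``.  The prephosphorylation /
hyperphosphorylation relationships are stored as a ``stage`` tag on each
edge (``pre`` / ``hyper`` / ``dephos``) — a static edge list, not a kinetic
model.  Aggregate metadata (per-kinase counts of known target sites, and the
45 Ser / 35 Thr / 5 Tyr composition of the 85 potential sites) ships
alongside the transcription, together with per-enzyme row-count checksums
used to guard the transcription against drift.

No isoform coordinate lifting is performed: positions are meaningful only
against 2N4R numbering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .sequences import SequenceRegion

#: Full span of the Tau 2N4R isoform.
TAU_2N4R_LENGTH = 441

_SITE_COLUMNS = [
    "position", "residue", "enzyme", "direction", "effect_pct", "stage", "evidence", "notes",
]


@dataclass(frozen=True)
class PhosphoSite:
    """One enzyme-site relationship on Tau (2N4R numbering)."""

    position: int
    residue: str
    enzyme: str
    direction: str
    effect_pct: float | None = None
    stage: str | None = None
    evidence: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"phosphosite residue must be S/T/Y, got {self.residue!r}")
        if self.direction not in ("phosphorylates", "dephosphorylates"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.effect_pct is not None and not 0 < self.effect_pct <= 100:
            raise ValueError(f"effect_pct must lie in (0, 100], got {self.effect_pct}")


@dataclass
class SiteTable:
    """The packaged Tau site table plus its aggregate metadata."""

    sites: list[PhosphoSite]
    provenance: list[str] = field(default_factory=list)
    known_target_site_counts: dict[str, int] = field(default_factory=dict)
    potential_site_composition: dict[str, int] = field(default_factory=dict)
    transcribed_row_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        triples = [(s.position, s.enzyme, s.direction) for s in self.sites]
        if len(triples) != len(set(triples)):
            raise ValueError("duplicate (position, enzyme, direction) triple in site table")

    def lookup(self, enzyme: str | None = None, position: int | None = None) -> list[PhosphoSite]:
        """Sites filtered by enzyme and/or position; unknown names give []."""
        out = self.sites
        if enzyme is not None:
            out = [s for s in out if s.enzyme == enzyme]
        if position is not None:
            out = [s for s in out if s.position == position]
        return sorted(out, key=lambda s: (s.position, s.enzyme, s.direction))

    def site_count(self, enzyme: str) -> int | None:
        """Reported number of known Tau target sites for ``enzyme``.

        This is survey metadata (e.g. MARK4 -> 2), distinct from the number
        of individually transcribed rows; returns None for unknown enzymes.
        """
        return self.known_target_site_counts.get(enzyme)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": s.position,
                    "residue": s.residue,
                    "enzyme": s.enzyme,
                    "direction": s.direction,
                    "effect_pct": s.effect_pct,
                    "stage": s.stage or "",
                    "evidence": s.evidence,
                    "notes": s.notes,
                }
                for s in self.sites
            ],
            columns=_SITE_COLUMNS,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Export the table with its documented column order."""
        self.to_frame().to_csv(path, sep="\t", index=False)


def _data_path(name: str):
    return resources.files("camscan.data").joinpath(name)


def load_site_table() -> SiteTable:
    """Load the packaged Tau site table."""
    with resources.as_file(_data_path("tau_phospho_sites.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", keep_default_na=False, na_values=[])
    meta = json.loads(_data_path("tau_site_counts.json").read_text())
    sites = []
    for row in frame.to_dict("records"):
        effect = row.get("effect_pct", "")
        effect = None if effect in ("", None) or pd.isna(effect) else float(effect)
        stage = row.get("stage", "") or None
        if isinstance(stage, float) and pd.isna(stage):
            stage = None
        notes = row.get("notes", "")
        if not isinstance(notes, str):
            notes = ""
        sites.append(
            PhosphoSite(
                position=int(row["position"]),
                residue=str(row["residue"]),
                enzyme=str(row["enzyme"]),
                direction=str(row["direction"]),
                effect_pct=effect,
                stage=stage,
                evidence=str(row["evidence"]),
                notes=notes,
            )
        )
    return SiteTable(
        sites=sites,
        provenance=meta["provenance"],
        known_target_site_counts=meta["known_target_site_counts"],
        potential_site_composition=meta["potential_site_composition"],
        transcribed_row_counts=meta["transcribed_row_counts"],
    )


def annotate_overlap(region: SequenceRegion, table: SiteTable) -> list[PhosphoSite]:
    """Sites falling inside ``region`` (2N4R coordinates), sorted by position."""
    return sorted(
        (s for s in table.sites if region.start <= s.position <= region.end),
        key=lambda s: (s.position, s.enzyme, s.direction),
    )
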