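"""Scan-result containers and TSV/JSON/BED serialization.

Column orders are fixed: motif rows are
``seq_id, motif_class, anchor_positions, fingerprint, span_start, span_end``
and candidate rows are ``seq_id, start, end, length, score, rank``.  Floats
print with 3 decimals and no locale-dependent formatting.  Spans are 1-based
inclusive everywhere except BED output, which converts to the 0-based
half-open convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping

from . import __version__
from .motifs import IQMatch, MotifMatch
from .phospho import PhosphoSite
from .predictor import CaMBDCandidate
from .sequences import SequenceRegion

MOTIF_COLUMNS = ("seq_id", "motif_class", "anchor_positions", "fingerprint", "span_start", "span_end")
CANDIDATE_COLUMNS = ("seq_id", "start", "end", "length", "score", "rank")
OVERLAP_COLUMNS = ("region", "position", "residue", "enzyme", "direction", "effect_pct", "stage", "evidence")


@dataclass
class ScanReport:
    """A serializable record of one scan run."""

    input: str
    mode: str = "curated"  # raw | curated
    anchor_set: str = "core"
    tool_version: str = __version__
    matches: dict[str, list[MotifMatch]] = field(default_factory=dict)
    iq: dict[str, list[IQMatch]] = field(default_factory=dict)
    candidates: dict[str, list[CaMBDCandidate]] = field(default_factory=dict)
    overlaps: dict[str, list[PhosphoSite]] = field(default_factory=dict)

    # -- JSON ---------------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "tool_version": self.tool_version,
            "input": self.input,
            "mode": self.mode,
            "anchor_set": self.anchor_set,
            "matches": {
                sid: [
                    {
                        "class": m.class_name,
                        "anchor_positions": list(m.anchor_positions),
                        "fingerprint": m.fingerprint,
                        "span_start": m.span_start,
                        "span_end": m.span_end,
                    }
                    for m in ms
                ]
                for sid, ms in self.matches.items()
            },
            "iq": {
                sid: [{"start": m.start, "matched": m.matched} for m in ms]
                for sid, ms in self.iq.items()
            },
            "candidates": {
                sid: [
                    {
                        "start": c.region.start,
                        "end": c.region.end,
                        "length": c.length,
                        "score": round(c.score, 3),
                        "rank": c.rank,
                    }
                    for c in cs
                ]
                for sid, cs in self.candidates.items()
            },
            "overlaps": {
                key: [
                    {
                        "position": s.position,
                        "residue": s.residue,
                        "enzyme": s.enzyme,
                        "direction": s.direction,
                        "effect_pct": s.effect_pct,
                        "stage": s.stage,
                        "evidence": s.evidence,
                    }
                    for s in ss
                ]
                for key, ss in self.overlaps.items()
            },
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScanReport":
        payload = json.loads(text)
        report = cls(
            input=payload["input"],
            mode=payload["mode"],
            anchor_set=payload["anchor_set"],
            tool_version=payload["tool_version"],
        )
        for sid, ms in payload.get("matches", {}).items():
            report.matches[sid] = [
                MotifMatch(
                    parent_id=sid,
                    class_name=m["class"],
                    anchor_positions=tuple(m["anchor_positions"]),
                    fingerprint=m["fingerprint"],
                    span_start=m["span_start"],
                    span_end=m["span_end"],
                )
                for m in ms
            ]
        for sid, ms in payload.get("iq", {}).items():
            report.iq[sid] = [IQMatch(parent_id=sid, start=m["start"], matched=m["matched"]) for m in ms]
        for sid, cs in payload.get("candidates", {}).items():
            report.candidates[sid] = [
                CaMBDCandidate(
                    region=SequenceRegion(sid, c["start"], c["end"]),
                    length=c["length"],
                    score=c["score"],
                    rank=c["rank"],
                )
                for c in cs
            ]
        for key, ss in payload.get("overlaps", {}).items():
            report.overlaps[key] = [
                PhosphoSite(
                    position=s["position"],
                    residue=s["residue"],
                    enzyme=s["enzyme"],
                    direction=s["direction"],
                    effect_pct=s["effect_pct"],
                    stage=s["stage"],
                    evidence=s["evidence"],
                )
                for s in ss
            ]
        return report

    # -- TSV / BED ----------------------------------------------------------
    def motifs_tsv(self) -> str:
        buf = StringIO()
        buf.write("\t".join(MOTIF_COLUMNS) + "\n")
        for sid in self.matches:
            for m in self.matches[sid]:
                buf.write(
                    "\t".join(
                        (
                            sid,
                            m.class_name,
                            ",".join(str(p) for p in m.anchor_positions),
                            m.fingerprint,
                            str(m.span_start),
                            str(m.span_end),
                        )
                    )
                    + "\n"
                )
        return buf.getvalue()

    def motifs_bed(self) -> str:
        """Motif spans as BED4 rows (0-based half-open)."""
        buf = StringIO()
        for sid in self.matches:
            for m in self.matches[sid]:
                bed_start, bed_end = SequenceRegion(sid, m.span_start, m.span_end).to_bed()
                buf.write(f"{sid}\t{bed_start}\t{bed_end}\t{m.class_name}|{m.fingerprint}\n")
        return buf.getvalue()

    def candidates_tsv(self) -> str:
        buf = StringIO()
        buf.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for sid in self.candidates:
            for c in self.candidates[sid]:
                buf.write(
                    f"{sid}\t{c.region.start}\t{c.region.end}\t{c.length}\t{c.score:.3f}\t{c.rank}\n"
                )
        return buf.getvalue()

    def overlaps_tsv(self) -> str:
        buf = StringIO()
        buf.write("\t".join(OVERLAP_COLUMNS) + "\n")
        for key in self.overlaps:
            for s in self.overlaps[key]:
                effect = "" if s.effect_pct is None else f"{s.effect_pct:.3f}".rstrip("0").rstrip(".")
                buf.write(
                    "\t".join(
                        (key, str(s.position), s.residue, s.enzyme, s.direction,
                         effect, s.stage or "", s.evidence)
                    )
                    + "\n"
                )
        return buf.getvalue()
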