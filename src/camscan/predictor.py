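"""Sliding-window propensity scoring for candidate CaM-binding domains.

Canonical calcium-dependent CaM-binding domains are short (roughly 18-22
residues) basic amphipathic helices.  This module scores each residue of a
protein by how much its surrounding window looks like such a segment, then
calls non-overlapping candidate windows from the profile.  The score blends
three classical per-residue signals over a centered window (default 21
residues, truncated at the termini):

* mean Kyte-Doolittle hydropathy, min-max normalized over the scale's
  theoretical range [-4.5, 4.5];
* net positive charge fraction, (#{R,K} - #{D,E}) / window size, clipped
  to [0, 1] (His is uncharged by default; a flag counts it +0.5);
* mean Chou-Fasman alpha-helix propensity, min-max normalized over the
  table's range.

The three components are combined as a convex weighted sum and rescaled to
the 0-9 presentation familiar from CaM-target prediction servers.  The
heuristic is a documented, self-contained propensity score; it makes no
attempt to reproduce any third-party server's numbers, and candidate
coordinates from real proteins should be confirmed by the motif engine and
by experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequences import ProteinSequence, SequenceRegion

#: Kyte & Doolittle (1982) J. Mol. Biol. 157:105-132 hydropathy index.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Chou & Fasman (1978) Annu. Rev. Biochem. 47:251-276 helix propensity P_alpha.
CHOU_FASMAN_HELIX: dict[str, float] = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

_KD_MIN, _KD_MAX = -4.5, 4.5
_CF_MIN = min(CHOU_FASMAN_HELIX.values())
_CF_MAX = max(CHOU_FASMAN_HELIX.values())

#: Top of the reported score scale.
SCORE_MAX = 9.0


@dataclass(frozen=True)
class ScoringWeights:
    """Convex weights for the three profile components (must sum to 1)."""

    w_hydropathy: float = 0.4
    w_charge: float = 0.4
    w_helix: float = 0.2

    def __post_init__(self) -> None:
        ws = (self.w_hydropathy, self.w_charge, self.w_helix)
        if any(w < 0 for w in ws):
            raise ValueError(f"weights must be non-negative, got {ws}")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(ws)!r}")


DEFAULT_WEIGHTS = ScoringWeights()


@dataclass
class ResidueScoreProfile:
    """Per-residue propensity profile on the 0-9 scale.

    Component arrays (each in [0, 1]) are kept alongside the combined score
    so the contribution of hydropathy, charge and helix propensity can be
    inspected separately.
    """

    parent_id: str
    scores: np.ndarray
    hydropathy: np.ndarray
    charge: np.ndarray
    helix: np.ndarray
    offset: int = 1
    window: int = 21

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class CaMBDCandidate:
    """A called candidate CaM-binding window, ranked by mean window score."""

    region: SequenceRegion
    length: int
    score: float
    rank: int


def _window_means(values: np.ndarray, half: int) -> np.ndarray:
    """Mean of ``values`` over centered windows, truncated at the edges."""
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n, idx + half + 1)
    csum = np.concatenate(([0.0], np.cumsum(values)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def residue_scores(
    seq: ProteinSequence,
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    window: int = 21,
    his_positive: bool = False,
) -> ResidueScoreProfile:
    """Compute the 0-9 propensity profile of ``seq``.

    ``window`` must be odd; sequences shorter than the window are rejected
    (for peptides that short, scan motifs directly instead of profiling).
    Residues missing from a table (``X``) take the table minimum.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and positive, got {window}")
    n = len(seq)
    if n < window:
        raise ValueError(
            f"sequence {seq.id!r} ({n} aa) is shorter than the scoring window "
            f"({window}); run the motif scanner directly on short peptides"
        )
    half = window // 2
    kd = np.array([KYTE_DOOLITTLE.get(c, _KD_MIN) for c in seq.residues])
    cf = np.array([CHOU_FASMAN_HELIX.get(c, _CF_MIN) for c in seq.residues])
    his = 0.5 if his_positive else 0.0
    chg = np.array(
        [1.0 if c in "RK" else -1.0 if c in "DE" else his if c == "H" else 0.0
         for c in seq.residues]
    )
    h = (_window_means(kd, half) - _KD_MIN) / (_KD_MAX - _KD_MIN)
    f = (_window_means(cf, half) - _CF_MIN) / (_CF_MAX - _CF_MIN)
    c = np.clip(_window_means(chg, half), 0.0, 1.0)
    scores = SCORE_MAX * (weights.w_hydropathy * h + weights.w_charge * c + weights.w_helix * f)
    return ResidueScoreProfile(
        parent_id=seq.id,
        scores=scores,
        hydropathy=h,
        charge=c,
        helix=f,
        offset=seq.offset,
        window=window,
    )


def _runs_at_or_above(scores: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs (0-based inclusive) of positions scoring >= threshold."""
    above = scores >= threshold
    runs: list[tuple[int, int]] = []
    start: int | None = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(scores) - 1))
    return runs


def _best_window(
    scores: np.ndarray, a: int, b: int, min_len: int, max_len: int
) -> tuple[int, int] | None:
    """Best-scoring (sum) window of allowed length trimmed to / extended
    around the run ``[a, b]``.  Returns 0-based ``(start, length)``.

    Ties resolve to the shortest, then leftmost window.
    """
    n = len(scores)
    run_len = b - a + 1
    best: tuple[float, int, int] | None = None  # (sum, length, start)
    for length in range(min_len, max_len + 1):
        if length <= run_len:
            starts = range(a, b - length + 2)  # trim: window inside the run
        else:
            lo = max(0, b - length + 1)  # extend: window covers the run
            hi = min(a, n - length)
            if hi < lo:
                continue
            starts = range(lo, hi + 1)
        for w0 in starts:
            total = float(scores[w0 : w0 + length].sum())
            if best is None or total > best[0] + 1e-12:
                best = (total, length, w0)
    if best is None:
        return None
    return best[2], best[1]


def call_candidates(
    profile: ResidueScoreProfile,
    threshold: float = 4.5,
    min_len: int = 18,
    max_len: int = 22,
) -> list[CaMBDCandidate]:
    """Call non-overlapping candidate windows from a profile.

    Maximal runs of positions scoring at or above ``threshold`` are trimmed
    or extended to the best-scoring window of length in
    ``[min_len, max_len]`` (by sum of scores).  Overlaps are resolved in
    favour of the higher mean score (ties leftmost) and ranks are assigned
    by descending mean score.  An empty list is a valid result.
    """
    if not 0.0 <= threshold <= SCORE_MAX:
        raise ValueError(f"threshold must lie in [0, {SCORE_MAX}], got {threshold}")
    scores = profile.scores
    windows: list[tuple[int, int]] = []
    for a, b in _runs_at_or_above(scores, threshold):
        win = _best_window(scores, a, b, min_len, max_len)
        if win is not None and win not in windows:
            windows.append(win)
    scored = [
        (float(scores[w0 : w0 + length].mean()), w0, length) for w0, length in windows
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    kept: list[tuple[float, int, int]] = []
    for mean, w0, length in scored:
        if all(w0 + length <= k0 or k0 + klen <= w0 for _, k0, klen in kept):
            kept.append((mean, w0, length))
    return [
        CaMBDCandidate(
            region=SequenceRegion(
                profile.parent_id, profile.offset + w0, profile.offset + w0 + length - 1
            ),
            length=length,
            score=mean,
            rank=rank,
        )
        for rank, (mean, w0, length) in enumerate(kept, start=1)
    ]
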