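# Methods

## The model

Calmodulin (CaM) is a small calcium sensor that binds its targets in two
modes. Calcium-loaded CaM opens two hydrophobic pockets and grips an
~18–22-residue basic amphipathic segment of the target — the CaM-binding
domain (CaMBD) — whose defining feature is not sequence conservation but
the *spacing* of bulky hydrophobic "anchor" residues. Calcium-free CaM
(apo-CaM) instead engages IQ motifs. `camscan` treats both modes as pure
sequence problems:

1. **Anchor-spacing motif classes.** A class is named by the inclusive
   1-based positions of its anchors counted from the first anchor, so
   "1-5-10" means anchors at relative positions 1, 5 and 10 (string offsets
   0, 4, 9). Built-in classes: 1-10, 1-12, 1-14, 1-16 (two anchors) and
   1-5-10, 1-8-13, 1-8-14 (three anchors). A three-anchor class *refines*
   the two-anchor class with the same terminal spacing (1-5-10 → 1-10,
   1-8-14 → 1-14; 1-8-13 has no two-anchor parent among the built-ins).
   The convention is validated against the published anchor assignment for
   the CaMKII CaMBD: Leu299/Ile303/Leu308 = fingerprint "LIL" for its
   1-5-10 motif.

2. **Anchor sets.** The default `core` set is {F, I, L, V, W} — the five
   classically cited anchor hydrophobics. An opt-in `extended` set adds
   M and Y, because some published fingerprints (a Val–Tyr 1-12; a 1-12
   anchored on Met in calcineurin) are unreachable with the core set.
   `X` (unknown residue) never matches either set, nor any bracketed
   class of the IQ pattern.

3. **RAW vs CURATED reporting.** `enumerate_matches` is exhaustive: every
   (class, start) pair whose anchor positions all carry anchor-set letters
   yields exactly one match. Published motif lists, however, are visually
   curated, and curators report one anchor arrangement once, under its
   most specific class. `apply_subsumption` reproduces that convention: a
   two-anchor match whose terminal anchors coincide with those of a
   reported three-anchor match of its refining class is dropped. CURATED
   is the default reporting mode because it reproduces the printed counts
   on the reproducible fixtures (e.g. the TGM2 CaMBD1 raw scan finds
   {1-16, 1-12, 1-10, 1-5-10}; curation removes the 1-10 that is coterminal
   with the 1-5-10, leaving the published three). Nothing is ever added by
   curation, and nothing other than coterminal refined two-anchor matches
   is removed.

4. **IQ motifs.** The calcium-independent pattern
   `[FILV]Qxxx[RK]Gxxx[RK]xx[FILVWY]` (14 residues, `x` = any residue) is
   scanned with explicit per-window membership tests, reporting all — also
   overlapping — windows. The test suite checks the scanner against the
   stdlib regex engine as an independent oracle; the implementation
   deliberately shares no code with it.

5. **Fingerprints.** The ordered anchor letters of a match ("LIL", "ILF",
   …) form a per-class fingerprint. `fingerprint_table` /
   `compare_fingerprints` support the observation that different
   CaM-regulated kinases carry *disjoint* anchor arrangements in the same
   class — e.g. the 1-5-10 of CaMKII (LIL) shares nothing with the 1-5-10
   of GSK3β (ILF) — which is the premise for motif-targeted, kinase-specific
   inhibitor design.

## Coordinates

All library coordinates are 1-based and inclusive, matching residue labels
like "296RRKLKGAILTTMLATR311". A `ProteinSequence` carries the
parent-protein position of its first residue (`offset`, FASTA header token
`start=<n>`), so peptides keep native numbering. BED export alone converts
to 0-based half-open.

Where a printed peptide's start/end labels disagree with the printed string
length, the string and the printed start are treated as authoritative and
the end is recomputed. One exception is deliberate: the Tau R2 CaMBD
peptide is stored at canonical 2N4R start 287 (its printed start is 286,
kept in the annotation sidecar), because 287 simultaneously reconciles the
printed end label (304) and places the peptide's two AD-phosphorylated
serines at Ser289/Ser293, the positions used by the phosphosite table. All
motif counting is offset-independent.

## Fixture curation statuses

Each packaged peptide carries a status, tested as an invariant:
`clean` ⟺ the curated core-anchor scan reproduces the printed motif count
and class multiset exactly. Clean: Tau-R2, CaMKIIA, ROCK1-CaMBD1,
TGM2-CaMBD1. `label-inconsistent` marks Cdk5-CaMBD1, whose 25 printed
letters cannot fill an 18-residue span label (a probable duplication typo);
`curation-ambiguous` marks peptides whose printed motif lists are not
reproducible by exhaustive scanning with the stated anchor set (several
printed counts also disagree with their own class lists). Ambiguous
fixtures are packaged exactly as printed, flagged, and excluded from
count-based tests — no attempt is made to guess the original curators'
intent.

## The propensity predictor

The upstream step that proposes CaMBDs in full-length proteins was done in
the source literature with a third-party database whose scoring algorithm
is unpublished. `camscan.predictor` is therefore a documented, self-contained
stand-in, not a reimplementation, and it makes no claim of numerical
agreement with any external server; predicted windows should be confirmed
by the motif engine and ultimately by experiment.

Per residue, over a centered window (default 21, odd, truncated at the
termini), three classical signals are combined:

* **Hydropathy** — mean Kyte–Doolittle index, min–max normalized over the
  scale's theoretical range [−4.5, 4.5].
* **Net positive charge** — (#{R,K} − #{D,E}) / window size, clipped to
  [0, 1]. His counts 0 by default (+0.5 with `his_positive`), reflecting
  its mostly-neutral state at physiological pH.
* **Helix propensity** — mean Chou–Fasman P(α), min–max normalized over
  the table's range [0.57, 1.51].

The convex combination (default weights 0.4 / 0.4 / 0.2 — hydrophobicity
and basicity are the two defining properties of canonical CaMBDs, helicity
is supporting evidence) is rescaled to a 0–9 presentation. Residues absent
from a table (`X`) take the table minimum. Note one scale quirk: Trp is
*less* hydrophobic than Gly on the Kyte–Doolittle scale (−0.9 vs −0.4), so
monotonicity of the hydropathy component under substitution holds for
residues like Leu/Ile/Val/Phe but not for Trp.

Candidate calling takes maximal runs of positions at or above a threshold,
trims or extends each run to the best-scoring window (sum of scores) of
length 18–22, resolves overlaps in favour of the higher mean score (ties
leftmost) and ranks by descending mean score. The default reporting
threshold is 4.5, the midpoint of the 0–9 scale — a deliberately
conservative default for exploratory scans of real proteins.

## Synthetic data

`synth_protein` emulates a random protein background with an optionally
embedded basic amphipathic segment. The default background alphabet
excludes the core anchors *and* R/K, so embedded-signal tests have a
zero-false-positive floor for both the motif engine and the predictor's
charge component; a `realistic` mode draws uniformly from all 20 letters
for stress tests. The standard embedded signal is the Trp/Leu/Lys-rich
20-mer `KLWKKLLKLFSKLWKQIKKV`. Everything is driven by a single
`numpy.random.default_rng(seed)` stream, so output is deterministic per
seed.

What the generator does **not** emulate: real amino-acid composition
(default mode), autocorrelation along the chain, real CaMBD diversity
(non-canonical and IQ-variant domains), or any structural context. Passing
the recovery benchmark therefore shows that the score separates an ideal
basic amphipathic segment from a charge- and anchor-free background — it
says nothing about sensitivity or specificity on real proteomes.

**Recovery benchmark.** Over seeds 1–100 (background length 400, one
embedded 20-mer), the top-ranked candidate must overlap the embedded span
with Jaccard ≥ 0.5 in at least 90 runs — a design target for the
predictor, checked in the test suite. The benchmark calls candidates at
threshold 3.5: the closed-form expected profile is ≈2.2 on the anchor-free
background and peaks at ≈4.5 over the embedded segment (the composition of
both is known exactly), so 3.5 is the midpoint of that separation. The
conservative 4.5 reporting default sits on top of the expected peak itself
and is not a sensible detection threshold for this construction.

## Phosphosite table

The Tau table transcribes enzyme → site relationships in 2N4R (441-residue)
numbering: CaMKII and Cdk5 target sites, the calcineurin (CN) site-specific
percent decreases in phosphorylation (Ser262 63%, Ser396 78%, Ser199 38%,
Thr217 32%, Ser422 32%), the MARK4 hyperphosphorylation of Ser262, the two
AD-phosphorylated serines inside the Tau CaMBD (Ser289/Ser293), and the
prephosphorylation → hyperphosphorylation → dephosphorylation relationships
as a static `stage` tag (pre / hyper / dephos) on each row — an edge list,
not a kinetic model. Aggregate survey metadata (per-kinase counts of known
target sites; the 45 Ser / 35 Thr / 5 Tyr composition of Tau's 85 potential
sites) is kept separate from the transcribed rows, and per-enzyme row-count
checksums guard the transcription against drift. One transcribed oddity is
flagged but not corrected: "S369" is retained as printed with a note that
it may be a typo for Ser396. No isoform coordinate lifting is performed.

## Numerical and degenerate-input choices

* Sort order of matches: (span start, span length, class name); candidate
  ties: shortest window, then leftmost.
* Weights must be non-negative and sum to 1 within 1e-9.
* Sequences shorter than the scoring window are rejected with advice to
  scan motifs directly (the CLI warns and continues per record).
* Empty match lists, empty overlap queries and empty candidate lists are
  valid results, not errors; unknown enzymes return empty lookups.
* Floats serialize with 3 decimals; no locale-dependent formatting.

## Known limitations

* The predictor is a heuristic stand-in and is deliberately not validated
  against published CaMBD coordinates of real proteins.
* Only canonical anchor-spacing classes and the basic IQ pattern are
  scanned; non-canonical CaMBDs and IQ variants are out of scope.
* Binding affinity, calcium dependence beyond IQ flagging, and structural
  validation are out of scope.
* The curation-ambiguous fixtures document, rather than resolve, the
  inconsistencies in their printed annotations.
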