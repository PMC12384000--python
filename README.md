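# camscan

Calmodulin-binding domain (CaMBD) scanning for protein sequences.

Calcium-loaded calmodulin (CaM) binds most of its targets through an
~18–22-residue basic amphipathic segment defined not by conserved sequence
but by the spacing of bulky hydrophobic **anchor** residues
(F, I, L, V, W; optionally M, Y). Classes are named by the inclusive
anchor positions counted from the first anchor — 1-10, 1-12, 1-14, 1-16,
1-5-10, 1-8-13, 1-8-14 — and calcium-free CaM instead recognizes the IQ
motif `[FILV]Qxxx[RK]Gxxx[RK]xx[FILVWY]`. `camscan` is for people studying
CaM regulation of tauopathy-relevant enzymes (CaMKII, GSK3β, Cdk5, MARK4,
ROCK1, calcineurin, TGM2) and, more generally, anyone who wants exhaustive,
reproducible motif-level annotation of putative CaMBDs:

* **Motif engine** — exhaustive enumeration of anchor-spacing motifs, a
  curated mode that reports each anchor arrangement once under its most
  specific class (a 1-10 coterminal with a 1-5-10 is subsumed), IQ-motif
  scanning, and anchor-**fingerprint** extraction/comparison (the 1-5-10
  of CaMKII is Leu-Ile-Leu, "LIL"; the 1-5-10 of GSK3β is "ILF" — no
  overlap, the basis for kinase-specific targeting).
* **Propensity predictor** — a documented sliding-window heuristic
  (Kyte–Doolittle hydropathy + net positive charge + Chou–Fasman helix
  propensity, 0–9 scale) that proposes 18–22-residue candidate windows in
  full-length proteins.
* **Tau phosphosite table** — kinase/phosphatase → site relationships on
  Tau 2N4R, including calcineurin's site-specific dephosphorylation
  percentages, with overlap queries against any scanned region.
* **Fixtures & synthetic data** — twelve published CaMBD peptides with
  their printed annotations and curation statuses, plus a seeded generator
  of anchor-free backgrounds with embedded amphipathic signals.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Scan the packaged CaMKII CaMBD peptide (residues 296–311 of CaMKIIα):

```python
from camscan import get_fixture, scan_motifs, fingerprint_table

seq = get_fixture("CaMKIIA").sequence      # 296RRKLKGAILTTMLATR311
for m in scan_motifs(seq):                 # curated mode, core anchors
    print(m.class_name, m.anchor_positions, m.fingerprint)
print(fingerprint_table(scan_motifs(seq)))
```

prints

```
1-5-10 (299, 303, 308) LIL
{'1-5-10': {'LIL'}}
```

i.e. a single 1-5-10 motif anchored on Leu299/Ile303/Leu308. (The raw scan
also contains the coterminal 1-10 Leu299/Leu308; curation reports that
anchor arrangement once, under the more specific class.) The same from the
shell, plus the Tau phosphosites inside the Tau R2 CaMBD (2N4R residues
287–304):

```sh
$ camscan scan-motifs camkii.fasta
seq_id	motif_class	anchor_positions	fingerprint	span_start	span_end
CaMKIIA	1-5-10	299,303,308	LIL	299	308

$ camscan annotate 287-304
region	position	residue	enzyme	direction	effect_pct	stage	evidence
Tau:287-304	289	S	GSK3B	phosphorylates			tau-cambd-serines
Tau:287-304	289	S	MAPK	phosphorylates			tau-cambd-serines
Tau:287-304	293	S	GSK3B	phosphorylates			tau-cambd-serines
Tau:287-304	293	S	MAPK	phosphorylates			tau-cambd-serines
```

The two rows per serine say that Ser289 and Ser293 — the two
AD-phosphorylated serines that fall inside Tau's CaM-binding domain — are
substrates of GSK3β and p38 MAPK. `camscan predict-cambd <fasta>` runs the
propensity predictor on full-length records, and `--format bed` exports
motif spans in 0-based half-open BED coordinates.

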