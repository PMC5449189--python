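# Methods

This note documents the models, parameters and design choices behind
`sectat`, and what the synthetic-fixture tests do and do not demonstrate
about real data.

## Free energy of membrane insertion

Helix hydrophobicity is scored as the apparent free energy of
translocon-mediated membrane insertion (ΔG_app, kcal/mol). Each residue
contributes according to its type and its fractional position `p ∈ [-9, 9]`
across the helix:

* most residues: `f(p) = a0 · exp(-a1 p²)` — polar/charged residues are
  maximally costly at the helix centre and cheap near the ends;
* tryptophan and tyrosine additionally carry symmetric flanking Gaussians
  (`a2, a3, a4`) capturing their preference for the membrane interfaces.

The per-residue parameters are transcribed from the biological
hydrophobicity scale of translocon-mediated insertion (Hessa et al., Nature
2005; Nature 2007) and ship as a versioned YAML file
(`src/sectat/data/biological_scale.yaml`); any other scale in the same
format can be supplied with `--scale`. Two caveats are deliberate:

* the published ΔG predictor additionally applies a helix hydrophobic-moment
  term; `sectat` scores a span as a pure sum of position-weighted residue
  contributions (plus the optional length term), which keeps the score
  linear in residue substitutions — the property the what-if machinery and
  several invariant tests rely on;
* the helix-length correction is modelled as a smooth quadratic bowl
  `ΔG_len(L) = 0.0123 · (L - 21)²`, zero at the 21-residue reference length,
  and is **off by default** (scored spans and scanned windows use the raw
  positional sum).

Consequently absolute ΔG_app values may deviate from the cited prediction
server by a few tenths of a kcal/mol; sign and ordering relations (first
TMD strongly negative, Tat-dependent final TMD positive, leucine
substitutions lowering ΔG_app) are preserved, and the validation test
against published reference values documents any residual per-value
deviation when the reference sequences are available. The ambiguity residue
X contributes a configurable value (default 0) and is flagged; U is scored
as C; B/Z/J are rejected.

## Window scanning

TM helices are predicted by exhaustive enumeration: every window of length
19–23 is scored, and windows with ΔG_app ≤ 0 (the `threshold_dg` default)
enter a greedy non-overlapping selection by ascending ΔG, ties broken by
smaller start then shorter length — fully deterministic, and verified
against an independently coded brute-force oracle on random sequences. The
weakly hydrophobic Tat-dependent final TMD is *invisible* to this threshold
scan by design; the screen re-queries the scanner for the best window
downstream of the motif (any ΔG) before rejecting a candidate for lacking a
final TMD.

## Orientation

When no external prediction is imported, orientation follows the
positive-inside rule: with `P_even`/`P_odd` the K+R counts in even/odd-parity
loops (loop 0 = region before the first helix; the C-terminal tail is the
last loop; histidine is not counted),

```
n_in_score = (P_even + 1) / (P_even + P_odd + 2)
```

The single pseudocount per parity keeps the score defined for chargeless
proteins and away from certainty for sparse evidence. N-in is called at
score ≥ 0.5; exact ties go to N-in and are flagged. This charge-bias score
is a deliberately simple, documented stand-in for a full HMM posterior; the
screen thresholds (0.9 / 0.5) apply to whichever score is present, and an
imported prediction (with its probability, when recorded) always takes
precedence. Note the stand-in is conservative: reaching 0.9 requires at
least nine net cytoplasmic charges, so proteins with heavily charged
periplasmic tails are best screened with an imported topology.

## The screen

Classification rules, applied per RR motif in ascending position (first
qualifying motif wins; all motifs are echoed):

| parameter | default | meaning |
|---|---|---|
| `n_in_threshold` | 0.9 | N-in score must exceed this for `N-in-even` |
| `n_out_threshold` | 0.5 | N-in score must be below this for `N-out-odd` |
| `max_gap` | 30 aa | bound on residues between the RR pair and the final TMD start (the motif "directly precedes" the final TMD in all known families; gap 6 in the Rieske reference) |
| `rescue_weak_final_tmd` | on | sub-threshold re-query downstream of the motif |
| `allow_zero_before` | off | admit zero upstream TMDs (formally even) |

Scores in (0.5, 0.9] match neither class and are reported as reason
`orientation` — the unclassified band is intentional, mirroring the
original genome screen rather than inventing a rule for it. `N-in-even`
additionally requires ≥ 2 upstream TMDs: the screen targets internal signal
anchors, and the known families have 2 or 4.

Boundary semantics: a motif strictly interior to a helix is skipped; a
predicted helix that straddles the arginine pair and extends downstream is
taken to be the TMD the motif precedes (gap 0) — this matters when the
final TMD's hydrophobic flank begins at the second arginine — while a helix
ending at the pair counts upstream.

## Sec-release features

For classified candidates: final vs first TMD ΔG_app (reported as a raw
difference, no cutoff, since none is established); K+R in the
`window_len = 20` residues after the final TMD (`sec_avoidance` at ≥ 2,
counting strictly after the helix end, truncated at the sequence end); loop
length between the upstream TMD end and the RR position (`short_loop` below
`min_loop = 8`, a flag only — the minimum was measured for Tat recognition,
not as a screening criterion). The 20-residue window reflects the span over
which C-terminal positive charges are known to act as Sec-avoidance
determinants; both parameters are configurable.

Leucine what-ifs rank in-span residues by helix-centre contribution
(least hydrophobic first, ties N-terminal first) and report the ΔG_app
reduction for the 1..n best substitution sets, each rescored over the same
span and over a re-scanned best window (the literature does not state which
convention its variant values used, so both are reported).

## Synthetic fixtures

`sectat.synth` builds proteins to order: TMDs are hill-climbed over a
charge-free hydrophobic alphabet until their ΔG_app is within ±0.2 kcal/mol
of target (bounded iterations, error on failure); loops come from a polar
alphabet with a controlled number of K residues on the designated membrane
side; the RR motif is planted in its full consensus context (`SRRGFLK`) at
a chosen gap before a chosen TMD. Two construction details keep the ground
truth well defined: two strong hydrophobics are pinned at each TMD end, and
a TMD is rebuilt (bounded retries) if the assembled sequence's locally
best-scoring window drifts more than ~2 residues from the constructed span
— a window scanner's "true span" is only meaningful when the span is its
own local optimum. Everything derives from one integer seed (recorded in
the FASTA header) via a single RNG stream.

Stock architectures emulate the four characterized dual-targeted families —
2+1-TMD N-in (Rieske-like), two 4+1-TMD N-in variants (heme/MoCo-like and
polyferredoxin-like) and 3+1-TMD N-out (YkuE-like) — plus negatives with no
RR pair or with two TMDs downstream of it. Defaults: 21-residue TMDs, Sec
TMD targets between −1.6 and −2.2 kcal/mol, final-TMD targets +0.4 to +1.0,
4 K per cytoplasmic loop, gaps of 6–8 residues between motif and final TMD
— values chosen once to represent well-separated instances of the published
architectures.

What passing on fixtures does **not** show: real proteins have hydrophobic
loops, marginal TMDs, signal peptides and charged periplasmic domains that
the polar-loop/greasy-helix construction never produces, so fixture recall
says nothing about scan accuracy on borderline natural sequences; the
charge-bias orientation score is exact on fixtures by construction but only
approximates an HMM posterior on real data. Fixture panels exercise the
combinatorial logic of the screen, not the hardness of topology prediction.

## Problem sizes

The test suite and the acceptance script use, as the package's own choice
of representative scale: 200 random sequences (≤ 200 aa) for
scanner/brute-force equivalence, 100 constructed topologies for the
orientation antisymmetry property, a 150-fixture panel (25 per architecture)
for screen recall and false positives, and 4 × 5 family fixtures for the
feature-flag signature. All are regenerated from seeds at run time; no
fixture data is stored.

## Known limitations

* No signal-peptide vs signal-anchor discrimination; cleavable Tat signal
  peptides of soluble substrates are outside the screen's classes.
* The scanner does not reproduce multi-segment decomposition modes of the
  cited ΔG server, and turn/hinge free-energy terms are not modelled.
* Full parity with the TATFind motif rules is not claimed; the
  adjacency-to-TMD requirement of the screen plays the equivalent role.
* Orientation from charge bias degrades when basic residues concentrate in
  periplasmic loops (see above); import a topology prediction in that case.
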